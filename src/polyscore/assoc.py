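"""Hardy-Weinberg screening and the four-model case-control association battery.

For each biallelic SNP the case and control genotype counts are compared
under four contrasts:

* ``allele``     — 2x2 table of allele counts (2N chromosomes per group);
* ``codominant`` — 2x3 table of the three genotypes 1/1, 1/2, 2/2;
* ``dominant``   — 2x2 table of 1/1 vs 1/2 + 2/2 (carrier of allele 2);
* ``recessive``  — 2x2 table of 1/1 + 1/2 vs 2/2.

Tests are Pearson chi-square without continuity correction, falling back to
Fisher's exact test for 2x2 tables with any expected cell below 5 (Cochran's
rule).  SNPs departing from Hardy-Weinberg equilibrium (p < 0.05 in either
group) are screened out before testing.  The family-wise Bonferroni
threshold is alpha / (number of SNPs x number of models).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GenotypeCounts, GenotypeMatrix, SNPPanel

logger = logging.getLogger(__name__)

MODELS = ("allele", "codominant", "dominant", "recessive")

#: HWE screening threshold (per group).
HWE_ALPHA = 0.05

#: Minimum expected cell count before a 2x2 table is sent to Fisher's exact test.
EXPECTED_CELL_MIN = 5.0


class DegenerateTableError(ValueError):
    """A contingency table has fewer than two non-empty columns."""


@dataclass(frozen=True)
class HWETest:
    """One-degree-of-freedom chi-square test against Hardy-Weinberg proportions."""

    statistic: float
    p: float
    monomorphic: bool = False


@dataclass(frozen=True)
class ModelTest:
    """Result of one genetic-model contrast.

    ``statistic`` is always the Pearson chi-square of the (column-reduced)
    table; when ``method == "fisher_exact"`` the p-value comes from the exact
    test while the statistic is retained as a descriptive effect measure.
    A table that collapses to a single non-empty column yields
    ``method == "degenerate"`` with statistic 0 and p 1.
    """

    model: str
    statistic: float
    df: int
    p: float
    method: str


@dataclass
class AssociationResult:
    rsid: str
    hwe_case: HWETest
    hwe_control: HWETest
    hwe_excluded: bool
    tests: dict[str, ModelTest] = field(default_factory=dict)
    favorable_freq_case: float = float("nan")
    favorable_freq_control: float = float("nan")
    freq_diff: float = float("nan")
    nominal: bool = False
    survives_bonferroni: bool = False
    bonferroni_models: list[str] = field(default_factory=list)

    @property
    def freq_diff_printed(self) -> float:
        """Difference of the two frequencies after per-group rounding to 0.1%.

        Published tables round each group's percentage to one decimal before
        subtracting; this mirrors that convention (on the proportion scale).
        """
        c = round(100 * self.favorable_freq_case, 1)
        k = round(100 * self.favorable_freq_control, 1)
        return round((c - k) / 100, 3)


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------

def hwe_chi2(counts: GenotypeCounts | tuple[int, int, int]) -> HWETest:
    """Pearson chi-square (1 df) of genotype counts against HWE expectations.

    Expected counts are p^2 N, 2pq N, q^2 N with q the sample allele-2
    frequency.  A monomorphic SNP (one allele absent) is in trivial
    equilibrium: statistic 0, p 1, flagged.
    """
    if not isinstance(counts, GenotypeCounts):
        counts = GenotypeCounts(*counts)
    n = counts.n_genotyped
    if n == 0:
        raise ValueError("no genotyped samples")
    q = counts.allele2_freq
    if q == 0.0 or q == 1.0:
        return HWETest(statistic=0.0, p=1.0, monomorphic=True)
    p = 1.0 - q
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    observed = counts.as_array()
    statistic = float(((observed - expected) ** 2 / expected).sum())
    return HWETest(statistic=statistic, p=float(stats.chi2.sf(statistic, df=1)))


def build_model_tables(
    case: GenotypeCounts, control: GenotypeCounts
) -> dict[str, np.ndarray]:
    """Contingency tables for the four genetic models (rows: case, control)."""
    if case.n_genotyped == 0 or control.n_genotyped == 0:
        raise ValueError("both groups must have genotyped samples")
    return {
        "allele": np.array([
            [case.allele2_count, case.n_alleles - case.allele2_count],
            [control.allele2_count, control.n_alleles - control.allele2_count],
        ]),
        "codominant": np.array([case.as_array(), control.as_array()]),
        "dominant": np.array([
            [case.n11, case.n12 + case.n22],
            [control.n11, control.n12 + control.n22],
        ]),
        "recessive": np.array([
            [case.n11 + case.n12, case.n22],
            [control.n11 + control.n12, control.n22],
        ]),
    }


def expected_cells(table: np.ndarray) -> np.ndarray:
    """Expected counts under independence for a contingency table."""
    t = np.asarray(table, dtype=float)
    return np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()


def _reduce_columns(table: np.ndarray) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    return t[:, t.sum(axis=0) > 0]


def pearson_chi2(table, model: str = "") -> ModelTest:
    """Pearson chi-square test without continuity correction.

    Empty columns (zero total in both groups) are removed first and the
    degrees of freedom adjusted; a table left with fewer than two columns
    raises :class:`DegenerateTableError`.
    """
    t = _reduce_columns(table)
    if t.shape[1] < 2:
        raise DegenerateTableError("degenerate table: fewer than 2 non-empty columns")
    statistic, p, df, _ = stats.chi2_contingency(t, correction=False)
    return ModelTest(
        model=model, statistic=float(statistic), df=int(df), p=float(p),
        method="pearson_chi2",
    )


def fisher_exact(table, model: str = "") -> ModelTest:
    """Two-sided Fisher exact test of a 2x2 table.

    The p-value is the sum of hypergeometric probabilities of all tables with
    the observed margins that are no more probable than the observed table.
    The reported statistic is the table's Pearson chi-square (descriptive).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"fisher_exact requires a 2x2 table, got {t.shape}")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    try:
        statistic = pearson_chi2(t).statistic
    except DegenerateTableError:
        statistic = 0.0
    return ModelTest(model=model, statistic=statistic, df=1, p=float(p),
                     method="fisher_exact")


def bonferroni_threshold(alpha: float, n_snps: int, n_models: int) -> float:
    """Family-wise significance threshold alpha / (SNPs x models)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_snps <= 0 or n_models <= 0:
        raise ValueError("n_snps and n_models must be positive")
    return alpha / (n_snps * n_models)


# ---------------------------------------------------------------------------
# Per-SNP battery
# ---------------------------------------------------------------------------

def model_tests(
    case: GenotypeCounts, control: GenotypeCounts, rsid: str = ""
) -> dict[str, ModelTest]:
    """Run the four model contrasts, choosing chi-square or Fisher per table.

    Fisher's exact test is used for 2x2 tables with any expected cell below
    5; the 2x3 codominant table always uses chi-square after empty-column
    removal.  Fully degenerate tables are recorded with p = 1.
    """
    tables = build_model_tables(case, control)
    out: dict[str, ModelTest] = {}
    for model, table in tables.items():
        try:
            if (table.sum(axis=0) > 0).sum() < 2:
                raise DegenerateTableError("fewer than 2 non-empty columns")
            if table.shape == (2, 2) and (expected_cells(table) < EXPECTED_CELL_MIN).any():
                logger.info("%s %s: expected cell < %g, Fisher exact fallback",
                            rsid, model, EXPECTED_CELL_MIN)
                out[model] = fisher_exact(table, model=model)
            else:
                out[model] = pearson_chi2(table, model=model)
        except DegenerateTableError:
            logger.info("%s %s: degenerate table, recorded as p=1", rsid, model)
            out[model] = ModelTest(model=model, statistic=0.0, df=0, p=1.0,
                                   method="degenerate")
    return out


def association_from_counts(
    rsid: str,
    case: GenotypeCounts,
    control: GenotypeCounts,
    favorable_is_allele2: bool,
    alpha: float = 0.05,
    bonferroni_p: float | None = None,
) -> AssociationResult:
    """Full single-SNP battery from genotype counts (HWE screen + 4 models)."""
    hwe_case = hwe_chi2(case)
    hwe_control = hwe_chi2(control)
    excluded = hwe_case.p < HWE_ALPHA or hwe_control.p < HWE_ALPHA
    result = AssociationResult(
        rsid=rsid, hwe_case=hwe_case, hwe_control=hwe_control,
        hwe_excluded=excluded,
        favorable_freq_case=case.favorable_freq(favorable_is_allele2),
        favorable_freq_control=control.favorable_freq(favorable_is_allele2),
    )
    result.freq_diff = result.favorable_freq_case - result.favorable_freq_control
    if excluded:
        logger.info(
            "%s excluded from association tests: HWE p (case %.4g, control %.4g) < %g",
            rsid, hwe_case.p, hwe_control.p, HWE_ALPHA,
        )
        return result
    result.tests = model_tests(case, control, rsid=rsid)
    result.nominal = any(t.p < alpha for t in result.tests.values())
    if bonferroni_p is not None:
        result.bonferroni_models = [
            m for m, t in result.tests.items() if t.p < bonferroni_p
        ]
        result.survives_bonferroni = bool(result.bonferroni_models)
    return result


def run_association(
    matrix: GenotypeMatrix,
    panel: SNPPanel,
    alpha: float = 0.05,
    n_models: int = 4,
    bonferroni_snps: int | None = None,
) -> list[AssociationResult]:
    """Run the battery over every panel SNP of a labeled genotype matrix.

    ``bonferroni_snps`` sets the SNP count in the Bonferroni family (the
    number of candidate SNPs genotyped, which may exceed the panel actually
    scored); it defaults to the panel size.
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    for group in ("case", "control"):
        if matrix.group_size(group) == 0:
            raise ValueError(f"matrix has no {group} samples")
    threshold = bonferroni_threshold(
        alpha, bonferroni_snps if bonferroni_snps is not None else len(panel), n_models
    )
    results = []
    for snp in panel:
        results.append(
            association_from_counts(
                snp.rsid,
                matrix.genotype_counts(snp.rsid, "case"),
                matrix.genotype_counts(snp.rsid, "control"),
                snp.favorable_is_allele2,
                alpha=alpha,
                bonferroni_p=threshold,
            )
        )
    return results


def association_table(results: list[AssociationResult], panel: SNPPanel) -> pd.DataFrame:
    """Flatten association results into a report table (one row per SNP)."""
    rows = []
    for r in results:
        snp = panel.get(r.rsid)
        row: dict = {
            "rsid": r.rsid,
            "gene": snp.gene,
            "favorable_allele": snp.favorable_allele,
            "favorable_pct_case": round(100 * r.favorable_freq_case, 1),
            "favorable_pct_control": round(100 * r.favorable_freq_control, 1),
            "freq_diff": r.freq_diff,
            "hwe_p_case": r.hwe_case.p,
            "hwe_p_control": r.hwe_control.p,
            "hwe_excluded": r.hwe_excluded,
            "nominal": r.nominal,
            "survives_bonferroni": r.survives_bonferroni,
        }
        for m in MODELS:
            t = r.tests.get(m)
            row[f"{m}_statistic"] = t.statistic if t else float("nan")
            row[f"{m}_df"] = t.df if t else 0
            row[f"{m}_p"] = t.p if t else float("nan")
            row[f"{m}_method"] = t.method if t else ""
        rows.append(row)
    return pd.DataFrame(rows)
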