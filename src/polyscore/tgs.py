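"""Total genotype score (TGS): per-sample scoring, descriptives and closed-form moments.

Each SNP contributes 2 points for the favorable homozygote, 1 for the
heterozygote and 0 for the unfavorable homozygote.  The sum over K SNPs is
normalized to a 0-100 scale by dividing by the maximum possible score (2K)
and multiplying by 100, so the score is 100 x (favorable alleles) / (2K).
Greater values indicate a more favorable polygenic profile.  All SNPs carry
equal weight by construction.

Samples with missing genotypes are normalized by the number of SNPs actually
observed (the maximum score they could have attained); samples missing more
than 20% of the panel are flagged.

Under SNP independence the score has closed-form moments: with p_k the
favorable-allele frequency at SNP k, the mean is (100/K) * sum(p_k) and the
variance follows from the per-SNP genotype distribution.  These are used to
cross-check cohort summaries against published frequency tables.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenotypeMatrix, SNPPanel

logger = logging.getLogger(__name__)

#: Fraction of missing panel SNPs above which a sample is flagged in reports.
MISSING_FLAG_FRACTION = 0.2


def score_from_allele_count(favorable_alleles: int, n_snps: int) -> float:
    """Normalized TGS for a given favorable-allele count over ``n_snps`` SNPs."""
    if n_snps <= 0:
        raise ValueError("n_snps must be positive")
    if not 0 <= favorable_alleles <= 2 * n_snps:
        raise ValueError(
            f"allele count {favorable_alleles} outside [0, {2 * n_snps}]"
        )
    return 100.0 * favorable_alleles / (2 * n_snps)


def favorable_dose(dose_allele2, favorable_is_allele2):
    """Convert allele-2 dose codes to favorable-allele dose codes.

    Identity when the favorable allele is allele 2, else ``2 - dose``.
    Missing values (NaN) pass through.  Vectorized over arrays.
    """
    d = np.asarray(dose_allele2, dtype=float)
    out = np.where(np.asarray(favorable_is_allele2, dtype=bool), d, 2.0 - d)
    return out if out.ndim else float(out)


def tgs_scores(matrix: GenotypeMatrix, panel: SNPPanel) -> pd.DataFrame:
    """Per-sample TGS over a panel.

    Returns a DataFrame with columns sample_id, label (if present),
    n_observed, allele_count, score, flagged_missing.  Scores keep full
    precision; round to one decimal for display.  A sample with every panel
    genotype missing raises.
    """
    cols = [matrix.column(s.rsid) for s in panel]
    doses = np.column_stack(cols)
    fav = favorable_dose(doses, panel.favorable_is_allele2)
    observed = np.isfinite(fav)
    n_obs = observed.sum(axis=1)
    if (n_obs == 0).any():
        bad = [matrix.sample_ids[i] for i in np.where(n_obs == 0)[0]]
        raise ValueError(f"samples with all panel genotypes missing: {bad}")
    counts = np.nansum(fav, axis=1).astype(int)
    scores = 100.0 * counts / (2 * n_obs)
    flagged = (1 - n_obs / len(panel)) > MISSING_FLAG_FRACTION
    if flagged.any():
        logger.warning("%d samples missing >%d%% of the panel",
                       int(flagged.sum()), int(100 * MISSING_FLAG_FRACTION))
    out = pd.DataFrame({
        "sample_id": matrix.sample_ids,
        "n_observed": n_obs,
        "allele_count": counts,
        "score": scores,
        "flagged_missing": flagged,
    })
    if matrix.labels is not None:
        out.insert(1, "label", matrix.labels)
    return out


# ---------------------------------------------------------------------------
# Cohort descriptives
# ---------------------------------------------------------------------------

@dataclass
class TGSSummary:
    """Distribution summary of a group's scores, one published table row each.

    Skewness is the adjusted Fisher-Pearson coefficient
    G1 = g1 * sqrt(n(n-1)) / (n-2); kurtosis is bias-corrected excess
    kurtosis G2.  Standard errors use the classical normal-theory formulas
    SE_skew = sqrt(6n(n-1) / ((n-2)(n+1)(n+3))) and
    SE_kurt = 2 SE_skew sqrt((n^2-1) / ((n-3)(n+5))).
    For n < 4 (or zero variance) the shape moments are undefined and
    reported as None with ``moments_defined`` False.
    """

    group: str
    n: int
    min_score: float
    min_alleles: int
    max_score: float
    max_alleles: int
    mode_score: float
    mode_alleles: int
    mean: float
    sd: float
    skewness: float | None
    se_skewness: float | None
    kurtosis: float | None
    se_kurtosis: float | None
    moments_defined: bool

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _mode_smallest(values: np.ndarray) -> int:
    uniq, counts = np.unique(values, return_counts=True)
    top = uniq[counts == counts.max()]
    if top.size > 1:
        logger.info("mode tie among allele counts %s; reporting smallest", top.tolist())
    return int(top.min())


def se_skewness(n: int) -> float:
    return float(np.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3))))


def se_kurtosis(n: int) -> float:
    return float(2.0 * se_skewness(n) * np.sqrt((n * n - 1.0) / ((n - 3) * (n + 5))))


def cohort_summary(scores, allele_counts, group: str = "") -> TGSSummary:
    """Descriptive summary of one group's TGS distribution.

    ``allele_counts`` carries the favorable-allele counts matching ``scores``
    (the published convention reports extrema and mode on both scales).  SD
    uses the n-1 denominator.
    """
    s = np.asarray(scores, dtype=float)
    a = np.asarray(allele_counts, dtype=int)
    if s.size == 0 or s.size != a.size:
        raise ValueError("scores and allele_counts must be equal-length, non-empty")
    n = s.size
    i_min, i_max = int(np.argmin(s)), int(np.argmax(s))
    mode_a = _mode_smallest(a)
    # score corresponding to the modal allele count (n_observed assumed shared)
    mode_s = float(s[a == mode_a].min())
    mean = float(s.mean())
    sd = float(s.std(ddof=1)) if n > 1 else 0.0

    defined = n >= 4 and sd > 0
    skew = kurt = ses = sek = None
    if defined:
        m2 = float(((s - mean) ** 2).mean())
        m3 = float(((s - mean) ** 3).mean())
        m4 = float(((s - mean) ** 4).mean())
        g1 = m3 / m2 ** 1.5
        g2 = m4 / m2 ** 2 - 3.0
        skew = g1 * np.sqrt(n * (n - 1)) / (n - 2)
        kurt = ((n + 1) * g2 + 6.0) * (n - 1) / ((n - 2) * (n - 3))
        ses = se_skewness(n)
        sek = se_kurtosis(n)
    elif n >= 4 and sd == 0:
        logger.info("constant score vector in group %r; shape moments undefined", group)

    return TGSSummary(
        group=group, n=n,
        min_score=float(s[i_min]), min_alleles=int(a[i_min]),
        max_score=float(s[i_max]), max_alleles=int(a[i_max]),
        mode_score=mode_s, mode_alleles=mode_a,
        mean=mean, sd=sd,
        skewness=float(skew) if skew is not None else None,
        se_skewness=float(ses) if ses is not None else None,
        kurtosis=float(kurt) if kurt is not None else None,
        se_kurtosis=float(sek) if sek is not None else None,
        moments_defined=defined,
    )


def group_summaries(score_table: pd.DataFrame) -> dict[str, TGSSummary]:
    """Cohort summaries keyed by group label from a :func:`tgs_scores` table."""
    if "label" not in score_table.columns:
        raise ValueError("score table has no group labels")
    return {
        label: cohort_summary(sub["score"], sub["allele_count"], group=label)
        for label, sub in score_table.groupby("label", sort=True)
    }


# ---------------------------------------------------------------------------
# Closed-form moments under SNP independence
# ---------------------------------------------------------------------------

def expected_moments(prob_triples, panel: SNPPanel) -> tuple[float, float]:
    """Expected mean and SD of the TGS from per-SNP genotype probabilities.

    ``prob_triples`` is a K x 3 array of (P11, P12, P22) in allele-1/2
    orientation, one row per panel SNP; SNPs are treated as independent.
    The mean depends only on the favorable-allele frequencies; the SD sums
    the per-SNP favorable-dose variances.
    """
    t = np.asarray(prob_triples, dtype=float)
    if t.shape != (len(panel), 3):
        raise ValueError(f"expected {len(panel)} probability triples, got {t.shape}")
    if (t < 0).any() or not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("each probability triple must be non-negative and sum to 1")
    fav2 = panel.favorable_is_allele2
    p_hom_fav = np.where(fav2, t[:, 2], t[:, 0])
    p_het = t[:, 1]
    k = len(panel)
    mean_dose = 2 * p_hom_fav + p_het
    mean = 100.0 * mean_dose.sum() / (2 * k)
    var = (4 * p_hom_fav + p_het) - mean_dose ** 2
    sd = 100.0 * np.sqrt(var.sum()) / (2 * k)
    return float(mean), float(sd)


def expected_mean_from_frequencies(favorable_freqs) -> float:
    """Expected mean TGS from favorable-allele frequencies (proportions).

    Equals (100/K) * sum(p_k); the genotype distribution beyond the allele
    frequency does not affect the mean.
    """
    f = np.asarray(favorable_freqs, dtype=float)
    if f.size == 0 or (f < 0).any() or (f > 1).any():
        raise ValueError("frequencies must be proportions in [0, 1]")
    return float(100.0 * f.mean())
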