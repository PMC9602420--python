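"""SNP panel and genotype data model with TSV/VCF input and count reconstruction.

The central objects are :class:`SNPPanel` (an ordered set of biallelic SNP
definitions with a *favorable allele* orientation) and
:class:`GenotypeMatrix` (individuals x SNPs dose codes, where a dose is the
number of copies of allele 2 — the minor allele — carried by a sample).

Two packaged fixtures ship with the library:

* ``walkpace15.tsv`` — the 15-SNP high-speed-walking panel, with the
  per-group favorable-allele percentages observed in the sprinter study;
* ``table2_distributions.tsv`` — the per-group genotype distributions
  (percent of 1/1, 1/2 and 2/2 carriers) for the same 15 SNPs.

Published tables report percentages, not counts; :func:`counts_from_percentages`
reconstructs the underlying integer genotype counts so that exact tests can
be re-run from the printed values alone.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"
GROUPS = (CASE, CONTROL)

#: Study group sizes: 137 elite sprinters, 126 controls.
N_SPRINTERS = 137
N_CONTROLS = 126

#: Missing-dose sentinel in dose matrices (stored as float NaN).
MISSING = float("nan")


class PanelError(ValueError):
    """A panel definition violates its invariants."""


class GenotypeParseError(ValueError):
    """A genotype file could not be parsed."""


# ---------------------------------------------------------------------------
# Panel definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SNPDefinition:
    """A biallelic SNP with a frozen major/minor and favorable-allele orientation.

    ``allele1`` is the major (most frequent) allele, ``allele2`` the minor
    one.  ``favorable_allele`` is the allele associated with the phenotype of
    interest (here: brisk walking pace / sprinter status) and must be one of
    the two alleles.
    """

    rsid: str
    chrom: str
    gene: str
    allele1: str
    allele2: str
    favorable_allele: str
    consequence: str = ""

    def __post_init__(self) -> None:
        if self.allele1 == self.allele2:
            raise PanelError(f"{self.rsid}: allele1 and allele2 must differ")
        if self.favorable_allele not in (self.allele1, self.allele2):
            raise PanelError(
                f"{self.rsid}: favorable allele {self.favorable_allele!r} is "
                f"neither allele1 ({self.allele1!r}) nor allele2 ({self.allele2!r})"
            )

    @property
    def favorable_is_allele2(self) -> bool:
        return self.favorable_allele == self.allele2


@dataclass(frozen=True)
class SNPPanel:
    """An ordered, rsid-unique collection of SNP definitions."""

    snps: tuple[SNPDefinition, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.snps:
            raise PanelError("panel must contain at least one SNP")
        rsids = [s.rsid for s in self.snps]
        dupes = {r for r in rsids if rsids.count(r) > 1}
        if dupes:
            raise PanelError(f"duplicate rsids in panel: {sorted(dupes)}")
        object.__setattr__(self, "_index", {r: i for i, r in enumerate(rsids)})

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self) -> Iterator[SNPDefinition]:
        return iter(self.snps)

    @property
    def rsids(self) -> list[str]:
        return [s.rsid for s in self.snps]

    def index(self, rsid: str) -> int:
        try:
            return self._index[rsid]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"rsid {rsid!r} not in panel {self.name!r}") from None

    def get(self, rsid: str) -> SNPDefinition:
        return self.snps[self.index(rsid)]

    def subset(self, rsids: Sequence[str], name: str | None = None) -> "SNPPanel":
        return SNPPanel(
            tuple(self.get(r) for r in rsids),
            name=name if name is not None else self.name,
        )

    @property
    def favorable_is_allele2(self) -> np.ndarray:
        """Boolean vector, one entry per SNP, in panel order."""
        return np.array([s.favorable_is_allele2 for s in self.snps], dtype=bool)


_PANEL_COLUMNS = ["rsid", "chrom", "gene", "allele1", "allele2", "favorable_allele"]


def read_panel(path: str | Path, name: str | None = None) -> SNPPanel:
    """Read a panel from a TSV with columns rsid/chrom/gene/allele1/allele2/favorable_allele.

    Extra columns (e.g. observed allele frequencies) are ignored here and may
    be retrieved with :func:`pandas.read_csv` directly.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelError(f"panel file {path}: missing columns {missing}")
    snps = tuple(
        SNPDefinition(
            rsid=row.rsid,
            chrom=row.chrom,
            gene=row.gene,
            allele1=row.allele1,
            allele2=row.allele2,
            favorable_allele=row.favorable_allele,
            consequence=getattr(row, "consequence", "") or "",
        )
        for row in df.itertuples(index=False)
    )
    return SNPPanel(snps, name=name if name is not None else Path(path).stem)


def write_panel(panel: SNPPanel, path: str | Path) -> None:
    rows = [
        {
            "rsid": s.rsid, "chrom": s.chrom, "gene": s.gene,
            "allele1": s.allele1, "allele2": s.allele2,
            "favorable_allele": s.favorable_allele, "consequence": s.consequence,
        }
        for s in panel
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genotype counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeCounts:
    """Counts of the three genotypes 1/1, 1/2 and 2/2 in one group."""

    n11: int
    n12: int
    n22: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        if min(self.n11, self.n12, self.n22, self.n_missing) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n_genotyped(self) -> int:
        return self.n11 + self.n12 + self.n22

    @property
    def allele2_count(self) -> int:
        return self.n12 + 2 * self.n22

    @property
    def n_alleles(self) -> int:
        return 2 * self.n_genotyped

    @property
    def allele2_freq(self) -> float:
        if self.n_genotyped == 0:
            raise ValueError("no genotyped samples")
        return self.allele2_count / self.n_alleles

    def favorable_freq(self, favorable_is_allele2: bool) -> float:
        q = self.allele2_freq
        return q if favorable_is_allele2 else 1.0 - q

    def as_array(self) -> np.ndarray:
        return np.array([self.n11, self.n12, self.n22], dtype=int)


def counts_from_percentages(
    percentages: Sequence[float], n: int, tol: float = 0.5
) -> np.ndarray:
    """Reconstruct integer counts from a printed percentage breakdown of ``n``.

    Each count is ``round(pct / 100 * n)`` with ties rounded half away from
    zero (the convention used by the printed tables).  If the rounded counts
    miss ``n`` by one — which can happen when a printed percentage itself
    carries a typo — the cell whose rounding is least justified is adjusted
    (largest-remainder repair) and the repair is logged.  A discrepancy of
    more than one is treated as an inconsistent table and raises.
    """
    if n <= 0:
        raise ValueError("group size must be positive")
    pct = np.asarray(percentages, dtype=float)
    if pct.ndim != 1 or pct.size < 2:
        raise ValueError("percentages must be a 1-D vector of length >= 2")
    if abs(pct.sum() - 100.0) > tol:
        raise ValueError(
            f"percentages sum to {pct.sum():.2f}, expected 100 +/- {tol}"
        )
    exact = pct / 100.0 * n
    counts = np.floor(exact + 0.5).astype(int)  # half away from zero (values >= 0)
    diff = n - int(counts.sum())
    if diff != 0:
        if abs(diff) > 1:
            raise ValueError(
                f"reconstructed counts sum to {counts.sum()}, differs from n={n} by {diff}"
            )
        frac = exact - np.floor(exact)
        if diff == -1:
            # one cell too many was rounded up: take back the weakest round-up
            rounded_up = counts > np.floor(exact)
            cand = np.where(rounded_up, frac, np.inf)
            i = int(np.argmin(cand))
            counts[i] -= 1
        else:
            # one cell short: grant the strongest unrewarded fraction
            rounded_down = counts == np.floor(exact)
            cand = np.where(rounded_down, frac, -np.inf)
            i = int(np.argmax(cand))
            counts[i] += 1
        logger.info(
            "counts_from_percentages: adjusted cell %d by %+d to match n=%d "
            "(percentages %s)", i, diff, n, pct.tolist(),
        )
    return counts


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Samples x SNPs matrix of allele-2 dose codes (0/1/2, NaN = missing).

    ``labels`` assigns each sample to ``"case"`` or ``"control"``; it may be
    ``None`` for unlabeled cohorts (e.g. a quantitative-trait study).
    """

    sample_ids: list[str]
    rsids: list[str]
    doses: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        if self.doses.shape != (len(self.sample_ids), len(self.rsids)):
            raise ValueError(
                f"dose matrix shape {self.doses.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.rsids)} SNPs"
            )
        finite = self.doses[np.isfinite(self.doses)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing doses must be 0, 1 or 2")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape != (len(self.sample_ids),):
                raise ValueError("labels length does not match sample count")
            bad = set(self.labels) - set(GROUPS)
            if bad:
                raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.rsids)

    def column(self, rsid: str) -> np.ndarray:
        try:
            j = self.rsids.index(rsid)
        except ValueError:
            raise KeyError(f"rsid {rsid!r} not in genotype matrix") from None
        return self.doses[:, j]

    def group_mask(self, group: str | None) -> np.ndarray:
        if group is None:
            return np.ones(self.n_samples, dtype=bool)
        if self.labels is None:
            raise ValueError("matrix has no group labels")
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return self.labels == group

    def group_size(self, group: str | None) -> int:
        return int(self.group_mask(group).sum())

    def genotype_counts(self, rsid: str, group: str | None = None) -> GenotypeCounts:
        """Genotype counts (1/1, 1/2, 2/2 plus missing) for one SNP and group."""
        col = self.column(rsid)[self.group_mask(group)]
        miss = int(np.isnan(col).sum())
        obs = col[~np.isnan(col)].astype(int)
        return GenotypeCounts(
            n11=int((obs == 0).sum()),
            n12=int((obs == 1).sum()),
            n22=int((obs == 2).sum()),
            n_missing=miss,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.doses, columns=self.rsids)
        df.insert(0, "sample_id", self.sample_ids)
        if self.labels is not None:
            df.insert(1, "label", self.labels)
        return df


def read_genotypes(path: str | Path, panel: SNPPanel) -> GenotypeMatrix:
    """Read the genotype TSV dialect: ``sample_id<TAB>label<TAB><rsid>...``.

    Dose cells are 0/1/2 (count of allele 2) or ``NA``.  Columns are matched
    to the panel by rsid and reordered to panel order; every panel rsid must
    be present.  Unrecognized cell tokens become missing with a logged
    warning; a row with the wrong number of columns raises
    :class:`GenotypeParseError` naming the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise GenotypeParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header[:2] != ["sample_id", "label"]:
        raise GenotypeParseError(
            f"{path}: header must start with 'sample_id\\tlabel'"
        )
    file_rsids = header[2:]
    absent = [r for r in panel.rsids if r not in file_rsids]
    if absent:
        raise GenotypeParseError(f"{path}: panel rsids missing from file: {absent}")
    extra = [r for r in file_rsids if r not in panel.rsids]
    if extra:
        logger.warning("%s: ignoring %d non-panel columns: %s", path, len(extra), extra)
    col_of = {r: file_rsids.index(r) + 2 for r in panel.rsids}

    sample_ids: list[str] = []
    labels: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise GenotypeParseError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(fields)}"
            )
        sample_ids.append(fields[0])
        if fields[1] not in GROUPS:
            raise GenotypeParseError(
                f"{path}:{lineno}: label must be one of {GROUPS}, got {fields[1]!r}"
            )
        labels.append(fields[1])
        row = []
        for rsid in panel.rsids:
            tok = fields[col_of[rsid]]
            if tok in ("0", "1", "2"):
                row.append(float(tok))
            elif tok == "NA":
                row.append(MISSING)
            else:
                logger.warning(
                    "%s:%d: unknown genotype token %r at %s; treated as missing",
                    path, lineno, tok, rsid,
                )
                row.append(MISSING)
        rows.append(row)
    return GenotypeMatrix(
        sample_ids=sample_ids,
        rsids=list(panel.rsids),
        doses=np.array(rows, dtype=float) if rows else np.empty((0, len(panel))),
        labels=np.array(labels, dtype=object),
    )


def write_genotypes(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a genotype matrix in the TSV dialect read by :func:`read_genotypes`."""
    if matrix.labels is None:
        raise ValueError("cannot write an unlabeled matrix in the case/control dialect")
    with open(path, "w") as fh:
        fh.write("\t".join(["sample_id", "label", *matrix.rsids]) + "\n")
        for i, sid in enumerate(matrix.sample_ids):
            cells = [
                "NA" if math.isnan(d) else str(int(d)) for d in matrix.doses[i]
            ]
            fh.write("\t".join([sid, str(matrix.labels[i]), *cells]) + "\n")


def read_vcf_genotypes(
    path: str | Path,
    panel: SNPPanel,
    labels: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Import genotypes from a VCF, harmonizing alleles against the panel.

    Variants are matched to the panel by the VCF ID field.  If (REF, ALT)
    equals (allele1, allele2) the dose is the ALT-allele count; if it equals
    (allele2, allele1) the dose is flipped (2 - ALT count).  Any other allele
    configuration — including strand ambiguity — drops the SNP with a
    warning; no strand flipping is attempted.  SNPs absent from the VCF are
    likewise dropped.  ``labels`` maps sample id -> "case"/"control"; when
    omitted the matrix is unlabeled.
    """
    from cyvcf2 import VCF  # lazy: only needed for VCF input

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dose_by_rsid: dict[str, np.ndarray] = {}
    wanted = set(panel.rsids)
    for var in vcf:
        if var.ID not in wanted or var.ID in dose_by_rsid:
            continue
        snp = panel.get(var.ID)
        if len(var.ALT) != 1:
            logger.warning("%s: %s is not biallelic; dropped", path, var.ID)
            continue
        ref, alt = var.REF, var.ALT[0]
        if (ref, alt) == (snp.allele1, snp.allele2):
            flip = False
        elif (ref, alt) == (snp.allele2, snp.allele1):
            flip = True
        else:
            logger.warning(
                "%s: %s alleles %s/%s do not match panel %s/%s; dropped",
                path, var.ID, ref, alt, snp.allele1, snp.allele2,
            )
            continue
        gts = np.asarray(var.genotypes, dtype=object)
        doses = np.empty(len(samples), dtype=float)
        for i, gt in enumerate(gts):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                doses[i] = MISSING
            else:
                alt_count = float(a + b)
                doses[i] = 2.0 - alt_count if flip else alt_count
        dose_by_rsid[var.ID] = doses
    kept = [r for r in panel.rsids if r in dose_by_rsid]
    dropped = [r for r in panel.rsids if r not in dose_by_rsid]
    if dropped:
        logger.warning("%s: panel SNPs not usable from VCF: %s", path, dropped)
    if not kept:
        raise GenotypeParseError(f"{path}: no panel SNPs could be imported")
    doses = np.column_stack([dose_by_rsid[r] for r in kept])
    label_arr = None
    if labels is not None:
        label_arr = np.array([labels[s] for s in samples], dtype=object)
    return GenotypeMatrix(
        sample_ids=samples, rsids=kept, doses=doses, labels=label_arr
    )


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("polyscore.data").joinpath(name)


def load_walkpace_panel() -> SNPPanel:
    """The packaged 15-SNP high-speed-walking panel."""
    with resources.as_file(_data_path("walkpace15.tsv")) as p:
        return read_panel(p, name="walkpace15")


def load_walkpace_frequencies() -> pd.DataFrame:
    """Observed favorable-allele percentages per group for the packaged panel.

    Returns a DataFrame indexed by rsid with columns ``hswa_case_pct`` and
    ``hswa_control_pct`` (percent scale).
    """
    with resources.as_file(_data_path("walkpace15.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return df.set_index("rsid")[["hswa_case_pct", "hswa_control_pct"]]


def load_table2_distributions() -> pd.DataFrame:
    """Per-group genotype percentage triples for the packaged panel.

    Columns: rsid, group (case/control), pct_11, pct_12, pct_22.
    """
    with resources.as_file(_data_path("table2_distributions.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def table2_group_sizes() -> dict[str, int]:
    return {CASE: N_SPRINTERS, CONTROL: N_CONTROLS}


def table2_genotype_counts() -> dict[str, dict[str, GenotypeCounts]]:
    """Integer genotype counts reconstructed from the packaged percentage table.

    Returns ``{rsid: {"case": GenotypeCounts, "control": GenotypeCounts}}`` in
    panel order, with counts summing exactly to the study group sizes
    (137 sprinters, 126 controls).
    """
    dist = load_table2_distributions()
    sizes = table2_group_sizes()
    out: dict[str, dict[str, GenotypeCounts]] = {}
    for row in dist.itertuples(index=False):
        counts = counts_from_percentages(
            (row.pct_11, row.pct_12, row.pct_22), sizes[row.group]
        )
        out.setdefault(row.rsid, {})[row.group] = GenotypeCounts(*map(int, counts))
    return out
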