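"""Synthetic case-control cohorts and quantitative-trait datasets.

Genotypes are drawn independently per SNP (the panel's SNPs span many
chromosomes; linkage disequilibrium is not modeled) from either

* explicit per-group genotype probability triples (emulating a published
  genotype-distribution table), or
* Hardy-Weinberg proportions at given control allele frequencies with a
  per-allele odds-ratio enrichment in cases.

Randomness is reproducible: one cohort-level seed, from which an independent
stream is derived per (group, SNP) via ``numpy.random.SeedSequence`` spawn
keys, so appending a SNP to the panel never perturbs earlier columns.

A small quantitative-trait generator produces a muscle-fiber-composition
style dataset: fast-twitch fiber percentage as a linear function of the
favorable-allele dose and age plus Gaussian noise, truncated to [0, 100].
Its defaults mirror the biopsy cohort scale of the sprinter study
(n = 67 men, fast-twitch 49.4 +/- 17.7%, age 32.9 +/- 8.9 years).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import (
    CASE, CONTROL, GROUPS, GenotypeMatrix, N_CONTROLS, N_SPRINTERS, SNPPanel,
    load_table2_distributions, load_walkpace_panel,
)

_GROUP_INDEX = {CASE: 0, CONTROL: 1}


def _snp_rng(seed: int, group: str, snp_index: int) -> np.random.Generator:
    """Independent, reproducible stream for one (group, SNP) pair."""
    ss = np.random.SeedSequence(entropy=seed,
                                spawn_key=(_GROUP_INDEX[group], snp_index))
    return np.random.default_rng(ss)


@dataclass
class GroupGenotypeModel:
    """Per-group genotype probability triples (P11, P12, P22) per SNP."""

    triples: dict[str, np.ndarray]  # group -> K x 3
    n_case: int
    n_control: int

    def __post_init__(self) -> None:
        if set(self.triples) != set(GROUPS):
            raise ValueError(f"triples must be keyed by {GROUPS}")
        shapes = set()
        for g, t in self.triples.items():
            t = np.asarray(t, dtype=float)
            if t.ndim != 2 or t.shape[1] != 3 or (t < 0).any():
                raise ValueError(f"{g}: triples must be a non-negative K x 3 array")
            if not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{g}: each genotype triple must sum to 1")
            self.triples[g] = t
            shapes.add(t.shape)
        if len(shapes) != 1:
            raise ValueError("groups must share the same SNP count")
        if self.n_case <= 0 or self.n_control <= 0:
            raise ValueError("group sizes must be positive")

    @property
    def n_snps(self) -> int:
        return next(iter(self.triples.values())).shape[0]

    def group_size(self, group: str) -> int:
        return self.n_case if group == CASE else self.n_control


@dataclass
class EffectModel:
    """HWE genotypes in controls with per-allele odds-ratio enrichment in cases.

    ``allele2_freq`` gives control allele-2 frequencies; the case frequency
    p' of each SNP satisfies p'/(1-p') = OR * p/(1-p).  Both groups are in
    Hardy-Weinberg proportions at their respective frequencies.
    """

    allele2_freq: np.ndarray
    odds_ratio: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.allele2_freq, dtype=float)
        o = np.asarray(self.odds_ratio, dtype=float)
        if o.shape != f.shape:
            raise ValueError("allele2_freq and odds_ratio must align")
        if ((f <= 0) | (f >= 1)).any():
            raise ValueError("allele frequencies must be in (0, 1)")
        if (o <= 0).any():
            raise ValueError("odds ratios must be positive")
        self.allele2_freq, self.odds_ratio = f, o

    def case_freq(self) -> np.ndarray:
        odds = self.odds_ratio * self.allele2_freq / (1.0 - self.allele2_freq)
        if not np.isfinite(odds).all():
            raise ValueError("odds overflow for the given frequencies and ORs")
        return odds / (1.0 + odds)

    def to_group_model(self, n_case: int, n_control: int) -> GroupGenotypeModel:
        def hwe(freq: np.ndarray) -> np.ndarray:
            p = 1.0 - freq
            return np.column_stack([p * p, 2 * p * freq, freq * freq])

        return GroupGenotypeModel(
            triples={CASE: hwe(self.case_freq()), CONTROL: hwe(self.allele2_freq)},
            n_case=n_case, n_control=n_control,
        )


def simulate_from_distributions(
    model: GroupGenotypeModel, panel: SNPPanel, seed: int
) -> GenotypeMatrix:
    """Draw a labeled cohort with independent SNPs from per-group triples."""
    if model.n_snps != len(panel):
        raise ValueError(
            f"model has {model.n_snps} SNPs but panel has {len(panel)}"
        )
    sample_ids: list[str] = []
    labels: list[str] = []
    blocks: list[np.ndarray] = []
    for group in (CASE, CONTROL):
        n = model.group_size(group)
        cols = [
            _snp_rng(seed, group, j).choice(3, size=n, p=model.triples[group][j])
            for j in range(len(panel))
        ]
        blocks.append(np.column_stack(cols).astype(float))
        sample_ids.extend(f"{group}_{i + 1:05d}" for i in range(n))
        labels.extend([group] * n)
    return GenotypeMatrix(
        sample_ids=sample_ids,
        rsids=list(panel.rsids),
        doses=np.vstack(blocks),
        labels=np.array(labels, dtype=object),
    )


def simulate_under_effects(
    model: EffectModel,
    n_case: int,
    n_control: int,
    seed: int,
    panel: SNPPanel | None = None,
) -> GenotypeMatrix:
    """Draw a cohort under HWE with case allele-frequency enrichment.

    With every OR equal to 1 this is distributionally identical to
    :func:`simulate_from_distributions` with the control triples in both
    groups.  ``panel`` supplies rsids; when omitted a panel-free matrix with
    synthetic snp_### column names is returned.
    """
    k = model.allele2_freq.size
    if panel is not None and len(panel) != k:
        raise ValueError("panel size does not match effect model")
    rsids = list(panel.rsids) if panel is not None else [
        f"snp_{j + 1:03d}" for j in range(k)
    ]
    gm = model.to_group_model(n_case, n_control)
    sample_ids: list[str] = []
    labels: list[str] = []
    blocks: list[np.ndarray] = []
    for group in (CASE, CONTROL):
        n = gm.group_size(group)
        cols = [
            _snp_rng(seed, group, j).choice(3, size=n, p=gm.triples[group][j])
            for j in range(k)
        ]
        blocks.append(np.column_stack(cols).astype(float))
        sample_ids.extend(f"{group}_{i + 1:05d}" for i in range(n))
        labels.extend([group] * n)
    return GenotypeMatrix(
        sample_ids=sample_ids, rsids=rsids, doses=np.vstack(blocks),
        labels=np.array(labels, dtype=object),
    )


def table2_group_model(
    n_case: int = N_SPRINTERS, n_control: int = N_CONTROLS
) -> GroupGenotypeModel:
    """Genotype model parameterized by the packaged per-group distribution table.

    Percentage triples are normalized to sum exactly to one (printed rows sum
    to 100 within rounding).  Defaults to the study group sizes 137/126.
    """
    dist = load_table2_distributions()
    panel = load_walkpace_panel()
    triples: dict[str, np.ndarray] = {}
    for group in GROUPS:
        sub = dist[dist["group"] == group].set_index("rsid")
        t = sub.loc[panel.rsids, ["pct_11", "pct_12", "pct_22"]].to_numpy(dtype=float)
        triples[group] = t / t.sum(axis=1, keepdims=True)
    return GroupGenotypeModel(triples=triples, n_case=n_case, n_control=n_control)


def simulate_fiber_dataset(
    n: int = 67,
    allele_freq: float = 0.155,
    slope: float = 6.0,
    baseline: float = 49.4,
    age_mean: float = 32.9,
    age_sd: float = 8.9,
    age_coef: float = -0.2,
    noise_sd: float = 17.7,
    seed: int = 0,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Synthetic muscle-fiber cohort: one SNP, age covariate, Gaussian noise.

    fast% = baseline + slope * dose + age_coef * (age - age_mean) + N(0, noise_sd),
    truncated to [0, 100]; genotype drawn under HWE at ``allele_freq`` (the
    favorable-allele frequency).  Defaults follow the biopsy cohort scale:
    n = 67, baseline 49.4%, noise SD 17.7%, age 32.9 +/- 8.9 years; the
    dose effect (percentage points of fast-twitch fibers per favorable
    allele) and the age coefficient are the tunable effect parameters.
    Returns an unlabeled single-SNP genotype matrix and a phenotype table
    (sample_id, phenotype, age).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not 0 < allele_freq < 1:
        raise ValueError("allele_freq must be in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(9,)))
    p = 1.0 - allele_freq
    dose = rng.choice(3, size=n, p=[p * p, 2 * p * allele_freq,
                                    allele_freq * allele_freq]).astype(float)
    age = rng.normal(age_mean, age_sd, size=n)
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    fast = baseline + slope * dose + age_coef * (age - age_mean) + noise
    fast = np.clip(fast, 0.0, 100.0)
    sample_ids = [f"subj_{i + 1:03d}" for i in range(n)]
    matrix = GenotypeMatrix(
        sample_ids=sample_ids, rsids=["rs699785"],
        doses=dose.reshape(-1, 1), labels=None,
    )
    pheno = pd.DataFrame({"sample_id": sample_ids, "phenotype": fast, "age": age})
    return matrix, pheno
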