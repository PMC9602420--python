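"""End-to-end orchestration: simulate/load -> association -> TGS -> ROC -> regression.

A :class:`RunConfig` describes one reproducible run; :func:`run_pipeline`
executes every stage on the same genotype matrix and writes a consolidated
set of artifacts to the output directory:

* ``assoc.tsv``        per-SNP association report
* ``tgs_scores.tsv``   per-sample scores
* ``tgs_summary.json`` per-group distribution summaries
* ``roc.tsv``          ROC curve points
* ``cutoffs.tsv``      cutoff sweep with odds ratios
* ``report.json``      consolidated report with provenance

TSV output mirrors the published table style (frequencies to 0.1%, p-values
to two significant figures floored at 1e-6); ``report.json`` keeps full
precision.  Re-running with the same config and seed reproduces the numeric
tables byte for byte (timestamps live only in report.json).
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import association_table, run_association
from .discrim import cutoffs_table, roc_auc, sweep_cutoffs
from .panel import (
    CASE, CONTROL, GenotypeMatrix, SNPPanel, load_walkpace_panel, read_genotypes,
)
from .quant import additive_regression, read_phenotypes
from .simulate import simulate_from_distributions, table2_group_model
from .tgs import favorable_dose, group_summaries, tgs_scores

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """A run configuration is invalid."""


@dataclass
class RunConfig:
    outdir: str | Path
    panel: str | Path | None = None        # None -> packaged 15-SNP panel
    genotypes: str | Path | None = None    # mutually exclusive with simulate
    simulate: dict | None = None           # {"n_case": int, "n_control": int}
    phenotypes: str | Path | None = None
    regress_snp: str | None = None
    regress_covariates: list[str] = field(default_factory=lambda: ["age"])
    alpha: float = 0.05
    n_models: int = 4
    bonferroni_snps: int | None = None
    cutoffs: list[float] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_models <= 0:
            raise ConfigError("n_models must be positive")
        if (self.genotypes is None) == (self.simulate is None):
            raise ConfigError("exactly one of 'genotypes' or 'simulate' is required")
        for attr in ("panel", "genotypes", "phenotypes"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{attr} file does not exist: {p}")
        if self.phenotypes is not None and self.regress_snp is None:
            raise ConfigError("phenotypes given but no regress_snp")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc

    def to_jsonable(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, Path):
                d[k] = str(v)
        return d


@dataclass
class RunReport:
    config: RunConfig
    association: pd.DataFrame
    tgs_scores: pd.DataFrame
    tgs_summaries: dict
    roc: object
    cutoffs: pd.DataFrame
    regression: object | None
    provenance: dict


def _fmt_p(p: float) -> str:
    if not np.isfinite(p):
        return "NA"
    return f"{max(p, 1e-6):.2g}"


def _assoc_tsv(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if col.endswith("_p") or col in ("hwe_p_case", "hwe_p_control"):
            out[col] = out[col].map(_fmt_p)
        elif col.endswith("_statistic"):
            out[col] = out[col].map(lambda v: f"{v:.3f}" if np.isfinite(v) else "NA")
        elif col == "freq_diff":
            out[col] = out[col].map(lambda v: f"{v:.3f}")
    return out


def _provenance(config: RunConfig) -> dict:
    cfg_json = json.dumps(config.to_jsonable(), sort_keys=True)
    return {
        "polyscore_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }


def _load_matrix(config: RunConfig, panel: SNPPanel) -> GenotypeMatrix:
    if config.genotypes is not None:
        return read_genotypes(config.genotypes, panel)
    sim = dict(config.simulate or {})
    model = table2_group_model(
        n_case=int(sim.get("n_case", 137)),
        n_control=int(sim.get("n_control", 126)),
    )
    return simulate_from_distributions(model, panel, seed=config.seed)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage on one genotype matrix and write all artifacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = (
        load_walkpace_panel() if config.panel is None
        else __import__("polyscore.panel", fromlist=["read_panel"]).read_panel(config.panel)
    )
    matrix = _load_matrix(config, panel)
    logger.info("pipeline: %d samples x %d SNPs", matrix.n_samples, matrix.n_snps)

    results = run_association(
        matrix, panel, alpha=config.alpha, n_models=config.n_models,
        bonferroni_snps=config.bonferroni_snps,
    )
    assoc_df = association_table(results, panel)
    _assoc_tsv(assoc_df).to_csv(outdir / "assoc.tsv", sep="\t", index=False)

    scores = tgs_scores(matrix, panel)
    scores_out = scores.copy()
    scores_out["score"] = scores_out["score"].map(lambda v: f"{v:.1f}")
    scores_out.to_csv(outdir / "tgs_scores.tsv", sep="\t", index=False)
    summaries = group_summaries(scores)
    with open(outdir / "tgs_summary.json", "w") as fh:
        json.dump({g: s.to_dict() for g, s in summaries.items()}, fh, indent=2)

    case_scores = scores.loc[scores["label"] == CASE, "score"].to_numpy()
    control_scores = scores.loc[scores["label"] == CONTROL, "score"].to_numpy()
    roc = roc_auc(case_scores, control_scores)
    roc.curve.to_csv(outdir / "roc.tsv", sep="\t", index=False)
    cuts = sweep_cutoffs(case_scores, control_scores, extra_cutoffs=config.cutoffs)
    cuts_df = cutoffs_table(cuts)
    cuts_df.to_csv(outdir / "cutoffs.tsv", sep="\t", index=False, float_format="%.6g")

    regression = None
    if config.phenotypes is not None and config.regress_snp is not None:
        pheno = read_phenotypes(config.phenotypes)
        snp = panel.get(config.regress_snp)
        dose2 = matrix.column(config.regress_snp)
        order = {sid: i for i, sid in enumerate(matrix.sample_ids)}
        idx = [order[s] for s in pheno["sample_id"]]
        dose = favorable_dose(dose2[idx], snp.favorable_is_allele2)
        covars = pheno[[c for c in config.regress_covariates if c in pheno.columns]]
        regression = additive_regression(pheno["phenotype"], dose, covariates=covars)

    report = RunReport(
        config=config,
        association=assoc_df,
        tgs_scores=scores,
        tgs_summaries={g: s.to_dict() for g, s in summaries.items()},
        roc=roc,
        cutoffs=cuts_df,
        regression=regression,
        provenance=_provenance(config),
    )
    payload = {
        "config": config.to_jsonable(),
        "provenance": report.provenance,
        "association": assoc_df.to_dict(orient="records"),
        "tgs_summaries": report.tgs_summaries,
        "roc": roc.to_dict(),
        "cutoffs": cuts_df.to_dict(orient="records"),
        "regression": regression.to_dict() if regression else None,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
    return report
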