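"""Additive-dose regression of a quantitative phenotype on genotype.

Ordinary least squares of a phenotype (e.g. percent fast-twitch muscle
fibers) on the favorable-allele dose (0/1/2), optionally adjusted for
covariates such as age, with a two-sided t-test on the dose coefficient.
Dominant (carrier vs non-carrier) and recessive (favorable homozygote vs
rest) recodings of the dose are available behind the ``coding`` flag; the
additive 0/1/2 coding is the default.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

CODINGS = ("additive", "dominant", "recessive")


class MonomorphicPredictorError(ValueError):
    """The dose vector is constant; no genetic effect is estimable."""


@dataclass
class RegressionResult:
    slope_per_allele: float
    se: float
    t: float
    p: float
    n: int
    df_resid: int
    intercept: float
    coding: str
    covariate_coefficients: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _recode(dose: np.ndarray, coding: str) -> np.ndarray:
    if coding == "additive":
        return dose
    if coding == "dominant":
        return (dose >= 1).astype(float)
    if coding == "recessive":
        return (dose == 2).astype(float)
    raise ValueError(f"coding must be one of {CODINGS}, got {coding!r}")


def additive_regression(
    phenotype,
    dose,
    covariates: pd.DataFrame | dict | None = None,
    coding: str = "additive",
) -> RegressionResult:
    """OLS fit of phenotype ~ intercept + dose (+ covariates).

    ``dose`` is the favorable-allele dose in {0, 1, 2} per sample; missing
    doses or phenotypes are not accepted (filter beforehand).  Raises
    :class:`MonomorphicPredictorError` for a constant dose vector and
    ``ValueError`` for a rank-deficient design.
    """
    y = np.asarray(phenotype, dtype=float)
    d = np.asarray(dose, dtype=float)
    if y.ndim != 1 or y.shape != d.shape:
        raise ValueError("phenotype and dose must be equal-length vectors")
    if not np.isfinite(y).all() or not np.isfinite(d).all():
        raise ValueError("phenotype and dose must be complete (no NaN)")
    if not np.isin(d, (0.0, 1.0, 2.0)).all():
        raise ValueError("doses must be 0, 1 or 2")
    coded = _recode(d, coding)
    if np.ptp(coded) == 0:
        raise MonomorphicPredictorError("monomorphic predictor: dose vector is constant")

    X = pd.DataFrame({"dose": coded})
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        if len(cov) != len(y):
            raise ValueError("covariates length does not match phenotype")
        if not np.isfinite(cov.to_numpy(dtype=float)).all():
            raise ValueError("covariates must be complete for included samples")
        X = pd.concat([X, cov], axis=1)
    if len(y) <= X.shape[1] + 2:
        raise ValueError("too few samples for the number of predictors")
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, X).fit()
    covar_names = [c for c in X.columns if c not in ("const", "dose")]
    return RegressionResult(
        slope_per_allele=float(fit.params["dose"]),
        se=float(fit.bse["dose"]),
        t=float(fit.tvalues["dose"]),
        p=float(fit.pvalues["dose"]),
        n=int(len(y)),
        df_resid=int(fit.df_resid),
        intercept=float(fit.params["const"]),
        coding=coding,
        covariate_coefficients={c: float(fit.params[c]) for c in covar_names},
    )


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype TSV with columns sample_id, phenotype and covariates."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "phenotype"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if not np.isfinite(df["phenotype"].to_numpy(dtype=float)).all():
        raise ValueError(f"{path}: phenotype values must be finite")
    return df
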