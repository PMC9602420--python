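"""ROC discrimination of cases from controls by score, cutoff sweep and odds ratios.

The AUC is computed as the Mann-Whitney probability that a random case
outscores a random control (ties counted half), with a Hanley-McNeil
standard error for the 95% confidence interval.  A cutoff sweep dichotomizes
the score at every observed value ("score >= cutoff" predicts case),
reporting the 2x2 table, the odds ratio with a Woolf logit interval and a
Fisher exact p-value at each cutoff, and annotating the Youden-optimal one.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .assoc import DegenerateTableError, fisher_exact, pearson_chi2

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054


@dataclass
class ROCReport:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_case: int
    n_control: int
    curve: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p": self.p, "n_case": self.n_case, "n_control": self.n_control,
        }


@dataclass(frozen=True)
class OddsRatio:
    value: float
    ci_low: float
    ci_high: float
    p_fisher: float
    p_chi2: float | None
    haldane_corrected: bool = False


@dataclass
class CutoffResult:
    """Dichotomization of the score at ``score >= cutoff`` (predicted case)."""

    cutoff: float
    table: np.ndarray  # rows case/control, cols >=cutoff/<cutoff
    odds_ratio: OddsRatio | None
    pct_case_above: float
    pct_control_above: float
    sensitivity: float
    specificity: float
    youden: float
    is_youden_optimal: bool = False


def hanley_mcneil_se(auc: float, n_case: int, n_control: int) -> float:
    """Hanley-McNeil (1982) standard error of a Mann-Whitney AUC."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1 - auc)
        + (n_case - 1) * (q1 - auc * auc)
        + (n_control - 1) * (q2 - auc * auc)
    ) / (n_case * n_control)
    return float(np.sqrt(max(var, 0.0)))


def roc_auc(case_scores, control_scores) -> ROCReport:
    """AUC = P(case score > control score) + 0.5 P(tie), with 95% CI.

    The point estimate is the normalized Mann-Whitney U statistic; the
    two-sided p-value is the (tie-corrected) asymptotic Mann-Whitney test of
    no discrimination; the CI is Hanley-McNeil, truncated to [0, 1].
    """
    case = np.asarray(case_scores, dtype=float)
    control = np.asarray(control_scores, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(case, control, alternative="two-sided",
                             method="asymptotic")
    auc = float(res.statistic) / (case.size * control.size)
    se = hanley_mcneil_se(auc, case.size, control.size)
    labels = np.concatenate([np.ones(case.size), np.zeros(control.size)])
    scores = np.concatenate([case, control])
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores)
    curve = pd.DataFrame({"threshold": thresholds, "sensitivity": tpr,
                          "one_minus_specificity": fpr})
    return ROCReport(
        auc=auc, se=se,
        ci_low=float(max(0.0, auc - Z95 * se)),
        ci_high=float(min(1.0, auc + Z95 * se)),
        p=float(res.pvalue),
        n_case=case.size, n_control=control.size,
        curve=curve,
    )


def odds_ratio(table, strict: bool = True) -> OddsRatio:
    """Odds ratio ad/bc of a 2x2 table with Woolf logit 95% CI.

    A zero cell triggers the Haldane-Anscombe +0.5 correction (flagged).
    A fully empty row or column leaves the ratio undefined: raises when
    ``strict``, otherwise still returns the corrected, flagged estimate.
    The p-value is the Fisher exact test of the uncorrected table; the
    chi-square p is reported alongside when the table is non-degenerate.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("odds_ratio requires a non-negative 2x2 table")
    degenerate_line = (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any()
    if degenerate_line and strict:
        raise ValueError("odds ratio undefined: a full row or column is zero")
    corrected = bool((t == 0).any())
    w = t + 0.5 if corrected else t
    if corrected:
        logger.info("odds_ratio: zero cell; Haldane-Anscombe +0.5 applied")
    a, b, c, d = w.ravel()
    value = (a * d) / (b * c)
    se_log = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    log_or = float(np.log(value))
    p_fisher = fisher_exact(t.astype(int)).p
    try:
        p_chi2 = pearson_chi2(t.astype(int)).p
    except DegenerateTableError:
        p_chi2 = None
    return OddsRatio(
        value=float(value),
        ci_low=float(np.exp(log_or - Z95 * se_log)),
        ci_high=float(np.exp(log_or + Z95 * se_log)),
        p_fisher=p_fisher,
        p_chi2=p_chi2,
        haldane_corrected=corrected,
    )


def cutoff_table(case_scores, control_scores, cutoff: float) -> np.ndarray:
    """2x2 table of group (case/control) by score >= cutoff / < cutoff."""
    case = np.asarray(case_scores, dtype=float)
    control = np.asarray(control_scores, dtype=float)
    a = int((case >= cutoff).sum())
    c = int((control >= cutoff).sum())
    return np.array([[a, case.size - a], [c, control.size - c]])


def evaluate_cutoff(case_scores, control_scores, cutoff: float) -> CutoffResult:
    t = cutoff_table(case_scores, control_scores, cutoff)
    n_case, n_control = t[0].sum(), t[1].sum()
    sens = t[0, 0] / n_case
    spec = t[1, 1] / n_control
    try:
        orr = odds_ratio(t, strict=False)
    except ValueError:
        orr = None
    return CutoffResult(
        cutoff=float(cutoff), table=t, odds_ratio=orr,
        pct_case_above=float(100.0 * t[0, 0] / n_case),
        pct_control_above=float(100.0 * t[1, 0] / n_control),
        sensitivity=float(sens), specificity=float(spec),
        youden=float(sens + spec - 1.0),
    )


def sweep_cutoffs(case_scores, control_scores,
                  extra_cutoffs=()) -> list[CutoffResult]:
    """Evaluate every distinct observed score (plus any requested cutoffs).

    Results are sorted by cutoff; the entry maximizing the Youden index
    (smallest cutoff on ties) is marked ``is_youden_optimal``.
    """
    case = np.asarray(case_scores, dtype=float)
    control = np.asarray(control_scores, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("both groups must be non-empty")
    cutoffs = np.unique(np.concatenate([case, control, np.asarray(extra_cutoffs,
                                                                  dtype=float)]))
    results = [evaluate_cutoff(case, control, c) for c in cutoffs]
    best = max(range(len(results)),
               key=lambda i: (results[i].youden, -results[i].cutoff))
    results[best].is_youden_optimal = True
    return results


def cutoffs_table(results: list[CutoffResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        orr = r.odds_ratio
        rows.append({
            "cutoff": r.cutoff,
            "case_above": int(r.table[0, 0]), "case_below": int(r.table[0, 1]),
            "control_above": int(r.table[1, 0]), "control_below": int(r.table[1, 1]),
            "pct_case_above": r.pct_case_above,
            "pct_control_above": r.pct_control_above,
            "sensitivity": r.sensitivity, "specificity": r.specificity,
            "youden": r.youden, "youden_optimal": r.is_youden_optimal,
            "odds_ratio": orr.value if orr else float("nan"),
            "or_ci_low": orr.ci_low if orr else float("nan"),
            "or_ci_high": orr.ci_high if orr else float("nan"),
            "or_p_fisher": orr.p_fisher if orr else float("nan"),
            "or_haldane": orr.haldane_corrected if orr else False,
        })
    return pd.DataFrame(rows)


def plot_roc(report: ROCReport, path) -> None:
    """Save a ROC curve plot (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(report.curve["one_minus_specificity"], report.curve["sensitivity"],
            drawstyle="steps-post", label=f"AUC = {report.auc:.3f}")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
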