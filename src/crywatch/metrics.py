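"""Diagnostic evaluation: ROC/AUC, cutpoint, exact CIs, kappa, group tests.

The stacked leave-one-out probabilities are evaluated as a diagnostic test:
AUC with a DeLong (rank-based asymptotic) confidence interval, the binary
cutpoint closest to perfect prediction (the (0, 1) corner of ROC space),
and the standard accuracy estimates — accuracy, sensitivity, specificity,
PPV, NPV — each with an exact Clopper–Pearson 95% binomial interval, plus
Cohen's kappa with an asymptotic interval. Subgroup sensitivity analyses
recompute everything on a subset of the predictions without refitting.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm

__all__ = [
    "RocCurve",
    "ConfusionMatrix",
    "DiagnosticReport",
    "roc_curve",
    "select_cutpoint",
    "confusion_at",
    "diagnostics",
    "exact_binomial_ci",
    "evaluate_predictions",
    "subgroup_analysis",
    "compare_groups",
]


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    auc_ci: tuple[float, float]


@dataclass
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class DiagnosticReport:
    """Point estimates with 95% CIs for one evaluation variant."""

    cm: ConfusionMatrix
    cutpoint: float
    auc: float = np.nan
    auc_ci: tuple[float, float] = (np.nan, np.nan)
    estimates: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    variant: str = "primary"
    n: int = 0

    def value(self, name: str) -> float:
        return self.estimates[name][0]

    def to_dict(self) -> dict:
        out = {
            "variant": self.variant,
            "n": self.n,
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "cutpoint": self.cutpoint,
            "confusion_matrix": {
                "tp": self.cm.tp, "fn": self.cm.fn, "fp": self.cm.fp, "tn": self.cm.tn,
            },
        }
        for k, (est, lo, hi) in self.estimates.items():
            out[k] = est
            out[f"{k}_ci"] = [lo, hi]
        return out

    def to_text(self) -> str:
        lines = [f"Diagnostic report ({self.variant}, n={self.n})"]
        if np.isfinite(self.auc):
            lines.append(
                f"  AUC         {self.auc:.2f} (95% CI, {self.auc_ci[0]:.2f}-{self.auc_ci[1]:.2f})"
            )
        for k in ("accuracy", "kappa", "sensitivity", "specificity", "ppv", "npv"):
            if k in self.estimates:
                est, lo, hi = self.estimates[k]
                if math.isnan(est):
                    lines.append(f"  {k:<11} undefined")
                else:
                    lines.append(f"  {k:<11} {est:.2f} (95% CI, {lo:.2f}-{hi:.2f})")
        c = self.cm
        lines.append(f"  cutpoint    {self.cutpoint:.4f}")
        lines.append(f"  confusion   TP={c.tp} FN={c.fn} FP={c.fp} TN={c.tn}")
        return "\n".join(lines)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, default=float))


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def _delong_auc(y: np.ndarray, scores: np.ndarray, level: float) -> tuple[float, tuple[float, float]]:
    """AUC (Mann–Whitney with ties counted 1/2) and its DeLong CI."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = pos.size, neg.size
    all_r = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (all_r[:m] - r_pos) / n  # placement of each positive among negatives
    v10 = 1.0 - (all_r[m:] - r_neg) / m
    var = 0.0
    if m > 1:
        var += np.var(v01, ddof=1) / m
    if n > 1:
        var += np.var(v10, ddof=1) / n
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(max(var, 0.0))
    return float(auc), (max(0.0, auc - half), min(1.0, auc + half))


def roc_curve(labels, scores, level: float = 0.95) -> RocCurve:
    """ROC curve over the distinct score thresholds.

    AUC equals the Mann–Whitney concordant-pair fraction with ties counted
    one half; the CI uses the DeLong rank-based variance. Raises if a single
    class is present.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes")
    fpr, tpr, thr = skm.roc_curve(y, s)
    auc, ci = _delong_auc(y, s, level)
    return RocCurve(fpr, tpr, thr, auc, ci)


def select_cutpoint(roc: RocCurve) -> float:
    """Threshold whose ROC point is closest (Euclidean) to perfect
    prediction (sensitivity 1, specificity 1); ties resolve to the lower
    threshold (the more sensitive operating point)."""
    d = np.sqrt((1.0 - roc.tpr) ** 2 + roc.fpr**2)
    best = np.flatnonzero(d <= d.min() + 1e-12)
    # thresholds are non-increasing: the last tied index is the lowest one
    return float(roc.thresholds[best[-1]])


def confusion_at(labels, scores, threshold: float) -> ConfusionMatrix:
    """Confusion matrix predicting positive when score >= threshold."""
    y = np.asarray(labels, dtype=int)
    pred = np.asarray(scores, dtype=float) >= threshold
    return ConfusionMatrix(
        tp=int(np.sum(pred & (y == 1))),
        fn=int(np.sum(~pred & (y == 1))),
        fp=int(np.sum(pred & (y == 0))),
        tn=int(np.sum(~pred & (y == 0))),
    )


# ---------------------------------------------------------------------------
# Proportions, kappa, diagnostics
# ---------------------------------------------------------------------------


def exact_binomial_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper–Pearson exact binomial interval via beta quantiles."""
    if not 0 <= successes <= n or n <= 0:
        raise ValueError("require 0 <= successes <= n with n > 0")
    a = 1.0 - level
    lo = 0.0 if successes == 0 else float(stats.beta.ppf(a / 2, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(stats.beta.ppf(1 - a / 2, successes + 1, n - successes))
    return lo, hi


def _ratio_with_ci(k: int, n: int, level: float) -> tuple[float, float, float]:
    if n == 0:
        return (np.nan, np.nan, np.nan)
    lo, hi = exact_binomial_ci(k, n, level)
    return (k / n, lo, hi)


def _kappa_with_ci(cm: ConfusionMatrix, level: float) -> tuple[float, float, float]:
    n = cm.n
    p0 = (cm.tp + cm.tn) / n
    pe = ((cm.tp + cm.fn) * (cm.tp + cm.fp) + (cm.fp + cm.tn) * (cm.fn + cm.tn)) / n**2
    if pe == 1.0:
        return (np.nan, np.nan, np.nan)
    kappa = (p0 - pe) / (1.0 - pe)
    se = math.sqrt(max(p0 * (1 - p0), 0.0) / n) / (1.0 - pe)
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (kappa, max(-1.0, kappa - z * se), min(1.0, kappa + z * se))


def diagnostics(cm: ConfusionMatrix, level: float = 0.95) -> DiagnosticReport:
    """Standard diagnostic accuracy estimates from a confusion matrix.

    Accuracy, sensitivity, specificity, PPV and NPV each carry an exact
    Clopper–Pearson interval; Cohen's kappa carries an asymptotic interval.
    Ratios with a zero denominator are reported as NaN.
    """
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    est = {
        "accuracy": _ratio_with_ci(cm.tp + cm.tn, cm.n, level),
        "sensitivity": _ratio_with_ci(cm.tp, cm.tp + cm.fn, level),
        "specificity": _ratio_with_ci(cm.tn, cm.tn + cm.fp, level),
        "ppv": _ratio_with_ci(cm.tp, cm.tp + cm.fp, level),
        "npv": _ratio_with_ci(cm.tn, cm.tn + cm.fn, level),
        "kappa": _kappa_with_ci(cm, level),
    }
    return DiagnosticReport(cm=cm, cutpoint=np.nan, estimates=est, n=cm.n)


def evaluate_predictions(
    labels, scores, level: float = 0.95, variant: str = "primary"
) -> DiagnosticReport:
    """Full evaluation of continuous predictions: ROC + AUC with DeLong CI,
    distance-optimal cutpoint, confusion matrix, and all diagnostics."""
    roc = roc_curve(labels, scores, level)
    cut = select_cutpoint(roc)
    cm = confusion_at(labels, scores, cut)
    report = diagnostics(cm, level)
    report.auc, report.auc_ci = roc.auc, roc.auc_ci
    report.cutpoint = cut
    report.variant = variant
    return report


def subgroup_analysis(
    predictions: pd.DataFrame, exclude: str | None = None, level: float = 0.95
) -> DiagnosticReport:
    """Re-evaluate stacked predictions after excluding one subgroup.

    ``predictions`` needs columns p_stacked, label, subgroup. The ROC,
    cutpoint and confusion matrix are recomputed on the retained infants; no
    models are refitted. ``exclude=None`` reproduces the primary report.
    """
    df = predictions if exclude is None else predictions[predictions["subgroup"] != exclude]
    if df["label"].nunique() < 2:
        raise ValueError("exclusion left a single class; cannot evaluate")
    variant = "primary" if exclude is None else f"exclude_{exclude}"
    return evaluate_predictions(df["label"], df["p_stacked"], level, variant)


# ---------------------------------------------------------------------------
# Group comparisons (demographics-style table)
# ---------------------------------------------------------------------------


def compare_groups(
    data: pd.DataFrame, group_col: str = "label", covariates: list[str] | None = None
) -> pd.DataFrame:
    """Two-group comparisons per covariate.

    Numeric covariates: Welch's t test (Satterthwaite df) and pooled-SD
    Cohen's d. Categorical covariates: Pearson chi-square on the contingency
    table, with Yates continuity correction for 2×2 tables.
    """
    groups = sorted(data[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError("compare_groups requires exactly two groups")
    g1 = data[data[group_col] == groups[1]]
    g0 = data[data[group_col] == groups[0]]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("both groups must be non-empty")
    covariates = covariates or [c for c in data.columns if c != group_col]
    rows = []
    for cov in covariates:
        if pd.api.types.is_numeric_dtype(data[cov]):
            a = g1[cov].dropna().to_numpy(dtype=float)
            b = g0[cov].dropna().to_numpy(dtype=float)
            res = stats.ttest_ind(a, b, equal_var=False)
            n1, n2 = a.size, b.size
            sp = math.sqrt(
                ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
            ) if n1 + n2 > 2 else np.nan
            d = abs(a.mean() - b.mean()) / sp if sp and sp > 0 else 0.0
            rows.append(
                {"covariate": cov, "test": "welch_t", "statistic": float(res.statistic),
                 "df": float(res.df), "p_value": float(res.pvalue), "cohen_d": float(d)}
            )
        else:
            tab = pd.crosstab(data[group_col], data[cov])
            correction = tab.shape == (2, 2)
            chi2, p, dof, _ = stats.chi2_contingency(tab, correction=correction)
            rows.append(
                {"covariate": cov, "test": "chi_square", "statistic": float(chi2),
                 "df": float(dof), "p_value": float(p), "cohen_d": np.nan}
            )
    return pd.DataFrame(rows)


def plot_roc_pr(labels, scores, path: str | Path) -> None:
    """ROC and precision–recall curves side by side, saved as SVG/PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    roc = roc_curve(labels, scores)
    cut = select_cutpoint(roc)
    prec, rec, _ = skm.precision_recall_curve(labels, scores)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.plot(roc.fpr, roc.tpr, drawstyle="steps-post")
    ax1.plot([0, 1], [0, 1], ls=":", c="gray")
    k = int(np.argmin(np.sqrt((1 - roc.tpr) ** 2 + roc.fpr**2)))
    ax1.plot(roc.fpr[k], roc.tpr[k], marker="^", ms=9, c="tab:red")
    ax1.set_xlabel("1 - specificity")
    ax1.set_ylabel("sensitivity")
    ax1.set_title(f"ROC (AUC = {roc.auc:.2f}, cutpoint = {cut:.2f})")
    ax2.plot(rec, prec, drawstyle="steps-post")
    ax2.set_xlabel("recall (sensitivity)")
    ax2.set_ylabel("precision (PPV)")
    ax2.set_title("Precision-recall")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
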