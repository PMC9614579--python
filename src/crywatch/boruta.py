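"""All-relevant feature selection (Boruta) and its stabilized ensemble.

Boruta tests each feature against permuted "shadow" copies of the feature
set: per iteration a random forest is fitted to the real features plus
shadows, a feature scores a hit when its importance exceeds the best shadow
importance, and cumulative hit counts are tested against Binomial(n, 1/2)
two-sided with a Bonferroni correction — significantly many hits confirms a
feature, significantly few rejects it. Features still undecided at the
iteration cap are tentative.

The ensemble wrapper repeats Boruta ``n_runs`` times (default 100) with
derived seeds and retains features confirmed in strictly more than
``retain_threshold`` runs (default 5); tentative decisions count as not
selected. Per-fold ensemble results aggregate into a stability profile:
the percentage of cross-validation folds in which each feature was retained,
alongside its mean importance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from ._seeding import derive_seed

__all__ = [
    "BorutaResult",
    "EnsembleSelectionResult",
    "StabilityProfile",
    "boruta_run",
    "ensemble_select",
    "stability_profile",
]

CONFIRMED, TENTATIVE, REJECTED = "confirmed", "tentative", "rejected"


@dataclass
class BorutaResult:
    decisions: dict[str, str]
    mean_importance: dict[str, float]
    #: one row per iteration: importance per feature (NaN once rejected)
    importance_history: pd.DataFrame
    iterations: int

    def confirmed(self) -> list[str]:
        return [f for f, d in self.decisions.items() if d == CONFIRMED]


@dataclass
class EnsembleSelectionResult:
    selection_count: dict[str, int]
    retained: list[str]
    mean_importance: dict[str, float]
    n_runs: int
    fold_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        feats = list(self.selection_count)
        return pd.DataFrame(
            {
                "feature": feats,
                "selection_count": [self.selection_count[f] for f in feats],
                "retained": [f in self.retained for f in feats],
                "mean_importance": [self.mean_importance.get(f, np.nan) for f in feats],
            }
        )


@dataclass
class StabilityProfile:
    """Per-feature retention stability across cross-validation folds."""

    stability_pct: dict[str, float]
    mean_importance: dict[str, float]
    n_folds: int

    def to_frame(self) -> pd.DataFrame:
        feats = sorted(self.stability_pct)
        return pd.DataFrame(
            {
                "feature": feats,
                "stability_pct": [self.stability_pct[f] for f in feats],
                "mean_importance": [self.mean_importance.get(f, np.nan) for f in feats],
            }
        )


def _forest_importance(
    X: np.ndarray, y: np.ndarray, n_trees: int, rng: np.random.Generator
) -> np.ndarray:
    """Mean impurity-decrease importance of a bagged random forest.

    Hand-rolled bagging of CART trees (bootstrap resampling, sqrt feature
    subsampling) — equivalent to a standard random-forest importance but
    without per-tree estimator-cloning overhead, which dominates at the tiny
    sample sizes Boruta is run on here (it is fitted thousands of times
    inside the selection ensemble).
    """
    n, p = X.shape
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    imp = np.zeros(p)
    for _ in range(n_trees):
        idx = rng.integers(0, n, n)
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(2**31))
        )
        tree.fit(X32[idx], y[idx], check_input=False)
        imp += tree.tree_.compute_feature_importances()
    return imp / n_trees


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{i}" for i in range(X.shape[1])]


def boruta_run(
    X,
    y,
    seed: int,
    max_iter: int = 100,
    alpha: float = 0.01,
    n_trees: int = 300,
    importance: str = "gini",
) -> BorutaResult:
    """One Boruta pass over features ``X`` (DataFrame or array) and binary ``y``.

    ``importance`` selects the forest importance measure: ``"gini"`` (mean
    decrease in impurity; fast, the default) or ``"permutation"`` (mean
    decrease in accuracy, the measure of the original algorithm; markedly
    slower). Missing values are median-imputed. Raises if ``y`` has a single
    class or fewer than two features are supplied.
    """
    Xm, names = _as_matrix(X)
    y = np.asarray(y)
    if Xm.shape[1] < 2:
        raise ValueError("Boruta requires at least 2 features")
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    med = np.nanmedian(Xm, axis=0)
    med = np.where(np.isfinite(med), med, 0.0)
    nan_mask = np.isnan(Xm)
    if nan_mask.any():
        Xm = np.where(nan_mask, med[None, :], Xm)

    rng = np.random.default_rng(seed)
    p = len(names)
    thr = alpha / (2.0 * p)  # Bonferroni over features, two-sided
    decisions = {f: TENTATIVE for f in names}
    hits = np.zeros(p, dtype=int)
    tested = np.zeros(p, dtype=int)  # iterations each feature was in the model
    history: list[np.ndarray] = []

    for it in range(1, max_iter + 1):
        active = [i for i, f in enumerate(names) if decisions[f] != REJECTED]
        undecided = [i for i, f in enumerate(names) if decisions[f] == TENTATIVE]
        if not undecided:
            break
        Xa = Xm[:, active]
        # shadows: permuted copies of the active features, at least 5
        shadow_src = list(range(len(active)))
        while len(shadow_src) < 5:
            shadow_src.append(int(rng.integers(len(active))))
        shadows = np.column_stack([rng.permutation(Xa[:, j]) for j in shadow_src])
        Xfull = np.column_stack([Xa, shadows])
        if importance == "permutation":
            from sklearn.inspection import permutation_importance

            clf = RandomForestClassifier(
                n_estimators=n_trees,
                max_features="sqrt",
                n_jobs=1,
                random_state=int(rng.integers(2**31)),
            )
            clf.fit(Xfull, y)
            imp = permutation_importance(
                clf, Xfull, y, n_repeats=5, random_state=int(rng.integers(2**31))
            ).importances_mean
        else:
            imp = _forest_importance(Xfull, y, n_trees, rng)
        real_imp = imp[: len(active)]
        shadow_max = imp[len(active) :].max()

        row = np.full(p, np.nan)
        for j, i in enumerate(active):
            row[i] = real_imp[j]
            tested[i] += 1
            if real_imp[j] > shadow_max:
                hits[i] += 1
        history.append(row)

        for i in undecided:
            n, k = tested[i], hits[i]
            if stats.binom.sf(k - 1, n, 0.5) < thr:
                decisions[names[i]] = CONFIRMED
            elif stats.binom.cdf(k, n, 0.5) < thr:
                decisions[names[i]] = REJECTED

    hist = pd.DataFrame(history, columns=names)
    mean_imp = {
        f: (float(np.nanmean(hist[f])) if hist[f].notna().any() else np.nan)
        for f in names
    }
    return BorutaResult(decisions, mean_imp, hist, iterations=len(history))


def ensemble_select(
    X,
    y,
    seed: int,
    n_runs: int = 100,
    retain_threshold: int = 5,
    fold_id: str = "",
    runner: Callable[..., BorutaResult] = boruta_run,
    **boruta_kwargs,
) -> EnsembleSelectionResult:
    """Repeat Boruta ``n_runs`` times; retain features confirmed in strictly
    more than ``retain_threshold`` runs.

    Run seeds derive deterministically from ``seed``; tentative decisions
    count as not selected. Mean importance averages each run's mean
    importance for the feature.
    """
    if not 0 <= retain_threshold <= n_runs:
        raise ValueError("retain_threshold must lie in [0, n_runs]")
    _, names = _as_matrix(X)
    counts = {f: 0 for f in names}
    imps: dict[str, list[float]] = {f: [] for f in names}
    for r in range(n_runs):
        res = runner(X, y, seed=derive_seed(seed, "boruta", r), **boruta_kwargs)
        for f in res.confirmed():
            counts[f] += 1
        for f, v in res.mean_importance.items():
            if np.isfinite(v):
                imps[f].append(v)
    retained = [f for f in names if counts[f] > retain_threshold]
    mean_imp = {f: (float(np.mean(v)) if v else np.nan) for f, v in imps.items()}
    return EnsembleSelectionResult(counts, retained, mean_imp, n_runs, fold_id)


def stability_profile(fold_results: Sequence[EnsembleSelectionResult]) -> StabilityProfile:
    """Stability = % of folds in which each feature was retained; importance
    averaged over folds where it was computed (NaN if never)."""
    if not fold_results:
        raise ValueError("need at least one fold result")
    feats: list[str] = []
    for res in fold_results:
        for f in res.selection_count:
            if f not in feats:
                feats.append(f)
    n = len(fold_results)
    stab = {
        f: 100.0 * sum(f in res.retained for res in fold_results) / n for f in feats
    }
    mean_imp: dict[str, float] = {}
    for f in feats:
        vals = [
            res.mean_importance[f]
            for res in fold_results
            if f in res.retained and np.isfinite(res.mean_importance.get(f, np.nan))
        ]
        mean_imp[f] = float(np.mean(vals)) if vals else np.nan
    return StabilityProfile(stab, mean_imp, n)


def plot_stability(profile: StabilityProfile, path) -> None:
    """Importance vs stability scatter (one point per feature) as SVG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = profile.to_frame().dropna(subset=["mean_importance"])
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(df["stability_pct"], df["mean_importance"], s=18)
    for _, row in df.iterrows():
        ax.annotate(row["feature"], (row["stability_pct"], row["mean_importance"]),
                    fontsize=6, alpha=0.7)
    ax.set_xlabel("stability (% of folds retained)")
    ax.set_ylabel("mean importance")
    ax.set_xlim(-2, 102)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
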