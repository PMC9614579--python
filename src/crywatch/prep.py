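"""Pre-selection feature filters.

Before any model fitting, infant-level feature tables are reduced by three
filters applied in order: (1) drop features with a high rate (> 60%) of
missing values; (2) drop near-zero-variance features (dominant-value
frequency ratio >= 19 together with < 10% distinct values, the common
machine-learning preprocessing convention); (3) greedily drop one member of
every feature pair with absolute Pearson correlation > 0.75 (the member with
the larger mean absolute correlation to all remaining features).

Filtering is applied once to the full table before cross-validation. This
mirrors the staged data-reduction design it implements but carries a mild
information-leakage risk; ``filter_within_folds`` in the model configuration
moves it inside the folds instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilterReport",
    "META_COLUMNS",
    "feature_columns",
    "missingness_filter",
    "near_zero_variance_filter",
    "correlation_filter",
    "filter_features",
]

#: Non-feature columns carried through every table.
META_COLUMNS = ("infant_id", "label", "subgroup")


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


@dataclass
class FilterReport:
    """Audit trail of a filtering pass."""

    removed: list[tuple[str, str, float]] = field(default_factory=list)
    kept: list[str] = field(default_factory=list)
    thresholds: dict[str, float] = field(default_factory=dict)

    def removed_names(self) -> list[str]:
        return [name for name, _, _ in self.removed]

    def extend(self, other: "FilterReport") -> None:
        self.removed.extend(other.removed)
        self.kept = other.kept
        self.thresholds.update(other.thresholds)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.removed, columns=["feature", "reason", "statistic"])


def missingness_filter(table: pd.DataFrame, max_missing: float = 0.60) -> FilterReport:
    """Remove features whose missing fraction is strictly greater than
    ``max_missing`` (default 60%)."""
    report = FilterReport(thresholds={"max_missing": max_missing})
    for col in feature_columns(table):
        frac = float(table[col].isna().mean())
        if frac > max_missing:
            report.removed.append((col, "missingness", frac))
        else:
            report.kept.append(col)
    return report


def near_zero_variance_filter(
    table: pd.DataFrame, freq_ratio: float = 19.0, unique_pct: float = 10.0
) -> FilterReport:
    """Remove near-zero-variance features.

    A feature is removed when the ratio of the most-common to the
    second-most-common value is >= ``freq_ratio`` AND the number of distinct
    values is below ``unique_pct`` percent of the row count. Constant
    features are always removed.
    """
    report = FilterReport(thresholds={"freq_ratio": freq_ratio, "unique_pct": unique_pct})
    n = len(table)
    for col in feature_columns(table):
        vals = table[col].dropna()
        counts = vals.value_counts()
        if len(counts) <= 1:
            report.removed.append((col, "near_zero_variance", np.inf))
            continue
        ratio = counts.iloc[0] / counts.iloc[1]
        distinct_pct = 100.0 * len(counts) / n
        if ratio >= freq_ratio and distinct_pct < unique_pct:
            report.removed.append((col, "near_zero_variance", float(ratio)))
        else:
            report.kept.append(col)
    return report


def correlation_filter(table: pd.DataFrame, cutoff: float = 0.75) -> FilterReport:
    """Greedy removal of excessively intercorrelated features.

    Absolute Pearson correlations are computed on pairwise-complete
    observations. While any pair exceeds ``cutoff`` (strict), the member of
    the worst pair with the larger mean absolute correlation to all other
    remaining features is removed; ties remove the earlier column. The
    procedure is deterministic.
    """
    report = FilterReport(thresholds={"correlation_cutoff": cutoff})
    cols = feature_columns(table)
    if len(cols) < 2:
        report.kept = list(cols)
        return report
    corr = table[cols].corr(method="pearson").abs()
    np.fill_diagonal(corr.values, np.nan)
    corr = corr.fillna(0.0)
    active = list(cols)
    while True:
        sub = corr.loc[active, active]
        max_r = float(sub.values.max()) if len(active) > 1 else 0.0
        if max_r <= cutoff:
            break
        i, j = np.unravel_index(np.nanargmax(sub.values), sub.shape)
        a, b = active[i], active[j]
        mean_a = float(sub.loc[a].mean())
        mean_b = float(sub.loc[b].mean())
        # remove the member more correlated with everything else;
        # tie -> the earlier column in the table
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:
            drop = a if cols.index(a) < cols.index(b) else b
        report.removed.append((drop, "correlation", max_r))
        active.remove(drop)
    report.kept = active
    return report


def filter_features(
    table: pd.DataFrame,
    max_missing: float = 0.60,
    freq_ratio: float = 19.0,
    unique_pct: float = 10.0,
    corr_cutoff: float = 0.75,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply missingness, near-zero-variance and correlation filters in order.

    Returns the reduced table (meta columns retained) and the concatenated
    report. Raises if no feature survives.
    """
    report = FilterReport()

    def subset(t: pd.DataFrame, kept: list[str]) -> pd.DataFrame:
        # preserve the original column order
        keep = set(kept) | set(META_COLUMNS)
        return t[[c for c in t.columns if c in keep]]

    r1 = missingness_filter(table, max_missing)
    report.extend(r1)
    table = subset(table, r1.kept)

    r2 = near_zero_variance_filter(table, freq_ratio, unique_pct)
    report.extend(r2)
    table = subset(table, r2.kept)

    if len(r2.kept) >= 2:
        r3 = correlation_filter(table, corr_cutoff)
        report.extend(r3)
        table = subset(table, r3.kept)

    if not report.kept:
        raise ValueError("all features removed by filtering; nothing to select")
    return table, report
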