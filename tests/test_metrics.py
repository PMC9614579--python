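"""Diagnostic evaluation: AUC vs brute-force pair counting, cutpoint
optimality, exact binomial CIs, kappa, subgroup analyses, group tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crywatch.metrics import (
    ConfusionMatrix,
    compare_groups,
    confusion_at,
    diagnostics,
    evaluate_predictions,
    exact_binomial_ci,
    roc_curve,
    select_cutpoint,
    subgroup_analysis,
)


def brute_force_auc(labels, scores) -> float:
    """Oracle: concordant-pair fraction with ties counted one half."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        r = roc_curve([1, 1, 0, 0], [0.9, 0.8, 0.7, 0.1])
        assert r.auc == 1.0

    def test_swap_gives_075(self):
        assert roc_curve([1, 1, 0, 0], [0.9, 0.7, 0.8, 0.1]).auc == 0.75

    def test_all_equal_gives_half(self):
        assert roc_curve([1, 0, 1, 0], [0.5] * 4).auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1, 1], [0.2, 0.3])

    def test_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        s = rng.random(30)
        r = roc_curve(y, s)
        assert r.fpr[0] == r.tpr[0] == 0.0
        assert r.fpr[-1] == r.tpr[-1] == 1.0
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)

    def test_auc_equals_brute_force_on_random_tables(self):
        rng = np.random.default_rng(1)
        for trial in range(25):
            n = int(rng.integers(4, 20))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.random(n), 2)  # coarse grid forces ties
            assert roc_curve(y, s).auc == pytest.approx(brute_force_auc(y, s))

    def test_delong_ci_contains_auc(self):
        rng = np.random.default_rng(2)
        y = np.r_[np.ones(20, int), np.zeros(30, int)]
        s = np.r_[rng.normal(1, 1, 20), rng.normal(0, 1, 30)]
        r = roc_curve(y, s)
        assert r.auc_ci[0] <= r.auc <= r.auc_ci[1]
        assert 0.0 <= r.auc_ci[0] < r.auc_ci[1] <= 1.0


class TestCutpoint:
    def test_distance_formula_at_paper_operating_point(self):
        # sens .89 / spec .83 lies at distance sqrt(.0121+.0289) from (0,1)
        assert math.hypot(1 - 0.89, 1 - 0.83) == pytest.approx(0.2025, abs=1e-4)

    def test_perfect_point_selected(self):
        r = roc_curve([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        cut = select_cutpoint(r)
        cm = confusion_at([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1], cut)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (2, 2, 0, 0)

    def test_tie_breaks_to_lower_threshold(self):
        # two operating points at equal distance; lower threshold = higher sens
        y = [1, 0]
        s = [0.8, 0.2]
        r = roc_curve(y, s)
        cut = select_cutpoint(r)
        assert cut <= 0.8

    def test_optimality_exhaustive(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 25)
        y[:2] = [0, 1]
        s = rng.random(25)
        r = roc_curve(y, s)
        cut = select_cutpoint(r)
        cm = confusion_at(y, s, cut)
        sens = cm.tp / (cm.tp + cm.fn)
        spec = cm.tn / (cm.tn + cm.fp)
        best = math.hypot(1 - sens, 1 - spec)
        for t in np.unique(s):
            c = confusion_at(y, s, t)
            d = math.hypot(1 - c.tp / (c.tp + c.fn), 1 - c.tn / (c.tn + c.fp))
            assert best <= d + 1e-12


class TestDiagnostics:
    def test_worked_example_matches_printed_metrics(self):
        # 19 treated / 46 controls with sens .89 and spec .83 -> TP 17, TN 38
        rep = diagnostics(ConfusionMatrix(tp=17, fn=2, fp=8, tn=38))
        assert rep.value("accuracy") == pytest.approx(0.85, abs=0.005)
        assert rep.value("ppv") == pytest.approx(0.68, abs=0.005)
        assert rep.value("npv") == pytest.approx(0.95, abs=0.005)
        assert rep.value("kappa") == pytest.approx(0.66, abs=0.005)
        assert rep.estimates["sensitivity"][1] == pytest.approx(0.67, abs=0.005)
        assert rep.estimates["npv"][1] == pytest.approx(0.83, abs=0.005)
        assert rep.estimates["specificity"][1] == pytest.approx(0.69, abs=0.005)

    def test_perfect_classifier(self):
        rep = diagnostics(ConfusionMatrix(tp=19, fn=0, fp=0, tn=46))
        for k in ("accuracy", "sensitivity", "specificity", "ppv", "npv", "kappa"):
            assert rep.value(k) == 1.0

    def test_chance_level_kappa_near_zero(self):
        rng = np.random.default_rng(4)
        kappas = []
        for _ in range(200):
            y = rng.integers(0, 2, 200)
            pred = rng.integers(0, 2, 200)
            cm = ConfusionMatrix(
                tp=int(np.sum((y == 1) & (pred == 1))),
                fn=int(np.sum((y == 1) & (pred == 0))),
                fp=int(np.sum((y == 0) & (pred == 1))),
                tn=int(np.sum((y == 0) & (pred == 0))),
            )
            kappas.append(diagnostics(cm).value("kappa"))
        assert abs(np.mean(kappas)) < 0.02

    def test_kappa_invariant_under_joint_label_swap(self):
        cm = ConfusionMatrix(tp=17, fn=2, fp=8, tn=38)
        swapped = ConfusionMatrix(tp=38, fn=8, fp=2, tn=17)
        assert diagnostics(cm).value("kappa") == pytest.approx(
            diagnostics(swapped).value("kappa")
        )

    def test_zero_denominator_reported_missing(self):
        rep = diagnostics(ConfusionMatrix(tp=0, fn=0, fp=3, tn=7))
        assert np.isnan(rep.value("sensitivity"))


class TestExactBinomialCI:
    @pytest.mark.parametrize(
        "k,n,lo,hi",
        [(17, 19, 0.67, 0.99), (38, 40, 0.83, 0.99)],
    )
    def test_printed_intervals(self, k, n, lo, hi):
        got = exact_binomial_ci(k, n)
        assert got[0] == pytest.approx(lo, abs=0.005)
        assert got[1] == pytest.approx(hi, abs=0.005)

    def test_degenerate_bounds(self):
        assert exact_binomial_ci(0, 10)[0] == 0.0
        assert exact_binomial_ci(10, 10)[1] == 1.0

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            exact_binomial_ci(5, 4)

    def test_coverage_at_95(self):
        # simulated coverage of the exact interval is >= nominal
        rng = np.random.default_rng(5)
        n, reps = 50, 2000
        for p in (0.1, 0.5, 0.9):
            ks = rng.binomial(n, p, size=reps)
            a = 0.05
            lo = np.where(ks == 0, 0.0, stats.beta.ppf(a / 2, ks, n - ks + 1))
            hi = np.where(ks == n, 1.0, stats.beta.ppf(1 - a / 2, ks + 1, n - ks))
            coverage = np.mean((lo <= p) & (p <= hi))
            assert coverage >= 0.95


class TestSubgroup:
    def _preds(self):
        rng = np.random.default_rng(6)
        sub = ["nows"] * 19 + ["exposed_no_nows"] * 7 + ["unexposed"] * 39
        label = [1] * 19 + [0] * 46
        p = np.r_[rng.uniform(0.5, 1, 19), rng.uniform(0, 0.6, 46)]
        return pd.DataFrame({"p_stacked": p, "label": label, "subgroup": sub})

    def test_exclusions_change_n(self):
        preds = self._preds()
        assert subgroup_analysis(preds, "unexposed").n == 26
        assert subgroup_analysis(preds, "exposed_no_nows").n == 58

    def test_no_exclusion_is_identity(self):
        preds = self._preds()
        a = subgroup_analysis(preds, None)
        b = evaluate_predictions(preds["label"], preds["p_stacked"])
        assert a.auc == b.auc and a.cutpoint == b.cutpoint

    def test_single_class_after_exclusion_rejected(self):
        preds = self._preds()[lambda d: d.subgroup != "unexposed"]
        preds = preds[preds.subgroup != "exposed_no_nows"]
        with pytest.raises(ValueError):
            subgroup_analysis(pd.DataFrame(preds), "nows")


class TestCompareGroups:
    def test_identical_groups_zero_effect(self):
        x = np.arange(20, dtype=float)
        df = pd.DataFrame({"label": [0] * 20 + [1] * 20, "v": np.r_[x, x]})
        out = compare_groups(df, covariates=["v"])
        assert out.loc[0, "statistic"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc[0, "cohen_d"] == pytest.approx(0.0, abs=1e-12)

    def test_cohen_d_closed_form(self):
        # means 3.1 vs 3.4, common SD 0.4 -> d = 0.75
        rng = np.random.default_rng(7)
        a = rng.standard_normal(19)
        a = (a - a.mean()) / a.std(ddof=1) * 0.4 + 3.1
        b = rng.standard_normal(46)
        b = (b - b.mean()) / b.std(ddof=1) * 0.4 + 3.4
        df = pd.DataFrame({"label": [1] * 19 + [0] * 46, "bw": np.r_[a, b]})
        out = compare_groups(df, covariates=["bw"])
        assert out.loc[0, "cohen_d"] == pytest.approx(0.75, abs=0.005)
        assert out.loc[0, "test"] == "welch_t"

    def test_categorical_chi_square_with_empty_cell(self):
        df = pd.DataFrame(
            {"label": [1] * 10 + [0] * 10, "use": ["yes"] * 4 + ["no"] * 6 + ["no"] * 10}
        )
        out = compare_groups(df, covariates=["use"])
        assert out.loc[0, "test"] == "chi_square"
        assert np.isfinite(out.loc[0, "p_value"])

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"label": [1] * 5, "v": np.arange(5.0)})
        with pytest.raises(ValueError):
            compare_groups(df, covariates=["v"])
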