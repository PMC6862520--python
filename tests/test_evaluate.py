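"""Validation statistics: rank tests, ROC, regression, detection limits."""

import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from chipdpcr import (
    auroc,
    cohort_summary,
    detection_limit,
    linear_fit,
    mann_whitney_u,
    roc_points,
)
from chipdpcr.evaluate import analyze_dilution_series


class TestMannWhitney:
    def test_exact_p_on_separated_triples(self):
        # fully separated 3 vs 3: p = 2 * (3! 3! / 6!) = 0.1 by enumeration
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_groups_no_separation(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.99

    def test_exact_p_unbalanced_separated(self):
        u, p = mann_whitney_u(list(range(3)), list(range(10, 40)))
        assert u == 0.0
        assert p == pytest.approx(2 / math.comb(33, 3))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestAuroc:
    def test_perfect_separation(self):
        auc, lo, hi = auroc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1], n_boot=200, seed=0)
        assert auc == 1.0
        assert (lo, hi) == (1.0, 1.0)

    def test_all_ties_is_half(self):
        auc, _, _ = auroc([5.0] * 6, [0, 1, 0, 1, 0, 1], n_boot=100, seed=0)
        assert auc == 0.5

    def test_worked_example(self):
        # 4 pos-neg pairs, 3 ordered correctly
        auc, _, _ = auroc([0.2, 0.4, 0.6, 0.8], [0, 1, 0, 1], n_boot=100, seed=0)
        assert auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([1.0, 2.0], [1, 1], n_boot=10, seed=0)

    def test_matches_u_statistic_and_sklearn(self):
        """AUROC equals U_pos/(n_pos*n_neg) and the library estimator on random data."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            scores = rng.normal(size=30)
            labels = (rng.random(30) < 0.4).astype(int)
            if labels.min() == labels.max():
                continue
            auc, _, _ = auroc(scores, labels, n_boot=10, seed=0)
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            u_pos, _ = mann_whitney_u(pos, neg)
            assert auc == pytest.approx(u_pos / (len(pos) * len(neg)))
            assert auc == pytest.approx(roc_auc_score(labels, scores))

    def test_shuffled_labels_near_half(self):
        rng = np.random.default_rng(1)
        scores = np.concatenate([rng.normal(1.5, 0.02, 30), rng.normal(1.0, 0.02, 100)])
        aucs = []
        for _ in range(50):
            labels = np.array([1] * 30 + [0] * 100)
            rng.shuffle(labels)
            aucs.append(auroc(scores, labels, n_boot=2, seed=0)[0])
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)


class TestRocPoints:
    def test_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=40)
        labels = (rng.random(40) < 0.5).astype(int)
        pts = roc_points(scores, labels)
        assert pts[0] == (0.0, 0.0)
        assert pts[-1] == (1.0, 1.0)
        fpr = [a for a, _ in pts]
        tpr = [b for _, b in pts]
        assert all(b >= a for a, b in zip(fpr, fpr[1:]))
        assert all(b >= a for a, b in zip(tpr, tpr[1:]))
        # trapezoid integral reproduces the pair-ordering AUROC
        assert np.trapezoid(tpr, fpr) == pytest.approx(
            auroc(scores, labels, n_boot=2, seed=0)[0]
        )

    def test_perfect_separation_passes_corner(self):
        pts = roc_points([1.0, 5.0], [0, 1])
        assert (0.0, 1.0) in pts


class TestLinearFit:
    def test_exact_line(self):
        slope, intercept, r, r2 = linear_fit([0, 1, 2, 3], [0, 2, 4, 6])
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0)
        assert r2 == pytest.approx(1.0)

    def test_hand_computed_fit(self):
        slope, intercept, _, r2 = linear_fit([0, 1, 2], [0, 1, 3])
        assert slope == pytest.approx(1.5)
        assert intercept == pytest.approx(-1 / 6)
        assert r2 == pytest.approx(81 / 84)

    def test_theoretical_mixture_line(self):
        f = [0.0, 0.05, 0.1, 0.3, 0.5, 0.7, 1.0]
        slope, intercept, _, r2 = linear_fit(f, [1 + x / 2 for x in f])
        assert slope == pytest.approx(0.5)
        assert intercept == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_r_squared_invariant_under_affine_x(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 1, 10)
        y = 1 + 0.5 * x + rng.normal(0, 0.02, 10)
        _, _, _, r2 = linear_fit(x, y)
        _, _, _, r2b = linear_fit(100 * x - 7, y)
        assert r2 == pytest.approx(r2b)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            linear_fit([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            linear_fit([1, 2], [1, 2])


class TestDetectionLimit:
    GRID = [round(0.1 * k, 1) for k in range(1, 11)]

    def _noiseless(self):
        return [[1 + f / 2] * 2 for f in self.GRID]

    def test_cutoffs_on_noiseless_grid(self):
        assert detection_limit(self.GRID, self._noiseless(), 1.068) == pytest.approx(0.2)
        assert detection_limit(self.GRID, self._noiseless(), 1.145) == pytest.approx(0.3)

    def test_unreachable_cutoff(self):
        assert detection_limit(self.GRID, self._noiseless(), 2.0) is None

    def test_monotone_in_cutoff(self):
        limits = [
            detection_limit(self.GRID, self._noiseless(), c)
            for c in (1.01, 1.068, 1.145, 1.3)
        ]
        assert limits == sorted(limits)

    def test_requires_consistent_exceedance(self):
        # a dip at a larger fraction pushes the limit upward
        reps = self._noiseless()
        reps[4] = [1.0, 1.0]  # f = 0.5 fails the cutoff
        assert detection_limit(self.GRID, reps, 1.068) == pytest.approx(0.6)

    def test_ci_lower_mode_is_conservative(self):
        reps = [[1 + f / 2 + d for d in (-0.05, 0.05)] for f in self.GRID]
        mean_limit = detection_limit(self.GRID, reps, 1.145, use_ci_lower=False)
        ci_limit = detection_limit(self.GRID, reps, 1.145, use_ci_lower=True)
        assert ci_limit is None or ci_limit >= mean_limit


def test_analyze_dilution_series_consistency():
    grid = [0.0, 0.1, 0.3, 0.5, 1.0]
    reps = [[1 + f / 2 - 0.004, 1 + f / 2 + 0.004] for f in grid]
    res = analyze_dilution_series("21", grid, reps, cutoff=1.068)
    assert res.r_squared == pytest.approx(res.pearson_r**2)
    assert res.slope == pytest.approx(1.0, abs=1e-6)
    assert res.detection_limit_fraction == pytest.approx(0.3)
    assert all(lo <= m <= hi for lo, m, hi in zip(res.ci_low, res.mean_ratios, res.ci_high))


class TestCohortSummary:
    def _scores(self, ratios_by_label):
        scores, truth = {}, {}
        i = 0
        for label, ratio_list in ratios_by_label.items():
            for r in ratio_list:
                sid = f"s{i}"
                i += 1
                scores[sid] = {"13": 1.0, "18": 1.0, "21": r} if label != "T13" else {
                    "13": r, "18": 1.0, "21": 1.0
                }
                truth[sid] = label
        return scores, truth

    def test_perfect_separation_cohort(self):
        scores, truth = self._scores(
            {"T21": [1.48, 1.50, 1.52], "euploid_female": [0.98, 1.0, 1.01, 0.99, 1.02]}
        )
        ev = cohort_summary(scores, truth, threshold=1.15, n_boot=200, seed=0).per_trisomy["21"]
        assert ev.auroc == 1.0
        assert ev.auroc_ci == (1.0, 1.0)
        assert ev.sensitivity == 1.0 and ev.specificity == 1.0
        assert ev.fp == 0 and ev.fn == 0

    def test_all_euploid_yields_no_entry(self):
        scores, truth = self._scores({"euploid_female": [1.0, 0.99, 1.01]})
        assert cohort_summary(scores, truth, n_boot=50, seed=0).per_trisomy == {}

    def test_missing_truth_rejected(self):
        scores, truth = self._scores({"T21": [1.5], "euploid_female": [1.0]})
        truth.pop("s0")
        with pytest.raises(ValueError):
            cohort_summary(scores, truth, n_boot=50, seed=0)
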