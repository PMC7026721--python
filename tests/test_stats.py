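"""ROC machinery, bootstrap, Kendall's W, ROC regression and tumor geometry."""

import numpy as np
import pytest
from scipy.stats import norm, rankdata

from angioquant.stats import (
    ReaderPanel,
    auc_mann_whitney,
    bootstrap_ci,
    kendalls_w,
    optimal_cutoff,
    placement_values,
    predicted_roc,
    roc_curve,
    roc_regression,
    size_metric_regression,
    tumor_geometry,
)
from angioquant.stats import ROCRegressionFit
from angioquant.synth import simulate_binormal_panel


def pair_counting_auc(scores, labels):
    """Brute-force AUC oracle: (wins + half ties) over all tumor-control pairs."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        c = roc_curve([3, 4, 5, 1, 2], [True, True, True, False, False])
        assert c.auc == pytest.approx(1.0)

    def test_complete_ties_give_half(self):
        c = roc_curve([1, 2, 3, 1, 2, 3], [True, True, True, False, False, False])
        assert c.auc == pytest.approx(0.5)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_curve([1, 2], [True, True])

    def test_trapezoid_equals_pair_counting_on_random_sets(self, rng):
        for _ in range(100):
            n1, n0 = rng.integers(3, 30, size=2)
            scores = np.concatenate(
                [rng.integers(0, 8, n1).astype(float), rng.integers(0, 8, n0).astype(float)]
            )
            labels = np.concatenate([np.ones(n1, bool), np.zeros(n0, bool)])
            c = roc_curve(scores, labels)
            oracle = pair_counting_auc(scores, labels)
            assert abs(c.auc - oracle) < 1e-12
            assert abs(auc_mann_whitney(scores, labels) - oracle) < 1e-12

    def test_curve_monotone(self, rng):
        scores = rng.normal(size=40)
        labels = np.arange(40) < 25
        c = roc_curve(scores, labels)
        assert np.all(np.diff(c.fpr) >= 0)
        assert np.all(np.diff(c.tpr) >= 0)


class TestBootstrap:
    def test_zero_variance_metric(self):
        lo, hi = bootstrap_ci(lambda d: float(np.mean(d)), np.array([5.0, 5.0, 5.0]),
                              n_boot=100, seed=0)
        assert (lo, hi) == (5.0, 5.0)

    def test_deterministic_under_seed(self, rng):
        data = rng.normal(size=30)
        a = bootstrap_ci(lambda d: float(np.mean(d)), data, n_boot=200, seed=42)
        b = bootstrap_ci(lambda d: float(np.mean(d)), data, n_boot=200, seed=42)
        assert a == b

    def test_rejects_tiny_n_boot(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.mean, np.arange(5.0), n_boot=10)


class TestOptimalCutoff:
    def test_perfect_separation_full_sens_spec(self):
        c = roc_curve([3, 4, 5, 1, 2], [True, True, True, False, False])
        _, sens, spec = optimal_cutoff(c, "youden")
        assert (sens, spec) == (1.0, 1.0)

    def test_youden_tie_breaks_toward_specificity(self):
        # exhaustive threshold search oracle gives cutoff 9: sens 2/3, spec 1
        scores = np.array([2, 9, 10, 1, 2, 3], dtype=float)
        labels = np.array([True, True, True, False, False, False])
        thr, sens, spec = optimal_cutoff(roc_curve(scores, labels), "youden")
        assert thr == pytest.approx(9.0)
        assert sens == pytest.approx(2 / 3)
        assert spec == pytest.approx(1.0)

    def test_unattainable_specificity_errors(self):
        # every threshold mislabels a control: max specificity is 2/3
        scores = np.array([5, 6, 7, 1, 2, 7], dtype=float)
        labels = np.array([True, True, True, False, False, False])
        c = roc_curve(scores, labels)
        with pytest.raises(ValueError):
            optimal_cutoff(c, "fix_spec", 0.9)


class TestKendallsW:
    def test_identical_untied_rankings(self):
        scores = np.tile(np.arange(1, 7), (3, 1))
        assert kendalls_w(scores) == pytest.approx(1.0)

    def test_reversed_pair_matches_direct_formula(self):
        scores = np.vstack([np.arange(1, 9), np.arange(8, 0, -1)]).astype(float)
        # direct brute-force evaluation of W from first principles
        ranks = np.vstack([rankdata(r) for r in scores])
        r = ranks.sum(0)
        s = ((r - r.mean()) ** 2).sum()
        k, n = scores.shape
        want = 12 * s / (k**2 * (n**3 - n))
        assert kendalls_w(scores) == pytest.approx(want)
        assert want == pytest.approx(0.0)

    def test_invariant_to_reader_order_and_monotone_transform(self, rng):
        scores = rng.integers(1, 7, size=(5, 20)).astype(float)
        w0 = kendalls_w(scores)
        assert kendalls_w(scores[::-1]) == pytest.approx(w0)
        transformed = scores.copy()
        transformed[2] = np.exp(transformed[2])  # strictly monotone
        assert kendalls_w(transformed) == pytest.approx(w0)

    def test_all_equal_reader_handled_by_tie_correction(self):
        scores = np.vstack([np.arange(1, 6), np.full(5, 3)]).astype(float)
        w = kendalls_w(scores)
        assert 0.0 <= w <= 1.0


class TestPlacementValues:
    def test_open_interval_clamp(self):
        pv = placement_values(np.array([100.0]), np.array([1.0, 2.0, 3.0, 4.0]))
        assert 0 < pv[0] < 1

    def test_midrank_ties(self):
        pv = placement_values(np.array([2.0]), np.array([1.0, 2.0, 3.0, 4.0]))
        assert pv[0] == pytest.approx((2 + 0.5) / 4)


class TestROCRegression:
    def test_beta_recovery_binormal(self):
        rng = np.random.default_rng(11)
        betas = [
            roc_regression(simulate_binormal_panel(beta=0.35, seed=rng), n_boot=0).beta
            for _ in range(40)
        ]
        assert np.mean(betas) == pytest.approx(0.35, rel=0.15)

    def test_predicted_roc_monotone_and_bounded(self):
        fit = roc_regression(simulate_binormal_panel(beta=0.35, seed=3), n_boot=0)
        curve = predicted_roc(fit, 3.0)
        assert np.all(np.diff(curve.tpr) >= -1e-12)
        assert curve.tpr.min() >= 0 and curve.tpr.max() <= 1

    def test_positive_beta_increases_auc_with_diameter(self):
        fit = roc_regression(simulate_binormal_panel(beta=0.35, seed=4), n_boot=0)
        aucs = [predicted_roc(fit, x).auc for x in (1.0, 3.0, 5.0)]
        assert aucs[0] < aucs[1] < aucs[2]

    def test_chance_line_identity(self):
        fit = ROCRegressionFit(
            alpha0=np.zeros(2), alpha1=1.0, beta=0.0, reader_ids=("a", "b"),
            p_grid=np.linspace(0.01, 0.99, 50),
        )
        curve = predicted_roc(fit, 0.0)
        assert curve.auc == pytest.approx(0.5, abs=1e-3)
        grid = np.linspace(0.05, 0.95, 19)
        on_grid = predicted_roc(fit, 0.0, p_grid=grid)
        assert np.allclose(on_grid.tpr[1:-1], grid, atol=1e-9)

    def test_binormal_auc_closed_form(self):
        a, b = 1.2, 1.0
        fit = ROCRegressionFit(
            alpha0=np.array([a]), alpha1=b, beta=0.0, reader_ids=("r",),
            p_grid=np.linspace(0.001, 0.999, 100),
        )
        want = norm.cdf(a / np.sqrt(1 + b**2))
        assert predicted_roc(fit, 0.0).auc == pytest.approx(want, abs=1e-3)

    def test_missing_diameter_raises(self):
        panel = simulate_binormal_panel(seed=0)
        bad = ReaderPanel(
            scores=panel.scores, labels=panel.labels,
            diameters=np.full_like(panel.diameters, np.nan),
        )
        with pytest.raises(ValueError):
            roc_regression(bad, n_boot=0)


class TestSizeRegression:
    def test_exact_line(self):
        x = np.array([1.0, 2, 3, 4])
        slope, intercept, r2, p = size_metric_regression(x, 2 * x + 1)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_r2_equals_squared_pearson(self, rng):
        x = rng.uniform(1, 8, 30)
        y = 3 * x + rng.normal(0, 2, 30)
        _, _, r2, _ = size_metric_regression(x, y)
        assert r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-12)

    def test_null_p_roughly_uniform_under_permutation(self, rng):
        x = rng.uniform(1, 8, 24)
        y = rng.normal(size=24)
        ps = []
        for _ in range(200):
            ps.append(size_metric_regression(x, rng.permutation(y))[3])
        assert 0.35 < np.mean(ps) < 0.65  # uniform mean 0.5

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            size_metric_regression([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestTumorGeometry:
    def test_unit_sphere(self):
        g = tumor_geometry((1.0, 1.0, 1.0))
        assert g.mean_diameter == pytest.approx(1.0)
        assert g.volume == pytest.approx(np.pi / 6)

    def test_geometric_mean(self):
        assert tumor_geometry((2.0, 4.0, 8.0)).mean_diameter == pytest.approx(4.0)

    def test_order_invariance(self):
        assert tumor_geometry((8.0, 2.0, 4.0)) == tumor_geometry((8.0, 2.0, 4.0))
        assert tumor_geometry((8.0, 2.0, 4.0)).volume == pytest.approx(
            tumor_geometry((2.0, 4.0, 8.0)).volume
        )

    def test_nonpositive_axis_errors(self):
        with pytest.raises(ValueError):
            tumor_geometry((1.0, -2.0, 3.0))
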