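"""Kriging boxes, acceptance rules, and surrogate neutrality in the sampler."""

import numpy as np
import pytest

from lj6p.surrogate import (
    SurrogateConfig,
    SurrogateDecision,
    build_box,
    predict,
)


class TestBuildBox:
    def test_quarter_domain_width_at_centre(self):
        box = build_box([0.5, 0.5], [0.0, 0.0], [1.0, 1.0],
                        np.zeros((0, 2)), np.zeros(0))
        np.testing.assert_allclose(box.lower, [0.375, 0.375])
        np.testing.assert_allclose(box.upper, [0.625, 0.625])

    def test_corner_box_clipped(self):
        box = build_box([0.0, 1.0], [0.0, 0.0], [1.0, 1.0],
                        np.zeros((0, 2)), np.zeros(0))
        np.testing.assert_allclose(box.lower, [0.0, 0.875])
        np.testing.assert_allclose(box.upper, [0.125, 1.0])
        assert np.all(box.upper - box.lower <= 0.25 + 1e-12)

    def test_training_set_filtered_to_box(self, rng):
        x = rng.random((200, 2))
        y = rng.random(200)
        box = build_box([0.5, 0.5], [0.0, 0.0], [1.0, 1.0], x, y)
        assert box.n_train > 0
        assert np.all((box.train_x >= box.lower) & (box.train_x <= box.upper))

    def test_empty_training_set_rejects(self):
        box = build_box([0.5], [0.0], [1.0], np.zeros((0, 1)), np.zeros(0))
        dec = predict(box, [0.5])
        assert not dec.accepted and dec.reason == "too_few_points"

    def test_max_train_cap(self, rng):
        cfg = SurrogateConfig(max_train=8)
        x = rng.random((500, 1)) * 0.25 + 0.375
        y = rng.random(500)
        box = build_box([0.5], [0.0], [1.0], x, y, cfg)
        assert box.n_train == 8


def _quadratic_box(n_train=7, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    x = np.linspace(0.4, 0.6, n_train)[:, None]
    y = 3.0 * (x[:, 0] - 0.5) ** 2 + 1.0 + noise * rng.standard_normal(n_train)
    return build_box([0.5], [0.0], [1.0], x, y)


class TestPredict:
    def test_interpolation_at_training_point(self):
        box = _quadratic_box()
        x0 = box.train_x[3, 0]
        dec = predict(box, [x0])
        assert dec.accepted
        assert dec.value == pytest.approx(box.train_y[3], abs=1e-4)  # up to nugget
        assert dec.predicted_error < 1e-3

    def test_quadratic_within_one_percent_on_interior(self):
        box = _quadratic_box()
        for x in np.linspace(0.42, 0.58, 33):
            dec = predict(box, [x])
            truth = 3.0 * (x - 0.5) ** 2 + 1.0
            assert dec.value == pytest.approx(truth, rel=0.01)

    def test_error_rule_rejects_uncertain_prediction(self):
        """Noisy, sparse training data pushes the kriging error above 5%."""
        box = _quadratic_box(n_train=3, noise=0.5, seed=4)
        # 3 points < 2*dim+1 -> too few; grow slightly but keep noise high
        rng = np.random.default_rng(5)
        x = np.array([[0.40], [0.41], [0.5], [0.59], [0.6]])
        y = 0.02 + 2.0 * rng.standard_normal(5)  # near-zero mean, huge spread
        box = build_box([0.5], [0.0], [1.0], x, y)
        dec = predict(box, [0.45])
        assert not dec.accepted
        assert dec.reason in ("error_gt_5pct", "too_few_points")

    def test_small_values_auto_reject_off_nodes(self):
        """Where 5% of |value| falls below the kriging error the rule rejects.

        A noisy objective crossing zero: off training nodes the kriging
        error stays O(noise) while |value| is small, so the relative rule
        cannot be met — the safe behaviour for near-zero objectives.
        """
        rng = np.random.default_rng(7)
        x = np.linspace(0.4, 0.6, 9)[:, None]
        y = 10.0 * (x[:, 0] - 0.5) + 0.5 * rng.standard_normal(9)
        box = build_box([0.5], [0.0], [1.0], x, y)
        dec = predict(box, [0.51])
        assert not dec.accepted and dec.reason == "error_gt_5pct"

    def test_band_rule_rejects_outlier_prediction(self):
        box = _quadratic_box()
        # observed objective pool whose 5-95% band excludes the prediction
        observed = np.linspace(100.0, 200.0, 50)
        dec = predict(box, [0.5], observed_values=observed)
        assert not dec.accepted and dec.reason == "outside_quantile_band"

    def test_band_rule_accepts_inside(self):
        box = _quadratic_box()
        observed = np.linspace(0.0, 3.0, 100)
        dec = predict(box, [0.5], observed_values=observed)
        assert dec.accepted and dec.reason == "ok"

    def test_min_points_rule(self):
        x = np.linspace(0.45, 0.55, 2)[:, None]  # 2 < 2*1+1
        y = np.ones(2)
        box = build_box([0.5], [0.0], [1.0], x, y)
        dec = predict(box, [0.5])
        assert dec.reason == "too_few_points"

    def test_singular_matrix_falls_back(self):
        """Duplicate training points never raise into the sampler."""
        x = np.full((7, 1), 0.5)
        y = np.ones(7)
        box = build_box([0.5], [0.0], [1.0], x, y)
        dec = predict(box, [0.5])
        assert isinstance(dec, SurrogateDecision)

    def test_decision_invariant(self):
        with pytest.raises(ValueError):
            SurrogateDecision(1.0, 0.0, True, "error_gt_5pct")


def test_kriging_mean_matches_sklearn_gpr():
    """Independent cross-check of the interpolant against sklearn's GP."""
    sklearn = pytest.importorskip("sklearn")
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import RBF, ConstantKernel

    rng = np.random.default_rng(3)
    x = np.sort(rng.random(12))[:, None] * 0.25 + 0.375
    y = np.sin(20 * x[:, 0]) + 2.0
    box = build_box([0.5], [0.0], [1.0], x, y)
    box.fit()
    # sklearn fit with the fitted length-scale (box-scaled coords)
    ls = box._fit.ls * 0.25  # back to original coordinates
    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(ls, (ls, ls))
    gpr = GaussianProcessRegressor(kernel=kernel, alpha=1e-8, normalize_y=True)
    gpr.fit(x, y)
    for xq in np.linspace(0.42, 0.58, 9):
        ours = predict(box, [xq]).value
        theirs = float(gpr.predict(np.array([[xq]]))[0])
        assert ours == pytest.approx(theirs, abs=0.02)


class TestSamplerIntegration:
    def test_accounting_invariant(self):
        """Queries split exactly into accepted + rejections; every rejection
        and out-of-box candidate triggers exactly one true evaluation."""
        from lj6p.experiments import _std_normal_logpdf
        from lj6p.likelihood import PriorSpec
        from lj6p.tmcmc import TMCMCConfig, run_tmcmc

        support = PriorSpec(("x",), np.array([-10.0]), np.array([10.0]))

        def log_lik(x):
            x = np.atleast_2d(x)[:, 0]
            return -0.5 * (x / 0.2) ** 2

        def sample_prior(rng, n):
            return np.clip(rng.standard_normal((n, 1)), -10, 10)

        cfg = TMCMCConfig(n_samples=300, seed=21)
        ens = run_tmcmc(_std_normal_logpdf, log_lik, support, cfg,
                        surrogate=SurrogateConfig(), sample_prior=sample_prior)
        s = ens.surrogate_stats
        assert s["queries"] == (s["accepted"] + s["rejected_error"]
                                + s["rejected_band"] + s["rejected_few"])
        rejected = s["queries"] - s["accepted"]
        assert s["true_evaluations"] == cfg.n_samples + rejected + s["outside_box"]

    def test_surrogate_neutral_on_conjugate_evidence(self):
        from lj6p.experiments import surrogate_neutrality_study

        res = surrogate_neutrality_study(n_seeds=3, n_samples=500)
        assert res["mean_gap"] < 0.1
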