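"""Tempered sampling, stage control, evidence, and ensemble summaries."""

import numpy as np
import pytest
from scipy.stats import kstest, norm

from lj6p.exceptions import (
    DegenerateLikelihoodError,
    InvalidInputError,
    NonConvergenceError,
)
from lj6p.likelihood import PriorSpec
from lj6p.tmcmc import (
    PosteriorEnsemble,
    TMCMCConfig,
    load_ensemble,
    mpv,
    next_exponent,
    quantiles,
    run_tmcmc,
    save_ensemble,
)

_HALF_LOG_2PI = 0.5 * np.log(2 * np.pi)


def _box(lo, hi, d=1, names=None):
    names = names or tuple(f"x{i}" for i in range(d))
    return PriorSpec(names, np.full(d, float(lo)), np.full(d, float(hi)))


class TestNextExponent:
    def test_identical_loglikelihoods_jump_to_one(self):
        assert next_exponent(0.0, np.zeros(50)) == 1.0
        assert next_exponent(0.3, np.full(50, -3.7)) == 1.0

    def test_two_sample_bisection_matches_grid_oracle(self):
        """CoV((1, e^(-10 dp))) = 1 solved independently on a dense grid."""
        ll = np.array([0.0, -10.0])
        got = next_exponent(0.0, ll, target_cov=1.0)

        def cov(dp):
            w = np.exp(dp * (ll - ll.max()))
            return w.std(ddof=1) / w.mean()

        grid = np.linspace(1e-6, 1.0, 2_000_001)
        covs = np.array([np.sqrt(2) * (1 - np.exp(-10 * g)) / (1 + np.exp(-10 * g))
                         for g in grid])
        oracle = grid[np.argmin(np.abs(covs - 1.0))]
        assert got == pytest.approx(oracle, abs=1e-5)
        assert cov(got) == pytest.approx(1.0, abs=1e-6)

    def test_clamps_near_one(self):
        rng = np.random.default_rng(0)
        assert next_exponent(0.999, rng.normal(size=100) * 1e-3) == 1.0

    def test_requires_current_below_one(self):
        with pytest.raises(InvalidInputError):
            next_exponent(1.0, np.zeros(10))


class TestRunTMCMC:
    def test_constant_likelihood_gives_prior_and_log_c(self):
        """Tempering is vacuous: posterior = prior, evidence = c."""
        support = _box(0.0, 1.0)
        c = -3.21

        def log_lik(x):
            return np.full(np.atleast_2d(x).shape[0], c)

        ens = run_tmcmc(support.log_pdf, log_lik, support,
                        TMCMCConfig(n_samples=2000, seed=5))
        assert ens.log_evidence == pytest.approx(c, abs=1e-6)
        stat = kstest(ens.samples[:, 0], "uniform").statistic
        assert stat < 0.05

    def test_conjugate_evidence_1d(self):
        from lj6p.experiments import CONJUGATE_LOG_EVIDENCE, conjugate_evidence_trial

        zs = [conjugate_evidence_trial(seed, 2000) for seed in range(5)]
        assert np.mean(np.abs(np.array(zs) - CONJUGATE_LOG_EVIDENCE)) < 0.05

    def test_conjugate_posterior_mean_2d(self):
        """Known posterior: mean = datum / 2 for N(0,I) prior, N(x,I) likelihood."""
        support = _box(-10.0, 10.0, d=2)
        datum = np.array([1.0, 2.0])

        def log_prior(x):
            x = np.atleast_2d(x)
            return -0.5 * np.sum(x ** 2, axis=1) - 2 * _HALF_LOG_2PI

        def log_lik(x):
            x = np.atleast_2d(x)
            return -0.5 * np.sum((x - datum) ** 2, axis=1) - 2 * _HALF_LOG_2PI

        def sample_prior(rng, n):
            return np.clip(rng.standard_normal((n, 2)), -10, 10)

        ens = run_tmcmc(log_prior, log_lik, support,
                        TMCMCConfig(n_samples=2000, seed=7),
                        sample_prior=sample_prior)
        post_sd = np.sqrt(0.5)
        mc_se = post_sd / np.sqrt(len(ens))  # ignores autocorrelation; 3 se below
        # allow inflation for correlated samples: use 3 x (5 x mc_se)
        np.testing.assert_allclose(ens.samples.mean(axis=0), datum / 2,
                                   atol=15 * mc_se)

    def test_nested_box_evidence_consistency(self):
        """Shrinking the prior box around the mode raises log Z by ~ln(volume ratio)."""
        def log_lik(x):
            x = np.atleast_2d(x)[:, 0]
            return -0.5 * x ** 2 - _HALF_LOG_2PI

        results = {}
        for half in (5.0, 2.0):
            support = _box(-half, half)
            ens = run_tmcmc(support.log_pdf, log_lik, support,
                            TMCMCConfig(n_samples=2000, seed=11))
            results[half] = ens.log_evidence
        got = results[2.0] - results[5.0]
        mass = lambda a: 2 * norm.cdf(a) - 1
        analytic = np.log(mass(2.0) / 4) - np.log(mass(5.0) / 10)
        assert got == pytest.approx(analytic, abs=0.1)

    def test_determinism(self):
        support = _box(0.0, 1.0)

        def log_lik(x):
            x = np.atleast_2d(x)[:, 0]
            return -0.5 * ((x - 0.5) / 0.05) ** 2

        cfg = TMCMCConfig(n_samples=500, seed=99)
        a = run_tmcmc(support.log_pdf, log_lik, support, cfg)
        b = run_tmcmc(support.log_pdf, log_lik, support, cfg)
        assert np.array_equal(a.samples, b.samples)
        assert a.log_evidence == b.log_evidence
        assert a.stage_exponents == b.stage_exponents

    def test_samples_stay_in_support(self):
        support = _box(0.0, 1.0)

        def log_lik(x):
            x = np.atleast_2d(x)[:, 0]
            return -0.5 * (x / 0.02) ** 2  # mode at the boundary

        ens = run_tmcmc(support.log_pdf, log_lik, support,
                        TMCMCConfig(n_samples=500, seed=3))
        assert np.all(support.contains(ens.samples))

    def test_degenerate_likelihood_raises(self):
        support = _box(0.0, 1.0)

        def log_lik(x):
            return np.full(np.atleast_2d(x).shape[0], -np.inf)

        with pytest.raises(DegenerateLikelihoodError):
            run_tmcmc(support.log_pdf, log_lik, support, TMCMCConfig(n_samples=200, seed=1))

    def test_nonconvergence_carries_partial_state(self):
        support = _box(0.0, 1.0)

        def log_lik(x):
            x = np.atleast_2d(x)[:, 0]
            return -0.5 * ((x - 0.5) / 1e-5) ** 2

        with pytest.raises(NonConvergenceError) as exc:
            run_tmcmc(support.log_pdf, log_lik, support,
                      TMCMCConfig(n_samples=200, seed=1, max_stages=2))
        assert "exponents" in exc.value.partial

    def test_config_validation(self):
        with pytest.raises(InvalidInputError):
            TMCMCConfig(n_samples=50)
        with pytest.raises(InvalidInputError):
            TMCMCConfig(beta=0.0)
        with pytest.raises(InvalidInputError):
            TMCMCConfig(target_cov=-1.0)
        with pytest.raises(InvalidInputError):
            TMCMCConfig(chain_steps=0)


def _toy_ensemble(samples, lp, ll):
    samples = np.asarray(samples, dtype=float).reshape(len(lp), -1)
    return PosteriorEnsemble(
        samples=samples,
        param_names=tuple(f"x{i}" for i in range(samples.shape[1])),
        log_priors=np.asarray(lp, dtype=float),
        log_likelihoods=np.asarray(ll, dtype=float),
        log_evidence=0.0,
        stage_exponents=[0.0, 1.0],
        seed=0,
    )


class TestSummaries:
    def test_mpv_single_sample(self):
        ens = _toy_ensemble([[2.0]], [0.0], [1.0])
        assert mpv(ens)[0] == 2.0

    def test_mpv_dominant_sample_and_ties(self):
        ens = _toy_ensemble([[1.0], [2.0], [3.0]], [0, 0, 0], [1.0, 5.0, 5.0])
        assert mpv(ens)[0] == 2.0  # tie broken at lowest index

    def test_quantiles_identical_samples(self):
        ens = _toy_ensemble([[3.3]] * 10, np.zeros(10), np.zeros(10))
        q = quantiles(ens, [0.05, 0.5, 0.95])
        np.testing.assert_allclose(q, 3.3)

    def test_quantile_interpolation_convention(self):
        vals = np.arange(1, 101, dtype=float)
        ens = _toy_ensemble(vals[:, None], np.zeros(100), np.zeros(100))
        assert quantiles(ens, [0.5])[0, 0] == pytest.approx(50.5)

    def test_quantile_ordering(self, rng):
        vals = rng.normal(size=200)
        ens = _toy_ensemble(vals[:, None], np.zeros(200), np.zeros(200))
        q = quantiles(ens, [0.05, 0.95])
        assert q[0, 0] <= q[1, 0]

    def test_quantile_level_validation(self):
        ens = _toy_ensemble([[1.0]], [0.0], [0.0])
        with pytest.raises(InvalidInputError):
            quantiles(ens, [0.0])


class TestEnsembleInvariantsAndIO:
    def test_stage_exponent_validation(self):
        with pytest.raises(InvalidInputError):
            _ = PosteriorEnsemble(
                samples=np.zeros((1, 1)), param_names=("x",),
                log_priors=np.zeros(1), log_likelihoods=np.zeros(1),
                log_evidence=0.0, stage_exponents=[0.0, 0.5], seed=0,
            )

    def test_save_load_roundtrip(self, tmp_path, dimer_dataset):
        from lj6p.calibrate import calibrate
        from lj6p.likelihood import MODEL_LJ6_P

        data, _ = dimer_dataset
        ens = calibrate(data, MODEL_LJ6_P, config=TMCMCConfig(n_samples=200, seed=1))
        save_ensemble(ens, tmp_path / "post")
        back = load_ensemble(tmp_path / "post")
        np.testing.assert_array_equal(back.samples, ens.samples)
        np.testing.assert_array_equal(back.log_likelihoods, ens.log_likelihoods)
        assert back.log_evidence == ens.log_evidence
        assert back.param_names == ens.param_names
        assert back.config == ens.config
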