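"""Gaussian data model, uniform prior boxes, and conditional prior families."""

import numpy as np
import pytest
from scipy.integrate import quad

from lj6p.exceptions import InvalidInputError
from lj6p.likelihood import (
    MODEL_LJ6_12,
    MODEL_LJ6_P,
    ParamVector,
    PriorSpec,
    conditional_log_prior,
    default_prior,
    gaussian_log_likelihood_batch,
    get_family,
    log_likelihood,
    physical_prior,
)
from lj6p.potential import LJParams


class TestParamVector:
    def test_roundtrip(self):
        pv = ParamVector(LJParams(0.252, 3.37, 12.703), 0.006, MODEL_LJ6_P)
        back = ParamVector.from_array(pv.to_array(), MODEL_LJ6_P)
        assert back == pv
        assert pv.names == ("epsilon", "sigma", "p", "sigma_n")

    def test_lj612_fixes_p(self):
        pv = ParamVector.from_array([0.3, 3.4, 0.1], MODEL_LJ6_12)
        assert pv.lj.p == 12.0
        with pytest.raises(InvalidInputError):
            ParamVector(LJParams(0.3, 3.4, 10.0), 0.1, MODEL_LJ6_12)

    def test_sigma_n_positive(self):
        with pytest.raises(InvalidInputError):
            ParamVector(LJParams(0.3, 3.4, 12.0), 0.0, MODEL_LJ6_12)


class TestLogLikelihood:
    def test_zero_case(self):
        """N=1, d=f, sigma_n = 1/sqrt(2 pi): the normalization cancels exactly."""
        assert log_likelihood([1.0], [1.0], 1 / np.sqrt(2 * np.pi)) == pytest.approx(0.0, abs=1e-14)

    def test_single_residual(self):
        expected = -0.5 * np.log(2 * np.pi) - 0.5
        assert log_likelihood([1.0], [0.0], 1.0) == pytest.approx(expected, rel=1e-14)

    def test_two_residuals(self):
        expected = -np.log(2 * np.pi) - 2.5
        assert log_likelihood([1.0, 2.0], [0.0, 0.0], 1.0) == pytest.approx(expected, rel=1e-14)

    def test_errors(self):
        with pytest.raises(InvalidInputError):
            log_likelihood([1.0, 2.0], [1.0], 1.0)
        with pytest.raises(InvalidInputError):
            log_likelihood([1.0], [np.inf], 1.0)
        with pytest.raises(InvalidInputError):
            log_likelihood([1.0], [1.0], 0.0)

    def test_sigma_n_profile_maximum(self):
        """The likelihood is maximized over sigma_n at sqrt(SSE/N)."""
        d = np.array([1.0, 2.0, 0.5, -1.0])
        f = np.array([0.8, 2.5, 0.0, -1.2])
        sse = np.sum((d - f) ** 2)
        s_star = np.sqrt(sse / d.size)
        at_star = log_likelihood(d, f, s_star)
        for s in (0.5 * s_star, 0.9 * s_star, 1.1 * s_star, 2 * s_star):
            assert log_likelihood(d, f, s) < at_star

    def test_batch_matches_scalar(self):
        d = np.array([1.0, 2.0, 3.0])
        curves = np.array([[1.1, 2.2, 2.9], [0.0, 0.0, 0.0]])
        sn = np.array([0.3, 1.7])
        batch = gaussian_log_likelihood_batch(d, curves, sn)
        for i in range(2):
            assert batch[i] == pytest.approx(log_likelihood(d, curves[i], sn[i]), rel=1e-13)


class TestUniformPrior:
    def test_interior_constant(self):
        spec = default_prior(MODEL_LJ6_12)
        expected = -(np.log(2.95) + np.log(1.0) + np.log(1 - 1e-6))
        x1 = np.array([0.3, 3.4, 0.1])
        x2 = np.array([2.0, 3.9, 0.9])
        assert spec.log_pdf(x1)[0] == pytest.approx(expected, rel=1e-12)
        assert spec.log_pdf(x1)[0] == spec.log_pdf(x2)[0]

    def test_outside_is_minus_inf(self):
        spec = default_prior(MODEL_LJ6_12)
        assert spec.log_pdf(np.array([0.3, 4.5, 0.1]))[0] == -np.inf

    def test_lj6p_box_bounds(self):
        spec = default_prior(MODEL_LJ6_P)
        np.testing.assert_allclose(spec.lower, [0.05, 3.0, 6.01, 1e-6])
        np.testing.assert_allclose(spec.upper, [10.0, 4.0, 15.0, 1.0])

    def test_invalid_bounds(self):
        with pytest.raises(InvalidInputError):
            PriorSpec(("a",), np.array([1.0]), np.array([1.0]))
        with pytest.raises(InvalidInputError):
            PriorSpec(("p",), np.array([5.0]), np.array([15.0]))

    def test_sampler_respects_box(self, rng):
        spec = default_prior(MODEL_LJ6_P)
        x = spec.sample(rng, 500)
        assert np.all(spec.contains(x))


class TestConditionalFamilies:
    @pytest.fixture
    def base(self):
        return physical_prior(default_prior(MODEL_LJ6_P))

    def test_uniform_family_reduces_to_base_prior(self, base, rng):
        fam = get_family("uniform_box", base)
        psi = fam.base_psi()
        theta = base.sample(rng, 50)
        got = conditional_log_prior(theta, psi, fam)
        np.testing.assert_allclose(got, base.log_pdf(theta), rtol=1e-12)

    def test_truncnorm_wide_scale_approaches_uniform(self, base):
        fam = get_family("independent_truncated_normal", base)
        loc = 0.5 * (base.lower + base.upper)
        psi = np.concatenate([loc, 1e3 * base.widths])
        theta = np.vstack([loc, base.lower + 0.1 * base.widths])
        got = fam.log_pdf(theta, psi)
        expected = base.log_pdf(theta)
        np.testing.assert_allclose(np.exp(got - expected), 1.0, rtol=1e-2)

    def test_truncnorm_mode_property(self, base, rng):
        fam = get_family("independent_truncated_normal", base)
        loc = 0.5 * (base.lower + base.upper)
        psi = np.concatenate([loc, 0.1 * base.widths])
        at_mode = fam.log_pdf(loc[None, :], psi)[0]
        others = base.sample(rng, 100)
        assert np.all(fam.log_pdf(others, psi) <= at_mode + 1e-12)

    def test_inadmissible_psi_rejected(self, base):
        fam = get_family("independent_truncated_normal", base)
        loc = 0.5 * (base.lower + base.upper)
        bad = np.concatenate([loc, np.zeros(base.dim)])  # zero scales
        with pytest.raises(InvalidInputError):
            conditional_log_prior(loc[None, :], bad, fam)

    @pytest.mark.parametrize("family", ["uniform_box", "independent_truncated_normal"])
    def test_density_normalized_over_box(self, base, family):
        """Quadrature identity for separable densities integrating to 1.

        For f(theta) = prod_j f_j(theta_j) with each factor normalized over
        its interval, prod_i integral_x f(mid with x at slot i) dx equals
        f(mid)^(d-1).  This pins the joint normalization to 1 within 1e-6
        per factor.
        """
        fam = get_family(family, base)
        if family == "uniform_box":
            psi = np.concatenate(
                [base.lower + 0.1 * base.widths, base.upper - 0.2 * base.widths]
            )
            mid = np.concatenate([[0.0], [0.0], [0.0]]) + 0.5 * (
                psi[: base.dim] + psi[base.dim:]
            )
        else:
            psi = np.concatenate([base.lower + 0.3 * base.widths, 0.15 * base.widths])
            mid = 0.5 * (base.lower + base.upper)
        log_f_mid = fam.log_pdf(mid[None, :], psi)[0]
        log_prod = 0.0
        for i in range(base.dim):
            def slice_density(x, i=i):
                theta = mid.copy()
                theta[i] = x
                v = fam.log_pdf(theta[None, :], psi)[0]
                return float(np.exp(v)) if np.isfinite(v) else 0.0

            val, _ = quad(slice_density, base.lower[i], base.upper[i], limit=400)
            assert val > 0
            log_prod += np.log(val)
        assert log_prod == pytest.approx((base.dim - 1) * log_f_mid, abs=3e-6)

    def test_unknown_family(self, base):
        with pytest.raises(InvalidInputError):
            get_family("cauchy", base)
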