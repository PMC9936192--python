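"""Analytic model layer: closed forms against independent quadrature oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import norm

import gelstruct as gs
from gelstruct import InvalidParameterError


# ---------------------------------------------------------------------------
# parameter containers


class TestParams:
    def test_fibre_derivations(self):
        f = gs.FibreParams(theta=0.01, D_F=2.0, L_F=40.0)
        assert f.eta == pytest.approx(0.8)
        assert f.phi_F == pytest.approx(1 - math.exp(-0.8))
        g = gs.FibreParams(eta=0.8, D_F=2.0, L_F=40.0)
        assert g.theta == pytest.approx(0.01)
        assert gs.FibreParams(eta=1.0, D_F=2.0).is_long_fibre

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(eta=-0.1, D_F=2.0),
            dict(eta=1.0, D_F=-1.0),
            dict(eta=1.0, D_F=2.0, L_F=1.0),  # L_F <= D_F
            dict(eta=1.0, theta=0.1, D_F=2.0, L_F=40.0),  # both given
            dict(D_F=2.0, L_F=40.0),  # neither given
            dict(theta=0.1, D_F=2.0),  # theta with infinite L_F
        ],
    )
    def test_fibre_invalid(self, kwargs):
        with pytest.raises(InvalidParameterError):
            gs.FibreParams(**kwargs)

    def test_aggregate_threshold(self):
        a = gs.AggregateParams(phi_A=0.3, L_A=8.0)
        assert 1 - norm.cdf(a.alpha) == pytest.approx(0.3, rel=1e-12)
        for bad in (0.0, 1.0, -0.2):
            with pytest.raises(InvalidParameterError):
                gs.AggregateParams(phi_A=bad, L_A=8.0)

    def test_curve_grid_validation(self):
        with pytest.raises(InvalidParameterError):
            gs.CorrelationCurve(r=[0.0, 1.0, 1.0], C=[1, 2, 3])
        with pytest.raises(InvalidParameterError):
            gs.CorrelationCurve(r=[0.5, 1.0], C=[1, 2])

    def test_histogram_counts(self):
        h = gs.IntensityHistogram(counts=np.eye(1, 256, 7, dtype=int)[0] * 42)
        assert h.n_pixels == 42


# ---------------------------------------------------------------------------
# fibre density / Poisson overlap


def test_fibre_density_values():
    assert gs.fibre_density(0.0) == 0.0
    assert gs.fibre_density(math.log(2)) == pytest.approx(0.5, rel=1e-12)
    # inverting the grey-tone CFM 2 mg/mL fibre density
    assert gs.fibre_density(-math.log(1 - 0.73)) == pytest.approx(0.73, rel=1e-12)
    with pytest.raises(InvalidParameterError):
        gs.fibre_density(-1.0)


def test_poisson_overlap():
    assert gs.poisson_overlap_pmf(0, 1.7) == pytest.approx(math.exp(-1.7))
    assert gs.poisson_overlap_pmf(1, 1.0) == pytest.approx(math.exp(-1.0))
    # total overlap probability for k >= 1 is the fibre density
    k = np.arange(1, 200)
    assert gs.poisson_overlap_pmf(k, 1.3).sum() == pytest.approx(gs.fibre_density(1.3), rel=1e-10)


# ---------------------------------------------------------------------------
# rectangle covariogram


def covariogram_quad(r, D, L):
    """Adaptive-quadrature oracle for the isotropized rectangle covariogram."""
    f = lambda t: max(1 - r / D * math.sin(t), 0.0) * (
        max(1 - r / L * math.cos(t), 0.0) if math.isfinite(L) else 1.0
    )
    val, _ = quad(f, 0.0, math.pi / 2, epsabs=1e-9, limit=200)
    return 2.0 / math.pi * val


class TestRectangleCovariogram:
    def test_normalization_at_zero(self):
        assert gs.rectangle_covariogram(0.0, 1.7, 33.0) == 1.0
        assert gs.rectangle_covariogram(0.0, 0.5) == 1.0

    def test_long_fibre_closed_forms(self):
        # r = D/2: (2/pi) * (pi/2 - 1/2) = 1 - 1/pi
        assert gs.rectangle_covariogram(1.0, 2.0) == pytest.approx(1 - 1 / math.pi, rel=1e-10)
        # r = 10 D: (2/pi) * [asin(0.1) - 10 (1 - sqrt(1 - 0.01))]
        expect = 2 / math.pi * (math.asin(0.1) - 10 * (1 - math.sqrt(0.99)))
        assert gs.rectangle_covariogram(20.0, 2.0) == pytest.approx(expect, rel=1e-10)
        # the long-fibre branch is the L -> infinity limit of the finite branch
        assert gs.rectangle_covariogram(3.0, 2.0) == pytest.approx(
            covariogram_quad(3.0, 2.0, 1e6 * 2.0), abs=1e-6
        )

    @pytest.mark.parametrize("L_F", [8.0, 40.0, math.inf])
    def test_matches_quadrature_oracle(self, L_F):
        D = 1.9
        for r in [0.0, 0.3, 1.2, 1.9, 3.7, 7.5, 20.0, 50.0]:
            assert gs.rectangle_covariogram(r, D, L_F) == pytest.approx(
                covariogram_quad(r, D, L_F), abs=1e-8
            )

    @given(
        D=st.floats(0.2, 10.0),
        ratio=st.floats(1.5, 100.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_non_increasing(self, D, ratio):
        r = np.linspace(0, 5 * D * ratio, 300)
        K = gs.rectangle_covariogram(r, D, D * ratio)
        assert K[0] == pytest.approx(1.0)
        assert np.all(np.diff(K) <= 1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            gs.rectangle_covariogram(-0.1, 2.0)
        with pytest.raises(InvalidParameterError):
            gs.rectangle_covariogram(1.0, 0.0)


# ---------------------------------------------------------------------------
# Boolean and clipped-GF covariances


class TestBooleanCovariance:
    def test_limits(self):
        f = gs.FibreParams(eta=0.8, D_F=2.0, L_F=40.0)
        assert gs.boolean_covariance(0.0, f) == pytest.approx(f.phi_F, rel=1e-12)
        assert gs.boolean_covariance(1e6, f) == pytest.approx(f.phi_F**2, rel=1e-10)

    @given(eta=st.floats(0.05, 4.0), D=st.floats(0.3, 5.0))
    @settings(max_examples=30, deadline=None)
    def test_bounds_and_monotonicity(self, eta, D):
        f = gs.FibreParams(eta=eta, D_F=D)
        r = np.linspace(0, 20 * D, 200)
        C = gs.boolean_covariance(r, f)
        assert np.all(C <= f.phi_F + 1e-12)
        assert np.all(C >= f.phi_F**2 - 1e-12)
        assert np.all(np.diff(C) <= 1e-12)


class TestClippedGF:
    def test_limit_identities(self):
        a = gs.AggregateParams(phi_A=0.72, L_A=8.2)
        assert gs.clipped_gf_covariance(0.0, a) == pytest.approx(a.phi_A, rel=1e-8)
        assert gs.clipped_gf_covariance(1e9, a) == pytest.approx(a.phi_A**2, rel=1e-8)

    def test_arcsine_closed_form_at_half(self):
        a = gs.AggregateParams(phi_A=0.5, L_A=8.0)
        r = np.linspace(0, 40, 50)
        g = np.exp(-0.5 * (r / 8.0) ** 2)
        closed = 0.25 + np.arcsin(g) / (2 * np.pi)
        assert gs.clipped_gf_covariance(r, a) == pytest.approx(closed, rel=1e-8)

    @pytest.mark.parametrize("phi_A", [0.1, 0.32, 0.72, 0.9])
    def test_matches_quadrature_oracle(self, phi_A):
        a = gs.AggregateParams(phi_A=phi_A, L_A=5.0)
        alpha = a.alpha
        for r in [0.0, 2.0, 5.0, 12.0]:
            g = math.exp(-0.5 * (r / 5.0) ** 2)
            val, _ = quad(
                lambda s: math.exp(-alpha**2 / (1 + s)) / math.sqrt(1 - s * s),
                0.0,
                g,
                epsabs=1e-11,
                limit=400,
                points=[g] if g < 1 else None,
            )
            expect = phi_A**2 + val / (2 * math.pi)
            assert gs.clipped_gf_covariance(r, a) == pytest.approx(expect, rel=1e-8)

    def test_rejects_invalid_field_correlation(self):
        a = gs.AggregateParams(phi_A=0.5, L_A=5.0)
        with pytest.raises(InvalidParameterError):
            gs.clipped_gf_covariance(1.0, a, g_w=lambda r: 1.5 * np.ones_like(r))


def test_two_scale_factorization():
    f = gs.FibreParams(eta=1.427, D_F=1.9)
    a = gs.AggregateParams(phi_A=0.72, L_A=8.2)
    r = np.linspace(0, 50, 100)
    C = gs.two_scale_covariance(r, f, a)
    assert C[0] == pytest.approx(f.phi_F * a.phi_A, rel=1e-8)
    expect = np.asarray(gs.boolean_covariance(r, f)) * np.asarray(gs.clipped_gf_covariance(r, a))
    np.testing.assert_allclose(C, expect, rtol=1e-12)
    assert gs.two_scale_covariance(1e9, f, a) == pytest.approx((f.phi_F * a.phi_A) ** 2, rel=1e-8)


# ---------------------------------------------------------------------------
# grey-tone layer


@pytest.fixture
def greytone_params():
    return gs.GreyToneParams(
        fibre=gs.FibreParams(eta=1.2, D_F=2.0, L_F=40.0),
        aggregate=gs.AggregateParams(phi_A=0.6, L_A=8.0),
        b=9.0,
        Delta=15.0,
        sigma=5.0,
    )


class TestGreyTone:
    def test_mean_intensity(self, greytone_params):
        p = greytone_params
        assert gs.mean_intensity(p) == pytest.approx(9.0 + 1.2 * 0.6 * 15.0)
        p0 = gs.GreyToneParams(
            fibre=p.fibre, aggregate=gs.AggregateParams(phi_A=1e-9, L_A=8.0),
            b=7.0, Delta=15.0, sigma=5.0,
        )
        assert gs.mean_intensity(p0) == pytest.approx(7.0, abs=1e-6)

    def test_correlation_decorrelates(self, greytone_params):
        mean = gs.mean_intensity(greytone_params)
        assert gs.greytone_correlation(1e6, greytone_params) == pytest.approx(mean**2, rel=1e-10)

    def test_noise_only_at_zero_lag(self, greytone_params):
        r = np.array([0.0, 1e-9, 0.5])
        C = gs.greytone_correlation(r, greytone_params)
        assert C[0] - C[1] == pytest.approx(greytone_params.sigma**2, rel=1e-6)

    def test_pdf_normalization_and_mean(self, greytone_params):
        I = np.linspace(-150.0, 400.0, 220_001)
        pdf = gs.intensity_pdf(I, greytone_params)
        assert np.trapezoid(pdf, I) == pytest.approx(1.0, abs=1e-9)
        assert np.trapezoid(I * pdf, I) == pytest.approx(
            gs.mean_intensity(greytone_params), rel=1e-9
        )

    def test_variance_matches_correlation_jump(self, greytone_params):
        # cross-equation consistency: Var[I] from the mixture equals C(0) - <I>^2
        p = greytone_params
        I = np.linspace(-150.0, 400.0, 220_001)
        pdf = gs.intensity_pdf(I, p)
        m1 = np.trapezoid(I * pdf, I)
        var = np.trapezoid(I * I * pdf, I) - m1 * m1
        jump = gs.greytone_correlation(0.0, p) - gs.mean_intensity(p) ** 2
        assert var == pytest.approx(jump, rel=1e-8)

    def test_component_weights_are_poisson(self, greytone_params):
        from gelstruct.models import _mixture_components

        p = greytone_params
        _, weights = _mixture_components(p)
        fibre_w = weights[1:]
        rel = fibre_w / fibre_w.sum()
        k = np.arange(1, fibre_w.size + 1)
        expect = gs.poisson_overlap_pmf(k, p.fibre.eta) / p.fibre.phi_F
        np.testing.assert_allclose(rel, expect, rtol=1e-9)

    def test_quantized_probabilities_sum_to_one(self, greytone_params):
        probs = gs.quantized_intensity_probabilities(greytone_params)
        # complete up to the 1e-10 Poisson truncation mass
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert probs.shape == (256,)

    def test_sigma_zero_rejected(self, greytone_params):
        p = gs.GreyToneParams(
            fibre=greytone_params.fibre, aggregate=greytone_params.aggregate,
            b=9.0, Delta=15.0, sigma=0.0,
        )
        with pytest.raises(InvalidParameterError):
            gs.intensity_pdf(10.0, p)
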