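"""Closed-form and quadrature-based evaluation of the two-scale gel model.

Model quantities
----------------
* ``fibre_density`` — area fraction of a Boolean model, ``phi_F = 1 - e^{-eta}``.
* ``rectangle_covariogram`` — isotropized, normalized geometrical covariogram
  ``K_F(r)`` of a random rectangle of size ``L_F x D_F`` (with a dedicated
  long-fibre branch for ``L_F`` infinite).
* ``boolean_covariance`` — two-point probability of the Boolean fibre phase,
  ``C_FF(r) = 2 phi_F - 1 + (1 - phi_F)^2 exp(eta K_F(r))``.
* ``clipped_gf_covariance`` — two-point probability of a one-cut excursion set
  of a stationary Gaussian field.
* ``two_scale_covariance`` — product ``C_FF(r) C_AA(r)`` of the independent
  small- and large-scale phases.
* ``poisson_overlap_pmf``, ``mean_intensity``, ``greytone_correlation``,
  ``intensity_pdf`` — grey-tone layer: fibre overlaps are Poisson(eta) inside
  aggregates, each contributing ``Delta`` grey levels on top of background
  ``b``, with additive Gaussian noise ``sigma``.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np
from scipy.stats import norm, poisson

from .params import (
    AggregateParams,
    FibreParams,
    GreyToneParams,
    InvalidParameterError,
)

__all__ = [
    "fibre_density",
    "eta_from_phi_F",
    "rectangle_covariogram",
    "boolean_covariance",
    "gaussian_field_correlation",
    "clipped_gf_covariance",
    "two_scale_covariance",
    "poisson_overlap_pmf",
    "poisson_truncation",
    "mean_intensity",
    "greytone_correlation",
    "intensity_pdf",
    "quantized_intensity_probabilities",
]

# 64-node Gauss-Legendre rule on [0, 1]; ample for the smooth (post-substitution)
# clipped-GF integrand.
_GL_X, _GL_W = np.polynomial.legendre.leggauss(64)
_GL_X = 0.5 * (_GL_X + 1.0)
_GL_W = 0.5 * _GL_W


def fibre_density(eta):
    """Area fraction ``phi_F = 1 - exp(-eta)`` of the Boolean fibre model.

    ``eta = theta * D_F * L_F`` is the coverage expected in absence of fibre
    overlap; the exponential accounts for overlaps.
    """
    eta = np.asarray(eta, dtype=float)
    if np.any(eta < 0):
        raise InvalidParameterError("eta must be >= 0")
    out = -np.expm1(-eta)
    return float(out) if out.ndim == 0 else out


def eta_from_phi_F(phi_F):
    """Inverse of :func:`fibre_density`: ``eta = -log(1 - phi_F)``."""
    phi_F = np.asarray(phi_F, dtype=float)
    if np.any((phi_F < 0) | (phi_F >= 1)):
        raise InvalidParameterError("phi_F must lie in [0, 1)")
    out = -np.log1p(-phi_F)
    return float(out) if out.ndim == 0 else out


def rectangle_covariogram(r, D_F: float, L_F: float = math.inf):
    """Normalized isotropized geometrical covariogram ``K_F(r)`` of a rectangle.

    For a rectangle of length ``L_F`` and diameter ``D_F`` with uniform random
    orientation, the orientation-averaged normalized self-overlap at
    displacement ``r`` is

        K_F(r) = (2/pi) * int_{t_lo}^{t_hi} (1 - (r/D_F) sin t)(1 - (r/L_F) cos t) dt

    with ``t_hi = pi/2`` for ``r < D_F`` and ``asin(D_F/r)`` otherwise, and
    ``t_lo = 0`` for ``r <= L_F`` and ``acos(L_F/r)`` otherwise (both factors
    must be non-negative).  The integral is evaluated in closed form through
    the antiderivative ``t + a cos t - c sin t + (a c / 2) sin^2 t`` with
    ``a = r/D_F``, ``c = r/L_F``.  The long-fibre limit ``L_F = inf`` sets
    ``c = 0``.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise InvalidParameterError("r must be >= 0")
    if not D_F > 0:
        raise InvalidParameterError("D_F must be > 0")
    if not L_F > 0:
        raise InvalidParameterError("L_F must be > 0")
    a = r / D_F
    c = r / L_F if math.isfinite(L_F) else np.zeros_like(r)

    with np.errstate(invalid="ignore"):
        t_hi = np.where(r < D_F, 0.5 * np.pi, np.arcsin(np.minimum(D_F / np.maximum(r, D_F), 1.0)))
        if math.isfinite(L_F):
            t_lo = np.where(r <= L_F, 0.0, np.arccos(np.minimum(L_F / np.maximum(r, L_F), 1.0)))
        else:
            t_lo = np.zeros_like(r)

    def F(t):
        s = np.sin(t)
        return t + a * np.cos(t) - c * s + 0.5 * a * c * s * s

    K = (2.0 / np.pi) * (F(t_hi) - F(t_lo))
    K = np.where(t_lo >= t_hi, 0.0, K)
    K = np.maximum(K, 0.0)
    return float(K) if K.ndim == 0 else K


def boolean_covariance(r, p: FibreParams):
    """Covariance ``C_FF(r)`` of the Boolean fibre phase.

    ``C_FF(r) = 2 phi_F - 1 + (1 - phi_F)^2 exp(eta K_F(r))``; equals ``phi_F``
    at r=0 and decays to ``phi_F^2`` once the covariogram has vanished.
    """
    K = rectangle_covariogram(r, p.D_F, p.L_F)
    phi = p.phi_F
    out = 2.0 * phi - 1.0 + (1.0 - phi) ** 2 * np.exp(p.eta * np.asarray(K))
    return float(out) if np.ndim(out) == 0 else out


def gaussian_field_correlation(L_A: float) -> Callable[[np.ndarray], np.ndarray]:
    """Default field correlation ``g_W(r) = exp(-r^2 / (2 L_A^2))``.

    A single-length-scale, smooth correlation that is positive definite in 2D;
    ``L_A`` is its ``e^{-1/2}`` decay length.
    """

    def g_w(r):
        r = np.asarray(r, dtype=float)
        return np.exp(-0.5 * (r / L_A) ** 2)

    return g_w


def clipped_gf_covariance(r, a: AggregateParams, g_w: Callable | None = None):
    """Covariance ``C_AA(r)`` of the one-cut clipped-Gaussian-field aggregates.

    For an excursion set {W >= alpha} of a standard stationary Gaussian field
    with correlation ``g_W``,

        C_AA(r) = phi_A^2 + (1/2pi) * int_0^{g_W(r)} exp(-alpha^2/(1+s)) / sqrt(1-s^2) ds.

    The endpoint singularity at s -> 1 is removed by the substitution
    ``s = sin u``; the resulting smooth integrand is evaluated by 64-node
    Gauss-Legendre quadrature, vectorized over ``r``.
    """
    r = np.asarray(r, dtype=float)
    if g_w is None:
        g_w = gaussian_field_correlation(a.L_A)
    g = np.asarray(g_w(r), dtype=float)
    if np.any(np.abs(g) > 1.0 + 1e-12):
        raise InvalidParameterError("field correlation g_W must satisfy |g_W| <= 1")
    g = np.clip(g, -1.0, 1.0)
    alpha = a.alpha

    u_max = np.arcsin(g)
    # nodes: u = u_max * x for x in (0,1); integral = u_max * sum w * f(u)
    u = np.multiply.outer(u_max, _GL_X)
    integrand = np.exp(-alpha * alpha / (1.0 + np.sin(u)))
    integral = u_max * (integrand @ _GL_W)
    out = a.phi_A**2 + integral / (2.0 * np.pi)
    return float(out) if out.ndim == 0 else out


def two_scale_covariance(r, f: FibreParams, a: AggregateParams, g_w: Callable | None = None):
    """Covariance ``C_11(r) = C_FF(r) * C_AA(r)`` of the two-scale solid phase.

    Fibres and aggregates are statistically independent, so the covariance of
    their intersection factorizes; at r=0 this gives the total density
    ``phi_1 = phi_F * phi_A``.
    """
    out = np.asarray(boolean_covariance(r, f)) * np.asarray(clipped_gf_covariance(r, a, g_w))
    return float(out) if out.ndim == 0 else out


def poisson_overlap_pmf(k, eta: float):
    """Probability that exactly ``k`` fibres overlap at a point: Poisson(eta)."""
    if eta < 0:
        raise InvalidParameterError("eta must be >= 0")
    k = np.asarray(k)
    if np.any(k < 0):
        raise InvalidParameterError("k must be >= 0")
    out = poisson.pmf(k, eta)
    return float(out) if out.ndim == 0 else out


def poisson_truncation(eta: float, tol: float = 1e-10, cap: int = 1000) -> int:
    """Smallest k_max with Poisson(eta) mass >= 1 - tol (capped)."""
    k_max = int(poisson.isf(tol, eta)) + 1 if eta > 0 else 1
    return min(max(k_max, 1), cap)


def mean_intensity(p: GreyToneParams) -> float:
    """Average image intensity ``<I> = b + eta * phi_A * Delta`` (grey levels)."""
    return p.b + p.fibre.eta * p.aggregate.phi_A * p.Delta


def greytone_correlation(r, p: GreyToneParams, g_w: Callable | None = None):
    """Grey-tone correlation function ``C(r) = <I(x) I(x+r)>``.

    ``C(r) = <I>^2 + eta Delta^2 K_F(r) C_AA(r) + (eta Delta)^2 (C_AA(r) - phi_A^2)
    + sigma^2 delta(r)`` where the noise term contributes only at the exact
    grid point r=0.
    """
    r = np.asarray(r, dtype=float)
    eta, Delta = p.fibre.eta, p.Delta
    K = np.asarray(rectangle_covariogram(r, p.fibre.D_F, p.fibre.L_F))
    CAA = np.asarray(clipped_gf_covariance(r, p.aggregate, g_w))
    mean = mean_intensity(p)
    out = (
        mean * mean
        + eta * Delta**2 * K * CAA
        + (eta * Delta) ** 2 * (CAA - p.aggregate.phi_A**2)
        + p.sigma**2 * (r == 0.0)
    )
    return float(out) if out.ndim == 0 else out


def _mixture_components(p: GreyToneParams):
    """Means and weights of the Gaussian mixture of the intensity distribution.

    Component 0 is the background (outside aggregates, or inside an aggregate
    but between fibres); component k >= 1 has k overlapping fibres.
    """
    eta = p.fibre.eta
    phi_A = p.aggregate.phi_A
    k_max = poisson_truncation(eta)
    k = np.arange(1, k_max + 1)
    weights = np.concatenate(([1.0 - phi_A * p.fibre.phi_F], phi_A * poisson.pmf(k, eta)))
    means = np.concatenate(([p.b], p.b + k * p.Delta))
    return means, weights


def intensity_pdf(I, p: GreyToneParams):
    """Probability density of the pixel intensity (pre-quantization).

    Gaussian mixture: a background component of weight ``1 - phi_A phi_F``
    centred at ``b`` and, for each k >= 1, a component of weight
    ``phi_A e^{-eta} eta^k / k!`` centred at ``b + k Delta``, all with the
    noise width ``sigma``.  The Poisson sum is truncated at the smallest k_max
    with residual mass below 1e-10.
    """
    if not p.sigma > 0:
        raise InvalidParameterError("intensity_pdf requires sigma > 0")
    I = np.asarray(I, dtype=float)
    means, weights = _mixture_components(p)
    dens = norm.pdf(I[..., None], loc=means, scale=p.sigma) @ weights
    return float(dens) if dens.ndim == 0 else dens


def quantized_intensity_probabilities(p: GreyToneParams, n_levels: int = 256) -> np.ndarray:
    """Exact per-level probabilities of the 8-bit quantized intensity.

    Quantization rounds to the nearest integer and clips to [0, n_levels-1],
    so level l collects mixture mass on [l-1/2, l+1/2), with the tails piled
    onto the first and last levels.
    """
    if not p.sigma > 0:
        raise InvalidParameterError("quantized probabilities require sigma > 0")
    means, weights = _mixture_components(p)
    edges = np.arange(n_levels + 1) - 0.5  # level l <- [l-0.5, l+0.5)
    cdf = norm.cdf((edges[:, None] - means) / p.sigma)
    cdf[0, :] = 0.0
    cdf[-1, :] = 1.0
    return np.diff(cdf, axis=0) @ weights
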