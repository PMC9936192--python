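"""Seeded simulators of the fibre, aggregate, and grey-tone models.

Every generator is a pure function of (parameters, seed): passing the same
seed reproduces the realization bit for bit.  A master seed spawns
independent substreams (numpy ``SeedSequence``) for the fibre, aggregate and
noise layers so the layers are statistically independent.

Edge effects are avoided by construction: fibre centres are drawn on a domain
extended by half a fibre extent on all sides, and the Gaussian field is
synthesized on a padded periodic grid and cropped, so the analysis window is
a stationary sample of the infinite-medium model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import fft2, ifft2, next_fast_len

from .params import (
    AggregateParams,
    FibreParams,
    GreyToneParams,
    InvalidParameterError,
)
from .models import eta_from_phi_F

__all__ = [
    "Domain",
    "OverlapImage",
    "simulate_fibres",
    "simulate_aggregates",
    "simulate_two_scale",
    "simulate_greytone",
    "SpheroidSeriesConfig",
    "SpheroidSeries",
    "simulate_spheroid_series",
]


@dataclass(frozen=True)
class Domain:
    """Rectangular pixel grid with a physical calibration (µm per pixel)."""

    width: int
    height: int
    pixel_size: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0 or self.pixel_size <= 0:
            raise InvalidParameterError("domain dimensions and pixel size must be positive")

    @property
    def width_um(self) -> float:
        return self.width * self.pixel_size

    @property
    def height_um(self) -> float:
        return self.height * self.pixel_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)


@dataclass(frozen=True)
class OverlapImage:
    """Per-pixel count of overlapping fibres; ``counts > 0`` is the Boolean set."""

    counts: np.ndarray
    domain: Domain

    @property
    def binary(self) -> np.ndarray:
        return self.counts > 0


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def simulate_fibres(d: Domain, theta: float, D_F: float, L_F: float, seed) -> OverlapImage:
    """Boolean model realization: Poisson rectangles with random orientation.

    Rectangle centres are Poisson with intensity ``theta`` (µm^-2) on the
    domain extended by half the rectangle diagonal on every side (edge
    correction), orientations uniform on [0, pi).  A pixel counts as covered
    by a rectangle when its centre lies inside it, which makes the expected
    binary area fraction exactly ``1 - exp(-theta D_F L_F)``.
    """
    if theta < 0 or D_F <= 0 or L_F <= 0:
        raise InvalidParameterError("theta must be >= 0 and D_F, L_F > 0")
    if not math.isfinite(L_F):
        raise InvalidParameterError("simulation requires finite L_F")
    rng = _rng(seed)
    px = d.pixel_size
    pad = 0.5 * math.hypot(L_F, D_F)
    w_ext = d.width_um + 2 * pad
    h_ext = d.height_um + 2 * pad
    n = rng.poisson(theta * w_ext * h_ext)
    cx = rng.uniform(-pad, d.width_um + pad, n)
    cy = rng.uniform(-pad, d.height_um + pad, n)
    ang = rng.uniform(0.0, np.pi, n)

    counts = np.zeros(d.shape, dtype=np.int32)
    xc = (np.arange(d.width) + 0.5) * px
    yc = (np.arange(d.height) + 0.5) * px
    hl, hd = 0.5 * L_F, 0.5 * D_F
    for j in range(n):
        ca, sa = math.cos(ang[j]), math.sin(ang[j])
        hx = hl * abs(ca) + hd * abs(sa)
        hy = hl * abs(sa) + hd * abs(ca)
        ix0 = max(0, int(np.searchsorted(xc, cx[j] - hx)))
        ix1 = min(d.width, int(np.searchsorted(xc, cx[j] + hx)))
        iy0 = max(0, int(np.searchsorted(yc, cy[j] - hy)))
        iy1 = min(d.height, int(np.searchsorted(yc, cy[j] + hy)))
        if ix0 >= ix1 or iy0 >= iy1:
            continue
        X = xc[ix0:ix1] - cx[j]
        Y = yc[iy0:iy1] - cy[j]
        U = np.abs(ca * X[None, :] + sa * Y[:, None])
        V = np.abs(-sa * X[None, :] + ca * Y[:, None])
        counts[iy0:iy1, ix0:ix1] += (U <= hl) & (V <= hd)
    return OverlapImage(counts=counts, domain=d)


def simulate_aggregates(d: Domain, a: AggregateParams, seed) -> np.ndarray:
    """Clipped-Gaussian-field realization of the aggregate phase.

    A stationary standard Gaussian field with correlation
    ``g_W(r) = exp(-r^2/(2 L_A^2))`` is synthesized by circulant embedding on
    a grid padded by 3 L_A per side, cropped to the domain, and thresholded
    at ``alpha`` so the excursion set has expected area fraction ``phi_A``.
    """
    if min(d.width_um, d.height_um) < 4 * a.L_A:
        raise InvalidParameterError(
            f"domain ({d.width_um:.0f}x{d.height_um:.0f} µm) must span at least "
            f"4*L_A = {4 * a.L_A:.0f} µm per side"
        )
    rng = _rng(seed)
    px = d.pixel_size
    pad = int(math.ceil(3.0 * a.L_A / px))
    mh = next_fast_len(d.height + 2 * pad, real=True)
    mw = next_fast_len(d.width + 2 * pad, real=True)
    iy = np.arange(mh)
    ix = np.arange(mw)
    dy = np.minimum(iy, mh - iy) * px
    dx = np.minimum(ix, mw - ix) * px
    kernel = np.exp(-0.5 * ((dy[:, None] ** 2 + dx[None, :] ** 2) / a.L_A**2))
    lam = np.maximum(fft2(kernel).real, 0.0)
    white = rng.standard_normal((mh, mw))
    field = ifft2(np.sqrt(lam) * fft2(white)).real
    return field[: d.height, : d.width] >= a.alpha


def simulate_two_scale(d: Domain, f: FibreParams, a: AggregateParams, seed) -> np.ndarray:
    """Binary two-scale realization: Boolean fibres masked by aggregates."""
    ss = _seedseq(seed)
    s_f, s_a = ss.spawn(2)
    fib = simulate_fibres(d, f.theta, f.D_F, f.L_F, np.random.default_rng(s_f))
    agg = simulate_aggregates(d, a, np.random.default_rng(s_a))
    return fib.binary & agg


def simulate_greytone(d: Domain, p: GreyToneParams, seed, quantize: bool = True) -> np.ndarray:
    """Grey-tone realization ``I = b + I_A * Delta * sum_i I_F^(i) + noise``.

    Composes the fibre overlap counts, the aggregate mask, the per-fibre
    intensity increment, the background, and uncorrelated Gaussian noise.
    With ``quantize`` the image is rounded and clipped to the 8-bit range
    (the recording step of the instrument); without it the analog intensity
    is returned, which lets tests separate discretization error.
    """
    ss = _seedseq(seed)
    s_f, s_a, s_n = ss.spawn(3)
    fib = simulate_fibres(d, p.fibre.theta, p.fibre.D_F, p.fibre.L_F, np.random.default_rng(s_f))
    agg = simulate_aggregates(d, p.aggregate, np.random.default_rng(s_a))
    noise = p.sigma * np.random.default_rng(s_n).standard_normal(d.shape)
    img = p.b + agg * p.Delta * fib.counts + noise
    if quantize:
        return np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img


# ---------------------------------------------------------------------------
# Spheroid time-series fixture


@dataclass(frozen=True, kw_only=True)
class SpheroidSeriesConfig:
    """Configuration of the synthetic spheroid invasion time series.

    The "cells" are a central disk growing at ``radius_growth`` plus
    ``n_sprouts`` radial sprouts elongating at ``sprout_speed`` (emulating
    invading strands).  The surrounding gel is a grey-tone model whose
    structural parameters ``phi_A`` and ``phi_F`` depend on (time, distance
    band from the cells), while the imaging parameters (b, Delta, sigma) are
    constant over the whole series, as in a time-lapse protocol with
    unchanged acquisition settings.
    """

    domain: Domain
    times_min: tuple[float, ...]
    band_edges_um: tuple[float, ...]
    phi_A: tuple[tuple[float, ...], ...]  # shape (n_times, n_bands)
    phi_F: tuple[tuple[float, ...], ...]
    D_F: float = 2.0
    L_A: float = 19.0
    L_F: float = 40.0
    b: float = 9.0
    Delta: float = 15.0
    sigma: float = 5.0
    spheroid_radius_um: float = 40.0
    radius_growth_um_per_min: float = 0.02
    n_sprouts: int = 6
    sprout_speed_um_per_min: float = 0.12
    sprout_width_um: float = 8.0

    def __post_init__(self) -> None:
        edges = self.band_edges_um
        if len(edges) < 2 or edges[0] != 0 or any(
            e2 <= e1 for e1, e2 in zip(edges, edges[1:])
        ):
            raise InvalidParameterError("band_edges_um must start at 0 and be strictly increasing")
        n_t, n_b = len(self.times_min), len(edges) - 1
        for name, surf in (("phi_A", self.phi_A), ("phi_F", self.phi_F)):
            if len(surf) != n_t or any(len(row) != n_b for row in surf):
                raise InvalidParameterError(
                    f"{name} surface must have shape (n_times={n_t}, n_bands={n_b})"
                )


@dataclass(frozen=True)
class SpheroidSeries:
    """Synthetic time series: per time point a cell mask and a gel image."""

    config: SpheroidSeriesConfig
    times_min: tuple[float, ...]
    cell_masks: list[np.ndarray]
    gel_images: list[np.ndarray]
    seed: int | None = None


def _cell_mask(cfg: SpheroidSeriesConfig, t: float) -> np.ndarray:
    d = cfg.domain
    px = d.pixel_size
    yc = (np.arange(d.height) + 0.5) * px - 0.5 * d.height_um
    xc = (np.arange(d.width) + 0.5) * px - 0.5 * d.width_um
    X, Y = np.meshgrid(xc, yc)
    R = np.hypot(X, Y)
    radius = cfg.spheroid_radius_um + cfg.radius_growth_um_per_min * t
    mask = R <= radius
    tip = radius + cfg.sprout_speed_um_per_min * t
    half_w = 0.5 * cfg.sprout_width_um
    for j in range(cfg.n_sprouts):
        phi = 2.0 * np.pi * j / cfg.n_sprouts + 0.3
        ux, uy = math.cos(phi), math.sin(phi)
        along = X * ux + Y * uy
        across = np.abs(-X * uy + Y * ux)
        mask |= (along >= 0) & (along <= tip) & (across <= half_w)
    return mask


def simulate_spheroid_series(config: SpheroidSeriesConfig, seed) -> SpheroidSeries:
    """Generate the spheroid fixture: growing cell mask + banded gel images.

    At each time point the distance layers are recomputed from the updated
    cell mask; the gel image is composited from one grey-tone realization per
    band, each with that band's (phi_F, phi_A) and the shared imaging
    parameters.  Pixels inside the cells carry background plus noise only
    (they are excluded from analysis by the mask).
    """
    from .spheroid import distance_layers  # local import avoids a cycle

    cfg = config
    d = cfg.domain
    ss = _seedseq(seed)
    n_bands = len(cfg.band_edges_um) - 1
    time_seeds = ss.spawn(len(cfg.times_min))
    masks: list[np.ndarray] = []
    images: list[np.ndarray] = []
    for it, t in enumerate(cfg.times_min):
        mask = _cell_mask(cfg, t)
        layers = distance_layers(mask, d.pixel_size, cfg.band_edges_um)
        band_seeds = time_seeds[it].spawn(n_bands + 1)
        noise = cfg.sigma * np.random.default_rng(band_seeds[-1]).standard_normal(d.shape)
        img = cfg.b + noise  # cells / beyond last band: background only
        for k in range(1, n_bands + 1):
            sel = layers.labels == k
            if not sel.any():
                continue
            p = GreyToneParams(
                fibre=FibreParams(
                    eta=eta_from_phi_F(cfg.phi_F[it][k - 1]), D_F=cfg.D_F, L_F=cfg.L_F
                ),
                aggregate=AggregateParams(phi_A=cfg.phi_A[it][k - 1], L_A=cfg.L_A),
                b=cfg.b,
                Delta=cfg.Delta,
                sigma=cfg.sigma,
            )
            band_img = simulate_greytone(d, p, band_seeds[k - 1], quantize=False)
            img[sel] = band_img[sel]
        images.append(np.clip(np.rint(img), 0, 255).astype(np.uint8))
        masks.append(mask)
    return SpheroidSeries(
        config=cfg,
        times_min=cfg.times_min,
        cell_masks=masks,
        gel_images=images,
        seed=None if isinstance(seed, np.random.SeedSequence) else seed,
    )
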