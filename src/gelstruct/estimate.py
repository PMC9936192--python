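"""Empirical two-point statistics and histograms from (masked) images.

The two-point estimator is the non-centered, non-periodic, pair-count
normalized autocorrelation

    C_hat(dx, dy) = sum_x I(x) I(x+d) M(x) M(x+d) / sum_x M(x) M(x+d)

computed with zero-padded FFTs (numerator from I*M, denominator from M).
Gel images are windows of a larger medium, so the non-periodic estimator is
the appropriate one, and an absent mask is simply the all-ones mask — the
masked and unmasked paths are a single code path.  For binary input the
estimator at lag 0 is the area fraction, so it reduces to the covariance of
the imaged phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.fft import irfft2, next_fast_len, rfft2

from .params import CorrelationCurve, IntensityHistogram, InvalidParameterError

__all__ = [
    "CorrelationMap",
    "autocorrelation_2d",
    "radial_profile",
    "greytone_histogram",
    "aggregate_replicates",
    "pool_histograms",
]


@dataclass(frozen=True)
class CorrelationMap:
    """2D lag-space autocorrelation with per-lag pixel-pair counts.

    Arrays have shape (2H-1, 2W-1) with lag (0, 0) at the central element;
    lags with zero pair count are NaN in ``values``.
    """

    values: np.ndarray
    pair_counts: np.ndarray

    @property
    def center(self) -> tuple[int, int]:
        return (self.values.shape[0] // 2, self.values.shape[1] // 2)


def autocorrelation_2d(image: np.ndarray, mask: np.ndarray | None = None) -> CorrelationMap:
    """Masked non-centered autocorrelation of a 2D image via FFT.

    Pair counts are exact integers (recovered by rounding the FFT of the
    mask); the value at lag (0,0) equals the mean of I^2 over the mask.
    """
    I = np.asarray(image, dtype=np.float64)
    if I.ndim != 2:
        raise InvalidParameterError("image must be 2-D")
    if not np.all(np.isfinite(I)):
        raise InvalidParameterError("image must be finite-valued")
    if mask is None:
        M = np.ones(I.shape, dtype=np.float64)
    else:
        M = np.asarray(mask)
        if M.shape != I.shape:
            raise InvalidParameterError("mask must have the same shape as the image")
        M = (M != 0).astype(np.float64)
        if not M.any():
            raise InvalidParameterError("mask is empty")
    H, W = I.shape
    sh = (next_fast_len(2 * H - 1, real=True), next_fast_len(2 * W - 1, real=True))
    FI = rfft2(I * M, sh)
    FM = rfft2(M, sh)
    num = irfft2(FI * np.conj(FI), sh)
    cnt = np.rint(irfft2(FM * np.conj(FM), sh)).astype(np.int64)
    # wrap circular lags into a centered (2H-1, 2W-1) window
    num = np.roll(num, (H - 1, W - 1), axis=(0, 1))[: 2 * H - 1, : 2 * W - 1]
    cnt = np.roll(cnt, (H - 1, W - 1), axis=(0, 1))[: 2 * H - 1, : 2 * W - 1]
    cnt = np.maximum(cnt, 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(cnt > 0, num / np.maximum(cnt, 1), np.nan)
    return CorrelationMap(values=values, pair_counts=cnt)


def radial_profile(
    corr_map: CorrelationMap,
    pixel_size: float,
    bin_width: float | None = None,
    r_max: float | None = None,
    min_pair_count: int = 100,
) -> CorrelationCurve:
    """Radial (isotropic) average of a 2D correlation map.

    Lags are averaged over annuli [k*w, (k+1)*w) with pair-count weights; the
    reported bin abscissa is the pair-count-weighted mean lag distance.  The
    zero lag is reported as its own r=0 point.  Annuli with fewer than
    ``min_pair_count`` pairs (or no valid lag at all) are flagged missing
    (NaN), not zero.
    """
    if pixel_size <= 0:
        raise InvalidParameterError("pixel_size must be positive")
    bw = pixel_size if bin_width is None else float(bin_width)
    if bw <= 0:
        raise InvalidParameterError("bin_width must be positive")
    vals, cnts = corr_map.values, corr_map.pair_counts
    H2, W2 = vals.shape
    H, W = (H2 + 1) // 2, (W2 + 1) // 2
    cy, cx = corr_map.center
    dy = (np.arange(H2) - cy)[:, None]
    dx = (np.arange(W2) - cx)[None, :]
    R = np.hypot(dy, dx) * pixel_size

    r_avail = R[cnts > 0].max() if (cnts > 0).any() else 0.0
    default_rmax = min(H, W) * pixel_size / 4.0
    rm = default_rmax if r_max is None else float(r_max)
    if rm > r_avail:
        warnings.warn(
            f"r_max={rm:.3g} µm exceeds available lags ({r_avail:.3g} µm); truncating",
            stacklevel=2,
        )
        rm = r_avail
    n_bins = int(np.ceil(rm / bw))

    sel = (R > 0) & (R < n_bins * bw) & (cnts > 0) & np.isfinite(vals)
    k = (R[sel] / bw).astype(np.int64)
    w = cnts[sel].astype(np.float64)
    num = np.bincount(k, weights=w * vals[sel], minlength=n_bins)
    den = np.bincount(k, weights=w, minlength=n_bins)
    rw = np.bincount(k, weights=w * R[sel], minlength=n_bins)

    good = den >= min_pair_count
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(good, num / np.maximum(den, 1.0), np.nan)
        r = np.where(good, rw / np.maximum(den, 1.0), (np.arange(n_bins) + 0.5) * bw)

    c0 = vals[cy, cx]
    r_out = np.concatenate(([0.0], r))
    C_out = np.concatenate(([c0], C))
    return CorrelationCurve(r=r_out, C=C_out)


def greytone_histogram(image: np.ndarray, mask: np.ndarray | None = None) -> IntensityHistogram:
    """Per-level pixel counts of an 8-bit image within an optional mask."""
    img = np.asarray(image)
    if img.ndim != 2:
        raise InvalidParameterError("image must be 2-D")
    if not np.issubdtype(img.dtype, np.integer):
        if np.issubdtype(img.dtype, np.floating) and np.all(img == np.rint(img)):
            img = img.astype(np.int64)
        else:
            raise InvalidParameterError("histogram requires integer grey levels; quantize first")
    if img.min() < 0 or img.max() > 255:
        raise InvalidParameterError("grey levels must lie in 0..255")
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != img.shape:
            raise InvalidParameterError("mask must have the same shape as the image")
        vals = img[mask != 0]
        if vals.size == 0:
            raise InvalidParameterError("mask is empty")
    else:
        vals = img.ravel()
    counts = np.bincount(vals.astype(np.int64), minlength=256)
    return IntensityHistogram(counts=counts)


def pool_histograms(hists: list[IntensityHistogram]) -> IntensityHistogram:
    """Sum per-level counts of replicate histograms."""
    if not hists:
        raise InvalidParameterError("no histograms to pool")
    counts = np.sum([h.counts for h in hists], axis=0)
    return IntensityHistogram(counts=counts)


def aggregate_replicates(curves: list[CorrelationCurve]) -> CorrelationCurve:
    """Pointwise mean and standard error across replicate curves.

    All curves must share the same distance grid.  The SEM is the sample
    standard deviation over replicates divided by sqrt(n); points missing in
    some replicates are averaged over the available ones, and points with
    fewer than two valid replicates are flagged missing.
    """
    if len(curves) < 2:
        raise InvalidParameterError("need at least two replicate curves")
    r0 = curves[0].r
    for c in curves[1:]:
        if c.r.shape != r0.shape or not np.allclose(c.r, r0, rtol=1e-8, atol=1e-9):
            raise InvalidParameterError("replicate curves must share the same distance grid")
    stack = np.vstack([c.C for c in curves])
    valid = np.isfinite(stack)
    n = valid.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
    mean = np.where(n >= 2, mean, np.nan)
    sem = np.where(n >= 2, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return CorrelationCurve(r=r0, C=mean, sem=sem, n_replicates=len(curves))
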