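"""Identification of model parameters from measured curves and histograms.

Three entry points:

* :func:`fit_binary_covariance` — fit the two-scale covariance (long-fibre
  limit by default) to the radially averaged covariance of binary images over
  (eta, D_F, phi_A, L_A), SEM-weighted when replicate SEMs are available.
* :func:`fit_greytone` — joint fit of the grey-tone correlation function and
  the intensity histogram over the seven parameters
  (eta, D_F, phi_A, L_A, b, Delta, sigma).  The histogram term is a Poisson
  deviance against the bin-integrated (quantized) mixture model; the
  correlation term excludes r=0, where the noise variance would double-count
  the sigma already identified by the histogram.
* :func:`fit_joint` — simultaneous fit of several (curve, histogram)
  conditions with a chosen set of parameters (typically the imaging
  parameters b, Delta, sigma) shared across all conditions.

The optimizer is bounded trust-region least squares with seeded
Latin-hypercube multi-starts; the internal parameterization uses eta rather
than phi_F because positivity bounds are simpler on eta.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.special import xlogy
from scipy.stats import qmc

from .estimate import aggregate_replicates, pool_histograms
from .models import (
    fibre_density,
    greytone_correlation,
    quantized_intensity_probabilities,
    two_scale_covariance,
)
from .params import (
    AggregateParams,
    CorrelationCurve,
    FibreParams,
    GreyToneParams,
    IntensityHistogram,
    InvalidParameterError,
)

__all__ = [
    "DEFAULT_BOUNDS",
    "FitConfig",
    "FitResult",
    "JointFitResult",
    "FitError",
    "fit_binary_covariance",
    "fit_greytone",
    "fit_greytone_replicates",
    "fit_joint",
]

BINARY_NAMES = ("eta", "D_F", "phi_A", "L_A")
GREYTONE_NAMES = ("eta", "D_F", "phi_A", "L_A", "b", "Delta", "sigma")
SHAREABLE = {"b", "Delta", "sigma", "D_F", "L_A"}

#: Generous envelopes around plausible collagen-gel values (lengths in µm,
#: intensities in grey levels of an 8-bit image).
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "eta": (0.01, 6.0),
    "D_F": (0.2, 10.0),
    "phi_A": (0.01, 0.99),
    "L_A": (1.0, 60.0),
    "b": (0.0, 64.0),
    "Delta": (0.5, 64.0),
    "sigma": (0.1, 32.0),
}


class FitError(RuntimeError):
    """No start converged; carries the best attempt in ``.best``."""

    def __init__(self, message: str, best: "FitResult | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True, kw_only=True)
class FitConfig:
    """Optimizer settings shared by all fitting entry points.

    ``w_hist`` and ``w_corr`` weight the two loss terms after each is
    normalized by its number of data points; ``fixed`` pins parameters at
    given values (``L_F`` defaults to the long-fibre limit); ``x0`` adds a
    warm start to the Latin-hypercube starts.
    """

    n_starts: int = 8
    seed: int = 0
    w_hist: float = 1.0
    w_corr: float = 1.0
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    fixed: dict[str, float] = field(default_factory=dict)
    x0: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.w_hist <= 0 or self.w_corr <= 0:
            raise InvalidParameterError("loss weights must be positive")
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise InvalidParameterError(f"bounds for {name} must satisfy lo < hi")

    def bound(self, name: str) -> tuple[float, float]:
        return self.bounds.get(name, DEFAULT_BOUNDS[name])


@dataclass(frozen=True)
class FitResult:
    """Point estimates with diagnostics.

    ``params`` holds the internal parameterization (eta rather than phi_F);
    the derived ``phi_F`` and ``phi_1 = phi_F * phi_A`` are exposed as
    properties.  ``spread`` (when present) is the per-parameter standard
    deviation across per-replicate fits.
    """

    params: dict[str, float]
    loss: float
    success: bool
    message: str
    fixed: dict[str, float] = field(default_factory=dict)
    shared: tuple[str, ...] = ()
    n_converged: int = 1
    spread: dict[str, float] | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def phi_F(self) -> float:
        return float(fibre_density(self.params["eta"]))

    @property
    def phi_A(self) -> float:
        return float(self.params["phi_A"])

    @property
    def phi_1(self) -> float:
        return self.phi_F * self.phi_A

    def at_bound(self, cfg: FitConfig | None = None, rel: float = 1e-3) -> list[str]:
        """Names of parameters whose estimate sits at a bound (degeneracy flag)."""
        cfg = cfg or FitConfig()
        flagged = []
        for name, value in self.params.items():
            lo, hi = cfg.bound(name)
            if value - lo <= rel * (hi - lo) or hi - value <= rel * (hi - lo):
                flagged.append(name)
        return flagged


@dataclass(frozen=True)
class JointFitResult:
    """Per-condition results of a multi-condition fit with shared parameters."""

    results: list[FitResult]
    shared: dict[str, float]
    loss: float


# ---------------------------------------------------------------------------
# internals


def _params_from_dict(d: dict[str, float], L_F: float) -> GreyToneParams:
    return GreyToneParams(
        fibre=FibreParams(eta=d["eta"], D_F=d["D_F"], L_F=L_F),
        aggregate=AggregateParams(phi_A=d["phi_A"], L_A=d["L_A"]),
        b=d["b"],
        Delta=d["Delta"],
        sigma=d["sigma"],
    )


def _sem_weights(y: np.ndarray, sem: np.ndarray | None) -> np.ndarray:
    """1/SEM weights; unweighted when SEMs are absent or degenerate."""
    if sem is None:
        return np.ones_like(y)
    sem = np.asarray(sem, dtype=float)
    pos = sem[np.isfinite(sem) & (sem > 0)]
    if pos.size == 0:
        return np.ones_like(y)
    floor = pos.min()
    safe = np.where(np.isfinite(sem) & (sem > 0), sem, np.median(pos))
    return 1.0 / np.maximum(safe, floor)


def _lhs_starts(names: list[str], cfg: FitConfig, n: int) -> list[np.ndarray]:
    """Latin-hypercube starting points, log-spaced for strictly positive bounds."""
    if n <= 0:
        return []
    sampler = qmc.LatinHypercube(d=len(names), seed=cfg.seed)
    unit = sampler.random(n)
    starts = np.empty_like(unit)
    for j, name in enumerate(names):
        lo, hi = cfg.bound(name)
        if lo > 0:
            starts[:, j] = np.exp(np.log(lo) + unit[:, j] * (np.log(hi) - np.log(lo)))
        else:
            starts[:, j] = lo + unit[:, j] * (hi - lo)
    return list(starts)


def _run_multistart(resid, names, cfg: FitConfig, extra_starts) -> tuple:
    lo = np.array([cfg.bound(n)[0] for n in names])
    hi = np.array([cfg.bound(n)[1] for n in names])
    margin = 1e-6 * (hi - lo)
    starts = [np.clip(np.asarray(s, dtype=float), lo + margin, hi - margin) for s in extra_starts]
    starts += [np.clip(s, lo + margin, hi - margin) for s in _lhs_starts(list(names), cfg, cfg.n_starts)]
    best = None
    n_converged = 0
    last_msg = "no start attempted"
    for x0 in starts:
        try:
            res = least_squares(
                resid, x0, bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=4000,
            )
        except (ValueError, FloatingPointError) as exc:  # pragma: no cover
            last_msg = str(exc)
            continue
        if res.status > 0:
            n_converged += 1
        last_msg = res.message
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError(f"all starts failed: {last_msg}")
    return best, n_converged, last_msg


# ---------------------------------------------------------------------------
# binary covariance fit


def _binary_heuristic_start(curve: CorrelationCurve, names, cfg: FitConfig) -> np.ndarray:
    y = curve.C[curve.valid]
    r = curve.r[curve.valid]
    phi1 = float(np.clip(y[0], 1e-3, 0.999))
    phi_A = float(np.clip(math.sqrt(phi1), *cfg.bound("phi_A")))
    phi_F = min(phi1 / phi_A, 0.99)
    eta = -math.log1p(-phi_F)
    c_inf = float(np.nanmedian(y[-max(3, y.size // 10):]))
    span = max(y[0] - c_inf, 1e-6)
    below = r[(y - c_inf) < 0.3 * span]
    L_A = float(np.clip(below[0] if below.size else r[-1] / 2, *cfg.bound("L_A")))
    defaults = {"eta": eta, "D_F": 2.0, "phi_A": phi_A, "L_A": L_A}
    return np.array([defaults[n] for n in names])


def fit_binary_covariance(curve: CorrelationCurve, cfg: FitConfig | None = None) -> FitResult:
    """Fit the two-scale covariance model to a binary-image covariance curve.

    Minimizes SEM-weighted squared residuals between the curve and
    ``C_FF(r) C_AA(r)`` over (eta, D_F, phi_A, L_A); the fibre length is held
    at the long-fibre limit unless fixed to a finite value through
    ``cfg.fixed["L_F"]``.
    """
    cfg = cfg or FitConfig()
    L_F = cfg.fixed.get("L_F", math.inf)
    names = [n for n in BINARY_NAMES if n not in cfg.fixed]
    if not names:
        raise InvalidParameterError("all parameters fixed; nothing to fit")
    sel = curve.valid
    r, y = curve.r[sel], curve.C[sel]
    w = _sem_weights(y, None if curve.sem is None else curve.sem[sel])

    def resid(x):
        d = dict(zip(names, x))
        d.update({k: v for k, v in cfg.fixed.items() if k != "L_F"})
        fib = FibreParams(eta=d["eta"], D_F=d["D_F"], L_F=L_F)
        agg = AggregateParams(phi_A=d["phi_A"], L_A=d["L_A"])
        return (two_scale_covariance(r, fib, agg) - y) * w

    extra = [_binary_heuristic_start(curve, names, cfg)]
    if cfg.x0:
        extra.insert(0, np.array([cfg.x0[n] for n in names]))
    best, n_conv, msg = _run_multistart(resid, names, cfg, extra)
    params = dict(zip(names, (float(v) for v in best.x)))
    params.update({k: float(v) for k, v in cfg.fixed.items() if k in BINARY_NAMES})
    result = FitResult(
        params=params,
        loss=float(2 * best.cost),
        success=n_conv > 0,
        message=msg,
        fixed=dict(cfg.fixed),
        n_converged=n_conv,
    )
    if n_conv == 0:
        raise FitError("no start converged", best=result)
    return result


# ---------------------------------------------------------------------------
# grey-tone joint fit


def _greytone_residual_builder(curve: CorrelationCurve, hist: IntensityHistogram, cfg: FitConfig):
    """Return a function mapping a full parameter dict to the residual vector."""
    obs = hist.counts.astype(float)
    n_pix = hist.n_pixels
    if n_pix == 0:
        raise InvalidParameterError("histogram is empty")
    if obs[-1] > 0.01 * n_pix:
        warnings.warn(
            "more than 1% of pixels are clipped at level 255; the intensity model "
            "is biased in this regime",
            stacklevel=3,
        )
    sel = curve.valid & (curve.r > 0)
    r, y = curve.r[sel], curve.C[sel]
    w = _sem_weights(y, None if curve.sem is None else curve.sem[sel])
    s_h = math.sqrt(cfg.w_hist / obs.size)
    s_c = math.sqrt(cfg.w_corr / max(r.size, 1))
    L_F = cfg.fixed.get("L_F", math.inf)

    def resid(d: dict[str, float]) -> np.ndarray:
        p = _params_from_dict(d, L_F)
        expected = np.maximum(quantized_intensity_probabilities(p) * n_pix, 1e-12)
        dev = np.maximum(2.0 * (xlogy(obs, obs / expected) - obs + expected), 0.0)
        r_hist = np.sign(obs - expected) * np.sqrt(dev) * s_h
        r_corr = (greytone_correlation(r, p) - y) * w * s_c
        return np.concatenate([r_hist, r_corr])

    return resid


def _greytone_heuristic_start(curve, hist, names, cfg) -> np.ndarray:
    counts = hist.counts.astype(float)
    levels = hist.levels.astype(float)
    b = float(levels[np.argmax(counts)])
    cdf = np.cumsum(counts) / max(counts.sum(), 1)
    p90 = float(levels[np.searchsorted(cdf, 0.90)])
    defaults = {
        "eta": 0.7,
        "D_F": 2.0,
        "phi_A": 0.5,
        "L_A": 10.0,
        "b": b,
        "Delta": max((p90 - b) / 1.5, 1.0),
        "sigma": 4.0,
    }
    return np.array([defaults[n] for n in names])


def fit_greytone(
    curve: CorrelationCurve, hist: IntensityHistogram, cfg: FitConfig | None = None
) -> FitResult:
    """Joint fit of the grey-tone correlation function and intensity histogram.

    The loss is ``w_h * L_hist + w_c * L_corr`` with each term normalized by
    its number of points: ``L_hist`` is the Poisson deviance between observed
    counts and the bin-integrated mixture model, ``L_corr`` the SEM-weighted
    squared correlation residual excluding r=0.  The noise jump
    ``C(0) - C(0+)`` implied by the curve is reported as the diagnostic
    ``sigma_from_c0`` for comparison with the histogram-identified sigma.
    """
    cfg = cfg or FitConfig()
    names = [n for n in GREYTONE_NAMES if n not in cfg.fixed]
    if not names:
        raise InvalidParameterError("all parameters fixed; nothing to fit")
    build = _greytone_residual_builder(curve, hist, cfg)

    def resid(x):
        d = dict(zip(names, x))
        d.update({k: v for k, v in cfg.fixed.items() if k != "L_F"})
        return build(d)

    extra = [_greytone_heuristic_start(curve, hist, names, cfg)]
    if cfg.x0:
        extra.insert(0, np.array([cfg.x0[n] for n in names]))
    best, n_conv, msg = _run_multistart(resid, names, cfg, extra)
    params = dict(zip(names, (float(v) for v in best.x)))
    params.update({k: float(v) for k, v in cfg.fixed.items() if k in GREYTONE_NAMES})

    p_hat = _params_from_dict(params, cfg.fixed.get("L_F", math.inf))
    c0_nonoise = float(greytone_correlation(np.array([0.0]), p_hat)[0]) - p_hat.sigma**2
    jump = float(curve.C[0]) - c0_nonoise if np.isfinite(curve.C[0]) else np.nan
    result = FitResult(
        params=params,
        loss=float(2 * best.cost),
        success=n_conv > 0,
        message=msg,
        fixed=dict(cfg.fixed),
        n_converged=n_conv,
        diagnostics={"sigma_from_c0": math.sqrt(jump) if jump > 0 else float("nan")},
    )
    if n_conv == 0:
        raise FitError("no start converged", best=result)
    return result


def fit_greytone_replicates(
    curves: list[CorrelationCurve],
    hists: list[IntensityHistogram],
    cfg: FitConfig | None = None,
) -> FitResult:
    """Replicate protocol: pooled point estimate plus per-replicate spreads.

    The point estimate fits the replicate-mean curve and the pooled
    histogram; each replicate is then refitted (warm-started at the point
    estimate) and the per-parameter standard deviations across replicates are
    reported as ``spread``.
    """
    if len(curves) != len(hists) or len(curves) < 2:
        raise InvalidParameterError("need matching lists of at least two replicates")
    cfg = cfg or FitConfig()
    mean_curve = aggregate_replicates(curves)
    pooled = pool_histograms(hists)
    point = fit_greytone(mean_curve, pooled, cfg)
    per_rep = []
    warm = replace(cfg, n_starts=0, x0=point.params)
    for c, h in zip(curves, hists):
        per_rep.append(fit_greytone(c, h, warm).params)
    free = [n for n in GREYTONE_NAMES if n not in cfg.fixed]
    spread = {
        n: float(np.std([p[n] for p in per_rep], ddof=1)) for n in free
    }
    return replace(
        point,
        spread=spread,
        diagnostics={**point.diagnostics, "replicate_params": per_rep},
    )


# ---------------------------------------------------------------------------
# multi-condition fit with shared parameters


def fit_joint(
    conditions: list[tuple[CorrelationCurve, IntensityHistogram]],
    shared: set[str] | tuple[str, ...],
    cfg: FitConfig | None = None,
) -> JointFitResult:
    """Fit several conditions simultaneously with shared parameters.

    A single optimization over the shared parameters plus per-condition
    structural parameters minimizes the sum of the per-condition grey-tone
    losses.  Typical use shares the imaging parameters (b, Delta, sigma)
    across a time-lapse series acquired with unchanged settings.
    """
    cfg = cfg or FitConfig()
    shared = tuple(sorted(set(shared)))
    if not set(shared) <= SHAREABLE:
        raise InvalidParameterError(f"shareable parameters are {sorted(SHAREABLE)}")
    if len(conditions) < 2:
        raise InvalidParameterError("need at least two conditions")
    if any(n in cfg.fixed for n in shared):
        raise InvalidParameterError("a parameter cannot be both shared and fixed")
    local_names = [n for n in GREYTONE_NAMES if n not in shared and n not in cfg.fixed]

    builders = [_greytone_residual_builder(c, h, cfg) for c, h in conditions]

    # stage 1: independent fits to get a warm start
    indep = [fit_greytone(c, h, cfg) for c, h in conditions]
    shared_init = {n: float(np.median([f.params[n] for f in indep])) for n in shared}

    n_s, n_l, n_c = len(shared), len(local_names), len(conditions)

    def unpack(x):
        sh = dict(zip(shared, x[:n_s]))
        locs = [
            dict(zip(local_names, x[n_s + i * n_l : n_s + (i + 1) * n_l])) for i in range(n_c)
        ]
        return sh, locs

    def resid(x):
        sh, locs = unpack(x)
        out = []
        for build, loc in zip(builders, locs):
            d = {**loc, **sh, **{k: v for k, v in cfg.fixed.items() if k != "L_F"}}
            out.append(build(d))
        return np.concatenate(out)

    x0 = np.concatenate(
        [[shared_init[n] for n in shared]]
        + [[f.params[n] for n in local_names] for f in indep]
    )
    lo = np.concatenate(
        [[cfg.bound(n)[0] for n in shared]] + [[cfg.bound(n)[0] for n in local_names]] * n_c
    )
    hi = np.concatenate(
        [[cfg.bound(n)[1] for n in shared]] + [[cfg.bound(n)[1] for n in local_names]] * n_c
    )
    margin = 1e-9 * (hi - lo)
    res = least_squares(
        resid, np.clip(x0, lo + margin, hi - margin), bounds=(lo, hi), method="trf",
        xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=2000,
    )
    sh, locs = unpack(res.x)
    results = []
    for loc in locs:
        params = {**{k: float(v) for k, v in loc.items()}, **{k: float(v) for k, v in sh.items()}}
        params.update({k: float(v) for k, v in cfg.fixed.items() if k in GREYTONE_NAMES})
        params = {n: params[n] for n in GREYTONE_NAMES}
        results.append(
            FitResult(
                params=params,
                loss=float(2 * res.cost),
                success=res.status > 0,
                message=res.message,
                fixed=dict(cfg.fixed),
                shared=shared,
                n_converged=int(res.status > 0),
            )
        )
    return JointFitResult(
        results=results, shared={k: float(v) for k, v in sh.items()}, loss=float(2 * res.cost)
    )
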