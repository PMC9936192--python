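"""Parameter containers for the two-scale fibre/aggregate gel model.

The model has two structural scales plus an imaging layer:

* small scale — a Boolean model of randomly oriented rectangles ("fibres"),
  parameterized by the number density ``theta`` (µm^-2), diameter ``D_F`` and
  length ``L_F`` (µm), or equivalently by the dimensionless expected coverage
  ``eta = theta * D_F * L_F``;
* large scale — "aggregates" obtained by thresholding a smooth stationary
  Gaussian random field at a level ``alpha`` chosen so the excursion set has
  area fraction ``phi_A``, with a single correlation length ``L_A`` (µm);
* imaging — each fibre adds an intensity increment ``Delta`` on top of a
  background ``b``, corrupted by uncorrelated Gaussian noise of standard
  deviation ``sigma`` (all in grey levels of an 8-bit image).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "INFINITE",
    "InvalidParameterError",
    "FibreParams",
    "AggregateParams",
    "GreyToneParams",
    "CorrelationCurve",
    "IntensityHistogram",
]

#: Distinguished fibre length for the long-fibre limit L_F -> infinity.
INFINITE = math.inf


class InvalidParameterError(ValueError):
    """Raised when a model parameter violates its domain."""


@dataclass(frozen=True, kw_only=True)
class FibreParams:
    """Boolean fibre model parameters.

    Exactly one of ``eta`` (dimensionless expected coverage) or ``theta``
    (number density, µm^-2) must be given; the other is derived through
    ``eta = theta * D_F * L_F``.  ``L_F`` may be :data:`INFINITE` for the
    long-fibre limit (then only ``eta`` is meaningful).
    """

    D_F: float
    L_F: float = INFINITE
    eta: float | None = None
    theta: float | None = None

    def __post_init__(self) -> None:
        if not (self.D_F > 0) or not math.isfinite(self.D_F):
            raise InvalidParameterError(f"D_F must be positive and finite, got {self.D_F}")
        if not (self.L_F > self.D_F):
            raise InvalidParameterError(
                f"L_F must exceed D_F (or be INFINITE), got L_F={self.L_F}, D_F={self.D_F}"
            )
        if (self.eta is None) == (self.theta is None):
            raise InvalidParameterError("exactly one of eta or theta must be given")
        if self.eta is None:
            if not math.isfinite(self.L_F):
                raise InvalidParameterError("theta parameterization requires finite L_F")
            if self.theta < 0:
                raise InvalidParameterError(f"theta must be >= 0, got {self.theta}")
            object.__setattr__(self, "eta", self.theta * self.D_F * self.L_F)
        else:
            if self.eta < 0:
                raise InvalidParameterError(f"eta must be >= 0, got {self.eta}")
            if math.isfinite(self.L_F):
                object.__setattr__(self, "theta", self.eta / (self.D_F * self.L_F))

    @property
    def phi_F(self) -> float:
        """Fibre area fraction 1 - exp(-eta), in [0, 1)."""
        return float(-np.expm1(-self.eta))

    @property
    def is_long_fibre(self) -> bool:
        return not math.isfinite(self.L_F)


@dataclass(frozen=True, kw_only=True)
class AggregateParams:
    """Clipped-Gaussian-field aggregate parameters.

    ``phi_A`` is the aggregate area fraction and ``L_A`` the correlation
    length of the underlying Gaussian field (for the default Gaussian
    correlation it is the e^{-1/2} decay length).  The clipping threshold
    ``alpha`` is derived from ``phi_A = 1 - Phi(alpha)``.
    """

    phi_A: float
    L_A: float

    def __post_init__(self) -> None:
        if not (0.0 < self.phi_A < 1.0):
            raise InvalidParameterError(f"phi_A must lie in (0,1), got {self.phi_A}")
        if not (self.L_A > 0) or not math.isfinite(self.L_A):
            raise InvalidParameterError(f"L_A must be positive and finite, got {self.L_A}")

    @property
    def alpha(self) -> float:
        """Clipping threshold of the standard-normal field: phi_A = 1 - Phi(alpha)."""
        return float(norm.isf(self.phi_A))


@dataclass(frozen=True, kw_only=True)
class GreyToneParams:
    """Structural plus imaging parameters of the grey-tone intensity model."""

    fibre: FibreParams
    aggregate: AggregateParams
    b: float
    Delta: float
    sigma: float

    def __post_init__(self) -> None:
        if self.b < 0:
            raise InvalidParameterError(f"b must be >= 0, got {self.b}")
        if not (self.Delta > 0):
            raise InvalidParameterError(f"Delta must be > 0, got {self.Delta}")
        if self.sigma < 0:
            raise InvalidParameterError(f"sigma must be >= 0, got {self.sigma}")

    @property
    def phi_1(self) -> float:
        """Total fibre density phi_F * phi_A of the two-scale structure."""
        return self.fibre.phi_F * self.aggregate.phi_A


@dataclass(frozen=True)
class CorrelationCurve:
    """Radially averaged two-point statistic C(r).

    ``C`` holds squared grey levels for grey-tone correlation functions and a
    probability for binary covariances.  Missing points (e.g. annuli with too
    few pixel pairs) are NaN.  ``sem`` is the standard error of the mean across
    replicates, present only after replicate aggregation.
    """

    r: np.ndarray
    C: np.ndarray
    sem: np.ndarray | None = None
    n_replicates: int = 1

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        C = np.asarray(self.C, dtype=float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "C", C)
        if r.ndim != 1 or C.shape != r.shape:
            raise InvalidParameterError("r and C must be 1-D arrays of equal length")
        if r.size == 0 or r[0] != 0.0:
            raise InvalidParameterError("distance grid must start at r=0")
        if np.any(np.diff(r) <= 0):
            raise InvalidParameterError("distance grid must be strictly increasing")
        if self.sem is not None:
            sem = np.asarray(self.sem, dtype=float)
            if sem.shape != r.shape:
                raise InvalidParameterError("sem must match r in length")
            object.__setattr__(self, "sem", sem)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.C)


@dataclass(frozen=True)
class IntensityHistogram:
    """Pixel counts per 8-bit grey level inside a region of interest."""

    counts: np.ndarray
    levels: np.ndarray = field(default_factory=lambda: np.arange(256))

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        levels = np.asarray(self.levels, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "levels", levels)
        if counts.shape != levels.shape or counts.ndim != 1:
            raise InvalidParameterError("counts and levels must be 1-D arrays of equal length")
        if np.any(counts < 0):
            raise InvalidParameterError("histogram counts must be non-negative")

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())
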