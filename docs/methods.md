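# Methods

This note records the models implemented in `gelstruct`, the estimators and
fitting procedures, the numerical choices, what the synthetic-data
generators do and do not emulate, and the known limitations.

## Two-scale structural model

The gel's solid phase is modelled as the intersection of two independent
stationary random sets.

**Small scale — Boolean fibre model.**  Fibres are `L_F × D_F` rectangles
(µm) with centres from a Poisson process of intensity `θ` (µm⁻²) and
orientations uniform on `[0, π)`.  The expected coverage in the absence of
overlap is `η = θ·D_F·L_F`; overlap gives the density `φ_F = 1 − e^(−η)` and
the covariance `C_FF(r) = 2φ_F − 1 + (1−φ_F)² exp[η K_F(r)]`.  The
isotropized normalized covariogram of the rectangle is

    K_F(r) = (2/π) ∫ (1 − (r/D_F) sin t)₊ (1 − (r/L_F) cos t)₊ dt

over `t ∈ [t_lo, t_hi]`, with `t_hi = asin(D_F/r)` for `r ≥ D_F` (else π/2)
and `t_lo = acos(L_F/r)` for `r > L_F` (else 0).  The integrand has the
exact antiderivative `t + a cos t − c sin t + (ac/2) sin²t` with `a = r/D_F`,
`c = r/L_F`, so `K_F` is evaluated in closed form for every branch,
including the long-fibre limit (`c = 0`).  The long-fibre limit is
represented by a distinguished infinite `L_F` with its own branch rather
than a large number, avoiding cancellation; it is the default in all fits
because the effective fibre length is controlled by the aggregates and is
not identifiable from the covariance.

**Large scale — clipped Gaussian field.**  Aggregates are the one-cut
excursion set `{W ≥ α}` of a standard stationary Gaussian field.  The field
correlation defaults to `g_W(r) = exp(−r²/(2 L_A²))` — a smooth,
single-length-scale family, positive definite in 2D, with `L_A` the
`e^{−1/2}` decay length — and is pluggable (`g_w=` argument) because the
exact published family for this quantity is not pinned down; fitted `L_A`
values are interpretable only relative to the chosen family.  A one-cut set
is used since the area fraction `φ_A` is the only level parameter:
`φ_A = 1 − Φ(α)`.  The covariance is

    C_AA(r) = φ_A² + (1/2π) ∫₀^{g_W(r)} exp(−α²/(1+s)) / √(1−s²) ds.

The integrable endpoint singularity at `s → 1` is removed by `s = sin u`;
the resulting smooth integrand is evaluated with a fixed 64-node
Gauss–Legendre rule vectorized over `r` (the rule reproduces the adaptive
quadrature oracle and the `α = 0` arcsine closed form to better than 1e−10).

Independence of the two sets gives `φ_1 = φ_F φ_A` and
`C_11(r) = C_FF(r) C_AA(r)`.

**Grey-tone layer.**  Each fibre adds `Δ` grey levels, so
`I(x) = b + I_A(x)·Δ·Σᵢ I_F⁽ⁱ⁾(x) + n(x)` with uncorrelated Gaussian noise
of SD `σ`.  Overlap counts inside aggregates are Poisson(η), giving the
mean `⟨I⟩ = b + ηφ_AΔ`, the grey-tone correlation function (σ² contributes
only at the exact grid point r=0, matching the uncorrelated-noise
definition), and a Gaussian-mixture intensity distribution with background
weight `1 − φ_Aφ_F` and components `φ_A e^{−η} η^k/k!` at `b + kΔ`.  The
Poisson sum is truncated at the smallest `k_max` whose cumulative mass
reaches `1 − 1e−10`, capped at 1000.  For 8-bit data the per-level model
probabilities are bin integrals over `[l−½, l+½)` with the tails piled onto
levels 0 and 255 — exactly the effect of rounding and clipping — so the
histogram model is exact for quantized images, including the regime where
the background peak touches level 0.

## Estimators

The two-point estimator is the non-centered, pair-count-normalized,
**non-periodic** autocorrelation computed with zero-padded FFTs: numerator
from `I·M`, denominator from the mask `M` (an absent mask is the all-ones
mask, so masked and unmasked paths are one code path).  Gel images are
windows of a larger medium, which is why the non-periodic estimator is used
rather than the wrap-around one.  Pair counts are recovered as exact
integers by rounding; lags with no pairs are flagged invalid (NaN).  The
estimator agrees with brute-force pair enumeration to floating-point
precision (~1e−15), which is what "exact" means for any FFT path.

Radial averaging weights lags by pair count over annuli of default width
one pixel, reports the pair-count-weighted mean lag as the bin abscissa,
keeps `r = 0` as its own point, and flags annuli with fewer than 100 pairs
(default) as missing rather than zero.  `r_max` defaults to a quarter of
the shorter image side, where estimator variance is still controlled.
Replicate aggregation returns the pointwise mean and the standard error of
the mean (SD/√n) across replicates, the uncertainty band used throughout.
Grey levels enter raw (0–255); `b` and `Δ` are absorbed by the model.

## Fitting

Internally the parameter vector is `(η, D_F, φ_A, L_A, b, Δ, σ)` — bounds
are simpler on `η` than on `φ_F`.  Default bounds are generous envelopes
around plausible collagen-gel values: `η ∈ [0.01, 6]`, `D_F ∈ [0.2, 10]` µm,
`φ_A ∈ [0.01, 0.99]`, `L_A ∈ [1, 60]` µm, `b ∈ [0, 64]`, `Δ ∈ [0.5, 64]`,
`σ ∈ [0.1, 32]` grey levels.

The optimizer is bounded trust-region least squares (`scipy`'s TRF) with
N = 8 seeded Latin-hypercube multi-starts (log-spaced for strictly positive
parameters) plus a moment-based heuristic start; the best converged start
wins, and total non-convergence raises an error carrying the best attempt.

* **Binary fit** minimizes SEM-weighted squared residuals between the
  measured covariance and `C_FF·C_AA` over `(η, D_F, φ_A, L_A)`.
* **Grey-tone fit** minimizes `w_h·L_hist + w_c·L_corr`, each term
  normalized by its number of points and `w_h = w_c = 1` by default (the
  neutral choice; the weighting is configurable because no canonical
  weighting exists for this pair of observables).  `L_hist` is the Poisson
  deviance between observed counts and the bin-integrated mixture model;
  `L_corr` is the SEM-weighted squared residual excluding `r = 0`, where
  the `σ²δ(r)` term would double-count the σ already identified by the
  histogram; the implied `C(0)` jump is instead reported as the diagnostic
  `sigma_from_c0`.  A histogram with more than 1% of mass clipped at 255
  triggers a model-bias warning.
* **Replicate protocol**: the point estimate fits the replicate-mean curve
  plus pooled histogram; each replicate is refit (warm-started) and the
  per-parameter SDs across replicates are reported as the spread.
* **Joint fit**: one optimization over shared parameters (any subset of
  `b, Δ, σ, D_F, L_A`) plus per-condition structural parameters, warm-started
  from independent per-condition fits; the loss is the sum of per-condition
  losses and is invariant to condition order.

Poisson-deviance counts from neighbouring pixels are spatially correlated,
so the absolute deviance is over-dispersed relative to its nominal degrees
of freedom; it is used as a relative objective, not as a goodness-of-fit
statistic.  Goodness-of-fit tests in the suite subsample pixels beyond the
correlation range so counts are approximately independent.

## Simulators

All generators are pure functions of (parameters, seed); a master
`SeedSequence` spawns independent substreams for the fibre, aggregate and
noise layers (and per replicate), so realizations are reproducible and
layers independent.

* Fibres: Poisson rectangles with centres on the domain extended by half
  the rectangle diagonal per side (edge correction); a pixel is covered
  when its centre lies inside a rectangle — the simplest rule that keeps
  the expected binary area fraction exactly `1 − e^{−η}`.
* Aggregates: circulant-embedding synthesis of the Gaussian field on a
  grid padded by `3·L_A` per side (wrap-around correlation ≤ e^{−4.5}),
  cropped, thresholded at α.  Domains narrower than `4·L_A` are refused.
* Grey-tone: composition of the layers with noise added before optional
  8-bit quantization.  Quantization is opt-in so estimator tests can
  separate discretization error from estimation error.
* Spheroid series: a central disk plus radial sprouts grows over time; at
  each time the distance layers are recomputed and the gel image is
  composited from one grey-tone realization per band, each with that
  band's `(φ_F, φ_A)` and series-wide `(b, Δ, σ)`.

What the generators emulate: stationary two-scale structure, per-fibre
additive intensity, Poisson overlaps, analog noise, 8-bit recording, and a
growing cell region with distance-dependent remodelling.  What they do not:
optics (PSF, depth attenuation), reflectance-mode anisotropy (vertical
fibres invisible to CRM), fibre curvature or bundling, mechanical coupling
between cells and gel, and temporal correlation of the gel between frames
(each time point is an independent realization).  Passing tests therefore
demonstrate correctness of the estimators and fits under the model's own
assumptions — not robustness to these instrument effects.

## Spheroid pipeline

Cell masks are inputs (an Otsu + small-object-removal + closing helper is
provided for fluorescence channels).  Distance layers use the exact
Euclidean distance transform in µm (isotropic pixels required), half-open
bands `[lo, hi)` starting at 0, default edges 0–500 µm in 100 µm steps;
pixels inside cells or beyond the last edge are excluded.  Layers are
recomputed at every time point.  Per (time, band) the masked histogram and
masked correlation are measured (the band is the mask), plus the
90th-percentile intensity — a model-free densification diagnostic, since
any increase of `φ_F` extends the grey-tone distribution upward while a
pure `φ_A` increase reshuffles weight between existing components without
moving them.  Conditions with fewer than 10⁴ pixels (default) are skipped
with a warning.  All retained conditions are fitted jointly with
`(b, Δ, σ)` shared; `D_F` and `L_A` can be added to the shared set, which
is the recommended mode when they are expected constant across the series —
per-condition length scales are the least-identified parameters in small
irregular bands, and sharing them stabilizes the `φ_F/φ_A` split.

## Validation problem sizes

The package's own validation runs at these scales, chosen to mirror the
fifteen-image acquisition protocol while keeping the suite fast:

* simulation↔model covariance agreement and binary-fit recovery: fifteen
  1000×1000 px realizations at 0.42 µm/px (2 mg/mL CFM operating point,
  `φ_F = 0.76, φ_A = 0.72, D_F = 1.9 µm, L_A = 8.2 µm`), simulated with
  `L_F = 60 µm` and fitted in the long-fibre limit;
* grey-tone recovery: fifteen 1000×1000 px realizations at 0.59 µm/px at
  the spheroid imaging point (`b = 9, Δ = 15, σ = 5`; `φ_A = 0.6,
  φ_F = 0.5, D_F = 2 µm, L_A = 19 µm`, `L_F = 40 µm`);
* spheroid series: five times × three 40 µm bands at 512×512 px.  This
  scaled-down geometry also scales the aggregate length to `L_A = 8 µm`
  (within the acellular range): a 512-px band at `L_A = 19 µm` holds only
  ~10–30 independent aggregate patches, so the realized per-band `φ_A`
  would fluctuate by ~0.1 and no estimator could resolve a 0.2 ramp; at
  `L_A = 8 µm` the per-band patch statistics match the full-scale study.

The replicate-mean covariance and the analytic model agree within
3 SEM at ≥99% of distances; the grey-tone fit recovers all seven
parameters within a few percent; the spheroid pipeline recovers a
near-field `φ_F` ramp and a far-field `φ_A` ramp in the correct band while
the flat parameters show no significant trend.  SEM-band coverage is
itself a random variable: replicate deviations are almost perfectly
correlated across `r` (a common density fluctuation moves the whole
curve), so occasional seeds put the entire curve near the 3-SEM edge.

## Numerical and degenerate-case notes

* `K_F` non-increasing and `C(0)/C(∞)` limits hold to 1e−8 or better by
  construction (closed forms / 64-node rule).
* Bin abscissae are pair-count-weighted mean lags, making the ≤1-pixel
  binning bias second order; missing points propagate as NaN, never zero.
* Zero or absent SEMs fall back to unweighted residuals (with a floor at
  the smallest positive SEM otherwise).
* A single-scale (no-aggregate) truth drives the fitted `φ_A` to its upper
  bound; `FitResult.at_bound()` flags such degeneracies.
* `φ_1 = φ_F·φ_A` is reported from the fitted parameters, so the identity
  holds to machine precision by construction.

## Limitations

2D only (single-Z slices; no volumetric covariograms), isotropic pixels,
convex rectangular grains, one clip level, no anisotropic or
sector-resolved correlation, no Bayesian uncertainty (spreads come from
per-replicate refits), and fitted `L_A` is tied to the Gaussian `g_W`
family.  These match the intended use: quantifying isotropic two-scale gel
structure and its remodelling from calibrated 8-bit confocal slices.
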