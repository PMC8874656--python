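# Methods

## Model

Every mixing unit of the line (Blender 1, Blender 2, tablet-press feed
frame) is modeled as a plug-flow delay in series with two equal ideally
mixed tanks. The plug-flow element contributes a pure delay `θ` (seconds);
each tank contributes an exponential stage of mean `τ` (seconds), so the
unit density is the shifted Erlang-2

    E(t) = (t − θ) exp(−(t − θ)/τ) / τ²,   t ≥ θ,

with first moment `MRT = θ + 2τ`. The general unequal-tank form
`(e^{−(t−θ)/τ₁} − e^{−(t−θ)/τ₂})/(τ₁ − τ₂)` is provided
(`e_unit_general`) but not fitted: with `τ₁ ≈ τ₂` the two tank sizes are
nearly unidentifiable and their standard errors blow up, which is exactly
why the equal-tank form is the working model.

Units in series compose by convolution, and MRTs add. The toolkit's
central empirical constraint is that within one unit the ratio
`R = τ/θ` is constant across operating conditions, giving
`MRT = τ(2 + 1/R)` and, inversely, `(τ, θ)` from any predicted MRT. `R`
discriminates mixing regimes: the first blender behaves as an almost pure
two-tank system (`R ~ 10⁴`, negligible delay), while the second blender
and the feed frame are transport-dominated (`R ≈ 0.38–0.39`).

## Numerics

* **Grids.** All curves live on uniform time grids, default step 1 s (the
  feeder/NIR measurement cadence). The default extent is
  `θ_total + 15·Στ`, which keeps truncated Erlang tail mass below 1e−4;
  shorter grids trigger a logged warning and renormalization.
* **Integrals.** Normalization and first moments use the trapezoid rule on
  the grid. The discrete Dirac delta (`e_pfr`) apportions its unit mass
  linearly over the two nodes bracketing `θ`, dividing by each node's
  trapezoid quadrature weight, so both the integral and the discrete mean
  are exact — this preserves MRT additivity even on coarse grids.
* **Convolution.** Direct `np.convolve` scaled by the step, truncated to
  the grid and renormalized to absorb truncation loss. MRT additivity
  under discrete convolution holds to within ~1 grid step (tested at
  2·step).
* **Degenerate inputs.** All-zero traces, non-positive `τ`, delays beyond
  the grid, mismatched grids, crossing rejection limits and rank-deficient
  surface designs raise typed errors (`rtdkit.errors`) rather than
  propagating NaNs.

## Joint fitting and deconvolution

Measured impulse traces are normalized to densities (optionally after
constant-baseline subtraction, off by default since synthetic traces are
generated baseline-free) and fitted by least squares on `E(t)` values over
the grid. One `τ` per condition and a single shared `R` per unit are free;
replicates contribute residuals simultaneously. Reported parameter counts
follow the bookkeeping convention of one `τ`, one shared `R`, and one
goodness-of-fit statistic per `τ` — `2·n_conditions + 1` (25 for a
12-condition blender, 9 for the 4-flow feed frame); the optimizer's free
unknowns are `n_conditions + 1`.

Because the blenders are in series and measurements are taken at the
Blender 2 outlet (blend NIR) or after the press (tablet assay), upstream
units are isolated by *forward* deconvolution: the candidate kernel is
convolved with the already-fitted downstream kernels and compared to data.
Numerical division in the frequency domain is never used — it amplifies
measurement noise. The characterization order is therefore fixed:
Blender 2 → Blender 1 → feed frame, and missing downstream results raise
dependency errors.

The optimization is strongly non-linear (the delay/tank split is nearly
flat in some directions), so the solver is bounded trust-region least
squares (`scipy.optimize.least_squares`) on log-parameters, `τ ∈ [0.1,
10⁴] s`, `R ∈ [10⁻³, 10⁶]`, with a Latin-hypercube multi-start (default 8
starts, seed 1234). The first start uses `τ₀ =` half the empirical curve
MRT and `R₀ = 1`. The best start's solution is kept; total failure of all
starts raises a fit error.

**Goodness of fit (ε).** ε of a parameter is its asymptotic standard
error: `√(diag(SSE/(n−p) · (JᵀJ)⁻¹))` from the Jacobian at the optimum,
mapped off the log scale by the delta method. ε propagates to the MRT via

    ε_MRT² = (2 + 1/R)² ε_τ² + (τ/R²)² ε_R².

Standard errors are the conventional per-parameter fit statistic and feed
the propagation formula naturally; a confidence half-width or RMSE would
only rescale the weights used downstream.

## Empirical surfaces

Blender MRT follows `A/ṁ + B/β + C/(ṁβ) + D`; the feed frame (whose
paddle speed is slaved to the press) follows `E/ṁ² + D`. Every term is
inverse in the operating factors, matching the observed monotone decrease
of residence time with throughput and impeller speed, and the constants'
units (s·kg/h, s·rpm, s·kg·rpm/h, s·kg²/h²) only cancel under division.
Both forms are linear in the constants, so the 1/ε-weighted fit (weight
applied to the residual, i.e. 1/ε² on squared residuals; uniform
rescaling of all ε leaves the solution unchanged) is a closed-form scaled
least-squares solve. Parity statistics report the squared Pearson
correlation between observed and predicted plus the RMSE; both weighted
observations and the unweighted statistic are available since parity-R²
conventions vary.

## Prediction, dampability, rejection limits

The full-line kernel is the triple convolution of the unit models. The
prediction engine convolves the 1 s feeder concentration trace with that
kernel; the normalized kernel has unit steady-state gain, so constant
input reproduces itself. Samples earlier than the kernel's 99.9% CDF time
are masked (NaN) by default because they depend on unknown pre-trace
history; `mask_startup=False` disables this.

Dampability is operationalized for linear time-invariant mixing: a
rectangular inlet disturbance of amplitude `a` and duration `T` produces
peak outlet deviation `a · max_t [F(t) − F(t−T)]`, the largest kernel-CDF
mass any window of width `T` captures. This is exact for LTI systems and
makes the funnel region monotone in `a`, `T`, and (by stochastic
dominance) kernel MRT. Note that under this operationalization a ±30 %LC
disturbance lasting 200 s is *not* dampened below 5 %LC even by the
slowest full-system kernel (the window then captures well over a sixth of
the CDF mass); a claim to the contrary would require a different
disturbance shape or criterion, so the toolkit computes and reports the
deviation rather than asserting such a region.

Validation compares composite tablet assays to predictions via
`RMSEP = √(Σ(x_tablet − x_model)²/N)` with a 6 %LC acceptance criterion.
The in-process limits are tightened from the 85–115 %LC specification by
`z₀.₉₅·√(RMSEP² + σ_w²)` with `z₀.₉₅ = 1.645` (one-sided 95%), where
`σ_w` is the tablet-weight variability contribution. σ_w is a
configuration input defaulting to 0 (with a logged warning in the CLI): it
is product-specific and not derivable from the model.

## Synthetic data

The generator emulates the characterization campaign of the reference
line: 12 Blender 2 pulse conditions (4 mass flows 15–90 kg/h × 3 impeller
speeds 150–300 rpm), 12 Blender 1 conditions (× 180–450 rpm, second
blender at its 210 rpm center point), and 4 full-system conditions at the
center-point speeds; 30 g tracer for Blender 2 pulses and 100 g for
Blender 1, blend NIR sampled at 1 s, composite tablet assays every 25 s
(the plant cadence is 20–30 s; 25 s is fixed for determinism). Ground
truth defaults to the reference regressed MRT tables combined with the
per-unit shared ratios.

A tracer mass `m` grams at flow `ṁ` produces a concentration deviation
`100·(m/ṁ_g/s)·E(t)/w_API` %LC with API weight fraction `w_API = 0.25`,
so mass is conserved exactly: integrating the trace times the flow
returns `m`. Traces are generated baseline-free (deviation above
background), so normalization round-trips without baseline handling.

Noise is additive Gaussian on %LC — 2.6 %LC for blend NIR (the
calibration's cross-validation error) and 1.0 %LC for tablet HPLC by
default — plus an optional multiplicative component for relative-noise
recovery studies. In `gen_tablet_samples` the HPLC sigma is per tablet
and composites of 10 average it down by √10; in the step-change validation
it is applied per composite assay, representing the assay error of the
reported composite value. What the generator does **not** emulate:
feeder loss-in-weight dynamics, powder segregation, NIR calibration drift,
non-Gaussian assay errors, and condition-dependent deviations from the
equal-tank model. Passing recovery tests therefore demonstrates the
correctness of the estimation machinery under the stated model, not the
model's adequacy for any particular plant.

The step-change validation protocol holds each level (100 → 115 → 100 →
85 %LC, spanning the specification range) long enough for the kernel to
settle, then samples duplicates at the t10/t50/t90 transition times (the
kernel CDF inverse at 0.10/0.50/0.90 from step onset): 3 flows × 3 steps
× 3 time points × 2 duplicates = 54 samples. Duplicates are modeled as
independent composites.

## Problem sizes and determinism

Default test and pipeline runs use 1 s grids spanning `θ + 15Στ`
(hundreds to a few thousand points per curve), full 12-condition joint
fits, and reduced multi-start counts where the noise-free objective is
convex enough to need none. All randomness flows from a single integer
seed through per-experiment spawned substreams, so campaigns, fits and
reports are bit-reproducible for a fixed configuration.

## Known limitations

* The shared-`R` constraint is an empirical regularity of the reference
  line, not a physical law; lines with speed-dependent delay fractions
  need per-condition `R`.
* For strongly back-mixed units (`R ≫ 1`) the delay is unidentifiable and
  the fitted `R` is only determined up to "large"; its standard error is
  correspondingly wide.
* The published per-condition MRT tables scatter about their own empirical
  surfaces by up to ~15% (second blender); surface predictions inherit
  that scatter. End-to-end surface recovery is exact only when data are
  generated from the surfaces themselves.
* Funnel analysis assumes rectangular disturbances and LTI mixing;
  feedback control at the feeders is out of scope.
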