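# Methods

## Problem and model

`econn` identifies directed (effective) connectivity between brain
regions from their sampled time series. Given R region responses
Y_1(t) … Y_R(t) at a fixed repetition time and per-region system inputs
u_1(t) … u_R(t), each region in turn is treated as the *seed* and
modelled as a polynomial NARX (nonlinear autoregressive with exogenous
input) expansion of all regions' pasts:

    Y_s(t) = b0 + Σ_{r,l} a_{rl} Y_r(t-l) + Σ_{r,l} b_{rl} u_r(t-l)
                + Σ_{r,l} g_{rl} Y_r(t-l)² + Σ_{r,l} h_{rl} u_r(t-l)²  + ε(t)

with lags l = 1 … P. Cross-region products (e.g. Y_2(t-1)·Y_3(t-2)) are
excluded: a term must name a single source region to read as a directed
edge. For R = 8 and P = 3 this is 96 predictors plus an intercept — 97
parameters against ~120 time points — so the model is estimated sparsely:

1. **Structure selection.** The LASSO objective
   (1/2N) Σ (y_i − b0 − x_iᵀβ)² + λ Σ|β_j| is solved over a descending
   λ path (default 100 log-spaced values from the data's λ_max down to
   λ_max·10⁻⁴). Predictors are standardised internally before
   penalisation so blocks on different scales (inputs vs squared terms)
   face the same shrinkage; reported coefficients are back on the
   original scale; the intercept is never penalised. K-fold
   cross-validation (default K = 10, fold membership by a seeded
   shuffle of rows) scores each λ by held-out mean squared prediction
   error. λ_min minimises the mean CV error; λ_1SE is the largest λ
   within one standard error (sd of fold errors / √K) of that minimum.
   The default rule selects λ_min.
2. **Inference.** The selected support is refit by ordinary least
   squares, and each term is tested by nested models: F =
   ((RRSS − URSS)/q) / (URSS/(N−k)) with q = 1, N the design rows and k
   the number of unrestricted parameters including the intercept
   (N = 117, k = 6 gives the reference df of 111). The signed t
   statistic is sign(β)·√F, so t² = F exactly; p-values come from
   F(1, N−k). Significant terms (default α = 0.05, no multiplicity
   correction; a Bonferroni flag exists) become directed edges:
   (Input, region 3, lag 2) in seed V1's model reads "u₃ → V1 at lag 2".

## System inputs

For periodic (block / phase-encoded) task designs the stimulus drive is
modelled by the *fundamental frequency of the response itself*: per
region, the non-DC DFT bin of maximum magnitude over bins 1 … ⌊T/2⌋
(ties to the lower frequency) is reconstructed as a time-domain
sinusoid, preserving amplitude and phase. The DC level is discarded —
the model intercept absorbs it. The extraction operates on whatever
series it is given; the pipeline applies it after Z-scoring, and that
choice is recorded in the run report. Resting state uses u ≡ 0, in
which case the input and squared-input blocks are dropped from the
design by default (they are identically zero); a flag retains them as
zero columns. A measured input may instead be supplied as a file.

## Pre-processing

The first frames of a scan (default 8 of 128) are discarded for
magnetisation equilibration, then each region is Z-scored over the
retained frames using the sample sd (divisor T−1). Z-scoring is
idempotent and trimming resets the normalisation flag, since trimming
invalidates exact column moments.

## Simulator

The generator runs the same polynomial model forward from a sparse
ground-truth coefficient set, with deterministic periodic inputs
(sinusoid or square wave; per-region cycle count, amplitude, phase) and
Gaussian innovation noise. Inputs do not depend on the random seed, so
seeds vary only the noise realisation. Initial values are standard
normal; a burn-in (default 100 steps) is discarded. Boundedness
(|Y| < 10⁶) is enforced because squared recursions diverge easily;
fixture quadratic coefficients stay ≤ 0.1 in magnitude.

The bundled 8-region fixture emulates a phase-encoded visual run: 120
frames at TR 3 s, sinusoidal drives, noise sd 0.25 so each region's
spectrum is dominated by its drive, and about five true terms per
region spanning the linear AR, input and quadratic blocks (self-AR at
lag 1, a ring of cross-region AR influences at lag 2, own input at
lag 1, a cross-region input at lag 3, and one squared term). Two
deliberate identifiability choices:

- **Distinct drive frequencies (6–13 cycles per record).** If every
  region shared one stimulus frequency — a literal reading of a
  travelling-wave design — any two lags of a sinusoidal input would
  span all its other lags, making the lag of an input edge
  algebraically unidentifiable at any sample size. Region-specific
  frequencies keep cross-region input terms identifiable; what still
  distinguishes AR terms from input terms at the same frequency is the
  region-specific innovation noise carried by the responses.
- **Collision-free squared sources.** A squared sinusoid oscillates at
  twice its fundamental, so squared-term sources are restricted to
  regions whose doubled frequency (16/20/24 cycles) coincides with no
  other drive in the system; otherwise a squared column aliases another
  region's input and produces strongly significant spurious edges.

What the fixture does *not* emulate: haemodynamic convolution and its
lag structure, physiological (cardiac/respiratory) noise, slow drifts,
inter-voxel averaging, or event-related designs. Passing recovery tests
therefore shows the estimator recovers the model class it assumes, not
that real BOLD data satisfy that class.

## Calibration results the suite computes

- The per-term F test, given a fixed (not selected) support, is well
  calibrated: empirical type-I error ≈ 0.05 at 200 seeded replicates,
  and power ≈ 1.0 for a standardised effect of 0.5 at n = 117.
- With noise off and the true support handed to the refit, generating
  coefficients are recovered to ~1e-15 (a short burn-in keeps the
  decaying initial transient in the record so the support columns are
  well conditioned).
- End-to-end on the fixture (25 seeds, true inputs supplied in file
  mode), the median fraction of true terms present in the min-deviance
  support is ≈ 97–100%.
- Median false *significant* edges per seed region is ≈ 3–4, not ≤ 2.
  This is a property of the procedure, not a defect of the
  implementation: min-deviance cross-validation on this low-noise
  regime genuinely selects 20–45 terms (R's cv.glmnet selects the same
  order on identical exported data, with λ_min/λ_1SE within ~10%), and
  naive OLS refit t-tests on ~20 selection-biased null terms then
  produce ~3–4 spurious significances at α = 0.05. The 1SE rule or a
  multiplicity correction would reduce this, but the default follows
  the min-deviance rule with uncorrected α. The per-seed JSON report
  carries a post-selection-inference caveat for exactly this reason.

When counting false edges the benchmark accounts for one basis-change
effect: the analysis Z-scores responses, and a raw Y_s² term re-expands
in the Z-scored basis as (quadratic + its linear partner + constant),
so the linear partner of a true squared-response term genuinely carries
a nonzero coefficient there and is not counted as false (nor credited
as a recovery).

## Numerical choices

- LASSO is solved by coordinate descent (scikit-learn's `lasso_path`)
  on standardised predictors and centred response, warm-started down
  the path with a precomputed Gram matrix; dual-gap tolerance 1e-7 for
  the final path and 1e-5 inside CV folds (the CV curve only ranks λ).
- Standardisation inside the selector uses the population sd, matching
  the λ_max subgradient formula; Z-scoring of data uses the sample sd.
- Exactly constant predictor columns (detected by zero peak-to-peak
  range) are excluded from the fit with a warning and report
  coefficient 0.
- OLS refits use `numpy.linalg.lstsq` (minimum-norm on rank
  deficiency); RRSS < URSS from round-off is clamped. A numerically
  perfect fit (URSS ≤ 1e-12·max(1, yᵀy)) reports F = ∞, p = 0 with a
  warning.
- λ_min ties break toward the larger λ (first index on the descending
  path). Empty supports refit to the intercept-only model, mean(y).
- CV on shuffled folds of autocorrelated series leaks some dependence
  across folds; this follows the generic K-fold convention of the
  reference implementations (cv.glmnet / lassoglm) and is the main
  reason min-deviance overselects here. A blocked-CV variant would be a
  natural extension but is deliberately not the default.

## Problem sizes

Defaults throughout match the reference protocol: 128 frames with 8
dropped, R = 8, P = 3 (so 117×96 designs), 10-fold CV, α = 0.05. The
calibration suites use 200 replicates for size/power and 25 fixture
seeds for structure recovery; a full 8-seed pipeline run on the fixture
takes well under two minutes on one CPU.
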