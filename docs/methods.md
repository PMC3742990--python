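# Methods

This note documents the models, parameter choices, and numerical decisions
behind the package, and what the synthetic-data validation does and does not
establish about real data.

## Experimental designs

The default design (`DesignSpec`) is a rapid event-related session: six runs
of 224 volumes at TR = 2 s (448 s per run), 3-s drifting-grating trials, 10
trials per speed per run, and 10-s buffers at both ends. Speeds are
{2, 4, 8, 13.3}°/s in the first stimulus set and {3, 6, 10}°/s in the
second; mean luminance is 30 cd/m² (high) or 1.5 cd/m² (low), assigned to
whole runs either alternately (first set) or in two blocks (second set).

Inter-trial intervals are integer seconds drawn from a Poisson law with
mean 5.5 s, rejection-sampled to [2, 10] s. Only the family, the mean, and
the range are specified by the design; we keep λ = 5.5 because the exact
mean of the truncated law is 5.465 s, indistinguishable from the nominal
mean at any realistic sample size. A run layout that overflows the closing
buffer is redrawn (bounded retries).

Trial onsets live on a 1-s grid and are deliberately *not* TR-aligned:
3-s trials plus integer ITIs land on both odd and even seconds. All
stimulus-locked regressors are therefore built on the 1-s grid and sampled
at TR instants. This onset jitter is what makes a 1-s-resolution FIR kernel
identifiable from 2-s samples.

## Synthetic BOLD model

Each voxel's series is

    x(t) = Σ_j a_j · h(t − t_j) + drift(t) + ε(t),   ε ~ N(0, σ²) iid,

with a shared double-gamma kernel *h* (modes at 5 s and 15 s, undershoot
ratio 1/6, unit area — any smooth single-peaked kernel would do, since the
analysis estimates the HRF rather than assuming it). Trial amplitudes follow
Gaussian tuning in log2 speed:

    a_j(v) = g_L(v) · exp(−(log2 s_j − c_v)² / 2w_v²) + u_v · [L_j = high].

Defaults (chosen once, on physical grounds; n = 120 voxels as a scaled-down
region of interest):

| parameter | default | rationale |
|---|---|---|
| gain g | 15 kernel units | ≈1.5% peak single-trial signal change, a strong visual response |
| noise σ | 1.0 % per TR sample | typical 3-T voxel noise |
| tuning width w | 1.0 log2 units | octave-scale bandwidth |
| center spread | 1.0 log2 units around 6°/s | voxel heterogeneity; population mean tuning is band-pass peaking mid-range |
| eccentricity gradient | 1.0 log2 unit across 25 mm | periphery prefers faster speeds |
| drift | 3 cosines < 0.025 Hz, 1% amplitude | removed by the specified high-pass filter |
| luminance gain ratio | 1.0 | no mean luminance effect |
| luminance pattern u | sd 0 (off) | exposed as a free parameter; the additive pattern is what the binary decode detects |

Preferred speed varies linearly (in log2) with cortical eccentricity; a
separate low-luminance gradient injects the luminance × eccentricity
interaction when desired. With `baseline > 0` the generator emits raw units
`baseline·(1 + x/100)` so the percent-signal-change step is exercised; with
the default `baseline = 0` the output is already in percent-like units and
noiseless recovery tests are exact to machine precision.

What the generator does **not** emulate: spatial noise correlations and
smoothness (the analysis uses no spatial operations), physiological noise
spectra, motion, susceptibility artifacts, nonlinear BOLD summation at short
ITIs, and session-to-session voxel misalignment. Passing tests therefore
establish correctness of the *computations* under the linear model the
analysis itself assumes — not robustness of the science to everything real
data can do.

## Preprocessing

Percent signal change first (per voxel: 100·(x − mean)/mean against the
raw-series temporal mean; voxels with non-positive baselines are zeroed with
a warning), then high-pass filtering. The order is recorded in provenance.
The filter removes the discrete-cosine components with frequency below
0.025 Hz (DC included): a zero-phase orthogonal projection with no edge
transients, exactly idempotent and linear, attenuating sub-cutoff sinusoids
by well over 90% while passing components above twice the cutoff within 5%.

## HRF deconvolution and trial amplitudes

Deconvolution fits, per condition, an unconstrained FIR kernel (default
window 20 s at 1-s lag resolution — roughly the span of the positive lobe
plus undershoot; the choice only needs to cover the response) to the
ROI-mean series, with per-run intercepts. Per-condition kernels are averaged
with equal weights and rescaled to unit area. When the data were high-pass
filtered, the design columns are filtered identically; otherwise slow
kernel components would be estimated with bias.

The trial GLM places one copy of the pooled unit-area kernel per trial
(built on the 1-s grid, sampled at TR instants, truncated at run end), adds
per-run intercepts, and solves per-voxel OLS. R² is computed around the
series mean; `mean_sign` (sign of the mean fitted amplitude) marks positive
responders. The R² > 0.25 responsiveness mask uses the condition-pooled
model fit.

## LARS-LASSO

The coefficient path is computed by least angle regression with the LASSO
drop modification: active absolute correlations decrease at a common unit
rate along the equiangular direction; breakpoints occur where an inactive
covariate's correlation reaches the shared maximum (entry) or an active
coefficient crosses zero (drop, with re-entry possible later at flipped
sign). Numerical decisions:

- Entering covariate ties break toward the lowest column index; exact
  duplicate columns can never co-enter (their entry step is degenerate and
  skipped), and constant columns are excluded with a warning.
- The active set is capped at `n_samples − 1` (the rank of a centered
  design) — beyond it the equiangular direction is undefined.
- `max_active` counts currently active covariates, so a drop frees a slot;
  the fitted model is the path solution at which covariate
  `max_active + 1` would enter (matching the usual n-nonzero truncation).
- Columns are centered and unit-variance scaled inside the estimator;
  reported coefficients are de-standardized.
- The permutation control reuses per-fold Gram matrices and runs the path
  in Gram form; a test pins this fast route to the estimator route.

Decoding covariates are per-trial patterns normalized to unit Euclidean
norm over the ROI; the univariate control deliberately uses non-normalized
amplitudes collapsed across voxels. Voxel selection happens inside every
cross-validation fold (no selection leakage). The label permutation of the
chance control is across all trials of the session, not stratified by run.

For the binary (0/1-coded) luminance decode, training runs are balanced per
fold by dropping surplus runs of the majority class (lowest index first):
with blocked single-luminance runs, an imbalanced pool would bias the
prediction toward the majority class and away from the held-out run's
class, producing systematically below-chance thresholded accuracy even for
uninformative patterns. Balancing restores the natural null behavior
(class means ≈ 0.5, accuracy ≈ 50%).

## Retinotopy

The phase-encoded fit is the DFT coefficient at the stimulus frequency
(cycles per run must be an exact bin, hence the integer-TR-per-cycle
requirement). Coherence is that bin's one-sided amplitude divided by the
root sum of squares of all non-DC bin amplitudes up to Nyquist; selection
uses a strict threshold (> 0.25 by convention). Phase follows
`x(t) = A cos(2πft − φ)`, so later responses have larger phase; no
hemodynamic phase-lag correction is applied. For synthetic data the
eccentricity coordinate is the generator's linear phase map; identifying
area boundaries on a cortical surface is out of scope (coordinates and
masks are inputs).

## Preference profiles and the slope test

Winner-takes-all labels use the largest *signed* t (the analysis is
restricted to positive responders), with ties broken toward the slower
speed. Binning uses 10 equal-width bins over the eccentricity span with the
2 most peripheral dropped; empty bins are recorded as missing and excluded
from regressions (no imputation), and bins with under 10% included voxels
carry a flag.

The slope test regresses the bin-wise difference between the high- and
low-luminance *mean* profiles on bin position (slope *b*, Pearson *r*; the
mean-profile convention, since a per-subject-then-average convention is
equally defensible but changes nothing under the null). The null pools all
subject × hemisphere × luminance profiles, splits them randomly into two
equal sets, and recomputes the difference regression; with no missing bins
the 10,000 iterations are fully vectorized. The default p-value counts
iterations where **both** |b| and |r| reach the observed magnitudes, with a
+1 correction; a signed one-sided mode exists.

**Calibration caveat.** The joint b-and-r condition follows the original
procedure but is anti-conservative: requiring two exceedances shrinks the
null count, and simulation with 24 exchangeable profiles puts its type-I
error near 0.09 at a nominal 0.05. `require_r=False` drops the second
condition and gives an exactly exchangeable single-statistic permutation
test (measured rejection ≈ 0.04–0.05, the +1 correction making it mildly
conservative). Users testing their own data should prefer
`require_r=False`; the default reproduces the published procedure.

The profile-level generator used for cohort analyses defaults to 6 subjects
× 2 hemispheres, 8 usable bins, a high-luminance slope of 0.1 log2 units
per bin, a low-luminance slope of 0.2 (the 0.1-per-bin interaction), and
per-bin profile noise of 0.3 log2 units — a realistic between-subject
spread for bin-mean preferences on a coarse speed grid.

## Determinism and problem sizes

A single master seed is split into named substreams (design, population,
noise, permutations, resampling) via `numpy.random.SeedSequence`, so any
stage can be re-run independently and the whole bundle is a pure function
of (config, seed); rerunning a pipeline writes byte-identical summaries.
Simulated regions default to 120 voxels and single sessions to 6 runs —
deliberately compact study-condition sizes at which every stage's
statistical behavior (recovery, decoding, calibration, power) is already
measurable; all sizes scale through configuration.
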