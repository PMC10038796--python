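# Methods

This note documents the statistical model behind each stage of `crossisc`,
the defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions a maintainer would want
written down.

## ISC estimation

Pearson correlations are computed on run-concatenated series after removing
each run's temporal mean (runs are normalized run-wise in typical
preprocessing, and a surviving run-mean offset would otherwise masquerade as
slow shared signal). Plain averaging of pair correlations is used — no
Fisher z transform — so the map is the mean r the field usually reports.
The per-voxel t-statistic divides mean pair r by the standard error of the
pair r's, treating pairs as independent observations. Pairs sharing a
subject are of course dependent; the statistic is used only as a ranking
quantity whose null distribution comes from the permutation machinery, which
absorbs that dependence. Voxels with a zero-variance series in any pair are
marked invalid (NaN) and excluded from inference.

Across-condition ISC uses only the N_A × N_B cross pairs. With 10 and 10
subjects that is 100 pairings; with 9 and 9, 81.

ROI analyses average the raw series over the mask voxels before
correlating; a 6 mm-radius sphere helper (3 mm voxels) matches common
reporting. Region-level group differences use the two-sided Wilcoxon
rank-sum test on per-pair ISC values with Bonferroni correction over
regions; W is reported as the sum of (mid)ranks of the first sample.

## Surrogate null and tail p-values

A surrogate series splits each run into `chunks_per_run = 3` contiguous
chunks (remainder timepoints joining the run's last chunk), pools the chunks
across runs, permutes them globally, and reverses each chunk in time with
probability 1/2. This preserves the value multiset exactly — hence mean,
variance, and amplitude distribution — and most of the autocorrelation,
while destroying stimulus locking. Reversal is per-chunk and independent
(maximal surrogate entropy under the scheme; it can be disabled). Every
subject's every voxel series is surrogated independently in each
permutation: the null hypothesis is the absence of stimulus-locked signal
in *all* subjects.

Permutation p-values use the never-zero counting estimator
(1 + #{null ≥ obs}) / (n + 1). When the observed statistic is in the extreme
tail (empirical p < 0.10) a generalized Pareto distribution is fitted by
maximum likelihood to the exceedances above the 90th percentile and the tail
probability is read off the fitted survival function. An Anderson–Darling
A² check guards the fit; on rejection the threshold is raised by 10
exceedances and the fit repeated, falling back to the counting estimate
below 30 exceedances. The A² critical values are shape-dependent constants
interpolated from published tables for the GPD with estimated parameters;
they control only the refit cadence, never the p-value formula. With fewer
than 50 null samples the counting estimator is returned directly (a tail
fit on less data is meaningless; this also keeps single-permutation
degenerate cases well defined).

Familywise error control thresholds at the (1 − α) quantile of the
per-permutation maximum statistic over voxels; maps can additionally be
filtered by minimum cluster extent (default 20 voxels) under 6/18/26
connectivity (default 18, common volumetric practice).

## Model mediation

Feature models are first orthogonalized against the editing descriptors:
each column is replaced by its residual on an intercept plus all linearly
independent editing columns (rank-deficient editing matrices are pruned
with a warning). The design is then built by convolving each column with a
canonical double-gamma HRF (peak 5 s, undershoot 15 s, peak:undershoot
6:1) at the model's native rate, averaging within TR bins, z-scoring per
run, and appending per-run intercept columns. HRF convolution can be
disabled (`hrf=False`) for lag-zero regression; the temporal alignment of
features to BOLD is genuinely open in this kind of analysis, and the
canonical HRF is the field's default assumption.

Residualization appends a global intercept only when the constant vector is
not already in the design span (run intercepts span it), then projects with
the annihilator I − XX⁺. Mediated ISC recomputes the across-condition ISC
on residuals; the drop is the voxelwise difference. Cross-modal assignment
removes visual features from the audio-only group and acoustic features
from the visual-only group, while an inherently multimodal semantic model
is removed from both.

Per-pair drops (pair r raw minus pair r residualized) decompose the
map-level drop and feed the low-vs-high contrast: per voxel, a Wilcoxon
signed-rank W (sum of ranks of positive paired differences, midranks for
ties, zeros dropped, fewer than 5 nonzero differences → untestable) with a
sign-flip permutation null. One flip pattern is shared by all voxels within
a permutation so the max-W and min-W distributions give two-sided
familywise thresholds. Exhaustive enumeration of all sign patterns is
available for small pair counts.

A caveat the tests make explicit: regressing k design columns out of a
short scan removes a visible share of slow shared variance even when the
design is independent of the latent (smooth regressors overlap slow signal
by construction), so the null-mediation property (mean drop ≈ 0) holds at
realistic scan lengths (~1,600 timepoints) and degrades at toy lengths.

## TRW mapping

ISC is recomputed after moving-average smoothing at widths from 2 s (one
TR, exactly the classical map) to 240 s in 2 s steps, sliding one timepoint
at a time; only full windows are used (padding would bias long-window
correlations). The per-voxel peak width is the argmax of mean r over
widths, ties broken toward the smallest width (the most conservative
integration claim). Significance evaluates surrogate ISC *at each voxel's
observed peak width* — its specific temporal tuning — with GPD tails and
max-statistic FWE; re-maximizing over widths per permutation is available
as a stricter option. Map similarity is Spearman ρ over a voxel mask,
tested two-sided against ρ's obtained by replacing one map with each of 200
surrogate-derived peak maps.

## Synthetic data

The generator emulates: two matched groups (default 10 subjects each)
whose every "shared" voxel carries one latent series embedded identically
in all subjects of both groups; per-subject AR(1) noise at lag TR
(coefficient 0.3, typical of preprocessed BOLD residuals; unit innovation
variance, re-initialized at run boundaries); defaults of TR = 2 s and 1,614
timepoints in six runs of 269. Feature-model-driven components are added
with known per-voxel weights, and feature models are built with an exact
collinearity structure: each model column is c·(editing mixture) +
√(1−c²)·(unique smooth component orthogonalized against the editing span),
so the squared multiple correlation on the editing set is c² by
construction. Stimulus streams are white noise sharing Hann-enveloped
sinusoids inside planted events (a rectangular burst would splatter
coherent power across periods).

The latent of a voxel "tuned" to timescale w is *narrowband* noise. A
low-pass latent (e.g. a moving average) cannot define a TRW: beyond the
smoothing width both it and white noise attenuate at the same 1/W rate, so
the ISC-by-width profile plateaus and the peak is undefined. Instead the
band centre is solved numerically — from the discrete rectangular-window
transfer, the AR(1) noise spectrum, and a 1 − |G_L|² model of per-run mean
removal — so that the expected windowed signal-to-noise ratio peaks exactly
at w (the closed-form seed is W* ≈ 0.371 P for a narrowband period P,
from maximizing sin²x/x). The amplitude spectrum is deterministic with
random phases: each realization then has the same power profile, so a
voxel's realized tuning does not wander with the few frequency bins a slow
band contains. Relative bandwidth is 0.15 — narrow enough for one
well-defined tuning, wide enough not to be a pure sinusoid. With amplitude
a and unit white noise the expected pair correlation is a²/(a²+1),
independent of band shape, which anchors the generator's calibration
tests.

Not emulated: hemodynamic forward modelling, spatial correlation between
voxels, head motion, scanner drift, and physiological noise spectra.
Passing tests therefore demonstrate the *statistical machinery* —
calibration, recovery, exactness — not robustness to those artifacts in
real data.

## Stream coherence

The continuous wavelet transform uses the analytic Morlet with ω₀ = 6
(Fourier factor 1.033), computed in the frequency domain, on a log-spaced
period grid of 12 voices per octave from 4/fs to duration/4. Coherence is
the magnitude-squared smoothed cross-spectrum over the product of smoothed
auto-spectra, with spectra scaled by 1/scale, Gaussian time-smoothing of
standard deviation 2·scale, and a 0.6-octave boxcar across scales. The
time-smoothing constant (2, rather than the 1 often used for significance
contouring) was chosen so that independent noise essentially never reaches
the default event threshold of 0.9 — event segmentation here uses a fixed
threshold, not a surrogate significance test, so the estimator itself must
be quiet under the null; a surrogate-pair null remains available as an
alternative criterion. The cone of influence marks cells within √2·scale
of either edge. Events are 8-connected components of supra-threshold cells
outside the cone with at least 64 cells (suppressing speckle), summarized
by onset, time extent, and coherence-weighted mean period. Detected
boundaries are smeared by the time smoothing; `smoothing_width_s` (the
kernel FWHM ≈ 4.7·scale) states that resolution explicitly, and recovery
tests assert onsets within one such width and durations within two (one
per edge).

## Problem sizes in tests

Calibration tests use 2 × 5 subjects, 200 voxels, 300 timepoints and 500
permutations (type-I error); 100 independent 4 + 4-subject, 50-voxel
datasets at 200 permutations each (FWE); 50 replicates of 10 + 10 subjects
at the full 1,614-timepoint scan for TRW recovery; 500 voxels at full scan
length for null mediation. These sizes keep the whole suite at a few
minutes on one CPU while leaving every estimate's Monte-Carlo error well
inside the asserted bands.

## Known limitations

- The pair-level t-statistic ignores pair dependence by design; only its
  permutation null is calibrated, not its nominal t distribution.
- GPD tail estimates inherit extrapolation variance; on a 10,000-sample
  exponential null the tail p at the 1e-4 level is typically within a
  factor ~1.5 of truth but occasional draws fall outside.
- The run-demeaning model used in TRW band calibration is multiplicative
  in the frequency domain and ignores window/run-boundary interactions;
  residual peak bias at the longest timescale (120 s) is about one width
  step.
- Event onset/duration from thresholded coherence are biased outward by
  the smoothing kernel; they are accurate at the stated resolution, not at
  sample resolution.
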