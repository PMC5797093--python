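# Methods

## Experimental layout and index conventions

`StimulusDesign` encodes the temporal structure the whole pipeline assumes:
`n_pieces` pieces of equal duration (default 40 × 46 s at TR = 2 s, so 23
volumes per piece) arranged into `n_medleys` medleys of
`pieces_per_medley` pieces; one medley per functional run; every medley
presented once in each of `n_sessions` sessions (four presentations per
piece at the defaults).  Runs carry 10 warm-up and 5 tail volumes that
never enter any analysis.  All volume indices are 0-based half-open
ranges.

Two windowing conventions matter everywhere:

- **Hemodynamic delay.**  The BOLD window of a piece is shifted forward by
  a rigid `hemodynamic_delay_vols` (default 3 volumes = 6 s); the feature
  window is not lagged.  Applying the shift on the BOLD side (rather than
  lagging features) was a genuinely open choice; it keeps feature matrices
  aligned with the stimulus and puts all lag bookkeeping in one function.
  The shift is absorbed by the run's tail volumes, which is why the design
  requires `hemodynamic_delay_vols ≤ tail_vols`.
- **Transition trimming.**  During decoding, 3 volumes at each end of the
  (already shifted) piece window are dropped, leaving 17 of 23, so the
  fade cross-over between adjacent pieces cannot inform identification.
  Training uses full 23-volume windows; trimming is a decoding concern.

Cross-validation folds partition pieces, never volumes.  Pairwise and
triple-wise folds are enumerated exhaustively (C(40,2) = 780,
C(40,3) = 9,880); deeper folds are sampled uniformly without replacement
(default cap 10,000) under an explicit seed recorded in outputs.  Inner
cross-validation for voxel ranking splits the *training pieces* into five
contiguous blocks, so roughly 80%/20% of the 3,496 training rows while
never letting one piece straddle folds; for miniature designs with fewer
training pieces than blocks the split degrades to one block per piece.

## Feature conditioning

The 21-channel feature schema (9 timbral, 10 sub-band-flux, pulse clarity,
key clarity) is fixed; extraction from audio is out of scope and synthetic
features stand in.  Conditioning is applied in a fixed, tested order:

1. **HRF convolution** with a double-gamma kernel (difference of two gamma
   densities, peak-normalised).  Defaults: peak delay 5 s (the auditory
   response peaks earlier than the canonical 6 s), undershoot delay 16 s,
   both dispersions 1 s, undershoot ratio 1/6, length 32 s.  These are a
   configurable stand-in — every parameter is exposed — because the exact
   auditory HRF parameterisation is a free choice of the analyst.
2. **Decimation** keeping every `decimation`-th sample starting at phase 0
   (phase configurable; 160 maps 12.5-ms hop frames to TR = 2 s; synthetic
   features are generated at TR resolution and use decimation 1).
3. **Savitzky–Golay detrending**: subtract the order-3 smooth with a 242-s
   window, i.e. 121 samples at TR 2 (the window is forced odd, a filter
   requirement).  An order-3 filter reproduces cubic trends exactly, so a
   cubic drift is removed to rounding error; edges use the filter's
   polynomial-fit (`interp`) behaviour.
4. **Joint normalisation**: each feature is z-scored over the
   concatenation of all medleys, never per medley, so between-medley level
   differences survive as genuine signal.  Population (n) variance is used
   here and in all correlation computations for internal consistency.

Variance inflation factors (VIF_j = 1/(1 − R²_j), R²_j from regressing
feature j on its peers with intercept) are computed on the conditioned
features; exactly collinear features get +inf.  Both the ascending and
descending orderings break ties by original index.

## BOLD preprocessing

Per run, in fixed order: Savitzky–Golay detrending per voxel (same filter
as the features) → nuisance regression (residualising on
[intercept | regressors]; the construction of physiological regressors is
out of scope, any regressor matrix is accepted, and linearly dependent
columns are dropped with a warning) → global-signal correction →
temporal Gaussian smoothing → per-voxel z-scoring within the run.

Two stated ambiguities are resolved as configurable defaults: the 5-s
Gaussian "width" is read as FWHM (σ = 5/√(8 ln 2) s, kernel truncated at
±4σ with edge renormalisation so constants pass unchanged), and
global-signal correction defaults to per-voxel regression, with direct
subtraction also implemented.  Note a physical consequence checked by the
tests: because the global signal of a linear mixture contains genuine
signal, global-signal regression slightly perturbs every voxel, so
"drift removal" is validated by comparing preprocessed drifting data
against the identically preprocessed drift-free signal rather than the raw
signal.

## Encoding model and voxel ranking

Per voxel, OLS on [intercept | selected features] over the aggregated
training rows; repeated presentations enter as separate rows.  With 3,496
rows against 22 parameters no regularisation is used.  Internally the
package caches per-piece sufficient statistics (X_pᵀX_p, X_pᵀY_p), so any
fold's fit is a 22 × 22 solve and the 780-fold sweep costs seconds; tests
verify the cached path against direct lstsq fits.

Voxel ranking scores each voxel by its mean prediction correlation over
the five inner folds (fit on the complement, predict the held-in rows,
correlate over time).  Zero-variance held-out series score 0 (they carry
no ranking information).  Ranking ties break by ascending voxel id.  Test
pieces are untouchable: mutating their BOLD changes neither weights nor
ranking (asserted exactly), and predicting a training piece raises.

## Identification

Measured test blocks are averaged over the four presentations and trimmed
to 17 volumes.  For a candidate set, the flattened space × time blocks of
measured and predicted data are compared by Pearson correlation; the
candidate with the highest correlation wins.  Conventions (the source
material is silent; chosen conservatively and logged): a tie counts
against the decoder; an identification whose own correlation is undefined
(zero-variance vector) is incorrect; an undefined competitor cannot win.
A consequence worth knowing: at a flattened length of 2 every correlation
is ±1, so the noiseless-data guarantee of 100% accuracy applies to cells
with v·t ≥ 3.

The sweep evaluates all (voxel-grid × 1..17 time points) cells per fold in
one pass using 2-D prefix sums over the ranking-ordered block (the
correlation of every top-(v,t) sub-block in O(V·T) total), validated
against a naive per-cell loop.  The default voxel grid is
{2, 5, 10, 25, 50, 100, 200, 300, 500, 1000}, clipped to the available
voxel count.

N-way identification ranks the N candidate predictions per measured piece
(ties give the true piece the worst tied rank); ranked accuracy is
(N − rank)/(N − 1).  The leave-one-medley-out variant holds out the 10
pieces of one run at a time.  The permutation null re-runs identification
with piece labels permuted over the whole stimulus set at the decoding
stage only; per-fold correlations against all 40 candidate predictions are
precomputed once so each of the (default 1,000) permutations is a pure
relabelling.  The resulting null is wider than an i.i.d. binomial on 1,560
trials because the 780 pairs share pieces — a property the tests assert.

## Entropy metric

Similarities are Pearson correlations between the 21-dimensional feature
vectors at all unordered distinct time-point pairs of the entire stimulus
set (self-pairs excluded), computed on conditioned features and full
23-volume windows by default (both configurable).  The global similarity
range is split into 10 equal bins (left-closed/right-open, last bin
closed so the maximum is counted); a piece's entropy is −Σ p_i log₂ p_i
over its within-piece pairs, 0 ≤ H ≤ log₂ 10.  Low/high-entropy splits
take the bottom and top 10 pieces (ties by piece id), optionally within a
category, and identification is evaluated over the 45 pairs inside each
subset.

## Feature topography

Each feature is correlated univariately with each of the top-300 (or
top-100) ranked voxels over all analysis volumes — deliberately no joint
regression, so feature collinearity cannot bias the map.  PCA is run on
the voxels × 21 correlation map: per-feature mean-centred, covariance
eigendecomposition, no re-scaling (correlations already share a scale);
the sign convention makes each component's largest-magnitude loading
positive.  Group components come from voxel-concatenated maps.
Individual-to-group matching uses Gale–Shapley with descending absolute
loading correlation as both sides' preferences (ties by component index);
with individuals proposing the result is proposer-optimal, and tests check
the no-blocking-pair property exhaustively for k ≤ 5.  For overlays,
component scores are scaled by each voxel's encoding training correlation.

## Sparsity sweep

For m = 1..21 and each VIF order, the full encode → rank → identify chain
is re-run with the first m features; the per-m accuracy is the mean over
the two orders (both orders coincide at m = 21 by construction, which is
asserted).  The accuracy curve is compared between a saturating
exponential a(1 − e^{−bm}) + c (nonlinear least squares, initialised at
a = max − min, b = 0.2, c = min, with a grid restart over b on
non-convergence, flagged if all restarts fail) and a logarithmic
a ln m + b (closed form); the functional forms are this package's choice —
the comparison is which family fits better, not parameter-exact.

## Synthetic data

Features per medley are stationary Gaussian AR(1) channels with marginal
covariance `feature_cov` (default identity) and lag-1 autocorrelation
`feature_ar_coeff` (default 0.85 — conditioned features are slow).
Optional per-piece knobs create information-content contrasts: a
fluctuation scale, a constant per-piece offset (sd `piece_offset_sd`), and
a per-piece AR coefficient.  BOLD per run is
`signal + drift + noise`: the signal places `F @ Wᵀ` at the delay-shifted
stimulus volumes; drift is a per-voxel random cubic (amplitude default 1.0,
deliberately a cubic so the order-3 detrend must remove it near-exactly —
a sharp test of preprocessing); noise is AR(1) Gaussian (sd 0.5,
coefficient 0.3 — fMRI-like autocorrelation; the choice of noise family
was open, AR(1) is analysable and realistic).  Ground truth (weights,
responsive voxel ids, per-run seed trail, noise-free signal) is returned
alongside.  Defaults: 150 voxels of which 100 responsive, mirroring the
observed ~100-voxel performance saturation; responsive weight rows are
N(0, 1/21).

`entropy_contrast_config` freezes the ensemble used for the
entropy-accuracy analyses: the first two medleys' pieces nearly constant
(scale 0.05 around per-piece offsets of sd 0.1 — within-piece similarities
pile into one bin, low H), the last two with rich dynamics (scale 1.2 —
similarities spread, high H), 40 responsive of 80 voxels, noise sd 8 so
identification runs well off ceiling.  The scale contrast is grouped by
medley because the HRF tail otherwise bleeds a rich neighbour's dynamics
into an impoverished piece's window and erases the contrast.

What the generator does *not* emulate: spatial smoothness of voxel noise,
physiological noise structure, motion, inter-subject variability, and any
nonlinearity between features and BOLD.  Passing tests therefore
demonstrate the correctness and internal consistency of the pipeline under
its own linear-Gaussian assumptions, not performance levels attainable on
real recordings.

## Problem sizes and determinism

Default analysis sizes were chosen so the full test suite runs in well
under a minute of compute per module and the acceptance script in about a
minute: 150 synthetic voxels (80 for the contrast ensemble), all 780
pairwise folds for sweeps, 10 seeded replicates (20 in the tests) for the
entropy split, 200 sampled folds for the sparsity sweep, 300 sampled folds
for 10-way decoding, 1,000 permutations for the null.  Every stochastic
step draws from an explicit seed; `run_full_analysis` derives all stage
seeds from one master seed and two runs with the same configuration
produce byte-identical TSV outputs (asserted in the tests).

## Known limitations

- The auditory HRF parameters are a documented stand-in; analyses of real
  data should set them from the acquisition at hand.
- Whether nuisance regression precedes global-signal correction is fixed
  (nuisance → global → smooth) but the evidence for the order is thin;
  both stages are exposed individually.
- Entropy defaults (conditioned features, full windows) resolve stated
  ambiguities; both alternatives are one keyword away.
- The number of retained PCA components defaults to 4 and is not selected
  by a stopping rule (parallel analysis / MAP tests are out of scope).
- Identification assumes equal piece durations; variable-length stimuli
  would need window bookkeeping the design does not model.
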