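# Methods

This note documents the models, the simulator, the numerical choices
and the known limitations of `soundcat`.

## Design generator

A run is a sequence of 6-s trials (4 s of sound — the same stimulus
twice, except on catch trials — plus 2 s of silence), with a 20-s rest
mid-run and another at the end. Defaults: 3 repetitions of each of the
24 stimuli plus 8 catch trials per run → 80 trials → 520 s. Trial order
is pseudo-randomised under the constraint that consecutive trials never
share a superordinate class (human / animal / manipulable / big-place).
The sequencer is a greedy random draw with a majority-class guard (when
one class holds more than half the remaining trials it must be drawn
next) and up to 1,000 restarts; an infeasible design raises
`ScheduleInfeasibleError` rather than looping. Note the catch-trial
bookkeeping: 8 catch trials among 80 is 10% of trials even where a
protocol might describe it as "8%"; `n_catch` is a parameter (default
8 per run).

## GLM

Design matrices contain 24 stimulus regressors (4-s boxcars convolved
with the canonical SPM double-gamma HRF via nilearn's
`compute_regressor`), one catch/no-interest regressor, `n_motion`
nuisance columns (default 6, zeros unless supplied — the package does
not estimate motion), and a constant: 32 columns at the defaults.
TR defaults to 2.0 s; a trailing partial frame is dropped with a
warning. Estimation is ordinary least squares (`numpy.linalg.lstsq`).
All-zero nuisance columns are inert and excluded from the rank check;
rank deficiency among active columns raises an error naming the
collinear columns. High-pass filtering and autocorrelation modelling
are deliberately absent: the synthetic noise is white at the β level,
and the analyses consume β (or t) images, not time series. A
`simulate_timeseries` forward model supports full round-trip testing
(β → time series → β̂).

## Synthetic β patterns

The generator plants a chosen representational geometry:

1. Take the target model DSM `D` (8×8, correlation-distance units) and
   form the similarity Gram matrix `G = 1 − D`.
2. Eigendecompose `G`; negative eigenvalues (non-embeddable targets)
   are clipped to zero with a warning. Rows of the factor are
   normalised to unit length.
3. Lift the 8 prototype vectors into voxel space through a random
   orthonormal basis constructed orthogonal to the constant vector, so
   every prototype is exactly zero-mean across voxels and pairwise
   Pearson correlations are preserved: for a positive-semidefinite
   target the noise-free condition DSM equals the target to machine
   precision.
4. Exemplars inherit their category's prototype; each subject/run
   observation is `signal_scale(group, roi) × prototype + N(0, noise_sd)`
   i.i.d. across voxels and runs.

Defaults mirror the study design: 5 runs, 100 voxels per region, two
regions ("occipital", "temporal"), noise SD 1, and a per-(group, region)
`signal_scale` map (unlisted pairs get zero signal). One master seed
drives every sub-stream through `numpy.random.SeedSequence` spawning.

What the simulator does **not** emulate: temporal autocorrelation,
physiological/motion artifacts, spatial smoothness, voxel-wise variance
heterogeneity, exemplar-level structure within a category, and
between-subject anatomical variability. Passing tests therefore
establish the correctness and calibration of the analysis chain under
its own assumptions, not the effect sizes one would observe in real
cohorts.

A consequence worth knowing: with the human-model geometry the two
human categories have model dissimilarity 0, i.e. *identical*
prototypes, so eight-way decoding of that geometry is capped near
0.875 + ε rather than 1.0, and Spearman correlations between a
continuous empirical DSM and the tied composite model are capped at
0.8766 exactly (the correlation between full ranks 1..28 and the
model's tie-averaged ranks). The geometry-recovery tests check against
this ceiling.

## Behavioral ratings and acoustics

Pitch (Hz) and HNR (dB) are drawn from per-category Gaussian profiles
chosen to be plausible for the sound classes (birdsong high-pitched and
periodic, machinery low and noisy); the deterministic table uses the
profile means. Rating DSMs are emitted directly as per-subject 8×8
matrices — a base structure (0 within category, 0.4 within
superordinate class, 1 otherwise, a 0–1 dissimilarity scale) plus
symmetric Gaussian subject noise (default SD 0.1), clipped at zero. The
group behavioral model is the elementwise mean of the group's rating
DSMs.

## ROIs and univariate analysis

The all-sounds-vs-baseline contrast is the mean β over all conditions
and runs. LOSO ROI definition computes a voxelwise Welch t between
groups on all subjects except the target and keeps the top-k voxels
(default k = 50; ties break to the lowest index for determinism).
Threshold-based selection is available and errors informatively when
empty. The Group × Category analysis is a split-plot ANOVA implemented
in closed form (subject-weighted sums of squares; the full partition —
group, subjects-within-groups, within-factor, interaction, error — is
exposed and additive by construction). Greenhouse–Geisser correction is
applied to within-factor tests when the factor has more than two
levels. An age covariate, when requested, is residualised out of every
within-level column (centred regression) before the ANOVA. With
unequal group sizes the subject-weighted SS are Type-I-style; the
designs of interest here are balanced or nearly so. `pingouin`'s
`mixed_anova` serves as an independent cross-check in the test suite,
never as the implementation.

## Decoding

Feature scoring is the one-way ANOVA F across the 8 classes
(scikit-learn `f_classif`; NaN scores from zero-variance voxels count
as 0; ties break to the lowest voxel index). The classifier is a
one-vs-one linear SVM with fixed C = 1 — no hyperparameter search, no
nonlinear kernels. Selection happens inside each training fold only;
a dedicated test verifies that replacing the held-out run with fresh
noise cannot change that fold's selected features. The searchlight
engine evaluates any scalar statistic (decoding DA, model correlation,
partial correlation, split-half stability) over spherical neighborhoods
(Euclidean, voxel units, default radius 3; radius 1.5 gives the
19-voxel neighborhood, 1.8 gives 27).

## RSA

Brain DSMs use condition-level t-maps by default (per-voxel mean/SE of
β across runs, emulating contrast t-images), averaged over the 3
exemplars per category; a β-mode flag skips the t transform. Distances
are 1 − Pearson r; every DSM is validated (symmetric, zero diagonal,
finite) on construction and only the 28-entry upper triangle enters any
statistic. Model comparison is plain Spearman ρ per model (average-rank
ties). Partial correlation rank-transforms all vectors, residualises
brain and model on the covariates plus an intercept by least squares,
and correlates residuals; collinear covariates and covariates
duplicating the model raise. Cross-region DSM correlation builds its
null by jointly permuting rows and columns of one matrix (condition
relabelling, default 10,000 draws). The noise-ceiling lower bound is
the mean leave-one-subject-out correlation; with few subjects it is a
noisy bound and a noise-free model can legitimately sit near or above
it. Split-half stability partitions runs odd/even ({1,3,5} vs {2,4}
for five runs, configurable), averages within halves, and reports mean
diagonal minus mean off-diagonal of the 24×24 cross-half correlation
matrix.

## Inference

Within-subject nulls shuffle condition labels independently within each
run (preserving the run structure the cross-validation uses); the group
null draws one value per subject with replacement and averages (default
100,000 draws; 100 permutations per subject). Group differences use
size-preserving label permutations (default 10,000), one-sided in the
hypothesised direction by default with a two-sided option, reported
with pooled-SD Cohen's d. Every p is `max(count ≥ observed, 1)/n`, so
permutation p-values are never zero. The ART interaction test subtracts
cell-mean estimates of both main effects, ranks the adjusted scores
with average ties, and runs the 2×2 mixed ANOVA on ranks, interpreting
only the interaction. Calibration suites verify type-I error within
±2 Monte-Carlo SE of 0.05 for both tests at 400 null simulations.

## Problem sizes in the validation suites

The packaged validation studies are deliberately desk-scale: chance
calibration uses 8 subjects × 100 voxels × 100 permutations with a
10,000-draw bootstrap (the null mean is insensitive to the bootstrap
depth; the library default remains 100,000); calibration suites use
400 null replicates at 1,000 permutations; structure-recovery suites
use 50 seeds at 60–80 voxels. These sizes were chosen so the whole
suite re-runs in minutes on one CPU while keeping Monte-Carlo standard
errors small relative to the tolerances tested.

## Known limitations

- No cluster-level or voxelwise corrected inference for searchlight
  maps; they are descriptive outputs.
- No motion estimation, slice-timing, distortion correction or
  normalisation: the package starts at (or simulates) the β level.
- The mixed ANOVA assumes a balanced within-subject factor.
- Exemplars within a category are statistically identical in the
  simulator, so exemplar-level decoding is not meaningful on synthetic
  data.
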