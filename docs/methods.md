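# Methods

This note documents the models, conventions, and numerical choices
behind `opgpred`, in the order data flows through the pipeline.

## Study design being modeled

The pipeline reproduces a retrospective case–control design for
pediatric optic pathway glioma (OPG) progression. A subject is a
*case* when any surveillance scan shows radiographic tumor growth or
best-corrected visual acuity worsens by ≥ 0.2 logMAR between successive
examinations in either eye (higher logMAR = worse acuity; a config flag
accepts the opposite recording convention, since clinical text
sometimes describes the acuity rather than the number). Subjects with
severe baseline loss (20/470 or worse, logMAR ≥ log₁₀(470/20) ≈ 1.371,
in the better eye) are excluded as a floor effect, as are subjects with
prior surgical biopsy. Cases contribute the index (progression) scan
plus up to 3 immediately preceding scans within 2 years of it; controls
contribute their 3 most recent scans within 2 years of the most recent.
Every label/exclusion/selection decision carries a machine-readable
reason string.

## Synthetic cohort

The generator's defaults are the study conditions: 19 cases + 19
controls, 3 scans per subject at ~0.8-year intervals with the index
scan at t = 0, seven co-registered modalities on a 32³ grid at 2 mm
isotropic spacing.

**Geometry.** Optic nerves are straight tubes of radius 3 mm along the
slice (axial) axis, one per side; this is a deliberate simplification —
every downstream operator depends on mask topology, not anatomy. Optic
radiations are defined the way the real analysis defines them: a
streamline bundle is generated from a central seed box (ROI A) to a
posterior target box per side (ROI B-L / B-R), a configurable fraction
of decoy lines violating the inclusion criteria is mixed in, the bundle
is filtered with `A AND B NOT C`, and the surviving lines are voxelized
into the OR mask. Radiographic progression is simulated as a 1.5×
radius increase of the optic-nerve tube on the case index scan — a
detectable signal for the morphometry operators. The case mix of
progression triggers follows the observed breakdown (~16:2:1
radiographic-only : both : VA-only per 19 cases); every case carries at
least one trigger, controls none.

**FA signal.** The scaled-FA group parameters default to the reported
summaries: cases 2.38 ± 1.79, controls 6.23 ± 3.56 (arbitrary units —
these sit outside the physical FA range [0, 1] because they describe
intensities after scaling, and the printed source is itself ambiguous
about which group is which; we assign the low values to cases, since FA
falls with white-matter disruption). The signal is hierarchical:

* subject OR-mean ~ N(μ_group, σ_b) with σ_b = √(σ_group² − σ_noise²),
* voxel = subject mean + N(0, σ_noise), with σ_noise = 0.3 by default —
  modest voxel-level measurement noise relative to the between-subject
  spread.

The SD split makes the *pooled* voxel distribution of a group carry
exactly the configured variance (normal-mixture identity), while
subject-level means carry (nearly) the printed SDs, so the realized
subject-level effect size matches the configured contrast,
d = (6.23 − 2.38)/√((3.56² + 1.79²)/2) ≈ 1.37.

**Truncation at zero.** Intensities are magnitudes, so draws are
clipped at 0 (censoring). Under the case parameters ~9% of the normal
mass lies below zero, and naive clipping would bias the realized
moments upward (inflating the effect size to ≈ 1.43). The generator
therefore moment-matches: the configured mean/SD are interpreted as the
moments of the *realized* non-negative distribution, and the
pre-censoring (μ*, σ*) are solved by root finding from the censored
normal moment equations. Rejection resampling was rejected as the
truncation mechanism because it distorts the moments several times
more.

Case subjects additionally carry a per-interval drift of the OR signal
(default: FA −0.5 per interval relative to the index scan, i.e. FA
declines toward progression), which gives the dynamic delta features a
real signal. One root seed sequence, spawned per subject, controls all
randomness; identical config + seed is bit-identical.

**What the phantom does not emulate:** MRI physics (bias fields, noise
correlations, partial-volume effects), anatomically realistic visual
pathways, registration error, ragged scan counts, or inter-rater
segmentation variability. Passing tests on this phantom demonstrate
that the operators and the training/evaluation machinery are correct
and leak-free — not that the classifier's synthetic performance
transfers to clinical data.

## Morphometry conventions

Voxel `i` owns the half-open world interval `[i·s, (i+1)·s)`; world
points map to voxels by `floor(p/s)`; voxel centers sit at
`(i + 0.5)·s`. Per-slice operators slice along the axial axis.

* **Volume** is exact: true-voxel count × voxel volume.
* **Perimeter**: boundary voxels (true voxels with a false 4-neighbor
  in-plane) are ordered by Moore (8-connected) contour tracing from the
  raster-first pixel, terminating when a (pixel, backtrack) state
  repeats; the perimeter is the summed Euclidean center-to-center
  distance along the closed walk (steps of 1 or √2 in-plane spacings).
  Multiple components in a slice contribute the sum of their
  perimeters; a single voxel is a degenerate loop of length 0.
  One-voxel-wide limbs are walked in both directions, as a physical
  walk around the border would be. Note the boundary-pixel walk is a
  grid-dependent estimator: it converges under re-digitization at finer
  resolution, but naive pixel replication inflates it (each diagonal
  becomes a staircase corner).
* **Thickness**: the centerline is the chain of per-slice in-plane
  centroids (no spline smoothing — the simplest reproducible reading of
  "a line in the center"); each boundary voxel contributes its in-plane
  distance to its slice's centroid, and the full pooled sample set is
  summarized.
* **Tortuosity index** is area/perimeter per slice (a more convoluted
  border gives a *smaller* ratio at equal area). Slices whose perimeter
  degenerates to zero are skipped for the ratio.
* **Streamline logic**: a polyline intersects a region when any sampled
  point maps into a true voxel; segments are subdivided to ≤ half the
  smallest voxel spacing so thin ROIs cannot be tunneled through. The
  filter keeps exactly the lines touching ≥ 1 voxel of both inclusion
  ROIs and 0 voxels of the exclusion ROI; voxelization marks every
  voxel traversed by any kept segment.

## Intensity features

Volumes are linearly histogram-matched before extraction: the affine
map sends the source (P₁, P₉₉) percentile pair onto the reference's and
is applied to all voxels, so outliers beyond the percentile band cannot
influence the fit. The reference is the first control subject's index
scan, per modality, fixed per run — the source text is silent on the
reference; a fixed one keeps runs comparable. A constant source volume
is a hard error (the scale is undefined), as is a missing modality (the
study excluded incomplete imaging rather than imputing).

Each (region, modality) pair yields min, max, mean, SD (population
form, so a one-voxel region has SD 0) and K quantiles on the grid
k/K, k = 1..K (default K = 10 deciles; the grid keeps the median at
even K). The published feature totals (268/532) are not reconstructable
from the text, so K is a config knob and totals are not a contract.

Static tables carry one row per scan. Dynamic tables carry one row per
subject: index-scan features plus delta blocks (later minus earlier;
scans lettered A, B, C chronologically, so blocks are named
`delta_B-A`, ...). "Successive" uses consecutive pairs (s−1 blocks),
"all pairs" every chronological pair (s(s−1)/2 blocks). Morphology
features enter the delta blocks along with intensities. Subjects with
one scan are excluded from dynamic tables with a warning; included
subjects must share one scan count, because per-pair blocks must share
one column schema — ragged designs raise a schema error rather than
imputing.

## Classifier and evaluation

* **SVM**: linear kernel, C = 1.0 by default, features z-scored with
  training-split statistics only (zero-variance columns get unit
  scale). Decision scores are oriented so positive = progression.
* **Sequential forward selection**: starting from the majority-class
  baseline, the candidate maximizing inner 5-fold stratified CV
  accuracy is added each step; selection stops at the first
  non-improving step (strict) or `max_features`; ties break to the
  lower column index. When a training set is too small to stratify
  2-fold, resubstitution accuracy is the fallback criterion. For tables
  with hundreds of columns an optional prescreen restricts the
  candidate pool to the top-N features by univariate AUC computed on
  the fold's training rows — a standard filter-then-wrapper economy
  that sees no held-out data.
* **Cross-validation**: one fold per (case, control) pair — the
  wording of leave-two-out admits a single-pass pairing, but the
  all-pairs enumeration is deterministic and uses every subject
  symmetrically. Within each fold, selection and fitting see only the
  training rows. A subject with several rows (static scheme) is
  predicted by majority vote over its row predictions; across folds a
  subject's final prediction is the majority vote of its per-fold
  predictions, with the mean decision score breaking ties, and its
  score is the across-fold mean. Confusion counts and metrics are per
  subject.
* **Metrics**: accuracy (TP+TN)/N, sensitivity TP/(TP+FN), specificity
  TN/(TN+FP). The standard specificity denominator is used and recorded
  in the report metadata (one published description of the denominator
  reads as the NPV formula; we treat that as a slip rather than guess
  an intent).
* **ROC/AUC**: AUC is computed from ranks (ties ½), which equals the
  Mann–Whitney U statistic over n₁n₂ exactly; the optimal cutoff
  minimizes the Euclidean distance to (0, 1); the 95% CI is a
  2000-resample stratified bootstrap percentile interval, seeded.
  Per-feature ranking reports the orientation-corrected AUC
  (max(A, 1−A)) and a two-sided Mann–Whitney p with normal
  approximation and tie correction; constant features record AUC 0.5
  and p = 1 rather than erroring.

## Problem sizes and determinism

Default problem sizes are chosen so the full test suite and the
acceptance script each run in minutes on one CPU: the demo pipeline
runs 19+19 subjects on 32³ grids; distributional checks use 16³ grids
with one scan per subject and a few hundred light subjects; the
label-recovery experiment (19+19 subjects, reported FA contrast + 50
noise features) uses prescreen 12 and at most 5 selected features.
Every stochastic component draws from one seeded root sequence;
reports, manifests, and feature CSVs embed the config hash and package
version, a completed output directory is never silently overwritten,
and identical config + seed reproduces artifacts byte for byte.

## Known limitations

* The pooled voxel sample of a *small* cohort is a finite normal
  mixture over its subjects' means, not an i.i.d. normal draw — pooled
  distributional tests need either many subjects or the level-wise
  decomposition used in the test suite.
* The perimeter estimator is the boundary-voxel walk, not a sub-voxel
  surface estimate; geodesic or curvature-based tortuosity measures are
  out of scope, as are texture/wavelet radiomics, nonlinear kernels,
  and hyperparameter searches.
* Leave-two-out accuracy at n = 38 has a sampling SD of ~7 percentage
  points; single-seed results near a decision boundary should be read
  accordingly.
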