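# Methods

## Evaluation model

A patient's mask pair (ground truth GT, prediction) is evaluated in five
steps.

**Instance extraction.** Instances are maximal connected components of the
binary mask. Default connectivity is 26 (faces, edges and corners): the
most permissive 3D neighbourhood, so a lesion joined by a single diagonal
voxel bridge is not split in two. 6 and 18 are available where a stricter
convention is wanted. Instance volume is voxel count × voxel volume from
the NIfTI header spacing; DSC itself is computed on voxel counts, so
spacing never affects matching, only reported volumes.

**Matching.** All overlapping (GT, prediction) instance pairs get a DSC,
then a one-to-one matching is built greedily: pairs sorted by descending
DSC (ties broken by larger GT volume, then smaller GT id, then smaller
prediction id — fully deterministic), accepted when both instances are
still free and DSC strictly exceeds the threshold τ = 0.1. The strict
inequality matters: DSC = 0.1 exactly is *not* a detection. Greedy
matching is the field's standard for lesion-wise evaluation and is optimal
in the common regime where each prediction overlaps at most one GT lesion;
a Hungarian max-total-DSC option (`method="maxweight"`) is provided, and
the test suite records a three-pair counterexample where the two differ.
One-to-one means a single prediction blob covering two GT lesions scores
one tp and one fn; merge-tolerant matching is deliberately out of scope.

**Detection metrics.** From tp (pairs), fp (unmatched predictions), fn
(unmatched GT): PPV, sensitivity, F1. Degenerate denominators use the
"no false claims" convention — no predictions ⇒ PPV := 1, no GT ⇒
sensitivity := 1 — and the patient record carries `no_predictions` /
`no_gt` flags so users can re-aggregate under a different convention.
Flagged patients stay in cohort aggregates.

**Lesion-wise voxel metrics.** Voxel DSC and sensitivity are computed per
GT instance against its matched prediction (0 when unmatched), voxel PPV
per prediction instance against its matched GT (0 when unmatched), each
over that pair's voxels only; per-patient values are the unweighted means
over instances. Undetected lesions therefore depress segmentation scores
too — the alternative (averaging over matched pairs only) would let a
model improve its DSC by missing hard lesions.

**Aggregation and comparison.** Patients are the unit of aggregation: a
1-lesion patient weighs as much as a 10-lesion patient. Cohort summaries
report mean ± SD (n−1 denominator) and median (IQR, linear-interpolation
quartiles). Two models on the same cohort are compared per metric with a
two-sided Mann–Whitney U test on the per-patient values (unpaired; a
single p per metric) and the difference of cohort means in percentage
points. No multiple-testing correction is applied; p-values are reported
raw, with a significance flag at α = 0.05. The Mann–Whitney implementation
uses the exact null distribution when both arms have n ≤ 8 (by classical
tables without ties, by exhaustive enumeration of group assignments with
ties, two-sided as deviation from the null mean of U), and otherwise the
normal approximation with midrank tie correction and continuity
correction; two all-constant samples return p = 1, flagged `degenerate`.

**Concordance.** With two models matched against the same GT instance
maps, every GT lesion is classified both / A-only / B-only / neither
(the fourth class is kept so the classes provably partition all lesions),
and the headline number is net additional detections per patient,
(#B-only − #A-only)/n. Records carry lesion volumes for volume-ordered
export, since detection differences concentrate in small lesions.

## Phantom cohort generator

The generator produces the study conditions the evaluation assumes, with
planted truth for every quantity the pipeline estimates.

- **Lesion count** per patient: uniform on 1..10, the trial inclusion
  criterion for newly diagnosed patients. The empirical count distribution
  of real cohorts is not published; uniform is an assumption and is the
  one knob the distributional tests do not constrain.
- **Lesion volume**: log-normal with μ = ln 0.13 and
  σ = ln(0.48/0.13)/z₀.₇₅ ≈ 1.937, solved so the population median is
  0.13 cm³ and the third quartile 0.48 cm³ (the reported statistics of the
  reference training cohort). The implied first quartile is
  0.13²/0.48 ≈ 0.035 cm³ against the reported 0.04 — a two-parameter fit
  to three quantiles; the small Q1 misfit is accepted, not enforced away.
- **Geometry**: spheres (volume targets analytic), rasterized by
  voxel-center inclusion on a 96³ grid at 1.0 mm isotropic spacing by
  default (configurable, e.g. 0.9 mm to mirror the reference MPRAGE
  protocol). Centers are rejection-sampled with surface-to-surface
  separation ≥ 3 mm, so GT lesions can never touch under 26-connectivity.
  A lesion whose sphere cannot be placed (too large for the grid, or no
  room after 100 center draws) has its volume redrawn — truncation at the
  grid capacity, removing ~10⁻⁵ probability mass at the defaults — and
  placement fails loudly after 500 attempts.
- **Detection model**: a lesion of volume v cm³ is detected with
  probability p(v) = logistic(a + b·ln v) — the simplest monotone curve
  for the well-documented difficulty of finding small lesions. The three
  default simulated models differ only in intercept: a = 3, 4, 5 at
  b = 1, giving expected cohort detection rates of roughly 0.65, 0.78 and
  0.87 over the default volume distribution — the baseline / improved /
  upper-bound pattern of the motivating comparison.
- **Boundary jitter**: each detected lesion is copied with a random
  dilation or erosion of integer radius up to ⌊jitter_mm/spacing⌋ voxels
  (default 1 mm), erosion never below one voxel. This perturbs voxel
  metrics while (by the 3 mm separation) keeping each copy a single
  component that overlaps only its own lesion, so detection flags remain
  exactly Bernoulli(p(v)).
- **False positives**: Poisson per patient (default 0.3), log-normal
  volumes (default μ = ln 0.05, σ = 0.8 — spurious blobs are small),
  placed with ≥ 3 mm + jitter clearance from every GT lesion so they can
  never be matched.
- **Annotation degradation (HAQ → NAQ)**: each lesion survives into the
  degraded annotation with probability q(v) = logistic(c + d·ln v),
  default c = 4, d = 1.2 (≈ 0.70 expected retention; small lesions lost
  preferentially). The identity configuration q ≡ 1 reproduces the input
  bit-for-bit. This emulates annotating on a lower-conspicuity sequence
  and drives the imperfect-ground-truth experiment: a perfect detector
  scored against NAQ truth shows mean instance PPV equal to the mean
  annotated lesion fraction (< 1) although every "false positive" is a
  real lesion — the mechanism behind expert re-review reclassifying model
  false positives as annotation misses.

**What the phantoms do not model**: intensity images (no MRI contrast,
no registration, no brain extraction), non-spherical or confluent lesion
shapes, spatially correlated detection failure, annotator boundary
variability (NAQ here only deletes lesions, never reshapes them), and any
real segmentation model. Passing tests therefore validate the *evaluation
machinery and its statistical behaviour* under known truth, not the
performance of any segmenter on clinical data.

**Determinism.** Every (patient, role) pair draws from its own RNG stream
keyed by (cohort seed, patient index, role), so adding a segmenter never
perturbs GT sampling. NIfTI gzip output is written with a zeroed mtime;
CSV/JSON outputs use fixed float formatting. Full pipeline reruns are
byte-identical.

## Numerical and reporting choices

- Masks must be strictly binary; a file with one nonzero value is
  binarized, more than one is rejected with guidance (multi-structure
  exports must be resolved by the caller). GT and prediction must share a
  grid; resampling is out of scope.
- Metrics live in [0, 1] internally; summary CSVs render ×100 with one
  decimal, matching clinical reporting convention.
- Quartiles: linear interpolation between order statistics ("type 7").
- Empty-cohort aggregation and zero-gap gap-closure are explicit errors;
  single-patient cohorts get sd = 0 with an `n=1` flag.

## Problem sizes in the shipped analyses

The test suite and acceptance script run cohorts of 40–200 patients on
64³–96³ grids: large enough that the Monte-Carlo checks (parameter
recovery within 3× analytic SE, type-I error of the rank test inside the
95% binomial band over 500 replicate nulls, ≥95% power at a planted
15-point sensitivity gap with 100 patients per arm) are sharp, while a
full run completes in well under a minute on one CPU. Calibration
replicates use the volume-free detection-table sampler
(`sample_patient_sensitivities`) — the statistical behaviour under test
does not depend on voxel geometry — whereas parameter recovery and the
imperfect-GT experiment exercise the full voxel pipeline.
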