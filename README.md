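# lesionwise

Lesion-wise evaluation of 3D brain-metastasis segmentation masks, with a
synthetic phantom-cohort generator.

Voxel-level Dice scores hide the clinical question in metastasis screening:
*which lesions were found at all?* A model that misses three 4-mm
metastases but outlines one large lesion beautifully can post an excellent
whole-brain Dice. `lesionwise` evaluates segmentations the way
radiosurgery planning consumes them — per lesion instance, per patient:

- **Instances** are maximal connected components of a binary mask under a
  chosen 3D connectivity (default 26).
- **Detection matching**: ground-truth (GT) and predicted instances are
  paired one-to-one greedily by descending Dice similarity coefficient,
  DSC(A, B) = 2|A∩B| / (|A| + |B|); a GT lesion counts as *detected* when
  its pair's DSC strictly exceeds 0.1. From the resulting tp/fp/fn counts
  come instance PPV = tp/(tp+fp), sensitivity = tp/(tp+fn), and
  F1 = 2tp/(2tp+fp+fn).
- **Lesion-wise (LW) voxel metrics**: voxel DSC and sensitivity per GT
  instance (0 if undetected) and voxel PPV per predicted instance
  (0 if spurious), averaged within each patient.
- **Cohort statistics**: per-patient values aggregated unweighted across
  patients (mean ± SD, median, IQR); two models compared metric-by-metric
  with two-sided Mann–Whitney U tests and B−A deltas in percentage points;
  gap closure (B−A)/(C−A) against an upper-bound model; and a concordance
  analysis classifying every GT lesion as found by both models, one only,
  or neither, summarized as net additional detections per patient.

Because clinical masks are private, the package ships a phantom generator
(`lesionwise.synthetic`) that emulates the relevant cohort statistics —
1–10 spherical lesions per patient, log-normal volumes (median 0.13 cm³,
IQR ≈ 0.04–0.48 cm³), ~1 mm voxels — plus volume-dependent detection
failure, boundary jitter, Poisson false positives, and an
annotation-quality degrader that turns high-quality (HAQ) ground truth
into normal-quality (NAQ) ground truth by dropping small lesions. That
last piece reproduces a real evaluation artefact: a good model scored
against an imperfect annotation accrues "false positives" that are
actually lesions the annotator missed.

## Worked example

```bash
lesionwise simulate --out cohort --seed 3 --n-patients 2
lesionwise compare --manifest cohort/manifest.json \
    --model-a modelA --model-b modelB --out results
```

prints (seed 3, two patients):

```
 inst_f1: delta   -5.3 points, p = 1
inst_ppv: delta  +25.0 points, p = 0.617
 inst_sn: delta  -32.1 points, p = 0.333
  lw_dsc: delta  -22.9 points, p = 0.333
  lw_ppv: delta  +49.1 points, p = 0.333
   lw_sn: delta  -57.3 points, p = 0.333
concordance: {'both': 5, 'A_only': 2, 'B_only': 0, 'neither': 2}; net additional per patient -1.000
```

Each line is one metric: the difference of cohort means (model B minus
model A, percentage points) and the two-sided Mann–Whitney p-value across
per-patient values. The concordance line classifies all nine GT lesions of
this toy cohort by which simulated model detected them; at two patients
nothing is significant — it is a smoke test, not a study. The same
analysis from Python:

```python
import lesionwise as lw

m = lw.load_manifest("cohort/manifest.json")
result = lw.run_pipeline(m, ["modelA", "modelB"], "results")
print(result["summaries"]["modelB"])          # mean/sd/median/q1/q3 per metric
print(result["concordance"].counts)
```

`results/` then contains `per_patient_metrics.csv`, `cohort_summary.csv`
(percent scale, mirroring clinical reporting), `comparison.json`,
`concordance.csv` (GT lesions sorted by volume), and `run_log.json`.
Reruns are byte-identical for a given seed.

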