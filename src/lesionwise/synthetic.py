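"""Synthetic phantom cohorts for lesion-wise evaluation.

Generates per-patient 3D binary ground-truth masks of spherical lesions,
a degraded "normal annotation quality" (NAQ) version of each ground truth,
and simulated model predictions — everything the evaluation pipeline
consumes, with full knowledge of the planted truth.

The generator emulates the lesion statistics of a stereotactic-radiosurgery
brain-metastasis cohort: 1–10 lesions per patient, lesion volumes
log-normal with median 0.13 cm³ and third quartile 0.48 cm³, ~1 mm
isotropic voxels. Detection failure is volume-dependent (small lesions are
harder to find, for models and annotators alike): a simulated segmenter
detects a lesion of volume v (cm³) with probability
``p(v) = logistic(a + b·ln v)``, and the NAQ degrader retains a lesion in
the annotation with probability ``q(v) = logistic(c + d·ln v)``. Detected
lesions are copied with random boundary dilation/erosion, and spurious
spherical false positives arrive as a Poisson process per patient.

No intensity images are simulated — only label masks.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volume import LabelVolume, write_label_volume

__all__ = [
    "CohortConfig",
    "SegmenterConfig",
    "AnnotationConfig",
    "LesionRecord",
    "PatientTruth",
    "ConfigurationError",
    "PlacementError",
    "logistic",
    "sphere_radius_mm",
    "sample_lesion_volumes",
    "generate_patient_gt",
    "degrade_annotation",
    "simulate_prediction",
    "generate_cohort",
    "default_segmenters",
    "sample_patient_sensitivities",
]

# Table-matched volume distribution: median 0.13 cm^3, Q3 0.48 cm^3.
# exp(mu) = 0.13 and exp(mu + 0.6745 sigma) = 0.48 give:
DEFAULT_VOLUME_LOG_MU = math.log(0.13)
DEFAULT_VOLUME_LOG_SIGMA = math.log(0.48 / 0.13) / 0.6744897501960817

# Minimum surface-to-surface clearance used when placing false positives,
# in addition to the configured lesion separation. Keeps jittered
# true-positive copies from merging with neighbouring objects.
_FP_CLEARANCE_MM = 3.0


class ConfigurationError(ValueError):
    """A configuration value violates its constraints."""


class PlacementError(RuntimeError):
    """Lesion placement failed after bounded retries."""


def logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def sphere_radius_mm(volume_cm3: float) -> float:
    """Radius in mm of a sphere with the given volume in cm³."""
    return (3.0 * 1000.0 * volume_cm3 / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass
class CohortConfig:
    """Phantom-cohort parameters.

    Defaults: 96³ grid at 1.0 mm isotropic spacing, 1–10 lesions per
    patient, log-normal lesion volumes matched to a median of 0.13 cm³ and
    third quartile of 0.48 cm³.
    """

    n_patients: int = 30
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lesion_count_range: tuple[int, int] = (1, 10)
    volume_log_mu: float = DEFAULT_VOLUME_LOG_MU
    volume_log_sigma: float = DEFAULT_VOLUME_LOG_SIGMA
    min_separation_mm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be positive")
        if len(self.grid_shape) != 3 or any(int(s) < 1 for s in self.grid_shape):
            raise ConfigurationError("grid_shape must be 3 positive voxel counts")
        if len(self.voxel_spacing_mm) != 3 or any(s <= 0 for s in self.voxel_spacing_mm):
            raise ConfigurationError("voxel_spacing_mm must be 3 positive reals")
        lo, hi = self.lesion_count_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("lesion_count_range must satisfy 1 <= lo <= hi")
        if self.volume_log_sigma <= 0:
            raise ConfigurationError("volume_log_sigma must be > 0")
        if self.min_separation_mm < 0:
            raise ConfigurationError("min_separation_mm must be nonnegative")
        # A median-volume lesion must fit in the grid with room to spare;
        # placement retries handle everything finer-grained than this.
        extent = min(n * s for n, s in zip(self.grid_shape, self.voxel_spacing_mm))
        r_med = sphere_radius_mm(math.exp(self.volume_log_mu))
        if 2.0 * r_med + 2.0 * self.min_separation_mm >= extent:
            raise ConfigurationError(
                f"grid extent {extent:.1f} mm cannot hold a median-volume lesion "
                f"(radius {r_med:.1f} mm) with separation {self.min_separation_mm} mm"
            )


@dataclass
class SegmenterConfig:
    """A simulated segmentation model.

    Detection probability is ``logistic(detect_intercept +
    detect_slope · ln v)`` with v in cm³; detected lesions get a random
    boundary dilation/erosion of up to ``boundary_jitter_mm``; false
    positives arrive Poisson(``fp_rate_per_patient``) with log-normal
    volumes.
    """

    detect_intercept: float = 4.0
    detect_slope: float = 1.0
    boundary_jitter_mm: float = 1.0
    fp_rate_per_patient: float = 0.3
    fp_volume_log_mu: float = math.log(0.05)
    fp_volume_log_sigma: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.boundary_jitter_mm < 0:
            raise ConfigurationError("boundary_jitter_mm must be nonnegative")
        if self.fp_rate_per_patient < 0:
            raise ConfigurationError("fp_rate_per_patient must be nonnegative")

    def detection_probability(self, volume_cm3: float) -> float:
        if volume_cm3 <= 0:
            raise ValueError("volume must be positive")
        return logistic(self.detect_intercept + self.detect_slope * math.log(volume_cm3))


@dataclass
class AnnotationConfig:
    """Volume-dependent annotation sensitivity for NAQ degradation.

    A lesion of volume v survives into the degraded annotation with
    probability ``q(v) = logistic(annot_intercept + annot_slope · ln v)``.
    ``AnnotationConfig.identity()`` (q ≡ 1) reproduces the input mask
    exactly.
    """

    annot_intercept: float = 4.0
    annot_slope: float = 1.2
    seed: int = 0

    @classmethod
    def identity(cls, seed: int = 0) -> "AnnotationConfig":
        return cls(annot_intercept=math.inf, annot_slope=0.0, seed=seed)

    def annotation_probability(self, volume_cm3: float) -> float:
        if volume_cm3 <= 0:
            raise ValueError("volume must be positive")
        if math.isinf(self.annot_intercept):
            return 1.0 if self.annot_intercept > 0 else 0.0
        return logistic(self.annot_intercept + self.annot_slope * math.log(volume_cm3))


@dataclass
class LesionRecord:
    lesion_id: int
    center_vox: tuple[float, float, float]
    radius_mm: float
    target_volume_cm3: float
    volume_cm3: float  # rasterized volume
    present_in_naq: bool = True
    detected_by: dict[str, bool] = field(default_factory=dict)


@dataclass
class PatientTruth:
    """Planted truth for one phantom patient.

    ``labels`` assigns each GT lesion a stable integer id; the records
    track each lesion's geometry, its survival into the NAQ annotation, and
    which simulated models detected it.
    """

    patient_id: str
    labels: np.ndarray  # int16, 0 = background
    lesions: list[LesionRecord]

    def __post_init__(self) -> None:
        ids = {r.lesion_id for r in self.lesions}
        present = {int(v) for v in np.unique(self.labels)} - {0}
        # Records may describe lesions absent from the mask (e.g. dropped
        # by NAQ degradation), but never the other way around.
        if not present <= ids:
            raise ValueError(
                f"label volume has lesions {sorted(present - ids)} with no truth record"
            )

    def lesion(self, lesion_id: int) -> LesionRecord:
        return next(r for r in self.lesions if r.lesion_id == lesion_id)


def sample_lesion_volumes(
    n: int, volume_log_mu: float, volume_log_sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw n i.i.d. log-normal lesion volumes (cm³)."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    if volume_log_sigma <= 0:
        raise ConfigurationError("volume_log_sigma must be > 0")
    return rng.lognormal(volume_log_mu, volume_log_sigma, size=n)


def _rasterize_sphere(
    labels: np.ndarray,
    spacing: tuple[float, float, float],
    center_mm: np.ndarray,
    radius_mm: float,
    value: int,
) -> int:
    """Paint voxels whose centers lie within radius of center; >= 1 voxel.

    Returns the number of voxels painted. Raises if any painted voxel is
    already claimed by another object.
    """
    sp = np.asarray(spacing)
    lo = np.maximum(np.floor((center_mm - radius_mm) / sp).astype(int), 0)
    hi = np.minimum(np.ceil((center_mm + radius_mm) / sp).astype(int) + 1, labels.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    grids = np.meshgrid(
        *[np.arange(a, b) * s for (a, b), s in zip(zip(lo, hi), sp)], indexing="ij"
    )
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center_mm))
    inside = d2 <= radius_mm**2
    if not inside.any():  # sub-voxel lesion: claim the voxel nearest the center
        nearest = tuple(
            int(np.clip(round(c / s), 0, n - 1))
            for c, s, n in zip(center_mm, sp, labels.shape)
        )
        if labels[nearest] != 0:
            raise PlacementError("sub-voxel lesion collides with an existing object")
        labels[nearest] = value
        return 1
    region = labels[sl]
    if np.any(region[inside] != 0):
        raise PlacementError("lesion rasterization collides with an existing object")
    region[inside] = value
    return int(inside.sum())


def _place_spheres(
    volumes: np.ndarray,
    grid_shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    min_separation_mm: float,
    rng: np.random.Generator,
    existing: list[tuple[np.ndarray, float]] | None = None,
    clearance_mm: float = 0.0,
    max_attempts_per_sphere: int = 500,
    resample: tuple[float, float] | None = None,
) -> list[tuple[np.ndarray, float, float]]:
    """Sample non-overlapping sphere centers (mm) for the given volumes.

    Returns (center_mm, radius_mm, volume_cm3) per sphere. Centers keep
    each sphere fully inside the grid and surface-to-surface distance of at
    least ``min_separation_mm`` from each other and ``clearance_mm`` from
    ``existing`` obstacles. A volume whose sphere cannot fit in the grid at
    all is redrawn from ``resample = (log_mu, log_sigma)`` when given
    (truncation at the grid size; negligible mass at the defaults).
    """
    extent = np.array([n * s for n, s in zip(grid_shape, spacing)])
    obstacles = list(existing or [])
    placed: list[tuple[np.ndarray, float, float]] = []
    for v in volumes:
        v = float(v)
        r = sphere_radius_mm(v)
        for attempt in range(max_attempts_per_sphere):
            infeasible = np.any(2 * r >= extent - 2 * min_separation_mm)
            # A sphere that cannot fit (or cannot find room among the ones
            # already placed) gets its volume redrawn: the distribution is
            # truncated at what the grid can hold, which at the default
            # parameters removes negligible probability mass.
            if infeasible or (attempt % 100 == 99):
                if resample is None:
                    raise PlacementError(
                        f"sphere of radius {r:.1f} mm cannot fit in grid extent "
                        f"{extent.min():.1f} mm"
                    )
                v = float(rng.lognormal(*resample))
                r = sphere_radius_mm(v)
                if infeasible:
                    continue
            center = rng.uniform(r, extent - r)
            ok = all(
                np.linalg.norm(center - c0) >= r + r0 + min_separation_mm
                for c0, r0, _ in placed
            ) and all(
                np.linalg.norm(center - c0) >= r + r0 + clearance_mm
                for c0, r0 in obstacles
            )
            if ok:
                placed.append((center, r, v))
                break
        else:
            raise PlacementError(
                f"could not place a sphere of radius {r:.1f} mm after "
                f"{max_attempts_per_sphere} attempts (separation "
                f"{min_separation_mm} mm, grid extent {extent.tolist()} mm)"
            )
    return placed


def generate_patient_gt(
    config: CohortConfig, rng: np.random.Generator, patient_id: str = "P000"
) -> tuple[LabelVolume, PatientTruth]:
    """Generate one patient's ground-truth mask and truth record.

    The lesion count is uniform over ``lesion_count_range``; volumes are
    log-normal; lesions are rasterized as spheres (a voxel belongs to a
    lesion iff its center lies within the radius) with pairwise
    surface-to-surface separation of at least ``min_separation_mm``.
    """
    k = int(rng.integers(config.lesion_count_range[0], config.lesion_count_range[1] + 1))
    volumes = sample_lesion_volumes(k, config.volume_log_mu, config.volume_log_sigma, rng)
    placed = _place_spheres(
        volumes,
        config.grid_shape,
        config.voxel_spacing_mm,
        config.min_separation_mm,
        rng,
        resample=(config.volume_log_mu, config.volume_log_sigma),
    )
    labels = np.zeros(config.grid_shape, dtype=np.int16)
    sp = np.asarray(config.voxel_spacing_mm)
    voxel_cm3 = float(np.prod(sp)) / 1000.0
    lesions = []
    for i, (center, r, v) in enumerate(placed, start=1):
        count = _rasterize_sphere(labels, config.voxel_spacing_mm, center, r, i)
        lesions.append(
            LesionRecord(
                lesion_id=i,
                center_vox=tuple(float(c / s) for c, s in zip(center, sp)),
                radius_mm=float(r),
                target_volume_cm3=float(v),
                volume_cm3=count * voxel_cm3,
            )
        )
    vol = LabelVolume(
        (labels > 0).astype(np.uint8),
        tuple(config.voxel_spacing_mm),
        np.diag((*config.voxel_spacing_mm, 1.0)),
    )
    return vol, PatientTruth(patient_id, labels, lesions)


def _check_truth(gt: LabelVolume, truth: PatientTruth) -> None:
    if gt.voxels.shape != truth.labels.shape or not np.array_equal(
        gt.voxels > 0, truth.labels > 0
    ):
        raise ValueError(
            f"patient {truth.patient_id!r}: truth labels inconsistent with the mask"
        )


def degrade_annotation(
    gt: LabelVolume,
    truth: PatientTruth,
    annot: AnnotationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[LabelVolume, PatientTruth]:
    """Degrade a ground truth to normal annotation quality (NAQ).

    Each lesion independently survives with probability q(v) of its
    rasterized volume; the output mask is the union of surviving lesions.
    The identity configuration (q ≡ 1) reproduces the input mask exactly.
    The returned truth keeps one record per original lesion with its
    ``present_in_naq`` flag set.
    """
    _check_truth(gt, truth)
    if rng is None:
        rng = np.random.default_rng(annot.seed)
    kept_ids = []
    new_records = []
    for rec in truth.lesions:
        keep = bool(rng.random() < annot.annotation_probability(rec.volume_cm3))
        if keep:
            kept_ids.append(rec.lesion_id)
        new_records.append(dataclasses.replace(rec, present_in_naq=keep))
    naq_labels = np.where(np.isin(truth.labels, kept_ids), truth.labels, 0).astype(np.int16)
    naq_vol = LabelVolume((naq_labels > 0).astype(np.uint8), gt.spacing_mm, gt.affine)
    return naq_vol, PatientTruth(truth.patient_id, naq_labels, new_records)


def _jitter_lesion(
    lesion_mask: np.ndarray,
    center_vox: tuple[float, float, float],
    shift: int,
) -> np.ndarray:
    """Dilate (shift>0) or erode (shift<0) one lesion, never below 1 voxel."""
    from scipy import ndimage

    if shift == 0:
        return lesion_mask
    struct = ndimage.generate_binary_structure(3, 1)
    if shift > 0:
        return ndimage.binary_dilation(lesion_mask, struct, iterations=shift)
    out = ndimage.binary_erosion(lesion_mask, struct, iterations=-shift)
    if not out.any():
        out = np.zeros_like(lesion_mask)
        nearest = tuple(
            int(np.clip(round(c), 0, n - 1)) for c, n in zip(center_vox, lesion_mask.shape)
        )
        out[nearest] = True
        if not lesion_mask[nearest]:  # fall back to any voxel of the lesion
            out[:] = False
            idx = np.argwhere(lesion_mask)[0]
            out[tuple(idx)] = True
    return out


def simulate_prediction(
    gt: LabelVolume,
    truth: PatientTruth,
    seg: SegmenterConfig,
    rng: np.random.Generator | None = None,
) -> tuple[LabelVolume, dict[int, bool]]:
    """Simulate one model's prediction for one patient.

    Each GT lesion is detected with probability p(v); detected lesions are
    copied with a random boundary dilation/erosion of up to
    ``boundary_jitter_mm`` (uniform integer voxel radius, sign included;
    erosion never removes the last voxel). Poisson false-positive spheres
    are placed disjoint from all GT lesions. Returns the prediction mask
    and the per-lesion detection flags.
    """
    _check_truth(gt, truth)
    if rng is None:
        rng = np.random.default_rng(seg.seed)
    spacing = gt.spacing_mm
    pred = np.zeros(gt.voxels.shape, dtype=bool)
    detected: dict[int, bool] = {}
    max_shift = int(seg.boundary_jitter_mm / min(spacing))
    for rec in truth.lesions:
        hit = bool(rng.random() < seg.detection_probability(rec.volume_cm3))
        detected[rec.lesion_id] = hit
        if not hit:
            continue
        lesion = truth.labels == rec.lesion_id
        shift = int(rng.integers(-max_shift, max_shift + 1)) if max_shift > 0 else 0
        pred |= _jitter_lesion(lesion, rec.center_vox, shift)

    n_fp = int(rng.poisson(seg.fp_rate_per_patient))
    if n_fp > 0:
        fp_volumes = rng.lognormal(seg.fp_volume_log_mu, seg.fp_volume_log_sigma, n_fp)
        obstacles = [
            (np.asarray(r.center_vox) * np.asarray(spacing), r.radius_mm)
            for r in truth.lesions
        ]
        placed = _place_spheres(
            fp_volumes,
            gt.voxels.shape,
            spacing,
            _FP_CLEARANCE_MM,
            rng,
            existing=obstacles,
            clearance_mm=_FP_CLEARANCE_MM + seg.boundary_jitter_mm,
            resample=(seg.fp_volume_log_mu, seg.fp_volume_log_sigma),
        )
        fp_labels = np.zeros(gt.voxels.shape, dtype=np.int16)
        for i, (center, r, _) in enumerate(placed, start=1):
            _rasterize_sphere(fp_labels, spacing, center, r, i)
        pred |= fp_labels > 0
    return LabelVolume(pred.astype(np.uint8), spacing, gt.affine), detected


def default_segmenters(seed: int = 0) -> dict[str, SegmenterConfig]:
    """Three simulated models of increasing detection sensitivity.

    ``modelA`` is the weakest detector (akin to training on degraded
    annotations), ``modelB`` closes part of the gap, ``modelC`` is the
    upper bound with the fewest false positives.
    """
    return {
        "modelA": SegmenterConfig(detect_intercept=3.0, seed=seed),
        "modelB": SegmenterConfig(detect_intercept=4.0, seed=seed),
        "modelC": SegmenterConfig(detect_intercept=5.0, fp_rate_per_patient=0.15, seed=seed),
    }


def generate_cohort(
    config: CohortConfig,
    annot: AnnotationConfig,
    segmenters: dict[str, SegmenterConfig],
    out_dir: str | Path,
) -> dict:
    """Generate and write a full phantom cohort; returns the manifest.

    Per patient this writes the HAQ ground truth, the NAQ-degraded ground
    truth, and one prediction per named segmenter as .nii.gz, plus a single
    ``manifest.json`` with file paths, planted lesion records and all
    configuration. Each (patient, role) pair gets its own RNG stream keyed
    by the cohort seed, so adding a segmenter never perturbs GT sampling.
    Predictions are simulated from the HAQ truth.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    patients = []
    for i in range(config.n_patients):
        pid = f"P{i:03d}"
        rng_gt = np.random.default_rng([config.seed, i, 0])
        gt_vol, truth = generate_patient_gt(config, rng_gt, pid)
        rng_annot = np.random.default_rng([config.seed, abs(annot.seed), i, 1])
        naq_vol, naq_truth = degrade_annotation(gt_vol, truth, annot, rng_annot)
        flagged = naq_truth.lesions

        files = {}
        haq_path = out_dir / f"{pid}_haq.nii.gz"
        naq_path = out_dir / f"{pid}_naq.nii.gz"
        write_label_volume(gt_vol, haq_path)
        write_label_volume(naq_vol, naq_path)
        files["haq"] = haq_path.name
        files["naq"] = naq_path.name

        records = {r.lesion_id: r for r in flagged}
        for j, (name, seg) in enumerate(segmenters.items()):
            rng_seg = np.random.default_rng([config.seed, abs(seg.seed), i, 10 + j])
            pred_vol, det = simulate_prediction(gt_vol, truth, seg, rng_seg)
            pred_path = out_dir / f"{pid}_{name}.nii.gz"
            write_label_volume(pred_vol, pred_path)
            files[name] = pred_path.name
            for lid, hit in det.items():
                records[lid].detected_by[name] = hit

        patients.append(
            {
                "patient_id": pid,
                "files": files,
                "lesions": [
                    {
                        "lesion_id": r.lesion_id,
                        "volume_cm3": r.volume_cm3,
                        "target_volume_cm3": r.target_volume_cm3,
                        "radius_mm": r.radius_mm,
                        "present_in_naq": r.present_in_naq,
                        "detected_by": r.detected_by,
                    }
                    for r in flagged
                ],
            }
        )

    manifest = {
        "config": {
            "n_patients": config.n_patients,
            "grid_shape": list(config.grid_shape),
            "voxel_spacing_mm": list(config.voxel_spacing_mm),
            "lesion_count_range": list(config.lesion_count_range),
            "volume_log_mu": config.volume_log_mu,
            "volume_log_sigma": config.volume_log_sigma,
            "min_separation_mm": config.min_separation_mm,
            "seed": config.seed,
        },
        "annotation": dataclasses.asdict(annot),
        "segmenters": {k: dataclasses.asdict(v) for k, v in segmenters.items()},
        "patients": patients,
    }
    manifest_path = out_dir / "manifest.json"
    try:
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except OSError as exc:
        raise OSError(f"failed to write manifest to {manifest_path}: {exc}") from exc
    return manifest


def sample_patient_sensitivities(
    n_patients: int,
    cohort: CohortConfig,
    seg: SegmenterConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-patient instance sensitivities under the detection model alone.

    Samples lesion counts and volumes from the cohort configuration and
    Bernoulli detection outcomes from the segmenter's p(v) curve, skipping
    voxel rasterization entirely. Intended for statistical calibration
    studies (type-I error, power) where thousands of cohorts are needed
    and the geometry is irrelevant.
    """
    lo, hi = cohort.lesion_count_range
    out = np.empty(n_patients)
    for i in range(n_patients):
        k = int(rng.integers(lo, hi + 1))
        vols = sample_lesion_volumes(k, cohort.volume_log_mu, cohort.volume_log_sigma, rng)
        p = np.array([seg.detection_probability(v) for v in vols])
        out[i] = float(np.mean(rng.random(k) < p))
    return out
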