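"""Phantom cohort generator: volume statistics, geometry, degradation,
simulated predictions, and cohort-level I/O."""

import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pytest

from lesionwise import (
    AnnotationConfig,
    CohortConfig,
    SegmenterConfig,
    degrade_annotation,
    extract_instances,
    generate_cohort,
    generate_patient_gt,
    sample_lesion_volumes,
    simulate_prediction,
)
from lesionwise.synthetic import (
    ConfigurationError,
    PlacementError,
    logistic,
    sample_patient_sensitivities,
    sphere_radius_mm,
)

SMALL = dict(grid_shape=(48, 48, 48))


class TestSampleLesionVolumes:
    def test_empty_draw(self, rng):
        assert len(sample_lesion_volumes(0, 0.0, 1.0, rng)) == 0

    def test_nonpositive_sigma_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            sample_lesion_volumes(5, 0.0, 0.0, rng)

    def test_degenerate_sigma_concentrates_at_median(self, rng):
        v = sample_lesion_volumes(100, math.log(0.13), 1e-9, rng)
        assert np.allclose(v, 0.13, rtol=1e-6)

    def test_default_parameters_reproduce_cohort_quartiles(self, rng):
        # mu = ln 0.13 and sigma = ln(0.48/0.13)/z_0.75 give median 0.13 and
        # q3 = 0.48 analytically; implied q1 = 0.13^2/0.48 ~ 0.035
        cfg = CohortConfig()
        v = sample_lesion_volumes(200_000, cfg.volume_log_mu, cfg.volume_log_sigma, rng)
        q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
        assert med == pytest.approx(0.13, rel=0.03)
        assert q3 == pytest.approx(0.48, rel=0.03)
        assert q1 == pytest.approx(0.13 * 0.13 / 0.48, rel=0.05)


class TestGeneratePatientGt:
    def test_forced_lesion_count(self, rng):
        cfg = CohortConfig(lesion_count_range=(3, 3), **SMALL)
        vol, truth = generate_patient_gt(cfg, rng)
        assert extract_instances(vol, 26).n_instances == 3
        assert len(truth.lesions) == 3

    def test_sphere_rasterization_equals_brute_force_scan(self, rng):
        cfg = CohortConfig(lesion_count_range=(1, 1), **SMALL)
        vol, truth = generate_patient_gt(cfg, rng)
        (rec,) = truth.lesions
        center_mm = np.array(rec.center_vox)  # spacing 1.0 -> vox == mm
        count = 0
        for idx in np.ndindex(*cfg.grid_shape):
            if np.sum((np.array(idx) - center_mm) ** 2) <= rec.radius_mm**2:
                count += 1
        assert vol.foreground_voxel_count() == max(count, 1)
        assert rec.volume_cm3 == pytest.approx(max(count, 1) * 0.001)

    def test_rasterized_volume_close_to_target(self, rng):
        cfg = CohortConfig(lesion_count_range=(1, 4), **SMALL)
        for _ in range(10):
            _, truth = generate_patient_gt(cfg, rng)
            for rec in truth.lesions:
                r = rec.radius_mm
                h = math.sqrt(3) / 2  # half voxel diagonal at 1 mm spacing
                lo = 4 / 3 * math.pi * max(r - h, 0) ** 3 / 1000
                hi = 4 / 3 * math.pi * (r + h) ** 3 / 1000
                assert lo <= rec.volume_cm3 <= max(hi, 0.001)

    def test_determinism_same_seed(self):
        cfg = CohortConfig(**SMALL)
        v1, t1 = generate_patient_gt(cfg, np.random.default_rng(42))
        v2, t2 = generate_patient_gt(cfg, np.random.default_rng(42))
        assert np.array_equal(v1.voxels, v2.voxels)
        assert np.array_equal(t1.labels, t2.labels)

    def test_lesions_never_touch_under_26_connectivity(self, rng):
        cfg = CohortConfig(lesion_count_range=(8, 10), grid_shape=(72, 72, 72))
        for _ in range(5):
            vol, truth = generate_patient_gt(cfg, rng)
            assert extract_instances(vol, 26).n_instances == len(truth.lesions)

    def test_impossible_placement_raises(self, rng):
        cfg = CohortConfig(
            grid_shape=(20, 20, 20),
            lesion_count_range=(2, 2),
            volume_log_mu=math.log(1.0),
            volume_log_sigma=1e-6,
        )
        with pytest.raises(PlacementError, match="place"):
            generate_patient_gt(cfg, rng)

    def test_infeasible_grid_rejected_at_config_time(self):
        with pytest.raises(ConfigurationError, match="grid"):
            CohortConfig(grid_shape=(8, 8, 8), volume_log_mu=math.log(1.0))


class TestDegradeAnnotation:
    def test_identity_curve_reproduces_mask(self, rng):
        cfg = CohortConfig(lesion_count_range=(4, 6), **SMALL)
        vol, truth = generate_patient_gt(cfg, rng)
        naq, t = degrade_annotation(vol, truth, AnnotationConfig.identity(), rng)
        assert np.array_equal(naq.voxels, vol.voxels)
        assert all(r.present_in_naq for r in t.lesions)

    def test_zero_curve_empties_mask(self, rng):
        cfg = CohortConfig(lesion_count_range=(4, 6), **SMALL)
        vol, truth = generate_patient_gt(cfg, rng)
        annot = AnnotationConfig(annot_intercept=-math.inf, annot_slope=0.0)
        naq, t = degrade_annotation(vol, truth, annot, rng)
        assert naq.foreground_voxel_count() == 0
        assert not any(r.present_in_naq for r in t.lesions)

    def test_truth_mask_mismatch_rejected(self, rng):
        cfg = CohortConfig(lesion_count_range=(2, 2), **SMALL)
        vol, truth = generate_patient_gt(cfg, rng)
        other_vol, _ = generate_patient_gt(cfg, np.random.default_rng(9))
        with pytest.raises(ValueError, match="inconsistent"):
            degrade_annotation(other_vol, truth, AnnotationConfig(), rng)

    def test_retention_matches_planted_curve(self, rng):
        # over many lesions the retained fraction must sit inside the 95%
        # binomial interval around the mean planted probability
        annot = AnnotationConfig(annot_intercept=4.0, annot_slope=1.2)
        cfg = CohortConfig(lesion_count_range=(5, 10), **SMALL)
        kept = total = 0
        expected = []
        for i in range(60):
            vol, truth = generate_patient_gt(cfg, np.random.default_rng(i))
            _, t = degrade_annotation(vol, truth, annot, np.random.default_rng(1000 + i))
            for r in t.lesions:
                total += 1
                kept += r.present_in_naq
                expected.append(annot.annotation_probability(r.volume_cm3))
        mean_q = float(np.mean(expected))
        se = math.sqrt(sum(q * (1 - q) for q in expected)) / total
        assert abs(kept / total - mean_q) <= 1.96 * se + 1e-9

    def test_naq_never_gains_lesions(self, rng):
        cfg = CohortConfig(lesion_count_range=(1, 10), **SMALL)
        for i in range(5):
            vol, truth = generate_patient_gt(cfg, np.random.default_rng(i))
            naq, t = degrade_annotation(vol, truth, AnnotationConfig(), rng)
            n_naq = extract_instances(naq).n_instances
            assert n_naq == sum(r.present_in_naq for r in t.lesions)
            assert n_naq <= len(truth.lesions)


class TestSimulatePrediction:
    def _patient(self, seed=0, counts=(3, 5)):
        cfg = CohortConfig(lesion_count_range=counts, **SMALL)
        return generate_patient_gt(cfg, np.random.default_rng(seed))

    def test_perfect_segmenter_copies_gt(self, rng):
        vol, truth = self._patient()
        seg = SegmenterConfig(
            detect_intercept=math.inf, boundary_jitter_mm=0.0, fp_rate_per_patient=0.0
        )
        pred, det = simulate_prediction(vol, truth, seg, rng)
        assert np.array_equal(pred.voxels, vol.voxels)
        assert all(det.values())

    def test_blind_segmenter_is_empty(self, rng):
        vol, truth = self._patient()
        seg = SegmenterConfig(
            detect_intercept=-math.inf, detect_slope=0.0, fp_rate_per_patient=0.0
        )
        pred, det = simulate_prediction(vol, truth, seg, rng)
        assert pred.foreground_voxel_count() == 0
        assert not any(det.values())

    def test_false_positive_rate_matches_poisson_mean(self):
        # blind detector, fp_rate 2.0: predicted components are exactly the
        # planted false positives
        seg = SegmenterConfig(
            detect_intercept=-math.inf, detect_slope=0.0, fp_rate_per_patient=2.0
        )
        counts = []
        for i in range(100):
            vol, truth = self._patient(seed=i, counts=(1, 3))
            pred, _ = simulate_prediction(vol, truth, seg, np.random.default_rng(500 + i))
            counts.append(extract_instances(pred).n_instances)
        mean = float(np.mean(counts))
        assert abs(mean - 2.0) <= 1.96 * math.sqrt(2.0 / len(counts))

    def test_jitter_keeps_detected_lesions_single_components(self):
        vol, truth = self._patient(seed=3, counts=(4, 6))
        seg = SegmenterConfig(
            detect_intercept=math.inf, boundary_jitter_mm=1.0, fp_rate_per_patient=0.0
        )
        pred, det = simulate_prediction(vol, truth, seg, np.random.default_rng(7))
        assert extract_instances(pred).n_instances == sum(det.values())


class TestGenerateCohort:
    def test_file_count_and_conservation(self, tmp_path):
        cfg = CohortConfig(n_patients=2, seed=3, **SMALL)
        segs = {
            "m1": SegmenterConfig(seed=1),
            "m2": SegmenterConfig(detect_intercept=5.0, seed=2),
        }
        manifest = generate_cohort(cfg, AnnotationConfig(), segs, tmp_path)
        niftis = list(tmp_path.glob("*.nii.gz"))
        assert len(niftis) == 2 * (2 + 2)  # per patient: haq, naq, two models
        assert (tmp_path / "manifest.json").exists()
        data = json.loads((tmp_path / "manifest.json").read_text())
        assert data == manifest
        for pat in manifest["patients"]:
            per_model = {m for lesion in pat["lesions"] for m in lesion["detected_by"]}
            assert per_model == {"m1", "m2"}

    def test_regeneration_is_bit_identical(self, tmp_path):
        cfg = CohortConfig(n_patients=2, seed=8, **SMALL)
        segs = {"m": SegmenterConfig()}
        sums = []
        for sub in ("a", "b"):
            out = tmp_path / sub
            generate_cohort(cfg, AnnotationConfig(), segs, out)
            sums.append(
                {p.name: hashlib.md5(p.read_bytes()).hexdigest()
                 for p in sorted(out.iterdir())}
            )
        assert sums[0] == sums[1]

    def test_lesion_totals_match_per_patient_counts(self, tmp_path):
        cfg = CohortConfig(n_patients=3, seed=5, lesion_count_range=(2, 6), **SMALL)
        manifest = generate_cohort(cfg, AnnotationConfig(), {"m": SegmenterConfig()}, tmp_path)
        total = sum(len(p["lesions"]) for p in manifest["patients"])
        per_patient = [len(p["lesions"]) for p in manifest["patients"]]
        assert total == sum(per_patient)
        assert all(2 <= k <= 6 for k in per_patient)


class TestDetectionTableSimulator:
    def test_sensitivities_in_unit_interval(self, rng):
        cfg = CohortConfig()
        sn = sample_patient_sensitivities(50, cfg, SegmenterConfig(), rng)
        assert sn.shape == (50,)
        assert np.all((0 <= sn) & (sn <= 1))

    def test_flat_curve_recovers_planted_rate(self, rng):
        cfg = CohortConfig()
        p = 0.7
        seg = SegmenterConfig(detect_intercept=math.log(p / (1 - p)), detect_slope=0.0)
        sn = sample_patient_sensitivities(400, cfg, seg, rng)
        assert np.mean(sn) == pytest.approx(p, abs=0.04)


def test_logistic_matches_closed_form():
    for x in (-30, -2.5, 0.0, 1.7, 30):
        assert logistic(x) == pytest.approx(1 / (1 + math.exp(-x)), rel=1e-12)
    assert logistic(800.0) == 1.0  # no overflow for extreme arguments
    assert logistic(-800.0) == pytest.approx(0.0, abs=1e-300)


def test_sphere_radius_roundtrip():
    for v in (0.001, 0.13, 2.0):
        r = sphere_radius_mm(v)
        assert 4 / 3 * math.pi * r**3 / 1000 == pytest.approx(v, rel=1e-12)
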