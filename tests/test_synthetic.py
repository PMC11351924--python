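import json
import math

import numpy as np
import pytest
from shapely.geometry import Polygon

from ropmap import io as rio
from ropmap.synthetic import (
    FieldSpec,
    GeneratorConfig,
    NoiseModel,
    adjacent_confusion,
    default_field_plan,
    field_visibility,
    generate_cohort,
    generate_eye,
    oracle_detector,
)
from ropmap.transforms import SimilarityTransform, project_box
from ropmap.zones import zone_of_point


class TestGenerateEye:
    def test_deterministic(self, default_config):
        assert generate_eye(default_config, 7) == generate_eye(default_config, 7)
        assert generate_eye(default_config, 7) != generate_eye(default_config, 8)

    def test_zero_lesion_rate_gives_empty_eye(self):
        cfg = GeneratorConfig(lesion_rates=(0, 0, 0, 0))
        eye = generate_eye(cfg, 7)
        assert eye.lesions == ()

    def test_fovea_lies_in_zone_one(self, default_config):
        # a lesion forced to the fovea is always zone I: |fovea - disc| < 2 |fovea - disc|
        for seed in range(5):
            eye = generate_eye(default_config, seed)
            assert zone_of_point(eye.fovea_center, eye.frame) == "I"

    def test_true_zones_self_consistent(self, default_config):
        for eye in generate_cohort(default_config, 40, seed=3):
            for lesion in eye.lesions:
                assert lesion.true_zone == zone_of_point(lesion.center, eye.frame)

    def test_lesion_frequencies_match_configured_rates(self, default_config):
        """Per-type lesion totals across 200 eyes vs the Poisson oracle (3 SE)."""
        eyes = generate_cohort(default_config, 200, seed=1)
        counts = {t: 0 for t in (1, 2, 3, 4)}
        for eye in eyes:
            for lesion in eye.lesions:
                counts[lesion.lesion_type] += 1
        for t, rate in zip((1, 2, 3, 4), default_config.lesion_rates):
            expected = 200 * rate
            se = math.sqrt(expected)
            assert abs(counts[t] - expected) <= 3 * se, (t, counts[t], expected)

    def test_plus_regime_separation(self, default_config):
        eyes = generate_cohort(default_config, 100, seed=2)
        plus = [e for e in eyes if e.plus_present]
        normal = [e for e in eyes if not e.plus_present]
        assert plus and normal
        assert min(e.tortuosity_amp for e in plus) >= 4.0
        assert max(e.tortuosity_amp for e in normal) <= 1.5
        assert min(e.vessel_width for e in plus) > max(e.vessel_width for e in normal)

    def test_infeasible_geometry_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            GeneratorConfig(ora_over_dfd_range=(1.5, 1.8))


class TestFieldPlan:
    def test_exactly_one_disc_centered_field(self, default_config):
        eye = generate_eye(default_config, 5)
        plan = default_field_plan(eye, default_config)
        labels = [f.orientation_label for f in plan]
        assert labels.count("disc-centered") == 1
        anchor = plan[labels.index("disc-centered")]
        assert anchor.transform_to_panorama.almost_equals(SimilarityTransform.identity())

    def test_adjacent_fields_overlap_at_least_quarter(self, default_config):
        eye = generate_eye(default_config, 5)
        plan = default_field_plan(eye, default_config)

        def footprint(f):
            w, h = f.raster_size
            pts = f.transform_to_panorama.apply(np.array([[0, 0], [w, 0], [w, h], [0, h]], float))
            return Polygon(pts)

        anchor = footprint(plan[0])
        for f in plan[1:]:
            overlap = anchor.intersection(footprint(f)).area
            assert overlap >= 0.25 * (f.raster_size[0] * f.raster_size[1])


class TestRenderFields:
    def test_round_trip_box_corners_within_one_px(self, default_config):
        """Panorama box -> field frame -> back recovers every corner < 1 px."""
        eye = generate_eye(default_config, 9)
        plan = default_field_plan(eye, default_config)
        for f in plan:
            t = f.transform_to_panorama
            for lesion in eye.lesions:
                x, y, w, h = lesion.bbox
                corners = np.array([[x, y], [x + w, y], [x, y + h], [x + w, y + h]])
                back = t.apply(t.inverse().apply(corners))
                assert np.abs(back - corners).max() < 1.0

    def test_identity_field_boxes_equal_panorama_boxes(self, default_config):
        eye = generate_eye(default_config, 9)
        plan = [FieldSpec("f0", "disc-centered", SimilarityTransform.identity(), raster_size=(2000, 2000))]
        gt, _ = field_visibility(eye, plan)
        by_id = {l.lesion_id: l for l in gt["f0"]}
        for i, lesion in enumerate(eye.lesions):
            assert by_id[i].bbox == pytest.approx(lesion.bbox, abs=1e-9)

    def test_straddling_lesion_clipped_in_both_fields(self, default_config):
        """A lesion in the overlap of two fields yields clipped boxes whose
        re-projections jointly cover the panorama box (within 1 px)."""
        shared = []
        for seed in range(30):
            eye = generate_eye(default_config, seed)
            plan = default_field_plan(eye, default_config)
            _, vis = field_visibility(eye, plan)
            shared = [(i, fids) for i, fids in vis.items() if len(fids) >= 2]
            if shared:
                break
        assert shared, "expected at least one lesion visible in two fields"
        gt, _ = field_visibility(eye, plan)
        for i, fids in shared:
            pano = eye.lesions[i].bbox
            boxes = []
            for fid in fids:
                f = next(p for p in plan if p.field_id == fid)
                det = next(l for l in gt[fid] if l.lesion_id == i)
                boxes.append(project_box(det.bbox, f.transform_to_panorama))
            x0 = min(b[0] for b in boxes)
            y0 = min(b[1] for b in boxes)
            x1 = max(b[0] + b[2] for b in boxes)
            y1 = max(b[1] + b[3] for b in boxes)
            assert x0 <= pano[0] + 1 and y0 <= pano[1] + 1
            assert x1 >= pano[0] + pano[2] - 1 and y1 >= pano[1] + pano[3] - 1

    def test_rasters_rendered_and_disc_visible(self, rendered_eye):
        assert set(rendered_eye.rasters) == {f.field_id for f in rendered_eye.plan}
        anchor = rendered_eye.rasters["f0"]
        assert anchor.shape == (480, 640, 3)
        # the bright disc must appear near the anchor field center
        disc = rendered_eye.eye.disc_center
        patch = anchor[int(disc[1]) - 5 : int(disc[1]) + 5, int(disc[0]) - 5 : int(disc[0]) + 5]
        assert patch[..., 0].mean() > 180


class TestOracleDetector:
    def test_zero_noise_equals_ground_truth(self, default_config):
        eye = generate_eye(default_config, 13)
        plan = default_field_plan(eye, default_config)
        gt, _ = field_visibility(eye, plan)
        det = oracle_detector(eye, plan, NoiseModel(), seed=0)
        for fid in gt:
            assert [(d.lesion_type, d.bbox, d.confidence) for d in det[fid]] == [
                (d.lesion_type, d.bbox, d.confidence) for d in gt[fid]
            ]

    def test_full_miss_rate_detects_nothing(self, default_config):
        eye = generate_eye(default_config, 13)
        plan = default_field_plan(eye, default_config)
        det = oracle_detector(eye, plan, NoiseModel(miss_rate=1.0), seed=0)
        assert all(len(v) == 0 for v in det.values())

    def test_confusion_counts_match_multinomial_oracle(self):
        """0.3 of type-4 mass moved to type 3: reported counts within 3 SE."""
        cfg = GeneratorConfig(lesion_rates=(0, 0, 0, 5.0))
        conf = np.eye(4)
        conf[3] = [0, 0, 0.3, 0.7]
        noise = NoiseModel(type_confusion=tuple(map(tuple, conf)))
        plan_of = {}
        reported = {3: 0, 4: 0}
        total = 0
        for eye in generate_cohort(cfg, 220, seed=3):
            plan = default_field_plan(eye)
            det = oracle_detector(eye, plan, noise, seed=3)
            seen = {}
            for dets in det.values():
                for d in dets:
                    seen[d.lesion_id] = d.lesion_type
            for t in seen.values():
                reported[t] += 1
                total += 1
            if total >= 1000:
                break
        p = 0.3
        se = math.sqrt(total * p * (1 - p))
        assert abs(reported[3] - total * p) <= 3 * se

    def test_invalid_confusion_rows_rejected(self):
        bad = tuple(tuple(row) for row in np.full((4, 4), 0.3))
        with pytest.raises(ValueError, match="sum to 1"):
            NoiseModel(type_confusion=bad).confusion_matrix()

    def test_adjacent_confusion_rows_sum_to_one(self):
        m = np.asarray(adjacent_confusion(0.3))
        assert np.allclose(m.sum(axis=1), 1.0)
        assert m[0, 1] == pytest.approx(0.3)  # edge type: all mass to its one neighbour
        assert m[1, 0] == m[1, 2] == pytest.approx(0.15)


class TestAnnotationsIO:
    def test_byte_identical_annotations_for_same_seed(self, tmp_path, default_config):
        def build(path):
            eyes = generate_cohort(default_config, 3, seed=21)
            plans = {}
            dets = {}
            for eye in eyes:
                plan = default_field_plan(eye, default_config)
                plans[eye.eye_id] = plan
                dets[eye.eye_id] = oracle_detector(eye, plan, NoiseModel(miss_rate=0.2, fp_rate=0.5), seed=21)
            rio.save_json(path, rio.cohort_to_coco(eyes, plans, dets))

        build(tmp_path / "a.json")
        build(tmp_path / "b.json")
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()

    def test_coco_round_trip(self, tmp_path, default_config):
        eyes = generate_cohort(default_config, 2, seed=4)
        plans = {e.eye_id: default_field_plan(e, default_config) for e in eyes}
        dets = {e.eye_id: oracle_detector(e, plans[e.eye_id], NoiseModel(), seed=4) for e in eyes}
        doc = rio.cohort_to_coco(eyes, plans, dets)
        eyes2, plans2, dets2 = rio.coco_to_cohort(json.loads(json.dumps(doc)))
        assert eyes2 == eyes
        for e in eyes:
            assert [f.field_id for f in plans2[e.eye_id]] == [f.field_id for f in plans[e.eye_id]]
            for f2, f1 in zip(plans2[e.eye_id], plans[e.eye_id]):
                assert f2.transform_to_panorama.almost_equals(f1.transform_to_panorama)
            for fid in dets[e.eye_id]:
                assert [d.bbox for d in dets2[e.eye_id][fid]] == [tuple(d.bbox) for d in dets[e.eye_id][fid]]
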