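import math

import numpy as np
import pytest

from conftest import make_registration_pair
from ropmap.registration import (
    AlignmentFailure,
    Montage,
    compose_montage,
    estimate_pairwise,
    map_lesions,
    merge_panorama_lesions,
)
from ropmap.synthetic import NoiseModel, field_visibility, oracle_detector
from ropmap.transforms import SimilarityTransform
from ropmap.types import Lesion


class TestEstimatePairwise:
    def test_identical_rasters_give_identity(self, rendered_eye):
        img = rendered_eye.rasters["f0"]
        t, score = estimate_pairwise(img, img)
        assert score > 0.99
        assert abs(t.scale - 1) < 1e-3
        assert abs(t.rotation) < 1e-3
        assert np.hypot(*t.translation) < 0.1

    def test_known_translation_recovered(self, big_scene):
        fixed, moving, true = make_registration_pair(big_scene, SimilarityTransform(translation=(20, -10)))
        t, score = estimate_pairwise(fixed, moving)
        assert score > 0.8
        assert abs(t.translation[0] - true.translation[0]) < 0.5
        assert abs(t.translation[1] - true.translation[1]) < 0.5
        assert abs(t.rotation - true.rotation) < 0.01

    def test_known_rotation_recovered(self, big_scene):
        t_scene = SimilarityTransform.about_center(1.0, math.radians(10), center=(700, 540))
        fixed, moving, true = make_registration_pair(big_scene, t_scene)
        t, _ = estimate_pairwise(fixed, moving)
        assert abs(math.degrees(t.rotation - true.rotation)) < 0.5

    def test_constant_raster_rejected(self):
        flat = np.full((480, 640, 3), 128, dtype=np.uint8)
        with pytest.raises(AlignmentFailure):
            estimate_pairwise(flat, flat)

    def test_unrelated_rasters_fail_with_low_score(self, big_scene):
        rng = np.random.default_rng(0)
        noise = (rng.uniform(0, 255, size=(480, 640, 3))).astype(np.uint8)
        fixed = big_scene[200:680, 200:840]
        with pytest.raises(AlignmentFailure) as exc:
            estimate_pairwise(fixed, noise)
        assert exc.value.score < 0.25


class TestComposeMontage:
    def test_single_field_montage_is_identity(self, rendered_eye):
        img = rendered_eye.rasters["f0"]
        m = compose_montage({"f0": img}, anchor="f0")
        assert m.transforms["f0"].almost_equals(SimilarityTransform.identity())
        assert m.excluded == []
        assert m.panorama.shape[:2] == img.shape[:2]

    def test_chain_composition_is_exact_product(self):
        ta = SimilarityTransform(scale=1.02, rotation=0.05, translation=(100, 5))
        tb = SimilarityTransform(scale=0.98, rotation=-0.03, translation=(90, -8))
        pairwise = {("A", "B"): (ta, 0.9), ("B", "C"): (tb, 0.8)}
        blank = np.zeros((10, 10, 3), np.uint8)
        m = compose_montage({"A": blank, "B": blank, "C": blank}, anchor="A", pairwise=pairwise, render=False)
        assert m.transforms["C"].almost_equals(ta.compose(tb), tol=1e-6)

    def test_five_field_plan_recovered_within_one_px(self, rendered_eye):
        plan = {f.field_id: f.transform_to_panorama for f in rendered_eye.plan}
        m = compose_montage(rendered_eye.rasters, anchor="f0", render=False)
        assert not m.excluded
        for fid, true in plan.items():
            got = m.transforms[fid]
            err = np.hypot(got.translation[0] - true.translation[0], got.translation[1] - true.translation[1])
            assert err < 1.0, (fid, err)

    def test_disconnected_field_reported(self, rendered_eye):
        rng = np.random.default_rng(1)
        noise = rng.uniform(0, 255, size=(480, 640, 3)).astype(np.uint8)
        rasters = dict(rendered_eye.rasters)
        rasters["junk"] = noise
        m = compose_montage(rasters, anchor="f0", render=False)
        assert m.excluded == ["junk"]


class TestMapLesions:
    @staticmethod
    def montage_with(transforms):
        return Montage(transforms=transforms, anchor="f0", scores={})

    def test_identity_transform_preserves_boxes(self):
        det = {"f0": [Lesion(2, (10, 20, 30, 40), 0.9, "f0")]}
        m = self.montage_with({"f0": SimilarityTransform.identity()})
        out = map_lesions(det, m)
        assert out[0].bbox == pytest.approx((10, 20, 30, 40))

    def test_pure_translation_shifts_boxes(self):
        det = {"f1": [Lesion(1, (10, 20, 30, 40), 0.9, "f1")]}
        m = self.montage_with({"f0": SimilarityTransform.identity(), "f1": SimilarityTransform(translation=(50, 0))})
        out = map_lesions(det, m)
        assert out[0].bbox == pytest.approx((60, 20, 30, 40))

    def test_unknown_field_raises(self):
        det = {"mystery": [Lesion(1, (0, 0, 5, 5), 1.0, "mystery")]}
        with pytest.raises(KeyError):
            map_lesions(det, self.montage_with({"f0": SimilarityTransform.identity()}))

    def test_duplicate_detections_merge_to_one(self, default_config):
        """Zero-noise detections of a lesion seen in two fields merge to a
        single panorama lesion per true lesion."""
        from ropmap.synthetic import default_field_plan, generate_eye

        for seed in range(30):
            eye = generate_eye(default_config, seed)
            plan = default_field_plan(eye, default_config)
            _, vis = field_visibility(eye, plan)
            if any(len(v) >= 2 for v in vis.values()) and eye.lesions:
                break
        det = oracle_detector(eye, plan, NoiseModel(), seed=0)
        m = self.montage_with({f.field_id: f.transform_to_panorama for f in plan})
        out = map_lesions(det, m)
        visible = sum(1 for v in vis.values() if v)
        assert len(out) == visible

    def test_merge_idempotent(self):
        rng = np.random.default_rng(8)
        lesions = [
            Lesion(int(rng.integers(1, 5)), tuple(rng.uniform(0, 500, 2)) + (20, 20), float(rng.uniform(0.2, 1)))
            for _ in range(40)
        ]
        once = merge_panorama_lesions(lesions)
        twice = merge_panorama_lesions(once)
        assert [l.bbox for l in twice] == [l.bbox for l in once]

    def test_equivariance_under_panorama_transform(self):
        """Applying T to every field transform maps outputs through T."""
        T = SimilarityTransform(scale=1.1, rotation=0.2, translation=(30, -40))
        det = {
            "f0": [Lesion(2, (100, 120, 30, 20), 0.9, "f0")],
            "f1": [Lesion(3, (50, 60, 25, 35), 0.8, "f1")],
        }
        base = {"f0": SimilarityTransform.identity(), "f1": SimilarityTransform(translation=(200, 0))}
        out1 = map_lesions(det, self.montage_with(base))
        moved = {k: T.compose(v) for k, v in base.items()}
        out2 = map_lesions(det, self.montage_with(moved))
        assert len(out1) == len(out2)
        for a, b in zip(out1, out2):
            assert np.allclose(b.center, T.apply(np.array(a.center)), atol=1e-6)
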