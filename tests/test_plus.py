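import json
import math
from importlib import resources

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from ropmap.plus import (
    VesselCenterline,
    classify_plus,
    extract_centerlines,
    plus_features,
    tortuosity_index,
)
from ropmap.synthetic import FieldSpec, GeneratorConfig, generate_eye, render_fields
from ropmap.transforms import SimilarityTransform
from ropmap.zones import PanoramaFrame


def sinusoid(amplitude, wavelength, n=1000, length=None):
    x = np.linspace(0, length if length is not None else wavelength, n)
    return np.c_[x, amplitude * np.sin(2 * math.pi * x / wavelength)]


class TestTortuosityIndex:
    def test_straight_segment_is_exactly_one(self):
        assert tortuosity_index(np.array([[0.0, 0.0], [10.0, 5.0]])) == 1.0
        # collinear multi-point polyline as well
        assert tortuosity_index(np.array([[0, 0], [1, 1], [2, 2], [7, 7]], float)) == pytest.approx(1.0)

    def test_dense_semicircle_is_half_pi(self):
        theta = np.linspace(0, math.pi, 4000)
        pts = np.c_[np.cos(theta), np.sin(theta)]
        assert tortuosity_index(pts) == pytest.approx(math.pi / 2, abs=1e-3)

    def test_sinusoid_matches_quadrature_oracle(self):
        A, lam = 5.0, 100.0
        pts = sinusoid(A, lam, n=1000, length=lam)
        k = 2 * math.pi / lam
        arc, _ = quad(lambda x: math.sqrt(1 + (A * k * math.cos(k * x)) ** 2), 0, lam)
        assert tortuosity_index(pts) == pytest.approx(arc / lam, rel=1e-4)

    def test_monotone_in_amplitude(self):
        values = [tortuosity_index(sinusoid(a, 80.0, n=2000, length=240.0)) for a in np.linspace(0, 10, 21)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    @settings(deadline=None, max_examples=40)
    @given(
        st.floats(0.1, 8.0),
        st.floats(-math.pi, math.pi),
        st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
        st.floats(0.1, 5.0),
    )
    def test_invariant_to_similarity_motion(self, amp, rot, trans, scale):
        pts = sinusoid(amp, 60.0, n=300, length=180.0)
        t = SimilarityTransform(scale=scale, rotation=rot, translation=trans)
        assert tortuosity_index(t.apply(pts)) == pytest.approx(tortuosity_index(pts), rel=1e-9)

    def test_zero_chord_rejected(self):
        theta = np.linspace(0, 2 * math.pi, 100)
        closed = np.c_[np.cos(theta), np.sin(theta)]
        with pytest.raises(ValueError, match="chord"):
            tortuosity_index(closed)


class TestExtractCenterlines:
    def test_blank_raster_yields_nothing(self):
        blank = np.full((480, 640, 3), 40, dtype=np.uint8)
        assert extract_centerlines(blank) == []

    def test_straight_vessel_width_recovered(self):
        """A rendered straight stroke of width 4 is traced with mean width within 1 px."""
        from ropmap.synthetic import COLOR_BG, COLOR_VESSEL, _stamp_polyline

        img = np.empty((200, 400, 3), dtype=np.uint8)
        img[:] = COLOR_BG
        mask = np.zeros((200, 400), dtype=bool)
        pts = np.c_[np.linspace(20, 380, 400), np.full(400, 100.0)]
        _stamp_polyline(mask, pts, 2.0)  # radius 2 -> stroke width 4
        img[mask] = COLOR_VESSEL
        cls = extract_centerlines(img, disc_center=(0.0, 0.0), disc_radius=1.0)
        assert len(cls) == 1
        assert cls[0].widths.mean() == pytest.approx(4.0, abs=1.0)
        assert tortuosity_index(cls[0]) < 1.01

    def test_eight_vessels_traced(self, default_config):
        eye = generate_eye(default_config, 31)
        plan = [FieldSpec("f0", "disc-centered", SimilarityTransform.identity())]
        rendered = render_fields(eye, plan)
        cls = extract_centerlines(rendered.rasters["f0"], disc_center=eye.disc_center)
        assert len(cls) == 8


class TestVesselCenterlineValidation:
    def test_rejects_single_point(self):
        with pytest.raises(ValueError):
            VesselCenterline(points=np.array([[0.0, 0.0]]), widths=np.array([3.0]))

    def test_rejects_nonpositive_widths(self):
        with pytest.raises(ValueError, match="positive"):
            VesselCenterline(points=np.array([[0.0, 0.0], [1.0, 0.0]]), widths=np.array([3.0, 0.0]))


class TestClassifyPlus:
    @pytest.fixture()
    def frame(self):
        return PanoramaFrame((320.0, 240.0), (170.0, 240.0), 450.0, "OD")

    def make_centerlines(self, amp, width, frame):
        out = []
        for ang in np.linspace(0, 2 * math.pi, 8, endpoint=False):
            d = np.array([math.cos(ang), math.sin(ang)])
            nrm = np.array([-d[1], d[0]])
            t = np.arange(30.0, 280.0, 1.0)
            pts = np.asarray(frame.disc_center) + t[:, None] * d + (amp * np.sin(2 * math.pi * t / 80.0))[:, None] * nrm
            out.append(VesselCenterline(points=pts, widths=np.full(len(pts), width)))
        return out

    def test_straight_thin_vessels_are_negative(self, frame):
        res = classify_plus(self.make_centerlines(0.0, 3.0, frame), frame, source="centerline")
        assert res.plus is False and res.score < 0.5

    def test_plus_regime_is_positive(self, frame):
        res = classify_plus(self.make_centerlines(8.0, 7.0, frame), frame, source="centerline")
        assert res.plus is True and res.score > 0.5

    def test_empty_input_is_indeterminate_not_negative(self, frame):
        res = classify_plus([], frame)
        assert res.indeterminate and res.plus is None and math.isnan(res.score)

    def test_score_monotone_in_each_feature(self, frame):
        scores_w = [classify_plus(self.make_centerlines(2.0, w, frame), frame, source="centerline").score
                    for w in np.linspace(2, 8, 7)]
        assert all(b >= a for a, b in zip(scores_w, scores_w[1:]))
        scores_a = [classify_plus(self.make_centerlines(a, 4.0, frame), frame, source="centerline").score
                    for a in np.linspace(0, 8, 9)]
        assert all(b >= a for a, b in zip(scores_a, scores_a[1:]))

    def test_shipped_coefficients_nonnegative(self):
        doc = json.loads(resources.files("ropmap").joinpath("plus_calibration.json").read_text())
        for source in ("raster", "centerline"):
            assert all(c >= 0 for c in doc[source]["coef"])

    def test_zone_one_restriction_ignores_periphery(self, frame):
        """Tortuosity added only beyond zone I must not change the features."""
        base = self.make_centerlines(0.5, 3.5, frame)
        distorted = []
        for c in base:
            pts = c.points.copy()
            r = np.linalg.norm(pts - np.asarray(frame.disc_center), axis=1)
            outside = r > frame.zone1_radius + 10
            pts[outside] += np.c_[10 * np.sin(pts[outside, 1]), 10 * np.cos(pts[outside, 0])]
            distorted.append(VesselCenterline(points=pts, widths=c.widths))
        f1 = plus_features(base, frame)
        f2 = plus_features(distorted, frame)
        assert f1["mean_tortuosity"] == pytest.approx(f2["mean_tortuosity"], rel=1e-6)

    def test_held_out_synthetic_accuracy(self, default_config):
        """Plus calls on held-out synthetic eyes match generator truth >= 95%."""
        from ropmap.synthetic import generate_cohort

        cfg = GeneratorConfig(plus_prevalence=0.5)
        eyes = generate_cohort(cfg, 120, seed=11)
        correct = 0
        for eye in eyes:
            cls = [VesselCenterline(points=p, widths=np.full(len(p), w)) for p, w in eye.vessel_centerlines()]
            res = classify_plus(cls, eye.frame, source="centerline")
            correct += int(res.plus == eye.plus_present)
        assert correct / len(eyes) >= 0.95
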