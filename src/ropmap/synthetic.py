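"""Seeded synthetic-eye generator.

Produces ground-truth eyes (landmarks, vessels, lesions with known panorama
positions and zones), renders multi-field fundus rasters related by known
similarity transforms, and provides a noise-configurable oracle detector that
stands in for a trained lesion detector.  Everything is deterministic given
(config, seed).

Geometry follows a fixed panorama scale: optic-disc diameter 60 px,
disc-fovea distance ~150 px, nasal ora-serrata radius ~3.1x the disc-fovea
distance, fields 640x480 px.  The disc-centered field anchors the panorama
frame (its transform is the identity), so panorama coordinates are the
disc-centered field's coordinates.

Rendered eyes are glyph-coded rather than photorealistic: vessels are
sinusoidally perturbed rays from the disc (amplitude = tortuosity, stroke
width = dilation), lesions are type-coded high-contrast shapes
(line / arc / arc+texture / wedge).  The downstream pipeline consumes
detections; rasters only need to support registration and vessel extraction.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw
from skimage import transform as sktf

from .transforms import SimilarityTransform, project_box
from .types import Lesion
from .zones import PanoramaFrame, zone_of_point

# panorama-scale constants (px)
DISC_RADIUS = 30.0
FIELD_SIZE = (640, 480)  # (width, height)

# scene palette, chosen so vessels separate from disc/lesions in (R - G)
COLOR_BG = (60, 30, 20)
COLOR_OUTSIDE = (18, 10, 8)
COLOR_DISC = (235, 190, 120)
COLOR_CUP = (200, 150, 90)
COLOR_FOVEA = (90, 45, 35)
COLOR_VESSEL = (150, 35, 30)
COLOR_LESION = (230, 225, 210)

VESSEL_WAVELENGTH = 80.0  # px, sinusoid period along the vessel ray
N_VESSELS = 8


@dataclass(frozen=True)
class GroundTruthLesion:
    lesion_type: int
    center: tuple[float, float]
    extent: tuple[float, float]  # (w, h), strictly positive
    true_zone: str

    def __post_init__(self) -> None:
        if self.lesion_type not in (1, 2, 3, 4):
            raise ValueError(f"lesion_type must be 1..4, got {self.lesion_type}")
        if not (self.extent[0] > 0 and self.extent[1] > 0):
            raise ValueError("lesion extent must be strictly positive")

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        cx, cy = self.center
        w, h = self.extent
        return (cx - w / 2.0, cy - h / 2.0, w, h)


@dataclass(frozen=True)
class GroundTruthEye:
    eye_id: str
    laterality: str
    disc_center: tuple[float, float]
    fovea_center: tuple[float, float]
    ora_radius_nasal: float
    lesions: tuple[GroundTruthLesion, ...]
    plus_present: bool
    tortuosity_amp: float
    vessel_width: float
    seed: int

    @property
    def frame(self) -> PanoramaFrame:
        return PanoramaFrame(
            disc_center=self.disc_center,
            fovea_center=self.fovea_center,
            ora_radius_nasal=self.ora_radius_nasal,
            laterality=self.laterality,
        )

    def vessel_centerlines(self) -> list[tuple[np.ndarray, float]]:
        """Analytic vessel centerlines as [(points (N,2), width), ...].

        Deterministic given the eye's seed; these are exactly the polylines
        the renderer strokes, so they double as serialized centerline input
        for the plus-disease scorer.
        """
        rng = np.random.default_rng([self.seed, 101])
        phases = rng.uniform(0, 2 * math.pi, size=N_VESSELS)
        angle0 = rng.uniform(0, 2 * math.pi / N_VESSELS)
        # uneven angular spacing: real vasculature has no rotational symmetry,
        # and a symmetric ray pattern would make registration ambiguous by pi
        jitter = rng.uniform(-math.radians(12), math.radians(12), size=N_VESSELS)
        length = 0.93 * self.ora_radius_nasal
        out = []
        for k in range(N_VESSELS):
            ang = angle0 + 2 * math.pi * k / N_VESSELS + jitter[k]
            d = np.array([math.cos(ang), math.sin(ang)])
            nrm = np.array([-d[1], d[0]])
            t = np.arange(DISC_RADIUS, length, 1.0)
            disp = self.tortuosity_amp * np.sin(2 * math.pi * t / VESSEL_WAVELENGTH + phases[k])
            pts = np.asarray(self.disc_center) + t[:, None] * d + disp[:, None] * nrm
            out.append((pts, self.vessel_width))
        return out


@dataclass(frozen=True)
class FieldSpec:
    field_id: str
    orientation_label: str
    transform_to_panorama: SimilarityTransform
    raster_size: tuple[int, int] = FIELD_SIZE


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort-level generation parameters.

    Defaults emulate a screening cohort skewed toward mild disease: posterior
    zone I and stage 4 findings are rare, zone III findings are an occasional
    peripheral temporal crescent case.
    """

    od_prob: float = 0.5
    lesion_rates: tuple[float, float, float, float] = (0.6, 0.5, 0.25, 0.08)  # Poisson mean per type 1..4
    plus_prevalence: float = 0.15
    zone3_fraction: float = 0.12  # fraction of lesions placed in the temporal periphery
    disc_fovea_range: tuple[float, float] = (140.0, 160.0)
    ora_over_dfd_range: tuple[float, float] = (3.0, 3.2)
    lesion_extent_range: tuple[float, float] = (22.0, 48.0)
    # vessel regimes: (amplitude range, width range), plus vs not
    plus_amp_range: tuple[float, float] = (4.0, 8.0)
    plus_width_range: tuple[float, float] = (5.0, 7.0)
    normal_amp_range: tuple[float, float] = (0.0, 1.5)
    normal_width_range: tuple[float, float] = (3.0, 4.0)
    field_offset: float = 220.0  # px, nasal/temporal field displacement
    field_offset_vertical: float = 185.0
    field_rotation_max_deg: float = 5.0
    field_scale_range: tuple[float, float] = (0.97, 1.03)

    def __post_init__(self) -> None:
        lo, hi = self.ora_over_dfd_range
        if lo <= 2.0:
            raise ValueError(
                "infeasible geometry: ora_over_dfd_range must exceed 2 so zone II strictly contains zone I"
            )


@dataclass(frozen=True)
class NoiseModel:
    """Detector imperfection model applied per lesion (consistently across
    fields that see the same lesion) plus per-field false positives."""

    miss_rate: float = 0.0
    fp_rate: float = 0.0  # expected false positives per field (Poisson)
    jitter_sigma: float = 0.0  # px, isotropic Gaussian on the panorama center
    type_confusion: tuple[tuple[float, ...], ...] | None = None  # 4x4, rows = true type

    def confusion_matrix(self) -> np.ndarray:
        if self.type_confusion is None:
            return np.eye(4)
        m = np.asarray(self.type_confusion, dtype=float)
        if m.shape != (4, 4) or (m < 0).any():
            raise ValueError("type_confusion must be a non-negative 4x4 matrix")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("type_confusion rows must sum to 1")
        return m

    @property
    def is_zero(self) -> bool:
        return (
            self.miss_rate == 0
            and self.fp_rate == 0
            and self.jitter_sigma == 0
            and np.allclose(self.confusion_matrix(), np.eye(4))
        )


def adjacent_confusion(p: float) -> tuple[tuple[float, ...], ...]:
    """Type-confusion matrix moving mass ``p`` to adjacent stages.

    Interior types split ``p`` equally between their two neighbours; edge
    types give all of it to their single neighbour.
    """
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    m = np.zeros((4, 4))
    for i in range(4):
        m[i, i] = 1 - p
        nbrs = [j for j in (i - 1, i + 1) if 0 <= j < 4]
        for j in nbrs:
            m[i, j] += p / len(nbrs)
    return tuple(tuple(row) for row in m)


def generate_eye(config: GeneratorConfig, seed: int, eye_id: str | None = None) -> GroundTruthEye:
    """Draw one self-consistent ground-truth eye.

    Identical (config, seed) always reproduce the identical eye; every
    lesion's ``true_zone`` is recomputed through :func:`zone_of_point` before
    the eye is returned.
    """
    rng = np.random.default_rng(seed)
    laterality = "OD" if rng.uniform() < config.od_prob else "OS"
    nasal = np.array([1.0, 0.0]) if laterality == "OD" else np.array([-1.0, 0.0])
    w, h = FIELD_SIZE
    disc = np.array([w / 2 + rng.uniform(-15, 15), h / 2 + rng.uniform(-10, 10)])
    dfd = rng.uniform(*config.disc_fovea_range)
    fovea = disc - dfd * nasal + np.array([0.0, rng.uniform(-10, 10)])
    ora = rng.uniform(*config.ora_over_dfd_range) * float(np.hypot(*(fovea - disc)))
    frame = PanoramaFrame(tuple(disc), tuple(fovea), ora, laterality)

    plus_present = bool(rng.uniform() < config.plus_prevalence)
    if plus_present:
        amp = rng.uniform(*config.plus_amp_range)
        width = rng.uniform(*config.plus_width_range)
    else:
        amp = rng.uniform(*config.normal_amp_range)
        width = rng.uniform(*config.normal_width_range)

    temporal_angle = math.atan2(-nasal[1], -nasal[0])
    lesions = []
    for t, rate in zip((1, 2, 3, 4), config.lesion_rates, strict=True):
        for _ in range(rng.poisson(rate)):
            if rng.uniform() < config.zone3_fraction:
                # peripheral temporal crescent, clear of the zone II boundary
                r = ora * rng.uniform(1.02, 1.05)
                ang = temporal_angle + math.radians(rng.uniform(-25, 25))
            else:
                # posterior/mid-periphery, biased outward (zone I disease is rare)
                r = ora * (0.5 + 0.35 * math.sqrt(rng.uniform()))
                ang = rng.uniform(0, 2 * math.pi)
            center = disc + r * np.array([math.cos(ang), math.sin(ang)])
            extent = (rng.uniform(*config.lesion_extent_range), rng.uniform(*config.lesion_extent_range))
            lesions.append(
                GroundTruthLesion(
                    lesion_type=t,
                    center=(float(center[0]), float(center[1])),
                    extent=extent,
                    true_zone=zone_of_point(center, frame),
                )
            )
    # generator self-consistency: recompute and verify every zone label
    for l in lesions:
        assert l.true_zone == zone_of_point(l.center, frame)

    return GroundTruthEye(
        eye_id=eye_id if eye_id is not None else f"eye{seed:010d}",
        laterality=laterality,
        disc_center=tuple(disc),
        fovea_center=tuple(fovea),
        ora_radius_nasal=ora,
        lesions=tuple(lesions),
        plus_present=plus_present,
        tortuosity_amp=float(amp),
        vessel_width=float(width),
        seed=int(seed),
    )


def default_field_plan(eye: GroundTruthEye, config: GeneratorConfig | None = None) -> list[FieldSpec]:
    """Five-field capture plan: disc-centered anchor + nasal/temporal/superior/
    inferior fields with small random rotation and scale.

    Adjacent fields overlap by well over 25% of the raster area, so pairwise
    registration is always possible.  Exactly one field is disc-centered and
    its transform is the identity (it anchors the panorama frame).
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng([eye.seed, 202])
    w, h = FIELD_SIZE
    center = (w / 2.0, h / 2.0)
    nasal = np.array(eye.frame.nasal_unit)
    offsets = {
        "nasal": config.field_offset * nasal,
        "temporal": -config.field_offset * nasal,
        "superior": np.array([0.0, -config.field_offset_vertical]),
        "inferior": np.array([0.0, config.field_offset_vertical]),
    }
    plan = [FieldSpec("f0", "disc-centered", SimilarityTransform.identity())]
    for i, (label, off) in enumerate(offsets.items(), start=1):
        rot = math.radians(rng.uniform(-config.field_rotation_max_deg, config.field_rotation_max_deg))
        scale = rng.uniform(*config.field_scale_range)
        t = SimilarityTransform.about_center(scale, rot, center, translation=tuple(off))
        plan.append(FieldSpec(f"f{i}", label, t))
    return plan


# ---------------------------------------------------------------------------
# rendering


def _stamp_polyline(canvas_mask: np.ndarray, pts: np.ndarray, radius: float) -> None:
    """Stroke a polyline into a boolean mask by stamping disks."""
    H, W = canvas_mask.shape
    r = max(radius, 0.5)
    for x, y in pts:
        rr, cc = skdraw.disk((y, x), r, shape=(H, W))
        canvas_mask[rr, cc] = True


def _lesion_glyph_mask(shape: tuple[int, int], lesion: GroundTruthLesion, origin: np.ndarray) -> np.ndarray:
    """Type-coded glyph inside the lesion's box: line / arc / arc+dots / wedge."""
    H, W = shape
    mask = np.zeros((H, W), dtype=bool)
    x, y, w, h = lesion.bbox
    x -= origin[0]
    y -= origin[1]
    t = lesion.lesion_type
    if t == 1:  # demarcation line: straight thick line across the box
        pts = np.linspace([x + 2, y + h / 2], [x + w - 2, y + h / 2], int(max(w, 2)))
        _stamp_polyline(mask, pts, 2.5)
    elif t in (2, 3):  # ridge: an arc bowing through the box
        xs = np.linspace(x + 2, x + w - 2, int(max(w, 2)))
        ys = y + h / 2 - (h / 2 - 3) * np.sin(np.linspace(0, math.pi, len(xs)))
        _stamp_polyline(mask, np.c_[xs, ys], 3.0)
        if t == 3:  # extraretinal proliferation: texture dots below the ridge
            rng = np.random.default_rng([int(abs(x)) + 1, int(abs(y)) + 1])
            for _ in range(8):
                px = rng.uniform(x + 4, x + w - 4)
                py = rng.uniform(y + h / 2, y + h - 2)
                rr, cc = skdraw.disk((py, px), 1.8, shape=(H, W))
                mask[rr, cc] = True
    else:  # detachment: filled wedge
        poly_r = np.array([y + 2, y + h - 2, y + h - 2])
        poly_c = np.array([x + w / 2, x + 2, x + w - 2])
        rr, cc = skdraw.polygon(poly_r, poly_c, shape=(H, W))
        mask[rr, cc] = True
    return mask


def render_scene(eye: GroundTruthEye, bounds: tuple[float, float, float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Render the panorama-space scene over ``bounds`` = (x0, y0, x1, y1).

    Returns (scene uint8 RGB of shape (H, W, 3), origin (x0, y0)); a scene
    pixel (row j, col i) sits at panorama point (x0 + i, y0 + j).
    """
    x0, y0, x1, y1 = bounds
    origin = np.array([math.floor(x0), math.floor(y0)], dtype=float)
    W = int(math.ceil(x1) - origin[0])
    H = int(math.ceil(y1) - origin[1])
    rng = np.random.default_rng([eye.seed, 303])

    img = np.empty((H, W, 3), dtype=float)
    img[:] = COLOR_BG
    # smooth mottle + fine grain give the registration something to lock onto
    mottle = ndi.gaussian_filter(rng.standard_normal((H, W)), 8.0)
    mottle *= 18.0 / max(mottle.std(), 1e-9)
    grain = rng.standard_normal((H, W)) * 4.0
    img += (mottle + grain)[:, :, None] * np.array([1.0, 0.8, 0.6])

    yy, xx = np.mgrid[0:H, 0:W]
    px = xx + origin[0]
    py = yy + origin[1]
    r2 = (px - eye.disc_center[0]) ** 2 + (py - eye.disc_center[1]) ** 2
    outside = r2 > (1.12 * eye.ora_radius_nasal) ** 2
    img[outside] = COLOR_OUTSIDE

    def disk_at(center, radius, color):
        rr, cc = skdraw.disk((center[1] - origin[1], center[0] - origin[0]), radius, shape=(H, W))
        img[rr, cc] = color

    disk_at(eye.fovea_center, 10, COLOR_FOVEA)

    vmask = np.zeros((H, W), dtype=bool)
    for pts, width in eye.vessel_centerlines():
        _stamp_polyline(vmask, pts - origin, width / 2.0)
    img[vmask] = COLOR_VESSEL

    disk_at(eye.disc_center, DISC_RADIUS, COLOR_DISC)
    disk_at(eye.disc_center, DISC_RADIUS * 0.4, COLOR_CUP)

    for lesion in eye.lesions:
        g = _lesion_glyph_mask((H, W), lesion, origin)
        img[g] = COLOR_LESION

    return np.clip(img, 0, 255).astype(np.uint8), origin


@dataclass
class RenderedEye:
    """Rendered multi-field capture of one eye plus per-field ground truth."""

    eye: GroundTruthEye
    plan: list[FieldSpec]
    rasters: dict[str, np.ndarray]
    field_ground_truth: dict[str, list[Lesion]]
    visibility: dict[int, list[str]]  # lesion index -> fields that see it
    warnings: list[str] = field(default_factory=list)


def field_visibility(eye: GroundTruthEye, plan: list[FieldSpec]) -> tuple[dict[str, list[Lesion]], dict[int, list[str]]]:
    """Per-field ground-truth boxes (clipped) and the lesion->fields table,
    computed geometrically (no rasters needed)."""
    gt: dict[str, list[Lesion]] = {f.field_id: [] for f in plan}
    vis: dict[int, list[str]] = {i: [] for i in range(len(eye.lesions))}
    for f in plan:
        inv = f.transform_to_panorama.inverse()
        fw, fh = f.raster_size
        for i, lesion in enumerate(eye.lesions):
            bx, by, bw, bh = project_box(lesion.bbox, inv)
            cx0, cy0 = max(bx, 0.0), max(by, 0.0)
            cx1, cy1 = min(bx + bw, fw), min(by + bh, fh)
            if cx1 - cx0 > 1.0 and cy1 - cy0 > 1.0:
                gt[f.field_id].append(
                    Lesion(
                        lesion_type=lesion.lesion_type,
                        bbox=(cx0, cy0, cx1 - cx0, cy1 - cy0),
                        confidence=1.0,
                        field_id=f.field_id,
                        lesion_id=i,
                    )
                )
                vis[i].append(f.field_id)
    return gt, vis


def render_fields(eye: GroundTruthEye, plan: list[FieldSpec] | None = None) -> RenderedEye:
    """Render every field of a capture plan by sampling the panorama scene
    through each field's known transform."""
    plan = plan if plan is not None else default_field_plan(eye)
    anchors = [f for f in plan if f.orientation_label == "disc-centered"]
    if len(anchors) != 1:
        raise ValueError(f"plan must contain exactly one disc-centered field, got {len(anchors)}")

    # scene bounds: union of field footprints + margin
    corners = []
    for f in plan:
        fw, fh = f.raster_size
        pts = np.array([[0, 0], [fw, 0], [0, fh], [fw, fh]], dtype=float)
        corners.append(f.transform_to_panorama.apply(pts))
    allc = np.vstack(corners)
    m = 8.0
    bounds = (allc[:, 0].min() - m, allc[:, 1].min() - m, allc[:, 0].max() + m, allc[:, 1].max() + m)
    scene, origin = render_scene(eye, bounds)

    rasters = {}
    for f in plan:
        fw, fh = f.raster_size
        # map field (x, y) -> scene (x, y): panorama transform then origin shift
        M = f.transform_to_panorama.matrix.copy()
        M[0, 2] -= origin[0]
        M[1, 2] -= origin[1]
        warped = sktf.warp(
            scene.astype(float), sktf.SimilarityTransform(matrix=M), output_shape=(fh, fw), order=1, mode="constant", cval=0.0
        )
        rasters[f.field_id] = np.clip(warped, 0, 255).astype(np.uint8)

    gt, vis = field_visibility(eye, plan)
    warn = []
    for i, fields in vis.items():
        if not fields:
            msg = f"lesion {i} (type {eye.lesions[i].lesion_type}) of {eye.eye_id} is visible in no field"
            warn.append(msg)
            _warnings.warn(msg, stacklevel=2)
    return RenderedEye(eye=eye, plan=plan, rasters=rasters, field_ground_truth=gt, visibility=vis, warnings=warn)


# ---------------------------------------------------------------------------
# oracle detector


def oracle_detector(
    eye: GroundTruthEye,
    plan: list[FieldSpec],
    noise: NoiseModel,
    seed: int,
) -> dict[str, list[Lesion]]:
    """Per-field detections from ground truth through a noise model.

    With all noise at zero, detections equal the per-field ground truth
    exactly.  Miss / type-confusion / center-jitter draws are made once per
    lesion (shared by every field that sees it) from an RNG keyed on
    (seed, eye.seed, lesion index), so sweeps over noise levels with a common
    seed are coupled through common random numbers.  False positives are
    drawn per field.
    """
    conf_m = noise.confusion_matrix()
    cum = np.cumsum(conf_m, axis=1)
    detections: dict[str, list[Lesion]] = {f.field_id: [] for f in plan}

    for i, lesion in enumerate(eye.lesions):
        rng = np.random.default_rng([seed, eye.seed, 11, i])
        u_miss = rng.uniform()
        u_type = rng.uniform()
        jitter = rng.standard_normal(2)
        if u_miss < noise.miss_rate:
            continue
        reported = int(np.searchsorted(cum[lesion.lesion_type - 1], u_type, side="right")) + 1
        reported = min(reported, 4)
        cx = lesion.center[0] + noise.jitter_sigma * jitter[0]
        cy = lesion.center[1] + noise.jitter_sigma * jitter[1]
        w, h = lesion.extent
        pano_box = (cx - w / 2, cy - h / 2, w, h)
        for f in plan:
            inv = f.transform_to_panorama.inverse()
            bx, by, bw, bh = project_box(pano_box, inv)
            fw, fh = f.raster_size
            x0, y0 = max(bx, 0.0), max(by, 0.0)
            x1, y1 = min(bx + bw, fw), min(by + bh, fh)
            if x1 - x0 > 1.0 and y1 - y0 > 1.0:
                detections[f.field_id].append(
                    Lesion(
                        lesion_type=reported,
                        bbox=(x0, y0, x1 - x0, y1 - y0),
                        confidence=1.0,
                        field_id=f.field_id,
                        lesion_id=i,
                    )
                )

    if noise.fp_rate > 0:
        for j, f in enumerate(plan):
            rng = np.random.default_rng([seed, eye.seed, 23, j])
            fw, fh = f.raster_size
            for _ in range(rng.poisson(noise.fp_rate)):
                w = rng.uniform(20, 50)
                h = rng.uniform(20, 50)
                x = rng.uniform(0, fw - w)
                y = rng.uniform(0, fh - h)
                detections[f.field_id].append(
                    Lesion(
                        lesion_type=int(rng.integers(1, 5)),
                        bbox=(x, y, w, h),
                        confidence=float(rng.uniform(0.2, 0.7)),
                        field_id=f.field_id,
                    )
                )
    return detections


def generate_cohort(config: GeneratorConfig, n_eyes: int, seed: int) -> list[GroundTruthEye]:
    """Generate ``n_eyes`` eyes with per-eye seeds spawned deterministically
    from ``seed`` (eye seeds are independent of cohort size up to prefix)."""
    root = np.random.default_rng([seed, 404])
    eye_seeds = root.integers(0, 2**31 - 1, size=n_eyes)
    return [generate_eye(config, int(s), eye_id=f"eye{idx:04d}") for idx, s in enumerate(eye_seeds)]
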