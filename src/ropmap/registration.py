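"""Field-to-panorama registration and lesion re-projection.

Pairwise similarity transforms are estimated classically: rotation and scale
from phase correlation of the log-polar-resampled Fourier magnitudes, then
translation from plain phase correlation after un-rotating/un-scaling the
moving raster.  Global (field -> panorama) transforms are obtained by
chaining pairwise estimates along a maximum-score spanning tree rooted at the
disc-centered anchor field, whose transform is the identity — panorama
coordinates therefore inherit the disc-centered frame.  No bundle adjustment
is performed; per-edge residual scores are reported so weak alignments stay
visible.  Externally supplied transforms can be passed anywhere a learned
registration model would plug in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import optimize
from skimage import transform as sktf
from skimage.color import rgb2gray
from skimage.feature import ORB, match_descriptors
from skimage.filters import difference_of_gaussians, window
from skimage.measure import ransac
from skimage.registration import phase_cross_correlation

from .transforms import SimilarityTransform, box_center, project_box
from .types import Lesion

DEFAULT_MIN_SCORE = 0.25
DEFAULT_MERGE_RADIUS = 15.0  # px, a quarter of the disc diameter
DEFAULT_FIELD_CENTER = (320.0, 240.0)  # 640x480 capture raster


class AlignmentFailure(RuntimeError):
    """Pairwise registration scored below threshold; carries the best score."""

    def __init__(self, message: str, score: float):
        super().__init__(message)
        self.score = score


def _as_gray(img: np.ndarray) -> np.ndarray:
    if img.ndim == 3:
        return rgb2gray(img)
    return img.astype(float)


def _fft_logpolar(gray: np.ndarray, radius: float, angular: int = 720, radial: int = 400) -> np.ndarray:
    f = np.abs(np.fft.fftshift(np.fft.fft2(gray)))
    return sktf.warp_polar(f, radius=radius, output_shape=(angular, radial), scaling="log", order=1)


def _bandpass(gray: np.ndarray) -> np.ndarray:
    """Difference-of-Gaussians: strips the smooth illumination/vignette
    component that would otherwise dominate overlap correlations."""
    return difference_of_gaussians(gray, 1, 12)


def _alignment_score(fixed: np.ndarray, moving: np.ndarray, t: SimilarityTransform) -> float:
    """Pearson correlation of the band-passed overlap after warping moving
    into the fixed frame, clipped to [0, 1]."""
    gf = _bandpass(_as_gray(fixed))
    gm = _bandpass(_as_gray(moving))
    h, w = gf.shape
    warped = sktf.warp(gm, sktf.SimilarityTransform(matrix=t.inverse().matrix), output_shape=(h, w), order=1, cval=np.nan)
    valid = ~np.isnan(warped)
    if valid.sum() < 0.05 * h * w:
        return 0.0
    a = gf[valid]
    b = warped[valid]
    sa, sb = a.std(), b.std()
    if sa < 1e-9 or sb < 1e-9:
        return 0.0
    r = float(np.corrcoef(a, b)[0, 1])
    return max(0.0, r)


def _ncc_loss_factory(f: np.ndarray, m: np.ndarray, ds: float):
    h, w = f.shape

    def loss(p):
        s, r, tx, ty = p
        t = SimilarityTransform(scale=max(s, 1e-3), rotation=r, translation=(tx / ds, ty / ds))
        warped = sktf.warp(m, sktf.SimilarityTransform(matrix=t.inverse().matrix), output_shape=(h, w), order=1, cval=np.nan)
        valid = ~np.isnan(warped)
        if valid.sum() < 0.05 * h * w:
            return 1.0
        a, b = f[valid], warped[valid]
        if a.std() < 1e-9 or b.std() < 1e-9:
            return 1.0
        return 1.0 - float(np.corrcoef(a, b)[0, 1])

    return loss


def _refine(gf: np.ndarray, gm: np.ndarray, t0: SimilarityTransform, stages=(4, 2)) -> SimilarityTransform:
    """Coarse-to-fine Nelder-Mead maximization of overlap correlation,
    polishing the FFT initialization to sub-pixel accuracy."""
    p = np.array([t0.scale, t0.rotation, t0.translation[0], t0.translation[1]])
    for ds in stages:
        f = sktf.rescale(gf, 1.0 / ds, anti_aliasing=True)
        m = sktf.rescale(gm, 1.0 / ds, anti_aliasing=True)
        res = optimize.minimize(
            _ncc_loss_factory(f, m, ds), p, method="Nelder-Mead",
            options=dict(xatol=5e-4, fatol=1e-7, maxiter=300),
        )
        p = res.x
    return SimilarityTransform(scale=float(p[0]), rotation=float(p[1]), translation=(float(p[2]), float(p[3])))


def _orb_ransac_estimate(gf: np.ndarray, gm: np.ndarray, seed: int = 0) -> SimilarityTransform | None:
    """Feature-based initialization: ORB keypoints matched across rasters,
    similarity model fit by RANSAC.  Rotation-unambiguous (unlike Fourier
    magnitude methods) and robust to partial overlap; returns None when too
    few inliers support a model."""
    try:
        def feats(g):
            orb = ORB(n_keypoints=500, fast_threshold=0.05)
            orb.detect_and_extract(g)
            return orb.keypoints, orb.descriptors

        kf, df = feats(gf)
        km, dm = feats(gm)
    except (RuntimeError, ValueError):
        return None
    if len(kf) < 8 or len(km) < 8:
        return None
    matches = match_descriptors(dm, df, cross_check=True)
    if len(matches) < 8:
        return None
    src = km[matches[:, 0]][:, ::-1]  # (row, col) -> (x, y)
    dst = kf[matches[:, 1]][:, ::-1]
    model, inliers = ransac(
        (src, dst), sktf.SimilarityTransform, min_samples=3, residual_threshold=2.0, max_trials=800, rng=seed
    )
    if model is None or inliers is None or int(inliers.sum()) < 8 or model.scale <= 0:
        return None
    return SimilarityTransform.from_matrix(model.params)


def estimate_pairwise(
    fixed: np.ndarray,
    moving: np.ndarray,
    min_score: float | None = None,
    upsample: int = 20,
    refine: bool = True,
) -> tuple[SimilarityTransform, float]:
    """Estimate the similarity transform mapping ``moving`` coordinates into
    the ``fixed`` frame, with an alignment score in [0, 1].

    ORB keypoint matching + RANSAC provides the initial similarity model;
    if that fails (featureless input), a log-polar Fourier estimate of
    rotation/scale plus phase-correlation translation is used instead.
    Either way a coarse-to-fine correlation maximization polishes the result
    (``refine=False`` skips the polish).  Raises :class:`AlignmentFailure`
    if the final score falls below ``min_score``.
    """
    gf = _as_gray(fixed)
    gm = _as_gray(moving)
    if gf.std() < 1e-9 or gm.std() < 1e-9:
        raise AlignmentFailure("constant-intensity raster cannot be registered", 0.0)
    h, w = gf.shape
    threshold = DEFAULT_MIN_SCORE if min_score is None else min_score

    t0 = _orb_ransac_estimate(gf, gm)
    if t0 is not None:
        t = _refine(gf, gm, t0, stages=(2,)) if refine else t0
        score = _alignment_score(fixed, moving, t)
        if score < threshold:
            raise AlignmentFailure(f"alignment score {score:.3f} below threshold {threshold:.3f}", score)
        return t, score

    # fallback: Fourier log-polar rotation/scale + phase-correlation shift.
    # band-pass + window reduce DC leakage and edge ringing in the spectra
    bf = difference_of_gaussians(gf, 1, min(h, w) * 0.25)
    bm = difference_of_gaussians(gm, 1, min(h, w) * 0.25)
    win = window("hann", gf.shape)
    radius = min(h, w) // 2
    angular, radial = 720, 400
    pf = _fft_logpolar(bf * win, radius, angular, radial)
    pm = _fft_logpolar(bm * win, radius, angular, radial)
    # Fourier magnitude is pi-periodic in angle: the upper half suffices
    shifts, _, _ = phase_cross_correlation(
        pf[: angular // 2], pm[: angular // 2], upsample_factor=upsample, normalization=None
    )
    dtheta = shifts[0] * (360.0 / angular)
    klog = radial / math.log(radius)
    scale = math.exp(shifts[1] / klog)

    center = (w / 2.0, h / 2.0)
    # rotation from Fourier magnitude is ambiguous by pi; keep the best
    # candidate of each branch, with translations tried from plain and
    # phase-normalized cross-correlation (they fail in different regimes)
    branch_best: list[tuple[float, SimilarityTransform]] = []
    for rot_deg in (dtheta, dtheta + 180.0):
        rot = math.radians(rot_deg)
        t_rs = SimilarityTransform.about_center(scale, rot, center)
        warped = sktf.warp(gm, sktf.SimilarityTransform(matrix=t_rs.inverse().matrix), order=1, cval=0.0)
        cands = []
        for norm in (None, "phase"):
            shift, _, _ = phase_cross_correlation(gf, warped, upsample_factor=upsample, normalization=norm)
            t = SimilarityTransform(
                scale=t_rs.scale,
                rotation=t_rs.rotation,
                translation=(t_rs.translation[0] + shift[1], t_rs.translation[1] + shift[0]),
            )
            cands.append((_alignment_score(fixed, moving, t), t))
        branch_best.append(max(cands, key=lambda c: c[0]))

    if refine:
        # a near-symmetric scene can make the wrong pi-branch score close to
        # the right one before refinement, so coarse-refine both branches and
        # let the refined correlation arbitrate, then polish the winner
        coarse = []
        for s0, t0 in branch_best:
            tc = _refine(gf, gm, t0, stages=(4,))
            coarse.append((_alignment_score(fixed, moving, tc), tc))
        s_c, t_c = max(coarse, key=lambda c: c[0])
        t = _refine(gf, gm, t_c, stages=(2,))
        score = max(s_c, _alignment_score(fixed, moving, t))
    else:
        score, t = max(branch_best, key=lambda c: c[0])
    if score < threshold:
        raise AlignmentFailure(f"alignment score {score:.3f} below threshold {threshold:.3f}", score)
    return t, score


@dataclass
class Montage:
    """Per-eye panorama: global transforms, pairwise residual scores, raster."""

    transforms: dict[str, SimilarityTransform]
    anchor: str
    scores: dict[tuple[str, str], float]
    excluded: list[str] = field(default_factory=list)
    panorama: np.ndarray | None = None
    panorama_origin: tuple[float, float] = (0.0, 0.0)


def compose_montage(
    rasters: dict[str, np.ndarray],
    anchor: str,
    pairwise: dict[tuple[str, str], tuple[SimilarityTransform, float]] | None = None,
    min_score: float = DEFAULT_MIN_SCORE,
    render: bool = True,
) -> Montage:
    """Chain pairwise transforms into global field->panorama transforms.

    ``pairwise[(a, b)]`` maps b-coordinates into the a-frame; if omitted, all
    unordered pairs are estimated from the rasters.  Global transforms are
    composed along the maximum-score spanning tree from the anchor (whose
    transform is the identity).  Fields unreachable in the overlap graph are
    excluded and reported in ``Montage.excluded``.
    """
    ids = list(rasters)
    if anchor not in ids:
        raise ValueError(f"anchor {anchor!r} not among rasters")
    if pairwise is None:
        pairwise = {}
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                try:
                    pairwise[(a, b)] = estimate_pairwise(rasters[a], rasters[b], min_score=min_score)
                except AlignmentFailure:
                    continue

    g = nx.Graph()
    g.add_nodes_from(ids)
    edges: dict[tuple[str, str], SimilarityTransform] = {}
    scores: dict[tuple[str, str], float] = {}
    for (a, b), (t, s) in pairwise.items():
        if s < min_score:
            continue
        g.add_edge(a, b, weight=s)
        edges[(a, b)] = t
        edges[(b, a)] = t.inverse()
        scores[(a, b)] = s

    transforms = {anchor: SimilarityTransform.identity()}
    if g.number_of_edges() > 0:
        tree = nx.maximum_spanning_tree(g, weight="weight")
        for parent, child in nx.bfs_edges(tree, anchor):
            transforms[child] = transforms[parent].compose(edges[(parent, child)])
    excluded = [i for i in ids if i not in transforms]
    if len(rasters) == 1:
        excluded = []
    if excluded and len(transforms) == 1:
        # only the anchor registered: still a valid (degraded) montage
        pass

    montage = Montage(transforms=transforms, anchor=anchor, scores=scores, excluded=excluded)
    if render:
        _render_panorama(montage, rasters)
    return montage


def _render_panorama(montage: Montage, rasters: dict[str, np.ndarray]) -> None:
    """Warp fields into panorama space, painting farthest-from-anchor first so
    the anchor wins wherever fields overlap (last-writer-wins)."""
    corners = []
    for fid, t in montage.transforms.items():
        h, w = rasters[fid].shape[:2]
        pts = np.array([[0, 0], [w, 0], [0, h], [w, h]], dtype=float)
        corners.append(t.apply(pts))
    allc = np.vstack(corners)
    x0, y0 = np.floor(allc.min(axis=0))
    x1, y1 = np.ceil(allc.max(axis=0))
    W, H = int(x1 - x0), int(y1 - y0)
    pano = np.zeros((H, W, 3), dtype=np.uint8)

    # paint order: descending distance of field center from anchor
    def dist(fid):
        h, w = rasters[fid].shape[:2]
        c = montage.transforms[fid].apply(np.array([w / 2, h / 2]))
        a = rasters[montage.anchor].shape
        ca = montage.transforms[montage.anchor].apply(np.array([a[1] / 2, a[0] / 2]))
        return float(np.hypot(*(c - ca)))

    for fid in sorted(montage.transforms, key=dist, reverse=True):
        t = montage.transforms[fid]
        M = t.matrix.copy()
        M[0, 2] -= x0
        M[1, 2] -= y0
        img = rasters[fid]
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        warped = sktf.warp(
            img.astype(float), sktf.SimilarityTransform(matrix=M).inverse, output_shape=(H, W), order=1, cval=np.nan
        )
        valid = ~np.isnan(warped[:, :, 0])
        pano[valid] = np.clip(warped[valid], 0, 255).astype(np.uint8)
    montage.panorama = pano
    montage.panorama_origin = (float(x0), float(y0))


def merge_panorama_lesions(
    lesions: list[Lesion],
    merge_radius: float = DEFAULT_MERGE_RADIUS,
    tie_break: list[float] | None = None,
) -> list[Lesion]:
    """Merge duplicate detections of the same lesion seen from several fields.

    Two panorama lesions merge when they share a type and either their
    centers are closer than ``merge_radius`` or their boxes overlap by at
    least half the smaller box's area (the overlap clause catches edge-clipped
    slivers whose centers drift).  The highest-confidence detection is kept;
    confidence ties go to the larger (least-clipped) box, then to the smaller
    ``tie_break`` value (the caller passes the distance from the lesion to
    its source field's center).  Idempotent.
    """
    if tie_break is None:
        tie_break = [0.0] * len(lesions)

    def area(l: Lesion) -> float:
        return l.bbox[2] * l.bbox[3]

    def overlaps(a: Lesion, b: Lesion) -> bool:
        ax, ay, aw, ah = a.bbox
        bx, by, bw, bh = b.bbox
        iw = min(ax + aw, bx + bw) - max(ax, bx)
        ih = min(ay + ah, by + bh) - max(ay, by)
        if iw <= 0 or ih <= 0:
            return False
        return iw * ih >= 0.5 * min(area(a), area(b))

    order = sorted(
        range(len(lesions)),
        key=lambda i: (-lesions[i].confidence, -area(lesions[i]), tie_break[i], lesions[i].field_id or ""),
    )
    remaining = [lesions[i] for i in order]
    out: list[Lesion] = []
    for l in remaining:
        dup = False
        for kept in out:
            if kept.lesion_type == l.lesion_type:
                dx = kept.center[0] - l.center[0]
                dy = kept.center[1] - l.center[1]
                if math.hypot(dx, dy) < merge_radius or overlaps(kept, l):
                    dup = True
                    break
        if not dup:
            out.append(l)
    return out


def map_lesions(
    detections: dict[str, list[Lesion]],
    montage: Montage,
    merge_radius: float = DEFAULT_MERGE_RADIUS,
) -> list[Lesion]:
    """Re-project per-field detections into panorama coordinates and merge
    duplicates from overlapping fields.

    Box corners are mapped through the field's global transform and the
    axis-aligned hull taken; the zoning anchor point is the mapped box center
    (exact under a similarity map).  Detections from fields excluded from the
    montage are dropped silently only if the field appears in
    ``montage.excluded``; an unknown field id raises.
    """
    out: list[Lesion] = []
    tie: list[float] = []
    for fid, dets in detections.items():
        if fid in montage.excluded:
            continue
        if fid not in montage.transforms:
            raise KeyError(f"field {fid!r} has no transform in the montage")
        t = montage.transforms[fid]
        for d in dets:
            bbox = project_box(d.bbox, t)
            fc = box_center(d.bbox)
            out.append(
                Lesion(
                    lesion_type=d.lesion_type,
                    bbox=bbox,
                    confidence=d.confidence,
                    field_id=fid,
                    lesion_id=d.lesion_id,
                )
            )
            # tie-break: how central the detection was in its source field
            tie.append(math.hypot(fc[0] - DEFAULT_FIELD_CENTER[0], fc[1] - DEFAULT_FIELD_CENTER[1]))
    return merge_panorama_lesions(out, merge_radius=merge_radius, tie_break=tie)
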