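"""Transparent plus-disease scoring from vessel tortuosity and dilation.

Plus disease — dilation and tortuosity of the posterior retinal vessels
within zone I — is scored from two classical features computed on vessel
centerlines of the disc-centered field:

* ``mean_tortuosity`` — mean arc/chord tortuosity index over centerlines
  (1.0 for a straight vessel);
* ``mean_width`` — mean vessel caliber in px from the distance transform.

The score is a logistic function of the standardized features with
coefficients calibrated once on a seeded synthetic set of disc-centered
fields and frozen in ``plus_calibration.json``; they are never refit at run
time.  Both calibrated coefficients are constrained non-negative, so the
score is monotone in each feature.  An image with no traceable vessels
yields an *indeterminate* result, distinct from a negative call.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from .zones import PanoramaFrame

CALIBRATION_RESOURCE = "plus_calibration.json"
CALIBRATION_SEED = 2024
MIN_CENTERLINE_PX = 20
PLUS_THRESHOLD = 0.5


@dataclass
class VesselCenterline:
    """Ordered vessel centerline with a per-point width profile (px)."""

    points: np.ndarray  # (N, 2) of (x, y)
    widths: np.ndarray  # (N,)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 2 or self.points.shape[1] != 2:
            raise ValueError("centerline needs >= 2 two-dimensional points")
        if len(self.widths) != len(self.points):
            raise ValueError("width profile must match point count")
        if (self.widths <= 0).any():
            raise ValueError("widths must be positive")
        if (np.linalg.norm(np.diff(self.points, axis=0), axis=1) == 0).any():
            raise ValueError("consecutive centerline points must be distinct")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class PlusResult:
    score: float
    plus: bool | None
    features: dict[str, float]
    indeterminate: bool = False


def tortuosity_index(centerline: VesselCenterline | np.ndarray) -> float:
    """Arc length divided by endpoint chord length; >= 1, exactly 1 when straight.

    Invariant to rigid motion and uniform scaling.  Raises on a (near-)closed
    curve whose chord vanishes.
    """
    pts = centerline.points if isinstance(centerline, VesselCenterline) else np.asarray(centerline, dtype=float)
    if len(pts) < 2:
        raise ValueError("tortuosity needs >= 2 points")
    arc = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    if chord < 1e-9:
        raise ValueError("zero chord: tortuosity undefined for a closed curve")
    return arc / chord


# ---------------------------------------------------------------------------
# centerline extraction from a disc-centered raster


def _vesselness(raster: np.ndarray) -> np.ndarray:
    """Scalar channel in which rendered vessels are bright: R - G separates
    the vessel stroke from background, disc, fovea and lesion glyphs."""
    r = raster[..., 0].astype(float)
    g = raster[..., 1].astype(float)
    return r - g


def _trace_component(coords: np.ndarray) -> np.ndarray | None:
    """Order a skeleton component's pixels along its longest path.

    Double-BFS over the 8-neighbour pixel graph: farthest node from an
    arbitrary start, then the longest shortest-path from there; side spurs
    from skeletonization fall off the main path.
    """
    index = {tuple(p): i for i, p in enumerate(coords)}
    nbrs: list[list[int]] = [[] for _ in coords]
    for i, (y, x) in enumerate(coords):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == 0 and dx == 0:
                    continue
                j = index.get((y + dy, x + dx))
                if j is not None:
                    nbrs[i].append(j)

    def bfs(start: int) -> tuple[int, dict[int, int]]:
        parent = {start: start}
        frontier = [start]
        last = start
        while frontier:
            nxt = []
            for u in frontier:
                for v in nbrs[u]:
                    if v not in parent:
                        parent[v] = u
                        nxt.append(v)
            if nxt:
                last = nxt[-1]
            frontier = nxt
        return last, parent

    a, _ = bfs(0)
    b, parent = bfs(a)
    path = [b]
    while path[-1] != a:
        path.append(parent[path[-1]])
    if len(path) < 2:
        return None
    return coords[path]


def extract_centerlines(
    raster: np.ndarray,
    disc_center: tuple[float, float] | None = None,
    disc_radius: float = 30.0,
    min_length: int = MIN_CENTERLINE_PX,
) -> list[VesselCenterline]:
    """Binarize, skeletonize and trace vessels in a disc-centered field.

    The vessel mask is thresholded (Otsu) in the R-G channel, the disc
    neighbourhood is cleared so each radiating vessel becomes one component,
    widths come from the Euclidean distance transform at skeleton points, and
    components shorter than ``min_length`` px are discarded.  Returns ``[]``
    when no vessels are found.
    """
    if raster.ndim != 3:
        raise ValueError("expected an RGB raster")
    v = _vesselness(raster)
    if v.max() - v.min() < 40:  # no vessel-like contrast at all
        return []
    mask = v > threshold_otsu(v)
    if not mask.any():
        return []
    h, w = mask.shape
    cx, cy = disc_center if disc_center is not None else (w / 2.0, h / 2.0)
    yy, xx = np.mgrid[0:h, 0:w]
    mask &= (xx - cx) ** 2 + (yy - cy) ** 2 > (disc_radius + 3.0) ** 2

    dist = ndi.distance_transform_edt(mask)
    skel = skeletonize(mask)
    labels, n = ndi.label(skel, structure=np.ones((3, 3)))
    out: list[VesselCenterline] = []
    for lab in range(1, n + 1):
        coords = np.argwhere(labels == lab)
        if len(coords) < min_length:
            continue
        path = _trace_component(coords)
        if path is None or len(path) < min_length:
            continue
        pts = path[:, ::-1].astype(float)  # (y, x) -> (x, y)
        widths = 2.0 * dist[path[:, 0], path[:, 1]]
        widths = np.maximum(widths, 0.5)
        out.append(VesselCenterline(points=pts, widths=widths))
    return out


# ---------------------------------------------------------------------------
# classification


def _load_calibration(source: str = "raster") -> dict:
    with resources.files(__package__).joinpath(CALIBRATION_RESOURCE).open() as fh:
        doc = json.load(fh)
    if source not in doc:
        raise KeyError(f"no calibration for feature source {source!r}")
    return doc[source]


def _zone1_portion(c: VesselCenterline, frame: PanoramaFrame) -> VesselCenterline | None:
    """Longest contiguous run of centerline points inside zone I."""
    d = np.linalg.norm(c.points - np.asarray(frame.disc_center), axis=1)
    inside = d <= frame.zone1_radius
    if not inside.any():
        return None
    # longest run of consecutive True
    best = (0, 0)
    start = None
    for i, flag in enumerate(np.r_[inside, False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start > best[1] - best[0]:
                best = (start, i)
            start = None
    s, e = best
    if e - s < 2:
        return None
    return VesselCenterline(points=c.points[s:e], widths=c.widths[s:e])


def plus_features(centerlines: list[VesselCenterline], frame: PanoramaFrame) -> dict[str, float] | None:
    """Tortuosity/dilation features on the zone-I portions of the centerlines."""
    torts = []
    widths = []
    for c in centerlines:
        part = _zone1_portion(c, frame)
        if part is None:
            continue
        torts.append(tortuosity_index(part))
        widths.append(float(part.widths.mean()))
    if not torts:
        return None
    return {
        "mean_tortuosity": float(np.mean(torts)),
        "max_tortuosity": float(np.max(torts)),
        "mean_width": float(np.mean(widths)),
    }


def classify_plus(
    centerlines: list[VesselCenterline],
    frame: PanoramaFrame,
    calibration: dict | None = None,
    threshold: float = PLUS_THRESHOLD,
    source: str = "raster",
) -> PlusResult:
    """Score plus disease from centerlines restricted to zone I.

    ``source`` selects the calibration matching the centerline provenance:
    ``"raster"`` for centerlines extracted from pixels (whose tortuosity and
    width carry a small skeletonization bias) or ``"centerline"`` for
    serialized analytic centerlines.  Empty or fully-peripheral centerline
    input yields an indeterminate result (``plus=None``) rather than a
    negative.
    """
    cal = calibration if calibration is not None else _load_calibration(source)
    feats = plus_features(centerlines, frame)
    if feats is None:
        return PlusResult(score=float("nan"), plus=None, features={}, indeterminate=True)
    z_t = (feats["mean_tortuosity"] - cal["mu"][0]) / cal["sigma"][0]
    z_w = (feats["mean_width"] - cal["mu"][1]) / cal["sigma"][1]
    eta = cal["intercept"] + cal["coef"][0] * z_t + cal["coef"][1] * z_w
    score = 1.0 / (1.0 + math.exp(-eta))
    return PlusResult(score=score, plus=bool(score >= threshold), features=feats)


def calibrate(seed: int = CALIBRATION_SEED, n: int = 200, source: str = "raster") -> dict:
    """Fit the logistic plus model on a balanced synthetic calibration set.

    Builds ``n`` disc-centered fields (half with the elevated plus vessel
    regime) and fits a logistic regression on the standardized
    (mean_tortuosity, mean_width) pair.  ``source="raster"`` renders the
    fields and extracts centerlines from pixels; ``source="centerline"``
    uses the generator's analytic polylines directly.  Both slopes must come
    out non-negative — the fit fails loudly otherwise.  The shipped
    ``plus_calibration.json`` holds the output of this function at the
    default seed for both sources; rerunning it reproduces the file.
    """
    from sklearn.linear_model import LogisticRegression

    from .synthetic import FieldSpec, GeneratorConfig, generate_eye, render_fields
    from .transforms import SimilarityTransform

    rows = []
    labels = []
    rng = np.random.default_rng([seed, 55])
    eye_seeds = rng.integers(0, 2**31 - 1, size=n)
    for i, s in enumerate(eye_seeds):
        want_plus = i % 2 == 1
        cfg = GeneratorConfig(plus_prevalence=1.0 if want_plus else 0.0)
        eye = generate_eye(cfg, int(s), eye_id=f"cal{i:04d}")
        if source == "raster":
            plan = [FieldSpec("f0", "disc-centered", SimilarityTransform.identity())]
            rendered = render_fields(eye, plan)
            cls = extract_centerlines(rendered.rasters["f0"], disc_center=eye.disc_center)
        elif source == "centerline":
            cls = [
                VesselCenterline(points=pts, widths=np.full(len(pts), w)) for pts, w in eye.vessel_centerlines()
            ]
        else:
            raise ValueError("source must be 'raster' or 'centerline'")
        feats = plus_features(cls, eye.frame)
        if feats is None:
            continue
        rows.append([feats["mean_tortuosity"], feats["mean_width"]])
        labels.append(int(want_plus))
    X = np.asarray(rows)
    y = np.asarray(labels)
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)
    sigma[sigma == 0] = 1.0
    model = LogisticRegression(C=1.0)
    model.fit((X - mu) / sigma, y)
    coef = model.coef_[0]
    if (coef < 0).any():
        raise RuntimeError(f"calibrated coefficients must be non-negative, got {coef}")
    acc = float(model.score((X - mu) / sigma, y))
    return {
        "mu": [float(v) for v in mu],
        "sigma": [float(v) for v in sigma],
        "coef": [float(v) for v in coef],
        "intercept": float(model.intercept_[0]),
        "seed": int(seed),
        "n": int(len(y)),
        "train_accuracy": acc,
        "features": ["mean_tortuosity", "mean_width"],
        "source": source,
    }
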