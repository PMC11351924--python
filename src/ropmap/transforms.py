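"""2-D similarity transforms (scale, rotation, translation).

The whole pipeline expresses field->panorama geometry as similarity maps

    p' = s * R(theta) @ p + t

acting on (x, y) pixel coordinates (origin top-left, x rightward, y downward,
0-based).  Boxes are half-open [x0, x1) x [y0, y1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SimilarityTransform:
    """Similarity map ``p' = scale * R(rotation) p + translation``.

    Parameters
    ----------
    scale : float
        Isotropic scale factor, > 0.
    rotation : float
        Rotation angle in radians, counter-clockwise in the (x right,
        y down) raster frame (i.e. visually clockwise on screen).
    translation : tuple of float
        (tx, ty) in pixels.
    """

    scale: float = 1.0
    rotation: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")
        object.__setattr__(self, "translation", (float(self.translation[0]), float(self.translation[1])))

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on column vectors [x, y, 1]."""
        c = self.scale * math.cos(self.rotation)
        s = self.scale * math.sin(self.rotation)
        tx, ty = self.translation
        return np.array([[c, -s, tx], [s, c, ty], [0.0, 0.0, 1.0]])

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "SimilarityTransform":
        scale = float(np.hypot(m[0, 0], m[1, 0]))
        rotation = float(math.atan2(m[1, 0], m[0, 0]))
        return cls(scale=scale, rotation=rotation, translation=(float(m[0, 2]), float(m[1, 2])))

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls()

    @classmethod
    def about_center(
        cls, scale: float, rotation: float, center: tuple[float, float], translation: tuple[float, float] = (0.0, 0.0)
    ) -> "SimilarityTransform":
        """Scale/rotate about ``center`` then translate by ``translation``."""
        cx, cy = center
        c = scale * math.cos(rotation)
        s = scale * math.sin(rotation)
        tx = cx - (c * cx - s * cy) + translation[0]
        ty = cy - (s * cx + c * cy) + translation[1]
        return cls(scale=scale, rotation=rotation, translation=(tx, ty))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (N, 2) array of (x, y) points (a single point is allowed)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix[:2, :2].T + np.asarray(self.translation)
        return out[0] if np.ndim(points) == 1 else out

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return ``self o other`` (apply ``other`` first)."""
        return SimilarityTransform.from_matrix(self.matrix @ other.matrix)

    def inverse(self) -> "SimilarityTransform":
        inv_scale = 1.0 / self.scale
        inv_rot = -self.rotation
        c = inv_scale * math.cos(inv_rot)
        s = inv_scale * math.sin(inv_rot)
        tx, ty = self.translation
        return SimilarityTransform(
            scale=inv_scale,
            rotation=inv_rot,
            translation=(-(c * tx - s * ty), -(s * tx + c * ty)),
        )

    def params(self) -> tuple[float, float, float, float]:
        """(scale, rotation_rad, tx, ty) — the serialization record."""
        return (self.scale, self.rotation, self.translation[0], self.translation[1])

    @classmethod
    def from_params(cls, params) -> "SimilarityTransform":
        s, r, tx, ty = params
        return cls(scale=float(s), rotation=float(r), translation=(float(tx), float(ty)))

    def almost_equals(self, other: "SimilarityTransform", tol: float = 1e-9) -> bool:
        return bool(np.allclose(self.matrix, other.matrix, atol=tol))


def project_box(box: tuple[float, float, float, float], transform: SimilarityTransform) -> tuple[float, float, float, float]:
    """Re-project an axis-aligned box ``(x, y, w, h)`` through a similarity map.

    The four corners are mapped and the axis-aligned hull returned.  Under a
    rotation the hull is larger than the tight rotated box — unavoidable for
    axis-aligned outputs — but the box *center* maps exactly, which is what
    zoning consumes.
    """
    x, y, w, h = box
    corners = np.array([[x, y], [x + w, y], [x, y + h], [x + w, y + h]], dtype=float)
    mapped = transform.apply(corners)
    x0, y0 = mapped.min(axis=0)
    x1, y1 = mapped.max(axis=0)
    return (float(x0), float(y0), float(x1 - x0), float(y1 - y0))


def box_center(box: tuple[float, float, float, float]) -> tuple[float, float]:
    x, y, w, h = box
    return (x + w / 2.0, y + h / 2.0)
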