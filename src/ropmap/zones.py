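"""ICROP zone geometry and the stage/zone aggregation rules.

Zones are concentric regions centered on the optic disc:

* zone I  — disk of radius twice the disc-fovea distance;
* zone II — annulus out to the disc-centered circle through the nasal ora
  serrata;
* zone III — everything beyond the zone II circle (the nasal cut-off where
  zone III does not anatomically exist is ignored — a deliberate
  simplification).

Points exactly on a boundary take the inner (more posterior, more severe)
zone, consistent with a screening posture that prefers over- to under-calling.

Eye-level stage is the type of the most severe lesion; eye-level zone follows
the most severe lesion(s), taking the most posterior zone among them when
several lesions tie on type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .types import EvidenceItem, Lesion

ZONE_ORDER = {"I": 0, "II": 1, "III": 2}


@dataclass(frozen=True)
class PanoramaFrame:
    """Per-eye coordinate frame defining zone geometry.

    All coordinates are panorama pixels.  ``nasal_unit`` points from the disc
    toward the nose (+x for a right eye OD, -x for a left eye OS); the fovea
    lies temporal to the disc, i.e. opposite ``nasal_unit``.
    """

    disc_center: tuple[float, float]
    fovea_center: tuple[float, float]
    ora_radius_nasal: float
    laterality: str  # "OD" | "OS"
    nasal_unit: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"laterality must be OD or OS, got {self.laterality!r}")
        d = self.disc_fovea_distance
        if not d > 0:
            raise ValueError("disc-fovea distance must be > 0")
        if not self.ora_radius_nasal > 2 * d:
            raise ValueError(
                f"ora_radius_nasal ({self.ora_radius_nasal}) must exceed twice the "
                f"disc-fovea distance ({d}): zone II must strictly contain zone I"
            )
        nu = self.nasal_unit
        if nu is None:
            nu = (1.0, 0.0) if self.laterality == "OD" else (-1.0, 0.0)
            object.__setattr__(self, "nasal_unit", nu)
        n = math.hypot(*nu)
        object.__setattr__(self, "nasal_unit", (nu[0] / n, nu[1] / n))
        dv = (self.fovea_center[0] - self.disc_center[0], self.fovea_center[1] - self.disc_center[1])
        if dv[0] * self.nasal_unit[0] + dv[1] * self.nasal_unit[1] >= 0:
            raise ValueError("fovea must lie temporal to the disc (opposite the nasal direction)")

    @property
    def disc_fovea_distance(self) -> float:
        return math.hypot(
            self.fovea_center[0] - self.disc_center[0],
            self.fovea_center[1] - self.disc_center[1],
        )

    @property
    def zone1_radius(self) -> float:
        """Zone I radius: twice the disc-fovea distance (ICROP3 convention)."""
        return 2.0 * self.disc_fovea_distance

    def translated(self, dx: float, dy: float) -> "PanoramaFrame":
        return PanoramaFrame(
            disc_center=(self.disc_center[0] + dx, self.disc_center[1] + dy),
            fovea_center=(self.fovea_center[0] + dx, self.fovea_center[1] + dy),
            ora_radius_nasal=self.ora_radius_nasal,
            laterality=self.laterality,
            nasal_unit=self.nasal_unit,
        )


def zone_of_point(p, frame: PanoramaFrame) -> str:
    """Classify a panorama point into zone "I", "II" or "III".

    Total on the plane; boundary radii resolve inward (a point exactly on the
    zone I circle is zone I).
    """
    r = math.hypot(p[0] - frame.disc_center[0], p[1] - frame.disc_center[1])
    if r <= frame.zone1_radius:
        return "I"
    if r <= frame.ora_radius_nasal:
        return "II"
    return "III"


def eye_stage(lesions: list[Lesion]) -> int:
    """Stage of the eye: type of the most severe lesion, 0 if none."""
    if not lesions:
        return 0
    types = [l.lesion_type for l in lesions]
    bad = [t for t in types if t not in (1, 2, 3, 4)]
    if bad:
        raise ValueError(f"lesion types outside 1..4: {bad}")
    return max(types)


def eye_zone(
    lesions: list[Lesion],
    frame: PanoramaFrame,
    most_posterior_overall: bool = False,
) -> str:
    """Zone of the eye: most posterior zone among the most severe lesions.

    ``most_posterior_overall=True`` switches to the alternative reading in
    which the zone follows the most posterior lesion regardless of type
    (closer to some clinical practice); off by default.
    Returns "none" for an empty lesion list.
    """
    if not lesions:
        return "none"
    if most_posterior_overall:
        pool = lesions
    else:
        top = max(l.lesion_type for l in lesions)
        pool = [l for l in lesions if l.lesion_type == top]
    zones = [zone_of_point(l.center, frame) for l in pool]
    return min(zones, key=ZONE_ORDER.__getitem__)


def lesion_evidence(lesions: list[Lesion], frame: PanoramaFrame) -> list[EvidenceItem]:
    """Per-lesion audit records: assigned zone and radius in disc-fovea units."""
    if not lesions:
        return []
    top = max(l.lesion_type for l in lesions)
    d = frame.disc_fovea_distance
    out = []
    for l in lesions:
        c = l.center
        r = math.hypot(c[0] - frame.disc_center[0], c[1] - frame.disc_center[1])
        out.append(
            EvidenceItem(
                lesion=l,
                zone=zone_of_point(c, frame),
                r_disc_fovea_units=r / d,
                is_most_severe=(l.lesion_type == top),
            )
        )
    return out
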