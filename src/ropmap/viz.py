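"""Zone-overlay rendering — the interpretability surface of the system.

The overlay draws the three zone boundary circles over the per-eye panorama
(zone I in red, the zone II boundary in purple, the outer render bound in
green), the disc and fovea landmarks, every mapped lesion box labeled with
its type, and the assessment summary, so a clinician can audit the call at a
glance.
"""

from __future__ import annotations

import numpy as np
from PIL import Image, ImageDraw

from .registration import Montage
from .types import Assessment, Lesion
from .zones import PanoramaFrame

ZONE1_COLOR = (230, 40, 40)
ZONE2_COLOR = (170, 60, 200)
ZONE3_COLOR = (60, 200, 80)
LESION_COLOR = (255, 220, 40)
TEXT_COLOR = (255, 255, 255)


def render_zone_overlay(
    montage: Montage,
    frame: PanoramaFrame,
    lesions: list[Lesion],
    assessment: Assessment,
) -> Image.Image:
    """Annotated panorama with zone circles, landmarks, lesions and summary."""
    if montage.panorama is None:
        raise ValueError("montage has no rendered panorama")
    ox, oy = montage.panorama_origin
    img = Image.fromarray(np.ascontiguousarray(montage.panorama))
    draw = ImageDraw.Draw(img)

    def circle(center, radius, color, width=3):
        x, y = center[0] - ox, center[1] - oy
        draw.ellipse([x - radius, y - radius, x + radius, y + radius], outline=color, width=width)

    # increasing radii: zone I, zone II boundary, outer render bound
    circle(frame.disc_center, frame.zone1_radius, ZONE1_COLOR)
    circle(frame.disc_center, frame.ora_radius_nasal, ZONE2_COLOR)
    circle(frame.disc_center, 1.12 * frame.ora_radius_nasal, ZONE3_COLOR)

    circle(frame.disc_center, 6, TEXT_COLOR, width=2)
    fx, fy = frame.fovea_center[0] - ox, frame.fovea_center[1] - oy
    draw.line([fx - 6, fy, fx + 6, fy], fill=TEXT_COLOR, width=2)
    draw.line([fx, fy - 6, fx, fy + 6], fill=TEXT_COLOR, width=2)

    for l in lesions:
        x, y, w, h = l.bbox
        draw.rectangle([x - ox, y - oy, x - ox + w, y - oy + h], outline=LESION_COLOR, width=2)
        draw.text((x - ox + 2, y - oy - 12), f"S{l.lesion_type}", fill=LESION_COLOR)

    lines = [
        f"stage {assessment.stage}  zone {assessment.zone}  plus {assessment.plus}",
        f"severity: {assessment.severity} (rule: {assessment.rule_fired})",
    ]
    if assessment.flags:
        lines.append("flags: " + ", ".join(assessment.flags))
    for i, text in enumerate(lines):
        draw.text((8, 8 + 14 * i), text, fill=TEXT_COLOR)
    return img
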