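"""Core record types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

LESION_TYPE_NAMES = {
    1: "demarcation line",
    2: "ridge",
    3: "ridge with extraretinal fibrovascular proliferation",
    4: "subtotal retinal detachment",
}


@dataclass
class Lesion:
    """A typed, localized detection — the atom of staging and zoning.

    ``bbox`` is (x, y, w, h) in the coordinate frame named by ``frame``
    ("field" with a ``field_id``, or "panorama" after re-projection).
    ``lesion_type`` 1-4 maps onto ROP stages I-IV (see LESION_TYPE_NAMES).
    """

    lesion_type: int
    bbox: tuple[float, float, float, float]
    confidence: float = 1.0
    field_id: str | None = None
    lesion_id: int | None = None

    def __post_init__(self) -> None:
        if self.lesion_type not in (1, 2, 3, 4):
            raise ValueError(f"lesion_type must be in 1..4, got {self.lesion_type}")

    @property
    def center(self) -> tuple[float, float]:
        x, y, w, h = self.bbox
        return (x + w / 2.0, y + h / 2.0)


@dataclass
class EvidenceItem:
    """One lesion's contribution to an eye-level call, for the audit trail."""

    lesion: Lesion
    zone: str
    r_disc_fovea_units: float
    is_most_severe: bool


@dataclass
class Assessment:
    """Per-eye (stage, zone, plus, severity) with its evidence trail."""

    stage: int
    zone: str  # "I", "II", "III", or "none"
    plus: bool
    severity: str  # "severe" | "not_severe"
    rule_fired: str
    severity_score: float
    plus_score: float
    plus_indeterminate: bool = False
    flags: list[str] = field(default_factory=list)
    evidence: list[EvidenceItem] = field(default_factory=list)
    degraded: bool = False
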