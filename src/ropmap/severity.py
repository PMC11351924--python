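"""ETROP-style severity integration: (stage, zone, plus) -> severe / not severe.

An eye is called severe (treatment-requiring, high-risk) when any of these
fire, in order:

1. ``zone_I_any``         — any staged lesion in zone I;
2. ``zone_II_stage2_plus`` — stage 2 in zone II with plus disease;
3. ``zone_II_stage3``     — stage 3 in zone II (plus or not);
4. ``stage_4``            — stage 4 anywhere.

Everything else is not severe.  Stage 5 is outside the rule set (eyes that
advanced are treated immediately, not screened) and raises.  Plus disease
with stage 0 has no rule — such eyes are not severe but are flagged upstream
in the evidence trail so the finding stays clinically visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

VALID_ZONES = ("I", "II", "III", "none")

RULE_NAMES = ("zone_I_any", "zone_II_stage2_plus", "zone_II_stage3", "stage_4", "none")


@dataclass(frozen=True)
class SeverityInput:
    stage: int
    zone: str
    plus: bool

    def __post_init__(self) -> None:
        if self.stage == 5:
            raise ValueError("stage 5 is outside the screening rule set (treated immediately, not graded)")
        if self.stage not in (0, 1, 2, 3, 4):
            raise ValueError(f"stage must be in 0..4, got {self.stage}")
        if self.zone not in VALID_ZONES:
            raise ValueError(f"zone must be one of {VALID_ZONES}, got {self.zone!r}")
        if (self.stage == 0) != (self.zone == "none"):
            raise ValueError(f"stage 0 iff zone 'none' violated: stage={self.stage}, zone={self.zone!r}")


@dataclass(frozen=True)
class SeverityCall:
    severity: str  # "severe" | "not_severe"
    rule_fired: str


def classify(inp: SeverityInput) -> SeverityCall:
    """Apply the severity rules; the first matching rule is reported."""
    if inp.zone == "I" and inp.stage >= 1:
        return SeverityCall("severe", "zone_I_any")
    if inp.zone == "II" and inp.stage == 2 and inp.plus:
        return SeverityCall("severe", "zone_II_stage2_plus")
    if inp.zone == "II" and inp.stage == 3:
        return SeverityCall("severe", "zone_II_stage3")
    if inp.stage == 4:
        return SeverityCall("severe", "stage_4")
    return SeverityCall("not_severe", "none")


def valid_inputs() -> list[SeverityInput]:
    """All 26 valid (stage, zone, plus) combinations."""
    out = [SeverityInput(0, "none", plus) for plus in (False, True)]
    for stage in (1, 2, 3, 4):
        for zone in ("I", "II", "III"):
            for plus in (False, True):
                out.append(SeverityInput(stage, zone, plus))
    return out


def rule_table() -> pd.DataFrame:
    """Exhaustive rule table over all 26 valid combinations.

    Columns: stage, zone, plus, severity, rule_fired.  Exportable as CSV for
    clinician review.
    """
    rows = []
    for inp in valid_inputs():
        call = classify(inp)
        rows.append(
            {"stage": inp.stage, "zone": inp.zone, "plus": inp.plus, "severity": call.severity, "rule_fired": call.rule_fired}
        )
    return pd.DataFrame(rows)
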