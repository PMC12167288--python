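"""The two depth-prediction rules.

1. ``jes_predicted_depth`` — the JES type-B microvessel class read as a
   depth prediction: B1 → EP/LPM, B2 → MM/SM1, B3 → SM2-or-deeper.
2. ``np_risk`` — the combined NBI-ME + FDG-PET rule ("N-P category"):
   B1 is low-risk and B3 high-risk regardless of SUVmax; the ambiguous B2
   class is resolved by PET, high-risk iff SUVmax ≥ cutoff (default 2.4,
   boundary inclusive).

High-risk predicts deep (SM2/SM3) invasion, i.e. a lesion for which
endoscopic resection alone is unlikely to be curative.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

from .cohort import BType, DepthGroup3, LesionRecord
from .errors import UnclassifiableLesionError, ValidationError

__all__ = ["NPRuleConfig", "NPRisk", "jes_predicted_depth", "np_risk", "classify_cohort"]


class NPRisk(enum.Enum):
    low = "low"
    high = "high"


@dataclass(frozen=True)
class NPRuleConfig:
    """Configuration of the combined rule.

    suv_cutoff : SUV units, > 0.  Lesions of type B2 with SUVmax at or above
    the cutoff are high-risk.
    """

    suv_cutoff: float = 2.4

    def __post_init__(self):
        if not self.suv_cutoff > 0:
            raise ValidationError(f"suv_cutoff must be > 0, got {self.suv_cutoff}")


_JES_DEPTH = {
    BType.B1: DepthGroup3.EP_LPM,
    BType.B2: DepthGroup3.MM_SM1,
    BType.B3: DepthGroup3.SM2_SM3,
}


def jes_predicted_depth(b_type: BType) -> DepthGroup3:
    """Depth group predicted by the type-B vessel class alone."""
    return _JES_DEPTH[BType(b_type)]


def np_risk(
    b_type: BType,
    suv_max: float | None,
    config: NPRuleConfig = NPRuleConfig(),
) -> NPRisk:
    """Combined N-P risk label for one lesion.

    PET is consulted only for type B2; B1 (low) and B3 (high) are
    classifiable with any, or no, SUVmax.  A B2 lesion without a measured
    SUVmax is unclassifiable.
    """
    b_type = BType(b_type)
    if b_type is BType.B1:
        return NPRisk.low
    if b_type is BType.B3:
        return NPRisk.high
    if suv_max is None:
        raise UnclassifiableLesionError(
            "type B2 lesion without SUVmax: the combined rule requires PET for B2"
        )
    return NPRisk.high if suv_max >= config.suv_cutoff else NPRisk.low


def classify_cohort(
    records: Sequence[LesionRecord],
    config: NPRuleConfig = NPRuleConfig(),
) -> tuple[dict[str, NPRisk], list[LesionRecord]]:
    """Apply :func:`np_risk` to every lesion.

    Returns (lesion_id → risk, unclassifiable lesions).  Unclassifiable
    lesions (B2 with missing SUV) are reported, not silently dropped.
    """
    risks: dict[str, NPRisk] = {}
    unclassifiable: list[LesionRecord] = []
    for r in records:
        try:
            risks[r.lesion_id] = np_risk(r.b_type, r.suv_max, config)
        except UnclassifiableLesionError:
            unclassifiable.append(r)
    return risks, unclassifiable
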