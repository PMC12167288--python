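"""Published summary counts of the reference cohort, and a synthetic
per-lesion reconstruction consistent with them.

The reference study (137 superficial ESCC lesions, single centre) released
only aggregate tables, not per-lesion data.  This module embeds those
aggregates — the 3×3 B-type × depth-group cross-table, the PET 2×2 at
SUVmax cutoff 2.4, the combined-rule (N-P) 2×2, and the elevated-morphology
counts — and builds a synthetic 137-lesion cohort whose margins reproduce
all of them simultaneously.

The reconstruction is deterministic.  Within the published margins the
per-lesion assignment of SUV positivity, morphology and treatment is
*synthetic*: SUVmax is 2.4 for test-positive and 0.0 for test-negative
lesions, the joint allocation of high-SUV lesions across B-type cells is
the unique one implied by the N-P 2×2 for B2/B3 and an arbitrary (fixed)
choice elsewhere, and morphology is spread over lesions by a fixed
pseudo-random draw.  Every aggregate the pipeline evaluates is exact; any
finer joint structure is not data.
"""

from __future__ import annotations

import numpy as np

from .cohort import BType, Depth6, DepthGroup3, LesionRecord, Treatment
from .stats import ContingencyTable2x2, MultiClassTable

__all__ = [
    "BTYPE_DEPTH_TABLE",
    "PET_TABLE",
    "NP_TABLE",
    "ELEVATED_COUNTS",
    "SUV_CUTOFF",
    "reconstruct_study_cohort",
]

#: B-type (rows B1, B2, B3) × depth group (columns EP/LPM, MM/SM1, SM2/SM3).
BTYPE_DEPTH_TABLE = MultiClassTable(counts=((49, 6, 1), (8, 19, 30), (0, 2, 22)))

#: SUVmax ≥ 2.4 as predictor of deep (SM2/SM3) invasion.
PET_TABLE = ContingencyTable2x2(tp=42, fp=26, fn=11, tn=58)

#: N-P high-risk as predictor of deep invasion.
NP_TABLE = ContingencyTable2x2(tp=44, fp=9, fn=9, tn=75)

#: elevated-morphology lesions among (shallow of 84, deep of 53).
ELEVATED_COUNTS = {"shallow": (14, 84), "deep": (36, 53)}

#: the clinically derived SUVmax cutoff.
SUV_CUTOFF = 2.4

# High-SUV lesions per (B-type, depth-group) cell.  For B2 and B3 the deep
# counts are forced by the N-P 2×2 (44 high&deep = 22 B3 + 22 high-SUV B2);
# the remaining allocation within each margin is an arbitrary deterministic
# choice.  Row/column layout matches BTYPE_DEPTH_TABLE.
_SUV_HIGH_PER_CELL = (
    (11, 6, 0),  # B1: 17 of the 19 non-B2 shallow exceedances, none deep
    (0, 7, 22),  # B2: 7 shallow (completing 9 high-risk shallow), 22 deep
    (0, 2, 20),  # B3: remaining 2 shallow + 20 deep exceedances
)

_SUB_DEPTH = {
    DepthGroup3.EP_LPM: Depth6.LPM,
    DepthGroup3.MM_SM1: Depth6.MM,
    DepthGroup3.SM2_SM3: Depth6.SM2,
}


def reconstruct_study_cohort() -> list[LesionRecord]:
    """Deterministic 137-lesion synthetic cohort matching the published
    aggregates (see module docstring for what is and is not data)."""
    counts = BTYPE_DEPTH_TABLE.as_array()
    records: list[LesionRecord] = []
    k = 0
    for bi, b_type in enumerate(BType):
        for gi, group in enumerate(DepthGroup3):
            n_cell = int(counts[bi, gi])
            n_high = _SUV_HIGH_PER_CELL[bi][gi]
            for j in range(n_cell):
                k += 1
                records.append(
                    LesionRecord(
                        lesion_id=f"R{k:03d}",
                        b_type=b_type,
                        depth=_SUB_DEPTH[group],
                        suv_max=SUV_CUTOFF if j < n_high else 0.0,
                    )
                )

    # morphology: exact published counts, spread by a fixed pseudo-random
    # draw so neither risk stratum is forced to a single morphology
    rng = np.random.default_rng(20160123)
    deep_idx = [i for i, r in enumerate(records) if r.deep]
    shallow_idx = [i for i, r in enumerate(records) if not r.deep]
    elevated = set(rng.choice(deep_idx, size=ELEVATED_COUNTS["deep"][0], replace=False))
    elevated |= set(rng.choice(shallow_idx, size=ELEVATED_COUNTS["shallow"][0], replace=False))

    # treatment: 40 surgical lesions assigned among the deep, the rest ER
    surgery = set(deep_idx[:40])

    out = []
    for i, r in enumerate(records):
        is_elev = i in elevated
        out.append(
            LesionRecord(
                lesion_id=r.lesion_id,
                b_type=r.b_type,
                depth=r.depth,
                suv_max=r.suv_max,
                macro_type="0-IIa" if is_elev else "0-IIc",
                elevated=is_elev,
                treatment=Treatment.surgery if i in surgery else Treatment.ER,
            )
        )
    return out
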