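"""Lesion data model, validation, eligibility filtering and delimited-table I/O.

A cohort is a list of :class:`LesionRecord`, one per lesion.  The
histopathological depth of invasion uses the six-level Japanese staging
(EP, LPM, MM, SM1, SM2, SM3), collapsed for analysis into three groups —
EP/LPM, MM/SM1, SM2/SM3 — matching the three depth classes that the JES
type-B microvessel classification predicts.  The clinically decisive
dichotomy is "deep" (SM2/SM3, submucosal invasion > 200 µm) versus
everything shallower, because deep invasion contraindicates endoscopic
resection.
"""

from __future__ import annotations

import csv
import enum
import json
from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

from .errors import ValidationError

__all__ = [
    "Depth6",
    "DepthGroup3",
    "Morphology",
    "BType",
    "Treatment",
    "LesionRecord",
    "CohortSummary",
    "read_cohort",
    "write_cohort",
    "apply_eligibility",
    "group_depth",
    "is_deep",
    "classify_morphology",
    "compute_suv",
    "summarize_cohort",
]


class Depth6(enum.IntEnum):
    """Six-level histopathological depth, ordered shallow to deep."""

    EP = 0
    LPM = 1
    MM = 2
    SM1 = 3
    SM2 = 4
    SM3 = 5


class DepthGroup3(enum.IntEnum):
    """Three-level depth grouping used throughout the analysis."""

    EP_LPM = 0
    MM_SM1 = 1
    SM2_SM3 = 2


class BType(enum.IntEnum):
    """JES type-B intratumoral microvessel class from magnifying NBI."""

    B1 = 0
    B2 = 1
    B3 = 2


class Morphology(enum.Enum):
    elevated = "elevated"
    non_elevated = "non_elevated"


class Treatment(enum.Enum):
    ER = "ER"
    surgery = "surgery"


#: Macroscopic types counted as elevated under the Japanese Classification.
_ELEVATED_MACRO_TYPES = frozenset({"0-IIa", "0-Is"})

_DEPTH_TO_GROUP = {
    Depth6.EP: DepthGroup3.EP_LPM,
    Depth6.LPM: DepthGroup3.EP_LPM,
    Depth6.MM: DepthGroup3.MM_SM1,
    Depth6.SM1: DepthGroup3.MM_SM1,
    Depth6.SM2: DepthGroup3.SM2_SM3,
    Depth6.SM3: DepthGroup3.SM2_SM3,
}


def group_depth(depth: Depth6) -> DepthGroup3:
    """Collapse a six-level depth code into its three-level group."""
    return _DEPTH_TO_GROUP[Depth6(depth)]


def is_deep(depth: Depth6) -> bool:
    """True for SM2/SM3 invasion (the positive class of every analysis)."""
    return group_depth(depth) == DepthGroup3.SM2_SM3


def classify_morphology(macro_type: str) -> Morphology:
    """Dichotomise a Japanese-Classification macroscopic type code.

    Exactly ``0-IIa`` and ``0-Is`` are elevated; every other code is
    non-elevated.
    """
    if not macro_type:
        raise ValidationError("macro_type must be a non-empty code string")
    if macro_type in _ELEVATED_MACRO_TYPES:
        return Morphology.elevated
    return Morphology.non_elevated


def compute_suv(tissue_conc: float, injected_dose: float, body_weight: float) -> float:
    """Body-weight standardized uptake value.

    Parameters
    ----------
    tissue_conc
        Radioactive concentration of the lesion, MBq/mL.
    injected_dose
        Injected FDG dose, MBq.
    body_weight
        Patient body weight, g.

    Returns the dimensionless SUV ``tissue_conc / (injected_dose / body_weight)``.
    """
    for name, v in (
        ("tissue_conc", tissue_conc),
        ("injected_dose", injected_dose),
        ("body_weight", body_weight),
    ):
        if not v > 0:
            raise ValidationError(f"{name} must be > 0, got {v!r}")
    return tissue_conc / (injected_dose / body_weight)


@dataclass(frozen=True)
class LesionRecord:
    """One superficial-ESCC lesion.

    ``suv_max`` is ``None`` when PET was not measured; an SUV of 0.0 means
    measured but undetectable uptake — the two are deliberately distinct.
    ``depth_over_T1b`` marks invasion beyond T1b (muscularis propria or
    deeper) and is used only by eligibility filtering.
    """

    lesion_id: str
    b_type: BType
    depth: Depth6
    suv_max: float | None = None
    macro_type: str | None = None
    elevated: bool | None = None
    treatment: Treatment | None = None
    prior_therapy: bool = False
    depth_over_T1b: bool = False
    patient_id: str | None = None

    def __post_init__(self):
        if self.suv_max is not None and not self.suv_max >= 0:
            raise ValidationError(
                f"lesion {self.lesion_id!r}: suv_max must be >= 0, got {self.suv_max}"
            )

    @property
    def depth_group(self) -> DepthGroup3:
        return group_depth(self.depth)

    @property
    def deep(self) -> bool:
        return is_deep(self.depth)


# ---------------------------------------------------------------------------
# Delimited-table I/O

_REQUIRED_COLUMNS = ("lesion_id", "b_type", "depth")
_ALL_COLUMNS = (
    "lesion_id",
    "b_type",
    "suv_max",
    "depth",
    "macro_type",
    "elevated",
    "treatment",
    "prior_therapy",
    "depth_over_T1b",
    "patient_id",
)

_TRUE = {"1", "true", "True", "TRUE", "yes"}
_FALSE = {"0", "false", "False", "FALSE", "no", ""}


def _parse_bool(cell: str, row: int, column: str) -> bool:
    if cell in _TRUE:
        return True
    if cell in _FALSE:
        return False
    raise ValidationError(f"row {row}, column {column!r}: cannot parse boolean {cell!r}")


def _parse_enum(enum_cls, cell: str, row: int, column: str):
    try:
        return enum_cls[cell]
    except KeyError:
        valid = ", ".join(m.name for m in enum_cls)
        raise ValidationError(
            f"row {row}, column {column!r}: unknown code {cell!r} (expected one of {valid})"
        ) from None


def read_cohort(source: str | TextIO, delimiter: str = ",") -> list[LesionRecord]:
    """Read a lesion table from a path or text stream.

    The table must have a header row with at least ``lesion_id``, ``b_type``
    and ``depth``.  Empty cells are missing values: a missing ``suv_max``
    yields ``None``, never 0.  ``elevated`` may be given directly or derived
    from ``macro_type``; if both are present they must agree.  Row order is
    preserved.
    """
    if isinstance(source, str):
        with open(source, newline="", encoding="utf-8") as fh:
            return read_cohort(fh, delimiter=delimiter)

    reader = csv.DictReader(source, delimiter=delimiter)
    if reader.fieldnames is None:
        raise ValidationError("empty input: header row required")
    missing_cols = [c for c in _REQUIRED_COLUMNS if c not in reader.fieldnames]
    if missing_cols:
        raise ValidationError(f"missing required column(s): {', '.join(missing_cols)}")

    records: list[LesionRecord] = []
    for i, row in enumerate(reader, start=2):  # header is line 1
        get = lambda col: (row.get(col) or "").strip()

        b_type = _parse_enum(BType, get("b_type"), i, "b_type")
        depth = _parse_enum(Depth6, get("depth"), i, "depth")

        suv_cell = get("suv_max")
        if suv_cell == "":
            suv_max = None
        else:
            try:
                suv_max = float(suv_cell)
            except ValueError:
                raise ValidationError(
                    f"row {i}, column 'suv_max': cannot parse number {suv_cell!r}"
                ) from None
            if suv_max < 0:
                raise ValidationError(f"row {i}, column 'suv_max': negative SUV {suv_max}")

        macro_type = get("macro_type") or None
        elevated_cell = get("elevated")
        elevated: bool | None
        if elevated_cell != "":
            elevated = _parse_bool(elevated_cell, i, "elevated")
            if macro_type is not None:
                derived = classify_morphology(macro_type) is Morphology.elevated
                if derived != elevated:
                    raise ValidationError(
                        f"row {i}: elevated={elevated} inconsistent with macro_type "
                        f"{macro_type!r} ({'elevated' if derived else 'non_elevated'})"
                    )
        elif macro_type is not None:
            elevated = classify_morphology(macro_type) is Morphology.elevated
        else:
            elevated = None

        treatment_cell = get("treatment")
        treatment = (
            _parse_enum(Treatment, treatment_cell, i, "treatment")
            if treatment_cell
            else None
        )

        records.append(
            LesionRecord(
                lesion_id=get("lesion_id"),
                b_type=b_type,
                depth=depth,
                suv_max=suv_max,
                macro_type=macro_type,
                elevated=elevated,
                treatment=treatment,
                prior_therapy=_parse_bool(get("prior_therapy"), i, "prior_therapy"),
                depth_over_T1b=_parse_bool(get("depth_over_T1b"), i, "depth_over_T1b"),
                patient_id=get("patient_id") or None,
            )
        )
    return records


def _format_suv(v: float | None) -> str:
    return "" if v is None else repr(float(v))


def write_cohort(records: Iterable[LesionRecord], dest: str | TextIO, delimiter: str = ",") -> None:
    """Write a lesion table; inverse of :func:`read_cohort` for valid inputs."""
    if isinstance(dest, str):
        with open(dest, "w", newline="", encoding="utf-8") as fh:
            write_cohort(records, fh, delimiter=delimiter)
        return
    writer = csv.writer(dest, delimiter=delimiter, lineterminator="\n")
    writer.writerow(_ALL_COLUMNS)
    for r in records:
        writer.writerow(
            [
                r.lesion_id,
                r.b_type.name,
                _format_suv(r.suv_max),
                r.depth.name,
                r.macro_type or "",
                "" if r.elevated is None else str(r.elevated).lower(),
                r.treatment.value if r.treatment else "",
                str(r.prior_therapy).lower(),
                str(r.depth_over_T1b).lower(),
                r.patient_id or "",
            ]
        )


# ---------------------------------------------------------------------------
# Eligibility and summaries


@dataclass(frozen=True)
class Exclusion:
    record: LesionRecord
    reason: str


def apply_eligibility(
    records: Sequence[LesionRecord],
) -> tuple[list[LesionRecord], list[Exclusion]]:
    """Split a cohort into analysable and excluded lesions.

    Exclusion mirrors the study-entry criteria: lesions with prior
    chemo(radio)therapy and lesions whose resected specimen showed invasion
    beyond T1b.  Idempotent: the kept list passes unchanged through a second
    application.
    """
    kept: list[LesionRecord] = []
    excluded: list[Exclusion] = []
    for r in records:
        if r.prior_therapy:
            excluded.append(Exclusion(r, "prior chemotherapy or chemoradiotherapy"))
        elif r.depth_over_T1b:
            excluded.append(Exclusion(r, "invasion beyond T1b (pT2 or deeper)"))
        else:
            kept.append(r)
    return kept, excluded


@dataclass(frozen=True)
class CohortSummary:
    n_lesions: int
    n_per_depth_group: dict[str, int]
    n_elevated_per_binary_depth: dict[str, int]
    n_treated_ER: int
    n_surgery: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_lesions": self.n_lesions,
                "n_per_depth_group": self.n_per_depth_group,
                "n_elevated_per_binary_depth": self.n_elevated_per_binary_depth,
                "n_treated_ER": self.n_treated_ER,
                "n_surgery": self.n_surgery,
            },
            indent=2,
        )


def summarize_cohort(records: Sequence[LesionRecord]) -> CohortSummary:
    per_group = {g.name: 0 for g in DepthGroup3}
    elevated = {"shallow": 0, "deep": 0}
    n_er = n_surg = 0
    for r in records:
        per_group[r.depth_group.name] += 1
        if r.elevated:
            elevated["deep" if r.deep else "shallow"] += 1
        if r.treatment is Treatment.ER:
            n_er += 1
        elif r.treatment is Treatment.surgery:
            n_surg += 1
    return CohortSummary(
        n_lesions=len(records),
        n_per_depth_group=per_group,
        n_elevated_per_binary_depth=elevated,
        n_treated_ER=n_er,
        n_surgery=n_surg,
    )
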