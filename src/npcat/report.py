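"""End-to-end analysis: from a lesion cohort to the full set of result tables.

``run_full_analysis`` executes the stages in the order the evaluation is
defined: eligibility filtering → B-type × depth cross-table with per-row
one-vs-rest metrics → ROC and cutoff (derived by Youden's index or fixed)
→ PET 2×2 at the cutoff → combined N-P classification → N-P 2×2 with
Fisher's exact test, odds ratio and logistic adjustment for morphology.
All intermediate tables are retained on the report, and every metric block
is recomputable from its embedded counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from typing import Literal, Sequence

from .cohort import (
    BType,
    DepthGroup3,
    LesionRecord,
    apply_eligibility,
    summarize_cohort,
)
from .errors import SeparationError, ValidationError
from .roc import CutoffResult, RocCurve, roc_points, youden_cutoff
from .rules import NPRisk, NPRuleConfig, classify_cohort
from .stats import (
    ContingencyTable2x2,
    DiagnosticMetrics,
    EffectEstimate,
    MultiClassTable,
    confusion_table,
    dx_metrics,
    fisher_exact,
    odds_ratio,
    one_vs_rest_metrics,
)

logger = logging.getLogger("npcat")

__all__ = ["AnalysisReport", "run_full_analysis", "report_to_dict", "validate_report_dict"]

#: per-row target depth group for one-vs-rest evaluation
_ROW_TARGETS = {
    BType.B1: DepthGroup3.EP_LPM,
    BType.B2: DepthGroup3.MM_SM1,
    BType.B3: DepthGroup3.SM2_SM3,
}


@dataclass(frozen=True)
class AnalysisReport:
    n_input: int
    n_analyzed: int
    n_excluded: int
    exclusion_reasons: dict[str, int]
    cohort_summary: dict
    table1_analog: MultiClassTable
    table1_metrics: dict[str, DiagnosticMetrics]
    b3_table: ContingencyTable2x2
    b3_metrics: DiagnosticMetrics
    roc: RocCurve | None
    cutoff: CutoffResult | None
    suv_cutoff: float
    cutoff_mode: str
    pet_table: ContingencyTable2x2 | None
    pet_metrics: DiagnosticMetrics | None
    pet_n_skipped: int
    np_table: ContingencyTable2x2
    np_metrics: DiagnosticMetrics
    np_fisher_p: float
    np_odds_ratio: EffectEstimate
    np_unclassifiable: tuple[str, ...]
    effect_estimates: tuple[EffectEstimate, ...]
    provenance: dict


def _digest_records(records: Sequence[LesionRecord]) -> str:
    h = hashlib.sha256()
    for r in records:
        h.update(
            "|".join(
                [
                    r.lesion_id,
                    r.b_type.name,
                    "" if r.suv_max is None else repr(float(r.suv_max)),
                    r.depth.name,
                    r.macro_type or "",
                    repr(r.elevated),
                    r.treatment.value if r.treatment else "",
                ]
            ).encode()
        )
        h.update(b"\n")
    return h.hexdigest()


def run_full_analysis(
    records: Sequence[LesionRecord],
    suv_cutoff: float | Literal["derive"] = "derive",
    seed: int | None = None,
) -> AnalysisReport:
    """Run every evaluation stage on a cohort.

    ``suv_cutoff`` is either a fixed SUV value or ``"derive"``, in which
    case the Youden-optimal observed threshold of SUVmax against deep
    invasion is used.  Deriving requires at least one deep and one shallow
    lesion with measured SUV.
    """
    kept, excluded = apply_eligibility(records)
    reasons: dict[str, int] = {}
    for e in excluded:
        reasons[e.reason] = reasons.get(e.reason, 0) + 1
    logger.info("eligibility: %d in, %d kept, %d excluded", len(records), len(kept), len(excluded))
    if not kept:
        raise ValidationError("no analysable lesions after eligibility filtering")

    # --- B-type × depth cross-table and per-row one-vs-rest metrics
    table1 = MultiClassTable.from_records(kept)
    table1_metrics = {
        b.name: one_vs_rest_metrics(table1, b, _ROW_TARGETS[b]) for b in BType
    }
    b3_table, _ = confusion_table(kept, lambda r: r.b_type is BType.B3, lambda r: r.deep)
    b3_metrics = dx_metrics(b3_table)
    logger.info("b-type table: n=%d", table1.total)

    # --- ROC and cutoff over lesions with measured SUV
    scored = [r for r in kept if r.suv_max is not None]
    deep_scores = [r.suv_max for r in scored if r.deep]
    shallow_scores = [r.suv_max for r in scored if not r.deep]
    roc = cutoff = None
    if deep_scores and shallow_scores:
        roc = roc_points(deep_scores, shallow_scores, bootstrap_seed=seed or 0)
        cutoff = youden_cutoff(deep_scores, shallow_scores)
    if suv_cutoff == "derive":
        if cutoff is None:
            raise ValidationError(
                "cutoff derivation needs at least one deep and one shallow lesion with SUV"
            )
        chosen_cutoff = cutoff.threshold
        mode = "derive"
    else:
        chosen_cutoff = float(suv_cutoff)
        mode = "fixed"
    logger.info("cutoff: %s (%s)", chosen_cutoff, mode)

    # --- PET 2×2 at the cutoff (lesions without SUV skipped, counted)
    pet_table = pet_metrics = None
    pet_skipped = 0
    if scored:
        pet_table, skipped = confusion_table(
            kept,
            lambda r: None if r.suv_max is None else r.suv_max >= chosen_cutoff,
            lambda r: r.deep,
        )
        pet_skipped = len(skipped)
        pet_metrics = dx_metrics(pet_table)
        logger.info("pet 2x2: n=%d, skipped=%d", pet_table.total, pet_skipped)

    # --- combined N-P classification
    np_config = NPRuleConfig(suv_cutoff=chosen_cutoff)
    risks, unclassifiable = classify_cohort(kept, np_config)
    np_table, _ = confusion_table(
        kept,
        lambda r: (risks[r.lesion_id] is NPRisk.high) if r.lesion_id in risks else None,
        lambda r: r.deep,
    )
    np_metrics = dx_metrics(np_table)
    np_p = fisher_exact(np_table)
    np_or = odds_ratio(np_table)
    logger.info(
        "n-p category: n=%d, unclassifiable=%d", np_table.total, len(unclassifiable)
    )

    # --- logistic adjustment for morphology, where morphology is known
    effects: tuple[EffectEstimate, ...] = ()
    if any(r.elevated is not None for r in kept):
        from .stats import fit_depth_logistic

        try:
            effects = tuple(
                fit_depth_logistic(kept, covariates=("np_high", "elevated"), np_config=np_config)
            )
        except (SeparationError, ValidationError) as exc:
            logger.warning("logistic adjustment skipped: %s", exc)

    options = {"suv_cutoff": suv_cutoff, "seed": seed}
    provenance = {
        "config_hash": hashlib.sha256(
            json.dumps(options, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "input_digest": _digest_records(records),
        "seed": seed,
        "n_records": len(records),
    }
    return AnalysisReport(
        n_input=len(records),
        n_analyzed=len(kept),
        n_excluded=len(excluded),
        exclusion_reasons=reasons,
        cohort_summary=json.loads(summarize_cohort(kept).to_json()),
        table1_analog=table1,
        table1_metrics=table1_metrics,
        b3_table=b3_table,
        b3_metrics=b3_metrics,
        roc=roc,
        cutoff=cutoff,
        suv_cutoff=chosen_cutoff,
        cutoff_mode=mode,
        pet_table=pet_table,
        pet_metrics=pet_metrics,
        pet_n_skipped=pet_skipped,
        np_table=np_table,
        np_metrics=np_metrics,
        np_fisher_p=np_p,
        np_odds_ratio=np_or,
        np_unclassifiable=tuple(r.lesion_id for r in unclassifiable),
        effect_estimates=effects,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# JSON rendering and validation


def _metrics_dict(m: DiagnosticMetrics | None) -> dict | None:
    if m is None:
        return None
    d = {"n": m.n, "percent": m.as_percent_dict()}
    for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
        p = getattr(m, name)
        d[name] = (
            None
            if p is None
            else {
                "numer": p.numer,
                "denom": p.denom,
                "value": p.value,
                "ci95": [p.ci_low, p.ci_high],
            }
        )
    return d


def _table_dict(t: ContingencyTable2x2 | None) -> dict | None:
    if t is None:
        return None
    return {"tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn}


def _effect_dict(e: EffectEstimate) -> dict:
    return {
        "covariate": e.covariate,
        "odds_ratio": e.odds_ratio,
        "ci95": list(e.ci95),
        "p_value": e.p_value,
        "zero_cell_corrected": e.zero_cell_corrected,
    }


def report_to_dict(report: AnalysisReport) -> dict:
    """Render an :class:`AnalysisReport` as a JSON-serialisable dict."""
    return {
        "n_input": report.n_input,
        "n_analyzed": report.n_analyzed,
        "n_excluded": report.n_excluded,
        "exclusion_reasons": report.exclusion_reasons,
        "cohort_summary": report.cohort_summary,
        "table1": {
            "counts": [list(row) for row in report.table1_analog.counts],
            "rows": [b.name for b in BType],
            "columns": [g.name for g in DepthGroup3],
            "metrics": {k: _metrics_dict(v) for k, v in report.table1_metrics.items()},
        },
        "b3": {"table": _table_dict(report.b3_table), "metrics": _metrics_dict(report.b3_metrics)},
        "roc": None
        if report.roc is None
        else {
            "auc": report.roc.auc,
            "auc_ci95": list(report.roc.auc_ci),
            "operating_points": report.roc.to_rows(),
        },
        "cutoff": None
        if report.cutoff is None
        else {
            "threshold": report.cutoff.threshold,
            "youden_j": report.cutoff.youden_j,
            "sens_at_cutoff": report.cutoff.sens_at_cutoff,
            "spec_at_cutoff": report.cutoff.spec_at_cutoff,
        },
        "suv_cutoff": report.suv_cutoff,
        "cutoff_mode": report.cutoff_mode,
        "pet": {
            "table": _table_dict(report.pet_table),
            "metrics": _metrics_dict(report.pet_metrics),
            "n_skipped": report.pet_n_skipped,
        },
        "np_category": {
            "table": _table_dict(report.np_table),
            "metrics": _metrics_dict(report.np_metrics),
            "fisher_p": report.np_fisher_p,
            "odds_ratio": _effect_dict(report.np_odds_ratio),
            "unclassifiable": list(report.np_unclassifiable),
        },
        "effect_estimates": [_effect_dict(e) for e in report.effect_estimates],
        "provenance": report.provenance,
    }


_REQUIRED_KEYS = (
    "n_input",
    "n_analyzed",
    "table1",
    "b3",
    "suv_cutoff",
    "pet",
    "np_category",
    "provenance",
)


def validate_report_dict(d: dict) -> None:
    """Check report-dict structure and that every metric block is
    reproducible from its own embedded counts."""
    missing = [k for k in _REQUIRED_KEYS if k not in d]
    if missing:
        raise ValidationError(f"report missing keys: {missing}")
    if not d["provenance"].get("input_digest") or not d["provenance"].get("config_hash"):
        raise ValidationError("report provenance must carry input_digest and config_hash")
    for block in (d["b3"], d["pet"], d["np_category"]):
        t, m = block.get("table"), block.get("metrics")
        if t is None or m is None:
            continue
        recomputed = _metrics_dict(
            dx_metrics(ContingencyTable2x2(tp=t["tp"], fp=t["fp"], fn=t["fn"], tn=t["tn"]))
        )
        if recomputed != m:
            raise ValidationError("metric block does not match its embedded counts")
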