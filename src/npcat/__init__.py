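"""npcat — combined microvessel + FDG-PET prediction of deep submucosal
invasion in superficial esophageal squamous cell carcinoma.

The package implements the "N-P category" decision rule (JES type-B vessel
class from magnifying narrow-band imaging, with SUVmax from FDG-PET
resolving the ambiguous B2 class at a derivable cutoff), the diagnostic-
accuracy statistics used to evaluate it, ROC/Youden cutoff derivation, and
a calibrated synthetic cohort generator.
"""

from .cohort import (
    BType,
    CohortSummary,
    Depth6,
    DepthGroup3,
    LesionRecord,
    Morphology,
    Treatment,
    apply_eligibility,
    classify_morphology,
    compute_suv,
    group_depth,
    is_deep,
    read_cohort,
    summarize_cohort,
    write_cohort,
)
from .errors import NpcatError, SeparationError, UnclassifiableLesionError, ValidationError
from .roc import CutoffResult, RocCurve, c_statistic, roc_points, youden_cutoff
from .report import AnalysisReport, report_to_dict, run_full_analysis, validate_report_dict
from .rules import NPRisk, NPRuleConfig, classify_cohort, jes_predicted_depth, np_risk
from .simulate import SyntheticCohortConfig, default_study_config, generate_cohort
from .stats import (
    ContingencyTable2x2,
    DiagnosticMetrics,
    EffectEstimate,
    MultiClassTable,
    confusion_table,
    dx_metrics,
    fisher_exact,
    fit_depth_logistic,
    odds_ratio,
    one_vs_rest_metrics,
    rank_sum_compare,
)

__version__ = "0.1.0"

__all__ = [name for name in dir() if not name.startswith("_")]
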