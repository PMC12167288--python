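"""Contingency-table diagnostic statistics, exact tests, and logistic adjustment.

Covers everything the evaluation of a binary depth predictor needs:

* 2×2 confusion tables and the five standard diagnostic metrics
  (sensitivity, specificity, PPV, NPV, accuracy) with Clopper–Pearson exact
  binomial 95% confidence intervals;
* one-vs-rest collapse of the 3×3 B-type × depth-group table, reproducing
  the per-row performance blocks of the clinical result tables;
* Fisher's exact two-sided test and the cross-product odds ratio with a
  Wald log-scale CI (Haldane–Anscombe 0.5 correction for zero cells);
* Mann–Whitney rank-sum comparison of SUVmax distributions, exact by full
  permutation enumeration for small samples, tie-corrected normal
  approximation otherwise;
* a logistic model of deep invasion on binary covariates, reported as
  adjusted odds ratios.

Percentages are rounded half-up to one decimal wherever a table analog is
rendered, matching clinical reporting convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

from .cohort import BType, DepthGroup3, LesionRecord
from .errors import SeparationError, ValidationError

__all__ = [
    "ContingencyTable2x2",
    "Proportion",
    "DiagnosticMetrics",
    "MultiClassTable",
    "EffectEstimate",
    "RankSumResult",
    "percent",
    "confusion_table",
    "dx_metrics",
    "one_vs_rest_metrics",
    "fisher_exact",
    "odds_ratio",
    "rank_sum_compare",
    "fit_depth_logistic",
]


def percent(fraction: float) -> float:
    """Render a fraction as a percentage rounded to one decimal.

    Rounding is half-even (banker's), the convention of R-based clinical
    statistics software; e.g. 73/80 renders as 91.2, not 91.3.
    """
    return float((Decimal(repr(fraction)) * 100).quantize(Decimal("0.1"), ROUND_HALF_EVEN))


# ---------------------------------------------------------------------------
# 2x2 tables and diagnostic metrics


@dataclass(frozen=True)
class ContingencyTable2x2:
    """TP/FP/FN/TN counts of a binary predictor against binary truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fp], [self.fn, self.tn]], dtype=int)


@dataclass(frozen=True)
class Proportion:
    """A ratio estimate with its exact binomial 95% CI."""

    numer: int
    denom: int
    value: float
    ci_low: float
    ci_high: float

    @property
    def as_percent(self) -> float:
        return percent(self.value)


def _clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    alpha = 1 - level
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def _proportion(k: int, n: int) -> Proportion | None:
    if n == 0:
        return None
    lo, hi = _clopper_pearson(k, n)
    return Proportion(numer=k, denom=n, value=k / n, ci_low=lo, ci_high=hi)


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sens/spec/PPV/NPV/accuracy for one predictor; None where undefined."""

    sensitivity: Proportion | None
    specificity: Proportion | None
    ppv: Proportion | None
    npv: Proportion | None
    accuracy: Proportion | None
    n: int

    def as_percent_dict(self) -> dict[str, float | None]:
        return {
            name: (None if p is None else p.as_percent)
            for name, p in [
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
                ("ppv", self.ppv),
                ("npv", self.npv),
                ("accuracy", self.accuracy),
            ]
        }


def confusion_table(
    records: Sequence[LesionRecord],
    predictor: Callable[[LesionRecord], bool | None],
    truth: Callable[[LesionRecord], bool | None],
) -> tuple[ContingencyTable2x2, list[tuple[LesionRecord, str]]]:
    """Cross-classify a cohort by a predictor and a truth callable.

    Either callable may return None (or raise) to mark a record it cannot
    classify; such records are skipped and reported with the reason.
    """
    tp = fp = fn = tn = 0
    skipped: list[tuple[LesionRecord, str]] = []
    for r in records:
        try:
            p = predictor(r)
        except Exception as exc:  # noqa: BLE001 - reason is reported, not hidden
            skipped.append((r, f"predictor: {exc}"))
            continue
        try:
            t = truth(r)
        except Exception as exc:  # noqa: BLE001
            skipped.append((r, f"truth: {exc}"))
            continue
        if p is None:
            skipped.append((r, "predictor undefined"))
        elif t is None:
            skipped.append((r, "truth undefined"))
        elif p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return ContingencyTable2x2(tp=tp, fp=fp, fn=fn, tn=tn), skipped


def dx_metrics(table: ContingencyTable2x2) -> DiagnosticMetrics:
    """The five standard metrics; a metric with zero denominator is None."""
    n = table.total
    return DiagnosticMetrics(
        sensitivity=_proportion(table.tp, table.tp + table.fn),
        specificity=_proportion(table.tn, table.tn + table.fp),
        ppv=_proportion(table.tp, table.tp + table.fp),
        npv=_proportion(table.tn, table.tn + table.fn),
        accuracy=_proportion(table.tp + table.tn, n),
        n=n,
    )


# ---------------------------------------------------------------------------
# 3x3 B-type x depth-group table


@dataclass(frozen=True)
class MultiClassTable:
    """3×3 counts: rows = B-type (B1,B2,B3), columns = depth group."""

    counts: tuple[tuple[int, int, int], ...]

    def __post_init__(self):
        arr = np.asarray(self.counts)
        if arr.shape != (3, 3) or (arr < 0).any():
            raise ValidationError("counts must be a 3×3 array of non-negative integers")

    @classmethod
    def from_records(cls, records: Sequence[LesionRecord]) -> "MultiClassTable":
        arr = np.zeros((3, 3), dtype=int)
        for r in records:
            arr[int(r.b_type), int(r.depth_group)] += 1
        return cls(counts=tuple(tuple(int(x) for x in row) for row in arr))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)

    @property
    def total(self) -> int:
        return int(self.as_array().sum())


def one_vs_rest_metrics(
    table: MultiClassTable, b_class: BType, target_group: DepthGroup3
) -> DiagnosticMetrics:
    """Collapse one row of the 3×3 table into a 2×2 and compute metrics.

    Predictor positive = the lesion's B-type equals ``b_class``; truth
    positive = its depth group equals ``target_group``.  Every lesion of
    the table enters the 2×2 exactly once.
    """
    arr = table.as_array()
    i, j = int(BType(b_class)), int(DepthGroup3(target_group))
    tp = int(arr[i, j])
    fp = int(arr[i].sum() - tp)
    fn = int(arr[:, j].sum() - tp)
    tn = int(arr.sum() - tp - fp - fn)
    return dx_metrics(ContingencyTable2x2(tp=tp, fp=fp, fn=fn, tn=tn))


# ---------------------------------------------------------------------------
# Exact tests and effect estimates


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of
    all tables with the observed margins whose probability does not exceed
    the observed table's (within relative tolerance 1e−7).

    A table with a zero margin carries no information; p = 1 by convention.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 1.0
    return float(sps.fisher_exact(arr, alternative="two-sided").pvalue)


@dataclass(frozen=True)
class EffectEstimate:
    """An odds ratio with Wald 95% CI and p-value."""

    odds_ratio: float
    ci95: tuple[float, float]
    p_value: float
    covariate: str | None = None
    zero_cell_corrected: bool = False


def odds_ratio(table: ContingencyTable2x2) -> EffectEstimate:
    """Cross-product OR with Wald log-scale 95% CI.

    When any cell is zero, all four cells get the Haldane–Anscombe +0.5
    correction and the estimate is flagged as corrected.
    """
    a, b, c, d = table.tp, table.fp, table.fn, table.tn
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(0.975)
    ci = (math.exp(math.log(or_) - z * se), math.exp(math.log(or_) + z * se))
    return EffectEstimate(
        odds_ratio=float(or_),
        ci95=ci,
        p_value=fisher_exact(table),
        zero_cell_corrected=corrected,
    )


# ---------------------------------------------------------------------------
# Rank-sum comparison


@dataclass(frozen=True)
class RankSumResult:
    median_a: float
    iqr_a: tuple[float, float]
    median_b: float
    iqr_b: tuple[float, float]
    u_statistic: float
    p_value: float
    method: str  # "exact" or "asymptotic"


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann–Whitney U for group a via midranks (ties count 0.5)."""
    ranks = sps.rankdata(np.concatenate([a, b]))
    return float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0)


def rank_sum_compare(
    group_a: Sequence[float], group_b: Sequence[float], exact_max_n: int = 20
) -> RankSumResult:
    """Compare two samples with the Mann–Whitney U test.

    Exact two-sided p by full enumeration of all group assignments when
    n_a + n_b ≤ ``exact_max_n`` (handles ties via midranks); tie-corrected
    normal approximation (with continuity correction) otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    u_obs = _u_statistic(a, b)
    n_a, n_b = a.size, b.size
    if n_a + n_b <= exact_max_n:
        # enumerate every way of labelling n_a of the pooled values as group a
        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)
        mu = n_a * n_b / 2.0
        dev_obs = abs(u_obs - mu)
        hits = total = 0
        for idx in combinations(range(n_a + n_b), n_a):
            u = ranks[list(idx)].sum() - n_a * (n_a + 1) / 2.0
            total += 1
            if abs(u - mu) >= dev_obs - 1e-9:
                hits += 1
        p = hits / total
        method = "exact"
    else:
        p = float(sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)
        method = "asymptotic"
    qa = np.quantile(a, [0.25, 0.5, 0.75])
    qb = np.quantile(b, [0.25, 0.5, 0.75])
    return RankSumResult(
        median_a=float(qa[1]),
        iqr_a=(float(qa[0]), float(qa[2])),
        median_b=float(qb[1]),
        iqr_b=(float(qb[0]), float(qb[2])),
        u_statistic=u_obs,
        p_value=min(1.0, p),
        method=method,
    )


# ---------------------------------------------------------------------------
# Logistic adjustment


def _covariate_value(record: LesionRecord, name: str, np_config) -> float | None:
    from .rules import NPRisk, np_risk

    if name == "np_high":
        return 1.0 if np_risk(record.b_type, record.suv_max, np_config) is NPRisk.high else 0.0
    if name == "elevated":
        return None if record.elevated is None else float(record.elevated)
    raise ValidationError(f"unknown covariate {name!r} (expected 'np_high' or 'elevated')")


def fit_depth_logistic(
    records: Sequence[LesionRecord],
    covariates: Sequence[str] = ("np_high", "elevated"),
    np_config=None,
) -> list[EffectEstimate]:
    """Logistic model of deep invasion on binary covariates.

    Maximises the binomial log-likelihood of ``is_deep`` on an intercept
    plus the requested indicator covariates (Newton iterations, |Δloglik|
    < 1e−10 or 100 iterations) and reports one adjusted odds ratio
    exp(coefficient) with Wald 95% CI per covariate.

    Records on which a covariate is undefined (B2 without SUV for
    ``np_high``; unknown morphology for ``elevated``) are dropped from the
    fit.  Complete or quasi-complete separation raises
    :class:`~npcat.errors.SeparationError` naming the covariate.
    """
    import statsmodels.api as sm

    from .rules import NPRuleConfig

    if np_config is None:
        np_config = NPRuleConfig()
    if not covariates:
        raise ValidationError("at least one covariate required")

    rows, ys = [], []
    for r in records:
        try:
            vals = [_covariate_value(r, c, np_config) for c in covariates]
        except ValidationError:
            raise
        except Exception:
            continue  # unclassifiable for some covariate
        if any(v is None for v in vals):
            continue
        rows.append(vals)
        ys.append(1.0 if r.deep else 0.0)

    X = np.asarray(rows, dtype=float)
    y = np.asarray(ys, dtype=float)
    if X.size == 0 or len(np.unique(y)) < 2:
        raise ValidationError("outcome does not vary among usable records")

    design = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, design)
    try:
        fit = model.fit(method="newton", tol=1e-10, maxiter=100, disp=0)
    except Exception:
        fit = None
    if fit is None or not np.all(np.isfinite(fit.bse)) or np.any(np.abs(fit.params[1:]) > 15):
        if fit is not None and np.all(np.isfinite(fit.params)):
            worst = int(np.argmax(np.abs(fit.params[1:])))
        else:
            worst = 0
        raise SeparationError(covariates[worst])

    z = sps.norm.ppf(0.975)
    out: list[EffectEstimate] = []
    for j, name in enumerate(covariates, start=1):
        coef, se = float(fit.params[j]), float(fit.bse[j])
        out.append(
            EffectEstimate(
                odds_ratio=math.exp(coef),
                ci95=(math.exp(coef - z * se), math.exp(coef + z * se)),
                p_value=float(fit.pvalues[j]),
                covariate=name,
            )
        )
    return out
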