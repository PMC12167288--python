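"""Contingency-table metrics, exact tests, rank-sum and logistic fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom, mannwhitneyu

from npcat.cohort import BType, Depth6, DepthGroup3, LesionRecord
from npcat.errors import SeparationError, ValidationError
from npcat.stats import (
    ContingencyTable2x2,
    MultiClassTable,
    confusion_table,
    dx_metrics,
    fisher_exact,
    fit_depth_logistic,
    odds_ratio,
    one_vs_rest_metrics,
    percent,
    rank_sum_compare,
)

TABLE1 = MultiClassTable(counts=((49, 6, 1), (8, 19, 30), (0, 2, 22)))

tables = st.builds(
    ContingencyTable2x2,
    tp=st.integers(0, 60),
    fp=st.integers(0, 60),
    fn=st.integers(0, 60),
    tn=st.integers(0, 60),
)


def enumerate_fisher(table: ContingencyTable2x2) -> float:
    """Independent oracle: full hypergeometric enumeration with fixed margins."""
    a, b, c, d = table.tp, table.fp, table.fn, table.tn
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 in (0, n) or c1 in (0, n):
        return 1.0
    support = range(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = {k: hypergeom.pmf(k, n, c1, r1) for k in support}
    p_obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7)))


class TestPercent:
    @pytest.mark.parametrize(
        "frac,expected",
        [(44 / 53, 83.0), (75 / 84, 89.3), (73 / 80, 91.2), (49 / 56, 87.5), (0.9, 90.0)],
    )
    def test_one_decimal(self, frac, expected):
        assert percent(frac) == expected


class TestDxMetrics:
    @pytest.mark.parametrize(
        "table,expected",
        [
            (  # combined-rule 2x2
                ContingencyTable2x2(tp=44, fp=9, fn=9, tn=75),
                dict(sensitivity=83.0, specificity=89.3, ppv=83.0, npv=89.3, accuracy=86.9),
            ),
            (  # B3-alone 2x2
                ContingencyTable2x2(tp=22, fp=2, fn=31, tn=82),
                dict(sensitivity=41.5, specificity=97.6, ppv=91.7, npv=72.6, accuracy=75.9),
            ),
            (
                ContingencyTable2x2(tp=1, fp=0, fn=0, tn=1),
                dict(sensitivity=100.0, specificity=100.0, ppv=100.0, npv=100.0, accuracy=100.0),
            ),
        ],
    )
    def test_reference_tables(self, table, expected):
        assert dx_metrics(table).as_percent_dict() == expected

    def test_all_zero_table_undefined(self):
        m = dx_metrics(ContingencyTable2x2(tp=0, fp=0, fn=0, tn=0))
        assert all(v is None for v in m.as_percent_dict().values())

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable2x2(tp=-1, fp=0, fn=0, tn=0)

    @given(t=tables)
    @settings(max_examples=200, deadline=None)
    def test_bayes_and_accuracy_identities(self, t):
        m = dx_metrics(t)
        n = t.total
        if n == 0 or m.sensitivity is None or m.specificity is None:
            return
        prev = (t.tp + t.fn) / n
        sens, spec = m.sensitivity.value, m.specificity.value
        assert m.accuracy.value == pytest.approx(prev * sens + (1 - prev) * spec, abs=1e-12)
        denom = prev * sens + (1 - prev) * (1 - spec)
        if m.ppv is not None and denom > 0:
            assert m.ppv.value == pytest.approx(prev * sens / denom, abs=1e-12)

    @given(t=tables)
    @settings(max_examples=100, deadline=None)
    def test_ci_brackets_estimate(self, t):
        m = dx_metrics(t)
        for p in (m.sensitivity, m.specificity, m.ppv, m.npv, m.accuracy):
            if p is not None:
                assert p.ci_low - 1e-12 <= p.value <= p.ci_high + 1e-12


class TestOneVsRest:
    def test_b1_row(self):
        m = one_vs_rest_metrics(TABLE1, BType.B1, DepthGroup3.EP_LPM)
        assert m.as_percent_dict()["accuracy"] == 89.1

    def test_b2_row(self):
        m = one_vs_rest_metrics(TABLE1, BType.B2, DepthGroup3.MM_SM1)
        d = m.as_percent_dict()
        assert d["ppv"] == 33.3 and d["accuracy"] == 66.4

    def test_pure_table_is_perfect(self):
        t = MultiClassTable(counts=((0, 0, 0), (0, 5, 0), (0, 0, 0)))
        m = one_vs_rest_metrics(t, BType.B2, DepthGroup3.MM_SM1)
        assert m.as_percent_dict()["accuracy"] == 100.0

    @given(
        counts=st.lists(st.integers(0, 30), min_size=9, max_size=9),
        b=st.sampled_from(list(BType)),
        g=st.sampled_from(list(DepthGroup3)),
    )
    @settings(max_examples=100, deadline=None)
    def test_each_lesion_used_exactly_once(self, counts, b, g):
        t = MultiClassTable(counts=tuple(tuple(counts[i * 3:(i + 1) * 3]) for i in range(3)))
        m = one_vs_rest_metrics(t, b, g)
        assert m.n == t.total


class TestConfusionTable:
    def _cohort(self):
        return [
            LesionRecord(lesion_id=f"C{i}", b_type=BType.B1, depth=d, suv_max=s)
            for i, (d, s) in enumerate(
                [(Depth6.EP, 0.0), (Depth6.SM2, 3.0), (Depth6.SM3, None), (Depth6.MM, 1.0)]
            )
        ]

    def test_empty(self):
        t, skipped = confusion_table([], lambda r: True, lambda r: True)
        assert t == ContingencyTable2x2(0, 0, 0, 0) and skipped == []

    def test_predictor_equals_truth(self):
        t, _ = confusion_table(self._cohort(), lambda r: r.deep, lambda r: r.deep)
        assert t.fp == 0 and t.fn == 0

    def test_undefined_predictor_reported(self):
        t, skipped = confusion_table(
            self._cohort(),
            lambda r: None if r.suv_max is None else r.suv_max >= 2.4,
            lambda r: r.deep,
        )
        assert t.total == 3
        assert [r.lesion_id for r, _ in skipped] == ["C2"]


class TestFisher:
    def test_derived_enumeration_value(self):
        assert fisher_exact(ContingencyTable2x2(3, 1, 1, 3)) == pytest.approx(34 / 70)

    def test_strong_association(self):
        assert fisher_exact(ContingencyTable2x2(44, 9, 9, 75)) < 0.001

    def test_zero_margin_convention(self):
        assert fisher_exact(ContingencyTable2x2(0, 0, 5, 7)) == 1.0

    @given(t=tables)
    @settings(max_examples=100, deadline=None)
    def test_invariances(self, t):
        p = fisher_exact(t)
        transposed = ContingencyTable2x2(tp=t.tp, fp=t.fn, fn=t.fp, tn=t.tn)
        swapped = ContingencyTable2x2(tp=t.tn, fp=t.fn, fn=t.fp, tn=t.tp)
        assert fisher_exact(transposed) == pytest.approx(p, rel=1e-9)
        assert fisher_exact(swapped) == pytest.approx(p, rel=1e-9)

    @given(
        t=st.builds(
            ContingencyTable2x2,
            tp=st.integers(0, 10), fp=st.integers(0, 10),
            fn=st.integers(0, 10), tn=st.integers(0, 10),
        )
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_enumeration_oracle(self, t):
        assert fisher_exact(t) == pytest.approx(enumerate_fisher(t), abs=1e-9)


class TestOddsRatio:
    def test_cross_product(self):
        e = odds_ratio(ContingencyTable2x2(44, 9, 9, 75))
        assert e.odds_ratio == pytest.approx(3300 / 81)
        assert e.ci95[0] <= e.odds_ratio <= e.ci95[1]
        assert not e.zero_cell_corrected

    def test_null(self):
        assert odds_ratio(ContingencyTable2x2(1, 1, 1, 1)).odds_ratio == pytest.approx(1.0)

    def test_zero_cell_correction(self):
        e = odds_ratio(ContingencyTable2x2(2, 0, 1, 3))
        assert e.zero_cell_corrected
        assert e.odds_ratio == pytest.approx((2.5 * 3.5) / (0.5 * 1.5))


class TestRankSum:
    def test_identical_groups(self):
        res = rank_sum_compare([1, 2, 3], [1, 2, 3])
        assert res.method == "exact" and res.p_value == pytest.approx(1.0)

    def test_small_sample_exact(self):
        res = rank_sum_compare([1, 2], [3, 4])
        assert res.p_value == pytest.approx(1 / 3)

    def test_medians_and_iqr(self):
        res = rank_sum_compare([0, 0, 0, 4], [1, 2, 3, 10])
        assert res.median_a == 0.0 and res.median_b == 2.5

    @given(
        a=st.lists(st.integers(0, 8).map(float), min_size=1, max_size=8),
        b=st.lists(st.integers(0, 8).map(float), min_size=1, max_size=8),
    )
    @settings(max_examples=100, deadline=None)
    def test_u_complement_identity(self, a, b):
        ua = rank_sum_compare(a, b).u_statistic
        ub = rank_sum_compare(b, a).u_statistic
        assert ua + ub == pytest.approx(len(a) * len(b))

    def test_large_sample_uses_asymptotic(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 30)
        res = rank_sum_compare(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert res.method == "asymptotic"
        assert res.p_value == pytest.approx(float(ref))

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            rank_sum_compare([], [1.0])


def _binary_cohort(x1, x2, y):
    """Encode covariates as records: np_high via B-type B3/B1, elevated flag."""
    return [
        LesionRecord(
            lesion_id=f"G{i}",
            b_type=BType.B3 if a else BType.B1,
            depth=Depth6.SM2 if out else Depth6.EP,
            suv_max=0.0,
            elevated=bool(b),
        )
        for i, (a, b, out) in enumerate(zip(x1, x2, y))
    ]


class TestLogistic:
    def test_single_binary_covariate_equals_crossproduct_or(self, study_cohort):
        (effect,) = fit_depth_logistic(study_cohort, covariates=("np_high",))
        from npcat.rules import NPRisk, classify_cohort

        risks, _ = classify_cohort(study_cohort)
        tab, _ = confusion_table(
            study_cohort, lambda r: risks[r.lesion_id] is NPRisk.high, lambda r: r.deep
        )
        assert effect.odds_ratio == pytest.approx(odds_ratio(tab).odds_ratio, abs=1e-6)

    def test_independent_covariate_has_unit_or(self):
        # balanced 2x2x2: outcome depends on x1 only; x2 balanced within strata
        x1, x2, y = [], [], []
        for a in (0, 1):
            for b in (0, 1):
                for out in (0, 1):
                    reps = 10 if out == a else 5
                    x1 += [a] * reps
                    x2 += [b] * reps
                    y += [out] * reps
        effects = fit_depth_logistic(_binary_cohort(x1, x2, y), covariates=("np_high", "elevated"))
        by_name = {e.covariate: e for e in effects}
        assert by_name["elevated"].odds_ratio == pytest.approx(1.0, abs=1e-6)

    def test_parameter_recovery_at_n_10000(self):
        rng = np.random.default_rng(2024)
        n = 10_000
        beta0, beta1, beta2 = -1.0, 1.5, 0.7
        x1 = rng.random(n) < 0.4
        x2 = rng.random(n) < 0.3
        logit = beta0 + beta1 * x1 + beta2 * x2
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        effects = fit_depth_logistic(_binary_cohort(x1, x2, y), covariates=("np_high", "elevated"))
        for e, beta in zip(effects, (beta1, beta2)):
            coef = math.log(e.odds_ratio)
            se = (math.log(e.ci95[1]) - math.log(e.ci95[0])) / (2 * 1.959963984540054)
            assert abs(coef - beta) < 3 * se

    def test_complete_separation_detected(self):
        x1 = [0] * 10 + [1] * 10
        x2 = [0, 1] * 10
        y = x1[:]  # outcome identical to x1
        with pytest.raises(SeparationError) as exc:
            fit_depth_logistic(_binary_cohort(x1, x2, y), covariates=("np_high", "elevated"))
        assert exc.value.covariate == "np_high"

    def test_constant_outcome_rejected(self):
        recs = _binary_cohort([0, 1, 0, 1], [0, 0, 1, 1], [1, 1, 1, 1])
        with pytest.raises(ValidationError):
            fit_depth_logistic(recs, covariates=("np_high",))
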