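import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cehkit.association import (
    AssociationResult,
    ContingencyTable2x2,
    MultiplicityContext,
    RankDeficientDesignError,
    UndefinedORError,
    adjust_pvalues,
    carrier_or,
    class1_class2_association,
    compare_or_z,
    conditional_carrier_or,
    dose_regression,
    dose_vector,
    fisher_exact_two_sided,
)
from cehkit.haplotypes import Diplotype, as_pattern
from cehkit.simulate import assign_phenotypes, build_pool, sample_diplotypes

from conftest import make_ceh


def fisher_oracle(a, b, c, d):
    """Exact two-sided Fisher p by direct enumeration with integer binomials."""
    n, r, k = a + b + c + d, a + b, a + c
    denom = math.comb(n, k)
    support = range(max(0, r + k - n), min(r, k) + 1)
    probs = {x: math.comb(r, x) * math.comb(n - r, k - x) for x in support}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs) / denom


class TestCarrierOR:
    def test_null_table(self):
        res = carrier_or(ContingencyTable2x2(50, 50, 50, 50))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_wald_interval(self):
        res = carrier_or(ContingencyTable2x2(30, 70, 10, 90))
        assert res.odds_ratio == pytest.approx(30 * 90 / (70 * 10), rel=1e-12)
        assert res.ci_low == pytest.approx(1.7666, abs=2e-3)
        assert res.ci_high == pytest.approx(8.422, abs=5e-3)

    def test_zero_cell_takes_haldane_correction_path(self):
        res = carrier_or(ContingencyTable2x2(10, 10, 0, 10))
        assert np.isfinite(res.odds_ratio)
        assert res.corrected
        assert res.odds_ratio == pytest.approx((10.5 * 10.5) / (10.5 * 0.5))

    def test_structural_zero_margin_rejected(self):
        with pytest.raises(UndefinedORError):
            carrier_or(ContingencyTable2x2(0, 0, 5, 5))

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(st.tuples(*[st.integers(1, 60)] * 4))
    def test_reciprocal_symmetry_under_label_swap(self, cells):
        a, b, c, d = cells
        res = carrier_or(ContingencyTable2x2(a, b, c, d))
        swapped = carrier_or(ContingencyTable2x2(c, d, a, b))
        assert swapped.odds_ratio == pytest.approx(1.0 / res.odds_ratio, rel=1e-9)
        assert swapped.p_value == pytest.approx(res.p_value, rel=1e-9)


class TestConditionalCarrierOR:
    @staticmethod
    def _dataset(risk_hap_rr, n, seed, freqs=(0.15, 0.45, 0.40)):
        target = make_ceh("01", "10000000000")
        other = make_ceh("02", "01000000000")
        third = make_ceh("03", "00100000000")
        pool = build_pool(haplotypes=[target, other, third], frequencies=list(freqs),
                          risk={target: risk_hap_rr} if risk_hap_rr else {})
        dips = sample_diplotypes(pool, n, seed=seed)
        y = assign_phenotypes(dips, pool, baseline_odds=0.25, seed=seed + 1)
        return target, dips, y

    def test_dose_dependent_ceh_ci_covers_programmed_value(self):
        covered = 0
        for seed in range(40):
            target, dips, y = self._dataset((3.0, 9.0), 2000, 1000 + 2 * seed)
            res = conditional_carrier_or(dips, y, target, copies=1)
            if res.ci_low <= 3.0 <= res.ci_high:
                covered += 1
        assert covered >= 33  # ~95% nominal coverage over 40 seeds

    def test_recessive_ceh_pattern(self):
        target, dips, y = self._dataset((1.0, 4.0), 30_000, 77)
        het = conditional_carrier_or(dips, y, target, copies=1)
        hom = conditional_carrier_or(dips, y, target, copies=2)
        assert het.ci_low <= 1.0 <= het.ci_high
        assert hom.ci_low <= 4.0 <= hom.ci_high

    def test_self_exclusion_leaves_target_carriers_in(self):
        target, dips, y = self._dataset((3.0, 9.0), 3000, 55)
        unconditional = conditional_carrier_or(dips, y, target, copies=1)
        self_excluded = conditional_carrier_or(
            dips, y, target, copies=1, exclusion=target
        )
        assert self_excluded.table == unconditional.table
        assert self_excluded.odds_ratio == pytest.approx(unconditional.odds_ratio)

    def test_exclusion_motif_removes_other_carriers(self):
        target = make_ceh("01", "10000000000")
        excl = make_ceh("02", "01000000000")
        neutral = make_ceh("03", "00100000000")
        pool = build_pool(haplotypes=[target, excl, neutral],
                          frequencies=[0.2, 0.3, 0.5])
        dips = sample_diplotypes(pool, 2000, seed=9)
        y = assign_phenotypes(dips, pool, seed=10)
        res = conditional_carrier_or(dips, y, target, copies=1, exclusion=excl)
        kept = [d for d in dips if excl not in (d.hap1, d.hap2)]
        n_in_table = sum(res.table.cells)
        n_expected = sum(1 for d in kept if d.copies_of(target) in (0, 1))
        assert n_in_table == n_expected

    def test_empty_stratum_rejected(self):
        target = make_ceh("01")
        other = make_ceh("02")
        dips = [Diplotype(other, other)] * 10
        y = [1, 0] * 5
        with pytest.raises(UndefinedORError):
            conditional_carrier_or(dips, y, target, copies=1)


class TestCompareORZ:
    @staticmethod
    def _result(orr, lo, hi):
        return AssociationResult("x", 1, orr, lo, hi, 0.5,
                                 ContingencyTable2x2(1, 1, 1, 1))

    def test_identical_results_give_zero(self):
        r = self._result(3.2, 3.0, 3.5)
        z, p = compare_or_z(r, r)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        z, p = compare_or_z(self._result(3.2, 3.0, 3.5), self._result(0.7, 0.3, 1.3))
        assert z == pytest.approx(4.04, abs=0.01)
        assert p < 1e-4

    def test_antisymmetric_in_arguments(self):
        r1, r2 = self._result(2.0, 1.5, 2.7), self._result(1.2, 0.9, 1.6)
        z12, p12 = compare_or_z(r1, r2)
        z21, p21 = compare_or_z(r2, r1)
        assert z12 == pytest.approx(-z21)
        assert p12 == pytest.approx(p21)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            compare_or_z(self._result(2.0, 2.0, 2.0), self._result(1.0, 0.5, 2.0))


class TestClass1Class2:
    def test_small_table_takes_fisher_path(self):
        p, method = class1_class2_association(ContingencyTable2x2(3, 1, 1, 3))
        assert method == "fisher"
        assert p == pytest.approx(34 / 70)

    def test_large_balanced_table_takes_chi_square_path(self):
        p, method = class1_class2_association(ContingencyTable2x2(100, 100, 100, 100))
        assert method == "chi-square"
        assert p == pytest.approx(1.0)

    def test_expected_cell_exactly_five_goes_to_fisher(self):
        # margins 10/90, 50/50 -> smallest expected cell = 10*50/100 = 5
        p, method = class1_class2_association(ContingencyTable2x2(5, 5, 45, 45))
        assert method == "fisher"

    def test_fisher_matches_enumeration_on_moderate_tables(self):
        for a, b, c, d in [(3, 1, 1, 3), (0, 5, 5, 0), (2, 7, 8, 3), (6, 0, 1, 9),
                           (4, 4, 4, 4), (1, 1, 10, 10)]:
            assert fisher_exact_two_sided(
                ContingencyTable2x2(a, b, c, d)
            ) == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            class1_class2_association(ContingencyTable2x2(0, 0, 0, 0))


class TestAdjustPvalues:
    def test_bonferroni_threshold_for_146_tests(self):
        ctx = MultiplicityContext(m=146, method="bonferroni", alpha=0.05)
        out = adjust_pvalues([0.0001, 0.01], ctx)
        assert out.threshold == pytest.approx(0.05 / 146)
        assert round(out.threshold, 4) == 0.0003
        assert list(out.significant) == [True, False]

    def test_bh_step_up_hand_example(self):
        ctx = MultiplicityContext(m=4, method="benjamini-hochberg")
        out = adjust_pvalues([0.01, 0.02, 0.03, 0.04], ctx)
        assert np.allclose(out.adjusted, 0.04)

    def test_single_p_unchanged_under_bh(self):
        ctx = MultiplicityContext(m=1, method="benjamini-hochberg")
        out = adjust_pvalues([0.123], ctx)
        assert out.adjusted[0] == pytest.approx(0.123)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
    def test_bh_adjusted_at_least_raw_and_rank_monotone(self, pvals):
        ctx = MultiplicityContext(m=len(pvals), method="benjamini-hochberg")
        out = adjust_pvalues(pvals, ctx)
        assert np.all(out.adjusted >= out.raw - 1e-12)
        order = np.argsort(out.raw)
        assert np.all(np.diff(out.adjusted[order]) >= -1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([], MultiplicityContext(m=1))


class TestDoseRegression:
    @staticmethod
    def _sim(rr1, n, seed, baseline=0.25):
        target = make_ceh("01", "10000000000")
        other = make_ceh("02", "01000000000")
        pool = build_pool(haplotypes=[target, other], frequencies=[0.3, 0.7],
                          risk={target: (rr1, rr1**2)})
        dips = sample_diplotypes(pool, n, seed=seed)
        y = assign_phenotypes(dips, pool, baseline_odds=baseline, seed=seed + 1)
        return pd.DataFrame({"dose": dose_vector(dips, target)}), y

    def test_null_coverage_of_zero_coefficient(self):
        covered = 0
        for seed in range(30):
            X, y = self._sim(1.0, 1200, 4000 + 2 * seed)
            fit = dose_regression(y, X)
            lo = fit.loc["dose", "coef"] - 1.96 * fit.loc["dose", "se"]
            hi = fit.loc["dose", "coef"] + 1.96 * fit.loc["dose", "se"]
            if lo <= 0.0 <= hi:
                covered += 1
        assert covered >= 25  # ~95% nominal over 30 seeds

    def test_programmed_per_copy_log_or_recovered(self):
        X, y = self._sim(3.0, 6000, 991)
        fit = dose_regression(y, X)
        assert fit.loc["dose", "ci_low"] <= 3.0 <= fit.loc["dose", "ci_high"]

    def test_constant_covariates_are_no_ops(self):
        X, y = self._sim(2.0, 1500, 31)
        base = dose_regression(y, X)
        with_cov = dose_regression(
            y, X, covariates=pd.DataFrame({"c1": np.ones(len(y)),
                                           "c2": np.full(len(y), 3.7)})
        )
        assert base.loc["dose", "coef"] == pytest.approx(
            with_cov.loc["dose", "coef"], abs=1e-8
        )
        assert "c1" not in with_cov.index and "c2" not in with_cov.index

    def test_rank_deficiency_names_offending_column(self):
        X, y = self._sim(2.0, 400, 32)
        X["copy"] = X["dose"] * 1.0
        with pytest.raises(RankDeficientDesignError, match="copy"):
            dose_regression(y, X)

    def test_separation_flagged_not_raised(self):
        y = np.array([0] * 20 + [1] * 20)
        X = pd.DataFrame({"dose": np.r_[np.zeros(20), np.ones(20) * 2]})
        fit = dose_regression(y, X)
        assert fit.attrs["separated"]
        assert not fit.loc["dose", "estimable"]

    def test_region_dummies_and_covariates_enter_design(self):
        X, y = self._sim(2.0, 900, 33)
        rng = np.random.default_rng(5)
        regions = rng.choice(["R1", "R2", "R3"], size=len(y))
        cov = pd.DataFrame({"pc1": rng.standard_normal(len(y))})
        fit = dose_regression(y, X, covariates=cov, regions=regions)
        assert {"region_R2", "region_R3", "pc1"} <= set(fit.index)
        assert "region_R1" not in fit.index  # first level dropped
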