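"""Unit and property tests for per-trial effect measures."""

import math
import warnings

import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from splitmeta import (
    BinaryArms,
    ContinuousArms,
    EffectEstimate,
    FeasibilityWarning,
    InvalidInputError,
    PairedBinaryTable,
    PairedContinuous,
    follmann_impute_sd_diff,
    log_or_parallel,
    marginal_log_or_split_mouth,
    orient_effect,
    paired_cells_from_marginals,
    smd_parallel,
    smd_split_mouth,
)


class TestLogOrParallel:
    def test_symmetric_table_gives_null_log_or(self):
        est = log_or_parallel(BinaryArms(10, 20, 10, 20))
        assert est.value == 0.0
        assert est.variance == pytest.approx(0.4)
        assert est.scale == "log_odds_ratio" and est.design == "parallel"

    def test_zero_cell_triggers_continuity_correction_on_all_cells(self):
        est = log_or_parallel(BinaryArms(0, 20, 5, 20))
        assert est.value == pytest.approx(math.log((0.5 * 15.5) / (20.5 * 5.5)))
        assert est.variance == pytest.approx(1 / 0.5 + 1 / 20.5 + 1 / 5.5 + 1 / 15.5)

    def test_no_events_in_either_arm_is_excluded(self):
        est = log_or_parallel(BinaryArms(0, 20, 0, 20))
        assert est.excluded
        assert est.exclusion_reason == "double_zero"

    def test_all_events_in_both_arms_is_invalid(self):
        with pytest.raises(InvalidInputError):
            log_or_parallel(BinaryArms(20, 20, 15, 15))

    @pytest.mark.parametrize(
        "args", [(-1, 20, 5, 20), (25, 20, 5, 20), (5, 0, 5, 20)]
    )
    def test_malformed_tables_are_rejected(self, args):
        with pytest.raises(InvalidInputError):
            BinaryArms(*args)


class TestMarginalLogOr:
    def test_worked_example_value_and_variance(self):
        # margins p1=0.40, p2=0.35; variance from the delta-method form,
        # cross-checked against the Monte-Carlo oracle in the acceptance suite
        est = marginal_log_or_split_mouth(PairedBinaryTable(30, 10, 5, 55))
        assert est.value == pytest.approx(math.log((0.40 * 0.65) / (0.35 * 0.60)))
        assert est.value == pytest.approx(0.2136, abs=5e-5)
        assert est.variance == pytest.approx(0.0270, abs=5e-5)

    def test_equal_discordant_cells_force_null_or(self):
        est = marginal_log_or_split_mouth(PairedBinaryTable(20, 7, 7, 66))
        assert est.value == 0.0

    def test_independence_reduces_to_sum_of_binomial_variances(self):
        # pi11*pi00 == pi10*pi01: cells 16,24,24,36 over n=100
        est = marginal_log_or_split_mouth(PairedBinaryTable(16, 24, 24, 36))
        p1 = p2 = 0.4
        expected = (1 / (p1 * 0.6) + 1 / (p2 * 0.6)) / 100
        assert est.variance == pytest.approx(expected)

    def test_value_depends_only_on_margins(self):
        a = marginal_log_or_split_mouth(PairedBinaryTable(30, 10, 5, 55))
        b = marginal_log_or_split_mouth(PairedBinaryTable(20, 20, 15, 45))
        assert a.value == pytest.approx(b.value)
        assert a.variance != pytest.approx(b.variance)

    def test_no_events_at_either_site_is_excluded(self):
        assert marginal_log_or_split_mouth(PairedBinaryTable(0, 0, 0, 50)).excluded

    def test_events_everywhere_is_excluded(self):
        assert marginal_log_or_split_mouth(PairedBinaryTable(50, 0, 0, 0)).excluded

    def test_zero_marginal_cell_gets_continuity_correction(self):
        est = marginal_log_or_split_mouth(PairedBinaryTable(0, 0, 5, 45))
        assert not est.excluded and math.isfinite(est.value) and est.variance > 0

    def test_zero_discordant_cells_get_continuity_correction(self):
        # perfectly concordant table: raw delta-method variance would be 0
        est = marginal_log_or_split_mouth(PairedBinaryTable(10, 0, 0, 40))
        assert not est.excluded
        assert est.value == 0.0 and est.variance > 0

    @given(
        n11=st.integers(1, 50),
        n10=st.integers(1, 50),
        n01=st.integers(1, 50),
        n00=st.integers(1, 50),
    )
    def test_positive_dependence_shrinks_variance_below_independence(
        self, n11, n10, n01, n00
    ):
        table = PairedBinaryTable(n11, n10, n01, n00)
        assume(n11 * n00 > n10 * n01)  # positive within-patient dependence
        est = marginal_log_or_split_mouth(table)
        p1, p2 = table.margins()
        indep = (1 / (p1 * (1 - p1)) + 1 / (p2 * (1 - p2))) / table.n
        assert est.variance <= indep

    @given(
        n11=st.integers(0, 40),
        n10=st.integers(0, 40),
        n01=st.integers(0, 40),
        n00=st.integers(0, 40),
    )
    def test_variance_strictly_positive_when_not_excluded(self, n11, n10, n01, n00):
        assume(n11 + n10 + n01 + n00 > 0)
        est = marginal_log_or_split_mouth(PairedBinaryTable(n11, n10, n01, n00))
        if not est.excluded:
            assert est.variance > 0 and math.isfinite(est.value)


class TestPairedCellsFromMarginals:
    def test_independence_gives_product_cell(self):
        t = paired_cells_from_marginals(40, 35, 100, rho=0.0)
        assert t.n11 == pytest.approx(14.0)
        assert (t.n10, t.n01, t.n00) == (
            pytest.approx(26.0),
            pytest.approx(21.0),
            pytest.approx(39.0),
        )

    def test_perfect_correlation_with_equal_margins_kills_discordance(self):
        t = paired_cells_from_marginals(40, 40, 100, rho=1.0)
        assert t.n10 == pytest.approx(0.0) and t.n01 == pytest.approx(0.0)

    def test_default_correlation_concordant_cell(self):
        t = paired_cells_from_marginals(40, 35, 100, rho=0.5)
        expected = 0.14 + 0.5 * math.sqrt(0.4 * 0.6 * 0.35 * 0.65)
        assert t.n11 == pytest.approx(expected * 100)

    def test_infeasible_rho_is_clamped_with_warning(self):
        with pytest.warns(FeasibilityWarning):
            t = paired_cells_from_marginals(20, 60, 100, rho=0.9)
        assert min(t.n11, t.n10, t.n01, t.n00) >= 0

    @given(
        n=st.integers(2, 500),
        e1=st.integers(0, 500),
        e2=st.integers(0, 500),
        rho=st.floats(-1, 1),
    )
    def test_margins_round_trip_when_rho_feasible(self, n, e1, e2, rho):
        assume(e1 <= n and e2 <= n)
        with warnings.catch_warnings():
            warnings.simplefilter("error", FeasibilityWarning)
            try:
                t = paired_cells_from_marginals(e1, e2, n, rho)
            except FeasibilityWarning:
                assume(False)
        assert t.n11 + t.n10 == pytest.approx(e1, abs=1e-8 * max(n, 1))
        assert t.n11 + t.n01 == pytest.approx(e2, abs=1e-8 * max(n, 1))
        assert t.n == pytest.approx(n)


class TestSmd:
    def test_null_difference_forces_known_variance(self):
        est = smd_parallel(ContinuousArms(1.0, 2.0, 20, 1.0, 3.0, 20))
        assert est.value == 0.0
        assert est.variance == pytest.approx(0.1)

    def test_unit_effect_closed_form(self):
        est = smd_parallel(ContinuousArms(1.0, 1.0, 50, 0.0, 1.0, 50))
        assert est.value == pytest.approx(1.0)
        assert est.variance == pytest.approx(0.045)

    def test_swapping_arms_negates_value_keeps_variance(self):
        a = smd_parallel(ContinuousArms(1.3, 1.1, 30, 0.4, 0.9, 25))
        b = smd_parallel(ContinuousArms(0.4, 0.9, 25, 1.3, 1.1, 30))
        assert a.value == pytest.approx(-b.value)
        assert a.variance == pytest.approx(b.variance)

    def test_split_mouth_null_difference_variance(self):
        data = PairedContinuous(1.0, 1.0, 1.5, 1.5, n=30, rho=0.4)
        est = smd_split_mouth(data)
        assert est.value == 0.0
        assert est.variance == pytest.approx(2 * (1 - 0.4) / 30)

    def test_split_mouth_worked_example(self):
        # d = 0.5, n = 25, rho = 0.5 -> [1/25 + 0.25/50] * 1 = 0.045
        data = PairedContinuous(0.5, 0.0, 1.0, 1.0, n=25, rho=0.5)
        est = smd_split_mouth(data)
        assert est.value == pytest.approx(0.5)
        assert est.variance == pytest.approx(0.045)

    def test_sd_diff_path_consistent_with_site_sds_at_default_rho(self):
        # rho = 0.5 and equal site SDs make sd_diff equal the site SD
        via_sds = smd_split_mouth(PairedContinuous(0.8, 0.2, 2.0, 2.0, n=40, rho=0.5))
        via_sdd = smd_split_mouth(
            PairedContinuous(0.8, 0.2, 2.0, 2.0, n=40, rho=0.5, sd_diff=2.0)
        )
        assert via_sds.value == pytest.approx(via_sdd.value)
        assert via_sds.variance == pytest.approx(via_sdd.variance)

    @given(rho=st.floats(-0.9, 0.95), d=st.floats(-2, 2), n=st.integers(5, 200))
    def test_variance_strictly_decreasing_in_rho(self, rho, d, n):
        lo = smd_split_mouth(PairedContinuous(d, 0.0, 1.0, 1.0, n=n, rho=rho))
        hi = smd_split_mouth(PairedContinuous(d, 0.0, 1.0, 1.0, n=n, rho=rho + 0.04))
        assert hi.variance < lo.variance

    def test_rho_one_with_sd_diff_is_invalid(self):
        data = PairedContinuous(1.0, 0.0, 1.0, 1.0, n=10, rho=1.0, sd_diff=0.5)
        with pytest.raises(InvalidInputError):
            smd_split_mouth(data)


class TestFollmann:
    @pytest.mark.parametrize(
        "sd_exp,sd_ctl,rho,expected",
        [
            (2.0, 2.0, 0.5, 2.0),
            (3.0, 4.0, 0.0, 5.0),
            (3.0, 4.0, 0.25, math.sqrt(19.0)),
        ],
    )
    def test_imputed_difference_sd(self, sd_exp, sd_ctl, rho, expected):
        assert follmann_impute_sd_diff(sd_exp, sd_ctl, rho) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            follmann_impute_sd_diff(-1.0, 2.0, 0.5)
        with pytest.raises(InvalidInputError):
            follmann_impute_sd_diff(1.0, 2.0, 1.5)


class TestOrientation:
    def _est(self, value):
        return EffectEstimate(value, 0.04, "smd", "parallel", "t1")

    def test_higher_is_better_negates(self):
        assert orient_effect(self._est(0.3), "higher").value == -0.3

    def test_lower_is_better_passes_through(self):
        assert orient_effect(self._est(-0.3), "lower").value == -0.3

    @given(value=st.floats(-3, 3), direction=st.sampled_from(["lower", "higher"]))
    def test_orientation_is_idempotent_and_variance_preserving(self, value, direction):
        est = self._est(value)
        once = orient_effect(est, direction)
        twice = orient_effect(once, direction)
        assert twice == once
        assert once.variance == est.variance
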