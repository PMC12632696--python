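from fractions import Fraction as F

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vaxavert.estimands import direct_impact
from vaxavert.estimators import (
    alt_unbiased_estimator,
    alt_unbiased_from_records,
    avertible_hd_estimator,
    hazard_components,
    hazard_difference_estimator,
    hd_bias,
    hd_expectation,
    unbiased_estimator,
    unbiased_from_records,
)
from vaxavert.trial_data import (
    ArmIncidence,
    IndividualRecord,
    StatusRow,
    StatusTable,
    Strategy,
    arm_incidence_from_records,
    status_table_from_records,
)

from conftest import make_records


def single_interval_table(n_vax, vax_events, n_unvax, unvax_events):
    s = Strategy(1, 60, (F(1, 2), F(1, 2)))
    return StatusTable(
        [StatusRow(0, n_vax, vax_events, n_unvax, unvax_events)],
        n_vax + n_unvax,
        s,
    )


class TestUnbiasedEstimator:
    def test_worked_example(self, fig1_arm):
        assert unbiased_estimator(fig1_arm) == 3

    def test_no_events_gives_zero(self, thirds_strategy):
        records = make_records(thirds_strategy, [[None, None]] * 3)
        assert unbiased_from_records(records, thirds_strategy) == 0

    def test_antisymmetry_under_arm_swap(self, fig1, thirds_strategy):
        records, strategy, _ = fig1
        swap = {0: 2, 1: 1, 2: 0}
        swapped = [
            IndividualRecord(r.id, swap[r.assigned_time], r.event_interval)
            for r in records
        ]
        assert unbiased_from_records(swapped, strategy) == -3


class TestHazardComponents:
    def test_worked_example_components(self, fig1_status):
        comp = hazard_components(fig1_status)
        assert comp.h_unvax == (F(1, 2), 1)
        assert comp.h_vax == (0, 0)
        assert comp.n_vax == (2, 3)
        assert comp.n_unvax == (4, 1)

    def test_no_events_all_zero_hazards(self, thirds_strategy):
        records = make_records(thirds_strategy, [[None, None]] * 3)
        comp = hazard_components(status_table_from_records(records, thirds_strategy))
        assert comp.h_vax == (0, 0) and comp.h_unvax == (0, 0)

    def test_simple_ratio(self):
        comp = hazard_components(single_interval_table(10, 3, 10, 0))
        assert comp.h_vax == (F(3, 10),)

    def test_empty_risk_sets_use_zero_convention_with_warning(self, thirds_strategy):
        table = StatusTable(
            [StatusRow(0, 2, 0, 4, 4), StatusRow(1, 2, 2, 0, 0)],
            6,
            thirds_strategy,
        )
        bad = StatusTable(
            [StatusRow(0, 6, 6, 0, 0), StatusRow(1, 0, 0, 0, 0)],
            6,
            thirds_strategy,
        )
        with pytest.warns(RuntimeWarning, match="empty risk set"):
            hazard_components(bad)
        assert hazard_components(table).h_vax[1] == 1


class TestHazardDifferenceEstimator:
    def test_worked_example(self, fig1_status):
        assert hazard_difference_estimator(fig1_status) == 4

    def test_equal_hazards_give_zero(self):
        table = single_interval_table(10, 2, 20, 4)
        assert hazard_difference_estimator(table) == 0

    def test_one_term_evaluation(self):
        table = single_interval_table(100, 10, 50, 10)
        # 100 * (0.2 - 0.1) = 10
        assert hazard_difference_estimator(table) == 10


class TestAvertibleHdEstimator:
    def test_worked_example(self, fig1_status):
        # 4 * (1/2 - 0) + 1 * (1 - 0) = 3
        assert avertible_hd_estimator(fig1_status) == 3

    def test_null_is_zero(self, thirds_strategy):
        records = make_records(thirds_strategy, [[None, None]] * 3)
        table = status_table_from_records(records, thirds_strategy)
        assert avertible_hd_estimator(table) == 0

    def test_one_term_evaluation(self):
        table = single_interval_table(100, 10, 50, 10)
        # 50 * (0.2 - 0.1) = 5
        assert avertible_hd_estimator(table) == 5


def eq6_plugin(arm: ArmIncidence) -> F:
    """Independent evaluation of the estimand rewrite that the aggregated
    estimator is the plug-in of, straight from arm-level increments."""
    s = arm.strategy
    rho = s.rho
    n = arm.n_total
    total = 0
    # first interval: rho0 * (pooled not-yet-vaccinated incidence - arm-0 incidence)
    pooled = sum(rho[x] * arm.delta(1, x) for x in range(1, s.n_arms))
    pooled /= sum(rho[x] for x in range(1, s.n_arms))
    total += rho[0] * (pooled - arm.delta(1, 0))
    for k in range(1, s.n_times):
        rho_vax = sum(rho[x] for x in range(k + 1))
        total += rho_vax * sum(
            rho[x] * arm.delta(k + 1, x) for x in range(k + 1, s.n_arms)
        ) / sum(rho[x] for x in range(k + 1, s.n_arms))
        total -= sum(rho[x] * arm.delta(k + 1, x) for x in range(k + 1))
    return n * total


class TestAltUnbiasedEstimator:
    def test_worked_example_matches_unbiased(self, fig1_status):
        # 2*(1/2) + (2/1)*1*1 - 3*0 = 3
        assert alt_unbiased_estimator(fig1_status) == 3

    def test_null_is_zero(self, thirds_strategy):
        records = make_records(thirds_strategy, [[None, None]] * 3)
        table = status_table_from_records(records, thirds_strategy)
        assert alt_unbiased_estimator(table) == 0

    def test_zero_never_vaccinated_proportion_rejected(self):
        s = Strategy(2, 60, (F(1, 2), F(1, 2), 0))
        table = StatusTable(
            [StatusRow(0, 2, 0, 2, 0), StatusRow(1, 4, 0, 0, 0)], 4, s
        )
        with pytest.raises(ZeroDivisionError, match="never"):
            alt_unbiased_estimator(table)

    @settings(max_examples=80, deadline=None)
    @given(
        st.lists(
            st.one_of(st.none(), st.integers(0, 1)), min_size=6, max_size=6
        )
    )
    def test_is_the_exact_plugin_of_the_estimand_rewrite(self, events):
        """On any record set of the mixed strategy (fixed arm sizes) the
        aggregated estimator equals the sample plug-in of the
        pooled-increment rewrite of the estimand, exactly."""
        strategy = Strategy(2, 60, (F(1, 3), F(1, 3), F(1, 3)))
        arms = [0, 0, 1, 1, 2, 2]
        records = [
            IndividualRecord(str(i), a, ev)
            for i, (a, ev) in enumerate(zip(arms, events))
        ]
        arm = arm_incidence_from_records(records, strategy)
        table = status_table_from_records(records, strategy)
        assert alt_unbiased_estimator(table) == eq6_plugin(arm)

    def test_matches_unbiased_when_early_incidence_is_pooled(self, thirds_strategy):
        """When the not-yet-vaccinated arms share the same realized early
        incidence, the aggregated estimator recovers the arm-level plug-in
        exactly (the information lost to aggregation is immaterial)."""
        records = make_records(
            thirds_strategy, [[None, None], [0, None], [0, 1]]
        )
        table = status_table_from_records(records, thirds_strategy)
        assert alt_unbiased_estimator(table) == unbiased_from_records(
            records, thirds_strategy
        )

    def test_differs_from_unbiased_when_aggregation_loses_the_arm_split(
        self, thirds_strategy
    ):
        """Arm-1 and arm-2 early incidences differ: the aggregated table
        cannot reproduce the arm-level plug-in realization-by-realization
        (they still agree in expectation; see the enumeration tests)."""
        records = make_records(thirds_strategy, [[None, None], [0, 0], [None, None]])
        table = status_table_from_records(records, thirds_strategy)
        assert unbiased_from_records(records, thirds_strategy) == -2
        assert alt_unbiased_estimator(table) == 1


def hd_expectation_first_term_only(arm, strategy):
    """Hand evaluation of the k=0 term N*rho0*(pooled unvax hazard - vax hazard)."""
    rho = strategy.rho
    pooled = sum(rho[x] * arm.delta(1, x) for x in (1, 2)) / (rho[1] + rho[2])
    return arm.n_total * rho[0] * (pooled - arm.delta(1, 0))


class TestHdExpectation:
    def test_equal_early_survival_means_no_bias(self, thirds_strategy):
        # identical interval-1 survival in all arms -> expectation = estimand
        arm = ArmIncidence(
            [(0, 0, 0), (F(1, 10),) * 3, (F(1, 10), F(2, 10), F(4, 10))],
            100,
            thirds_strategy,
        )
        assert hd_expectation(arm) == direct_impact(arm).value
        assert hd_bias(arm) == 0

    def test_null_vaccine_truth(self, thirds_strategy):
        arm = ArmIncidence(
            [(0, 0, 0), (F(1, 10),) * 3, (F(2, 10),) * 3], 100, thirds_strategy
        )
        assert hd_expectation(arm) == 0
        assert direct_impact(arm).value == 0

    def test_depleted_unvaccinated_arm_inflates_expectation(self, thirds_strategy):
        # never-arm survival lower by interval 1 -> overestimation; the two
        # not-yet-vaccinated arms share early incidence (no anticipation)
        arm = ArmIncidence(
            [(0, 0, 0), (F(1, 10), F(4, 10), F(4, 10)), (F(2, 10), F(5, 10), F(7, 10))],
            100,
            thirds_strategy,
        )
        assert hd_expectation(arm) > direct_impact(arm).value

    def test_fully_depleted_never_arm_warns_and_stays_defined(self, thirds_strategy):
        # never arm exhausted after interval 0: its later hazard is 0/0,
        # taken as 0 with a warning so the sum stays defined
        arm = ArmIncidence(
            [(0, 0, 0), (0, 0, 1), (0, 0, 1)], 100, thirds_strategy
        )
        with pytest.warns(RuntimeWarning, match="empty risk set"):
            value = hd_expectation(arm)
        assert value == hd_expectation_first_term_only(arm, thirds_strategy)
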