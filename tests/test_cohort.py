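"""Decision tree, Markov transitions, discounting and strategy runs."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fasdscreen.cohort import (
    LifeTable,
    StrategyDefinition,
    comparison_strategies,
    discount_factor,
    initial_distribution,
    run_comparison_pair,
    run_strategy,
    state_mortality,
)
from fasdscreen.parameters import MortalityParams, ValidationError, load_parameters
from fasdscreen.synthetic import make_life_table, zero_mortality_table


def _screen_arm(params):
    return comparison_strategies(params)[1]


def _no_screen_arm(params):
    return comparison_strategies(params)[0]


class TestInitialDistribution:
    def test_screen_arm_splits_by_accuracy(self, meconium_params):
        sv = initial_distribution(meconium_params, _screen_arm(meconium_params))
        assert sv["PENDING_FASD"] == pytest.approx(66.3 * 0.924)  # 61.26
        assert sv["UNDIAGNOSED"] == pytest.approx(66.3 * 0.076)  # 5.04
        assert sv["PENDING_NO_FASD"] == pytest.approx(33.7 * 0.485)  # 16.34
        assert sv["NO_FASD"] == pytest.approx(33.7 * 0.515)  # 17.36
        assert sum(sv.values()) == pytest.approx(100.0)

    def test_no_screen_arm_schedules_everyone(self, meconium_params):
        sv = initial_distribution(meconium_params, _no_screen_arm(meconium_params))
        assert sv["PENDING_FASD"] == pytest.approx(66.3)
        assert sv["PENDING_NO_FASD"] == pytest.approx(33.7)
        assert sv["UNDIAGNOSED"] == 0.0

    def test_perfect_screen_leaves_no_missed_or_false_positive(self, meconium_params):
        params = dataclasses.replace(
            meconium_params,
            tool=dataclasses.replace(
                meconium_params.tool, sensitivity=1.0, specificity=1.0
            ),
        )
        sv = initial_distribution(params, _screen_arm(params))
        assert sv["UNDIAGNOSED"] == 0.0
        assert sv["PENDING_NO_FASD"] == 0.0


class TestStateMortality:
    def test_smr_scales_background_rate(self):
        m = MortalityParams()
        assert state_mortality(0.0003, "DIAGNOSED", m) == pytest.approx(0.000945)
        assert state_mortality(0.0003, "PENDING_FASD", m) == pytest.approx(0.000945)
        assert state_mortality(0.0003, "UNDIAGNOSED", m) == pytest.approx(
            0.000945 * 1.10
        )

    def test_zero_background_rate(self):
        m = MortalityParams()
        for state in ("DIAGNOSED", "UNDIAGNOSED", "NO_FASD", "DEAD"):
            assert state_mortality(0.0, state, m) == 0.0

    def test_product_capped_at_one(self):
        m = MortalityParams()
        assert state_mortality(0.5, "DIAGNOSED", m) == 1.0

    def test_dead_stays_dead(self):
        assert state_mortality(0.9, "DEAD", MortalityParams()) == 0.0


class TestDiscountFactor:
    @pytest.mark.parametrize(
        "cycle, r, expected",
        [(0, 0.015, 0.99259), (12, 0.015, 0.8302), (5, 0.0, 1.0)],
    )
    def test_mid_cycle_values(self, cycle, r, expected):
        assert discount_factor(cycle, r) == pytest.approx(expected, abs=5e-5)

    def test_trapezoidal_averages_cycle_boundaries(self):
        r = 0.03
        expected = ((1.03) ** -2 + (1.03) ** -3) / 2
        assert discount_factor(2, r, "trapezoidal") == pytest.approx(expected)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            discount_factor(0, -0.01)


class TestRunStrategy:
    def test_conservation_every_cycle_both_arms(
        self, meconium_params, nst_params, default_life_table
    ):
        for params in (meconium_params, nst_params):
            for result in run_comparison_pair(params, default_life_table):
                for rec in result.trace:
                    assert sum(rec.occupancy.values()) == pytest.approx(100.0)

    def test_totals_equal_trace_sums(self, meconium_params, default_life_table):
        for result in run_comparison_pair(meconium_params, default_life_table):
            assert result.total_cost == pytest.approx(
                sum(r.discounted_cost for r in result.trace)
            )
            assert result.total_diagnosed_years == pytest.approx(
                sum(r.discounted_diagnosed_years for r in result.trace)
            )

    def test_discounted_accruals_never_exceed_undiscounted(
        self, meconium_params, default_life_table
    ):
        for result in run_comparison_pair(meconium_params, default_life_table):
            for rec in result.trace:
                assert rec.discounted_cost <= rec.cost + 1e-12
                assert rec.discounted_diagnosed_years <= rec.diagnosed_years + 1e-12

    def test_zero_mortality_zero_discount_closed_form(
        self, meconium_params, nst_params, immortal_life_table
    ):
        # No screening, no deaths, no discounting: the whole FASD group is
        # diagnosed at the testing age and accrues exactly one diagnosed year
        # per cycle to the horizon.
        for params in (meconium_params, nst_params):
            params = dataclasses.replace(params, discount_rate=0.0)
            result = run_strategy(
                params, _no_screen_arm(params), immortal_life_table
            )
            expected = 66.3 * (params.end_age - params.tool.testing_age)
            assert result.total_diagnosed_years == pytest.approx(expected)

    def test_all_dead_cohort_accrues_nothing(self, meconium_params):
        from fasdscreen.cohort import advance_cycle

        sv = {s: 0.0 for s in initial_distribution(
            meconium_params, _no_screen_arm(meconium_params)
        )}
        sv["DEAD"] = 100.0
        new, cost, effect = advance_cycle(
            sv, 3, meconium_params, _no_screen_arm(meconium_params),
            make_life_table(end_age=18),
        )
        assert cost == 0.0 and effect == 0.0
        assert new == sv

    def test_screen_equals_no_screen_when_everyone_is_tested(
        self, meconium_params, nst_params, default_life_table
    ):
        # With Se = 1, Sp = 0 and a free screen, screening routes every child
        # to diagnostic testing exactly as no screening does.
        for params in (meconium_params, nst_params):
            params = dataclasses.replace(
                params,
                tool=dataclasses.replace(
                    params.tool, sensitivity=1.0, specificity=0.0, unit_cost=0.0
                ),
            )
            ref, scr = run_comparison_pair(params, default_life_table)
            assert scr.total_cost == pytest.approx(ref.total_cost, rel=1e-12)
            assert scr.total_diagnosed_years == pytest.approx(
                ref.total_diagnosed_years, rel=1e-12
            )

    def test_perfect_screen_differs_only_by_rule_out_testing(
        self, meconium_params, immortal_life_table
    ):
        # With Se = Sp = 1 and a free screen the arms agree on effectiveness,
        # but the no-screen arm still rule-out tests the non-FASD group.
        params = dataclasses.replace(
            meconium_params,
            tool=dataclasses.replace(
                meconium_params.tool, sensitivity=1.0, specificity=1.0, unit_cost=0.0
            ),
        )
        ref, scr = run_comparison_pair(params, immortal_life_table)
        assert scr.total_diagnosed_years == pytest.approx(
            ref.total_diagnosed_years, rel=1e-12
        )
        d_test = discount_factor(5, params.discount_rate)
        expected_gap = 33.7 * params.effective_costs().diagnostic_testing * d_test
        assert ref.total_cost - scr.total_cost == pytest.approx(expected_gap)

    def test_diagnostic_cost_charged_once_per_tested_person(
        self, meconium_params, immortal_life_table
    ):
        # Zero out everything but the testing fee: total spend must equal
        # (persons ever tested) x fee, here TP + FP with no re-testing.
        params = dataclasses.replace(
            meconium_params,
            future_diagnosis_rate=0.0,
            tool=dataclasses.replace(meconium_params.tool, unit_cost=0.0),
            costs=dataclasses.replace(
                meconium_params.costs,
                first_year=0.0,
                diagnosed_annual=0.0,
                undiagnosed_annual=0.0,
                no_fasd_annual=0.0,
            ),
        )
        scr = run_strategy(params, _screen_arm(params), immortal_life_table)
        tested = 66.3 * 0.924 + 33.7 * 0.485
        expected = tested * 3870.0 * discount_factor(5, params.discount_rate)
        assert scr.total_cost == pytest.approx(expected)

    def test_future_diagnosis_converts_expected_mass(
        self, meconium_params, immortal_life_table
    ):
        scr = run_strategy(
            meconium_params, _screen_arm(meconium_params), immortal_life_table
        )
        # Missed cases decay at 5% per year from the testing cycle onward.
        missed0 = 66.3 * 0.076
        undiag_at_end = missed0 * 0.95 ** 13
        assert scr.trace[-1].occupancy["UNDIAGNOSED"] == pytest.approx(undiag_at_end)

    def test_monotone_in_discount_rate(self, nst_params, default_life_table):
        totals = []
        for r in (0.0, 0.015, 0.03):
            params = dataclasses.replace(nst_params, discount_rate=r)
            ref, _ = run_comparison_pair(params, default_life_table)
            totals.append((ref.total_cost, ref.total_diagnosed_years))
        assert totals[0] >= totals[1] >= totals[2]

    def test_sensitivity_raises_screen_arm_effectiveness(
        self, meconium_params, default_life_table
    ):
        effs = []
        for se in (0.7, 0.85, 0.99):
            params = dataclasses.replace(
                meconium_params,
                tool=dataclasses.replace(meconium_params.tool, sensitivity=se),
            )
            effs.append(
                run_strategy(
                    params, _screen_arm(params), default_life_table
                ).total_diagnosed_years
            )
        assert effs[0] < effs[1] < effs[2]

    def test_specificity_lowers_screen_arm_cost(
        self, meconium_params, default_life_table
    ):
        costs = []
        for sp in (0.3, 0.5, 0.9):
            params = dataclasses.replace(
                meconium_params,
                tool=dataclasses.replace(meconium_params.tool, specificity=sp),
            )
            costs.append(
                run_strategy(params, _screen_arm(params), default_life_table).total_cost
            )
        assert costs[0] > costs[1] > costs[2]

    def test_short_life_table_rejected(self, meconium_params):
        with pytest.raises(ValidationError, match="life table"):
            run_strategy(
                meconium_params,
                _no_screen_arm(meconium_params),
                make_life_table(end_age=10),
            )

    def test_nonpositive_horizon_rejected(self, nst_params):
        strategy = StrategyDefinition(
            kind="no_screen", tool=None, model_start_age=18, testing_age=18
        )
        with pytest.raises(ValidationError, match="horizon"):
            run_strategy(nst_params, strategy, make_life_table(end_age=18))

    @given(
        se=st.floats(0.01, 0.99),
        sp=st.floats(0.01, 0.99),
        prev=st.floats(0.05, 0.95),
        rho=st.floats(0.0, 0.5),
        q_flat=st.floats(0.0, 0.05),
        smr=st.floats(0.0, 20.0),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_conservation_property(self, se, sp, prev, rho, q_flat, smr):
        params = load_parameters(
            {
                "cohort": {"prevalence": prev},
                "tools": {"meconium": {"sensitivity": se, "specificity": sp}},
                "mortality": {"smr_diagnosed": smr},
                "model": {"future_diagnosis_rate": rho},
            }
        )
        table = LifeTable(np.full(18, q_flat))
        for result in run_comparison_pair(params, table):
            assert result.total_cost >= 0.0
            assert result.total_diagnosed_years >= 0.0
            for rec in result.trace:
                assert sum(rec.occupancy.values()) == pytest.approx(100.0)
                assert min(rec.occupancy.values()) >= -1e-12


class TestLifeTableIO:
    def test_csv_roundtrip(self, tmp_path):
        table = make_life_table(end_age=18)
        path = tmp_path / "lt.csv"
        table.to_csv(path)
        again = LifeTable.from_csv(path)
        assert np.allclose(table.qx, again.qx)

    def test_non_consecutive_ages_rejected(self, tmp_path):
        path = tmp_path / "lt.csv"
        path.write_text("age,qx\n0,0.001\n2,0.001\n")
        with pytest.raises(ValidationError, match="consecutive"):
            LifeTable.from_csv(path)

    def test_probabilities_validated(self):
        with pytest.raises(ValidationError):
            LifeTable(np.array([0.1, 1.5]))
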