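"""Distribution sampling, probabilistic analysis, CEAC and tornado."""

import dataclasses

import numpy as np
import pytest

from fasdscreen.cea import compare
from fasdscreen.cohort import run_comparison_pair
from fasdscreen.parameters import ValidationError
from fasdscreen.sensitivity import (
    DistributionSpec,
    ceac,
    cep_quadrant_counts,
    default_distributions,
    discount_scenarios,
    one_way,
    run_psa,
    sample_parameter,
)

RNG_SEED = 20190101


def _draws(spec, n, seed=RNG_SEED):
    rng = np.random.default_rng(seed)
    return np.array([sample_parameter(spec, rng) for _ in range(n)])


class TestSampleParameter:
    def test_beta_moment_matching(self):
        x = _draws(DistributionSpec("beta", 0.663, 0.014, name="prev"), 20_000)
        assert x.mean() == pytest.approx(0.663, abs=0.001)
        assert x.std() == pytest.approx(0.014, abs=0.001)
        assert ((x > 0) & (x < 1)).all()

    def test_uniform_respects_bounds(self):
        spec = DistributionSpec("uniform", 0.05, lower=0.03, upper=0.07, name="rho")
        x = _draws(spec, 5_000)
        assert x.min() >= 0.03 and x.max() <= 0.07

    def test_bounded_normal_rejection_sampling(self):
        spec = DistributionSpec("normal_bounded", 3870.0, 387.0, name="c_diag")
        x = _draws(spec, 5_000)
        assert x.min() >= 0.75 * 3870 and x.max() <= 1.25 * 3870
        assert x.mean() == pytest.approx(3870.0, rel=0.01)

    def test_log_normal_moment_matched(self):
        spec = DistributionSpec("log_normal", 3426.0, 343.0, name="c_d")
        x = _draws(spec, 20_000)
        assert x.mean() == pytest.approx(3426.0, rel=0.01)
        assert x.std() == pytest.approx(343.0, rel=0.05)
        assert (x > 0).all()

    def test_truncated_normal_floor(self):
        spec = DistributionSpec(
            "truncated_normal", 3.15, 2.0, lower=1.0, name="smr"
        )
        x = _draws(spec, 5_000)
        assert x.min() >= 1.0

    def test_fixed_returns_mean(self):
        spec = DistributionSpec("fixed", 0.42)
        assert sample_parameter(spec, np.random.default_rng(0)) == 0.42

    def test_infeasible_beta_names_parameter(self):
        with pytest.raises(ValidationError, match="specificity"):
            DistributionSpec("beta", 0.5, 0.6, name="specificity")

    def test_unknown_family_rejected(self):
        with pytest.raises(ValidationError):
            DistributionSpec("gamma", 1.0, 1.0, name="x")


class TestRunPsa:
    def test_reproducible_for_a_seed(self, meconium_params, default_life_table):
        a = run_psa(meconium_params, n_draws=40, seed=7, life_table=default_life_table)
        b = run_psa(meconium_params, n_draws=40, seed=7, life_table=default_life_table)
        assert np.array_equal(a.delta_cost, b.delta_cost)
        assert np.array_equal(a.delta_effect, b.delta_effect)
        assert a.draws[0].values == b.draws[0].values

    def test_different_seeds_differ(self, meconium_params, default_life_table):
        a = run_psa(meconium_params, n_draws=10, seed=1, life_table=default_life_table)
        b = run_psa(meconium_params, n_draws=10, seed=2, life_table=default_life_table)
        assert not np.array_equal(a.delta_cost, b.delta_cost)

    def test_all_fixed_specs_reproduce_base_deltas(
        self, meconium_params, default_life_table
    ):
        specs = {
            name: DistributionSpec("fixed", spec.mean, name=name)
            for name, spec in default_distributions(meconium_params).items()
        }
        psa = run_psa(
            meconium_params,
            n_draws=1,
            seed=0,
            life_table=default_life_table,
            distributions=specs,
        )
        base = compare(
            *run_comparison_pair(meconium_params, default_life_table),
            meconium_params.cohort_size,
        )
        assert psa.delta_cost[0] == pytest.approx(base.delta_cost, abs=1e-6)
        assert psa.delta_effect[0] == pytest.approx(base.delta_effect, abs=1e-6)

    def test_draw_values_respect_supports(self, nst_params, default_life_table):
        psa = run_psa(nst_params, n_draws=60, seed=3, life_table=default_life_table)
        frame = psa.to_frame()
        for col in ("prevalence", "sensitivity", "specificity"):
            assert frame[col].between(0, 1).all()
        assert frame["future_diagnosis_rate"].between(0.03, 0.07).all()
        assert frame["undiagnosed_multiplier"].between(1.0, 1.2).all()
        assert (frame["smr_diagnosed"] >= 1.0).all()

    def test_quadrant_counts_sum_to_draws(self, nst_params, default_life_table):
        psa = run_psa(nst_params, n_draws=50, seed=5, life_table=default_life_table)
        assert sum(cep_quadrant_counts(psa).values()) == 50

    def test_psa_requires_pre_inflation_cost_basis(self, meconium_params):
        inflated = dataclasses.replace(
            meconium_params, costs=meconium_params.effective_costs()
        )
        with pytest.raises(ValidationError, match="pre-inflation"):
            default_distributions(inflated)


class TestCeac:
    def test_point_mass_is_a_step_function(self):
        draws = [(-2359.0 * 5, -5.0)] * 10
        probs = {p.wta: p.probability for p in ceac(draws, [2000, 2359, 2400])}
        assert probs[2000] == 1.0
        assert probs[2359] == 1.0  # savings ratio meets the threshold exactly
        assert probs[2400] == 0.0

    def test_dominant_draws_always_acceptable(self):
        draws = [(-100.0, 5.0)] * 8
        assert all(p.probability == 1.0 for p in ceac(draws, [0, 1000, 1e9]))

    def test_dominated_draws_never_acceptable(self):
        draws = [(100.0, -5.0)] * 8
        assert all(p.probability == 0.0 for p in ceac(draws, [0, 1000, 1e9]))

    def test_monotone_non_increasing_for_sw_cloud(
        self, meconium_params, default_life_table
    ):
        psa = run_psa(
            meconium_params, n_draws=200, seed=11, life_table=default_life_table
        )
        sw = (psa.delta_cost < 0) & (psa.delta_effect < 0)
        draws = list(
            zip(psa.delta_cost[sw], psa.delta_effect[sw])
        )
        probs = [p.probability for p in ceac(draws, range(0, 6000, 250))]
        assert all(a >= b for a, b in zip(probs, probs[1:]))
        assert all(0.0 <= p <= 1.0 for p in probs)

    def test_empty_draws_rejected(self):
        with pytest.raises(ValidationError):
            ceac([], [1000])


class TestOneWay:
    def test_deterministic_and_sorted(self, nst_params, default_life_table):
        a = one_way(nst_params, life_table=default_life_table)
        b = one_way(nst_params, life_table=default_life_table)
        assert [e.parameter for e in a] == [e.parameter for e in b]
        ranges = [e.range for e in a]
        assert ranges == sorted(ranges, reverse=True)

    def test_screening_sensitivity_dominates(self, meconium_params, default_life_table):
        entries = one_way(meconium_params, life_table=default_life_table)
        assert entries[0].parameter == "sensitivity"

    def test_parameter_without_model_role_has_zero_range(
        self, meconium_params, default_life_table
    ):
        # The no-FASD annual cost accrues identically in both arms.
        entries = one_way(
            meconium_params,
            parameters=["no_fasd_annual_cost"],
            life_table=default_life_table,
        )
        assert entries[0].range == pytest.approx(0.0, abs=1e-6)

    def test_unknown_parameter_rejected(self, meconium_params, default_life_table):
        with pytest.raises(ValidationError, match="bogus"):
            one_way(
                meconium_params, parameters=["bogus"], life_table=default_life_table
            )

    def test_bounds_bracket_base_value(self, nst_params, default_life_table):
        for entry in one_way(nst_params, life_table=default_life_table):
            assert entry.low < entry.high


class TestDiscountScenarios:
    def test_base_rate_reproduces_base_icer(self, meconium_params, default_life_table):
        base = compare(
            *run_comparison_pair(meconium_params, default_life_table),
            meconium_params.cohort_size,
        )
        scen = dict(
            discount_scenarios(meconium_params, [0.015], default_life_table)
        )
        assert scen[0.015].icer == pytest.approx(base.icer)

    def test_rates_ordered_by_icer(self, meconium_params, default_life_table):
        results = discount_scenarios(
            meconium_params, [0.0, 0.015, 0.03], default_life_table
        )
        icers = [res.icer for _, res in results]
        assert icers[0] < icers[1] < icers[2]
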