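"""Cost accrual, incremental comparison, budget scaling."""

import numpy as np
import pandas as pd
import pytest

import traumacost as tc
from traumacost import fixtures
from traumacost.costs import (CohortSpec, CostComponents, CostInputs,
                              accumulate_costs, compare_scenarios,
                              scale_to_cohort, state_annual_cost,
                              state_cost_vector)
from traumacost.markov import MortalityTable, TransitionModel, run_trajectory
from traumacost.scenarios import SeverityDistribution

CONDS = ("ptsd", "depression", "anxiety", "adhd")


def _inputs(prevalence, base_np=(0.0, 0.0), base_bp=(0.0, 0.0), unit=100.0):
    return CostInputs(
        base_no_problems=CostComponents(*base_np),
        base_behavior_problems=CostComponents(*base_bp),
        condition_costs={c: CostComponents(unit, 0.0) for c in CONDS},
        prevalence=prevalence,
    )


class TestStateAnnualCost:
    def test_zero_condition_costs_return_base(self, config):
        prev = config.prevalence_table()
        inputs = _inputs(prev, base_np=(1000, 400), base_bp=(2500, 1200), unit=0.0)
        assert state_annual_cost(0, inputs, "direct") == 1000
        for s in (1, 2, 3):
            assert state_annual_cost(s, inputs, "direct") == 2500
            assert state_annual_cost(s, inputs, "societal") == 3700

    def test_q3_prevalence_weighted_dot_product(self, config):
        # unit condition costs of $100, zero base: Q3 cost is 100 x the sum of
        # the four Q3 prevalences (52.24% + 25.37% + 11.19% + 4.48%)
        inputs = _inputs(config.prevalence_table())
        expected = 100 * (70 / 134 + 34 / 134 + 15 / 134 + 6 / 134)
        assert state_annual_cost(2, inputs, "direct") == pytest.approx(expected, abs=1e-9)
        assert state_annual_cost(2, inputs, "direct") == pytest.approx(93.28, abs=0.005)

    def test_dead_state_costs_nothing(self, config):
        inputs = _inputs(config.prevalence_table(), base_bp=(9e9, 9e9))
        assert state_annual_cost(4, inputs, "direct") == 0.0

    def test_least_severe_state_skips_condition_costs_by_default(self, config):
        prev = config.prevalence_table()
        default = _inputs(prev, base_np=(500, 0))
        weighted = CostInputs(
            base_no_problems=CostComponents(500, 0),
            base_behavior_problems=CostComponents(0, 0),
            condition_costs={c: CostComponents(100, 0) for c in CONDS},
            prevalence=prev, include_q1_conditions=True,
        )
        assert state_annual_cost(0, default, "direct") == 500
        assert state_annual_cost(0, weighted, "direct") > 500

    def test_unknown_perspective_rejected(self, config):
        with pytest.raises(ValueError):
            state_annual_cost(1, _inputs(config.prevalence_table()), "payer")


@pytest.fixture(scope="module")
def fixture_trajectory(config):
    init = SeverityDistribution((0.131, 0.382, 0.293, 0.194, 0.0))
    return run_trajectory(init, config.to_transition_model(),
                          config.to_mortality_table(), 13, 5)


class TestAccumulateCosts:
    def test_zero_costs_zero_total(self, config, fixture_trajectory):
        inputs = _inputs(config.prevalence_table(), unit=0.0)
        total, per_cycle = accumulate_costs(fixture_trajectory, inputs, "direct")
        assert total == 0.0
        assert np.allclose(per_cycle, 0.0)

    def test_constant_occupancy_closed_form(self, config):
        zero_mort = MortalityTable({a: 0.0 for a in range(0, 40)})
        init = SeverityDistribution((0.131, 0.382, 0.293, 0.194, 0.0))
        traj = run_trajectory(init, TransitionModel.identity(), zero_mort, 13, 8)
        inputs = config.to_cost_inputs()
        total, _ = accumulate_costs(traj, inputs, "societal")
        annual = init.as_array() @ state_cost_vector(inputs, "societal")
        assert total == pytest.approx(8 * annual, abs=1e-9)

    def test_matches_cycle_by_cycle_oracle_to_the_cent(self, config, fixture_trajectory):
        # independent spreadsheet-style arithmetic over the occupancy table
        inputs = config.to_cost_inputs()
        for perspective in ("direct", "societal"):
            costs = [state_annual_cost(s, inputs, perspective) for s in range(5)]
            oracle = 0.0
            for t in range(fixture_trajectory.horizon):
                occ = fixture_trajectory.distributions[t].probs
                oracle += sum(occ[s] * costs[s] for s in range(5))
            total, _ = accumulate_costs(fixture_trajectory, inputs, perspective)
            assert total == pytest.approx(oracle, abs=0.01)

    def test_discounting_shrinks_later_cycles(self, config, fixture_trajectory):
        inputs = config.to_cost_inputs()
        undisc, per_cycle = accumulate_costs(fixture_trajectory, inputs, "direct")
        disc, per_cycle_d = accumulate_costs(fixture_trajectory, inputs, "direct",
                                             discount_rate=0.03)
        assert disc < undisc
        assert per_cycle_d[0] == pytest.approx(per_cycle[0])
        expected = per_cycle / 1.03 ** np.arange(len(per_cycle))
        assert np.allclose(per_cycle_d, expected, atol=1e-12)

    def test_perspective_additivity(self, config, fixture_trajectory):
        # societal total = direct total + indirect-only total, exactly
        inputs = config.to_cost_inputs()
        indirect_only = CostInputs(
            base_no_problems=CostComponents(inputs.base_no_problems.indirect, 0),
            base_behavior_problems=CostComponents(inputs.base_behavior_problems.indirect, 0),
            condition_costs={c: CostComponents(cc.indirect, 0)
                             for c, cc in inputs.condition_costs.items()},
            prevalence=inputs.prevalence,
        )
        direct, _ = accumulate_costs(fixture_trajectory, inputs, "direct")
        societal, _ = accumulate_costs(fixture_trajectory, inputs, "societal")
        indirect, _ = accumulate_costs(fixture_trajectory, indirect_only, "direct")
        assert societal == pytest.approx(direct + indirect, abs=1e-9)


class TestCompareAndScale:
    def test_published_direct_increments(self):
        totals = {"NoDetention": 23652, "FamilyDetention": 24281, "ZeroTolerance": 24887}
        inc = compare_scenarios(totals)
        assert inc == {"NoDetention": 0, "FamilyDetention": 629, "ZeroTolerance": 1235}

    def test_published_societal_increments(self):
        totals = {"NoDetention": 33008, "FamilyDetention": 33790, "ZeroTolerance": 34544}
        inc = compare_scenarios(totals)
        assert inc["FamilyDetention"] == 782
        assert inc["ZeroTolerance"] == 1536

    def test_identical_totals_zero_increments(self):
        inc = compare_scenarios({"NoDetention": 5.0, "A": 5.0, "B": 5.0})
        assert all(v == 0 for v in inc.values())

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            compare_scenarios({"A": 1.0}, reference="NoDetention")

    def test_cohort_products(self):
        assert scale_to_cohort(629, CohortSpec("cohort1", 2342)) == 1_473_118
        assert scale_to_cohort(1536, CohortSpec("cohort3", 23725)) == 36_441_600
        assert scale_to_cohort(0, CohortSpec("any", 99999)) == 0

    def test_budget_scaling_linearity(self):
        cohort = CohortSpec("c", 16790)
        assert (scale_to_cohort(629, cohort) + scale_to_cohort(606, cohort)
                == scale_to_cohort(629 + 606, cohort))

    def test_invalid_cohort_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec("bad", 0)


class TestPipelineOrdering:
    def test_policy_ordering_and_horizon_growth(self, config):
        df = tc.evaluate_policies(config)
        for (persp, h), grp in df.groupby(["perspective", "horizon"]):
            by_name = grp.set_index("scenario")["total"]
            assert by_name["NoDetention"] <= by_name["FamilyDetention"] \
                   <= by_name["ZeroTolerance"]
        # 10-year totals exceed 5-year totals for every scenario/perspective
        wide = df.pivot_table(index=["scenario", "perspective"],
                              columns="horizon", values="total")
        assert (wide[10] >= wide[5]).all()

    def test_fixture_per_child_totals_reproduce_published_increments(self):
        # with the published per-child totals injected as scenario results,
        # the comparison stage reproduces every published budget figure
        per_child = fixtures.published_per_child_totals()
        published = fixtures.published_cohort_incrementals()
        for _, row in per_child.iterrows():
            totals = {s: row[s] for s in
                      ("NoDetention", "FamilyDetention", "ZeroTolerance")}
            inc = compare_scenarios(totals)
            sel = published[(published.perspective == row.perspective)
                            & (published.horizon == row.horizon)]
            for _, p in sel.iterrows():
                got = scale_to_cohort(inc[p.scenario],
                                      CohortSpec(p.cohort, fixtures.COHORT_SIZES[p.cohort]))
                tol = 5 if (p.perspective, p.horizon, p.scenario, p.cohort) == \
                    ("societal", 5, "FamilyDetention", "cohort1") else 0
                assert abs(got - p.published_incremental) <= tol
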