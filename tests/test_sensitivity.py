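"""Deterministic and probabilistic sensitivity analyses."""

import numpy as np
import pytest
from scipy.stats import lognorm

import traumacost as tc
from traumacost.config import ConfigError, config_to_raw, revalidate, set_config_path
from traumacost.pipeline import evaluate_policies
from traumacost.sensitivity import (lognormal_from_ci, one_way_dsa, run_psa,
                                    trauma_fraction_sweep)


def _zt_incremental(config, perspective="direct", horizon=5):
    df = evaluate_policies(config)
    sel = df[(df.scenario == "ZeroTolerance") & (df.perspective == perspective)
             & (df.horizon == horizon)]
    return float(sel["incremental"].iloc[0])


class TestOneWayDSA:
    def test_degenerate_range_zero_spread(self, config):
        base_cost = config.costs.conditions["depression"].direct
        rng = [{"path": "costs.conditions.depression.direct",
                "low": base_cost, "high": base_cost}]
        table = one_way_dsa(rng, config)
        assert table["spread"].iloc[0] == 0.0
        assert table["outcome_at_low"].iloc[0] == table["outcome_at_base"].iloc[0]

    def test_base_values_reproduce_base_case_exactly(self, config):
        base = _zt_incremental(config)
        table = one_way_dsa(config.dsa_ranges, config)
        assert (table["outcome_at_base"] == base).all()

    def test_spread_matches_direct_reruns(self, config):
        # oracle: two direct pipeline evaluations at the range endpoints
        path = "costs.conditions.ptsd.direct"
        low, high = 2000.0, 6000.0
        raw = config_to_raw(config)
        vals = [_zt_incremental(revalidate(set_config_path(raw, path, v)))
                for v in (low, high)]
        table = one_way_dsa([{"path": path, "low": low, "high": high}], config)
        assert table["spread"].iloc[0] == pytest.approx(abs(vals[1] - vals[0]), abs=1e-9)

    def test_tornado_order_and_nonnegative_spreads(self, config):
        table = one_way_dsa(config.dsa_ranges, config)
        assert sorted(table["parameter"]) == sorted(r.path for r in config.dsa_ranges)
        assert (table["spread"] >= 0).all()
        assert (table["spread"].diff().dropna() <= 1e-12).all()

    def test_depression_cost_dominates_total_cost_tornado(self, config):
        # one-way variation of per-child TOTAL cost: the depression cost
        # range drives the tornado in both perspectives under the packaged
        # ranges, where depression dominates the cost mix
        for persp in ("direct", "societal"):
            table = one_way_dsa(config.dsa_ranges, config, outcome="total",
                                perspective=persp)
            assert table["parameter"].iloc[0] == "costs.conditions.depression.direct"

    def test_unknown_parameter_path_rejected(self, config):
        with pytest.raises(ConfigError, match="not found"):
            one_way_dsa([{"path": "costs.nonexistent", "low": 0, "high": 1}], config)


class TestTraumaFractionSweep:
    def test_zero_fraction_zero_incremental(self, config):
        table = trauma_fraction_sweep(config)
        assert table["incremental_direct"].iloc[0] == 0.0
        assert table["incremental_societal"].iloc[0] == 0.0

    def test_full_fraction_equals_zero_tolerance_incremental(self, config):
        table = trauma_fraction_sweep(config)
        for persp in ("direct", "societal"):
            assert table[f"incremental_{persp}"].iloc[-1] == \
                pytest.approx(_zt_incremental(config, persp), abs=1e-9)

    def test_increments_exactly_linear_in_fraction(self, config):
        # mixture-in, linear-through: per-10% steps are constant to rounding
        table = trauma_fraction_sweep(config)
        for persp in ("direct", "societal"):
            steps = np.diff(table[f"incremental_{persp}"])
            assert np.allclose(steps, steps[0], atol=1e-8)

    def test_out_of_range_fraction_rejected(self, config):
        with pytest.raises(ValueError):
            trauma_fraction_sweep(config, fractions=[0.0, 1.5])


class TestRunPSA:
    def test_degenerate_spec_reproduces_deterministic_result(self, config):
        raw = config_to_raw(config)
        raw["psa"]["parameters"] = []
        cfg = revalidate(raw)
        res = run_psa(cfg, iterations=5)
        det = _zt_incremental(config)
        assert np.allclose(res.draws["incremental_ZeroTolerance_direct"], det)

    def test_lognormal_or_sampling_reproduces_ci_quantiles(self):
        mu, sigma = lognormal_from_ci(1.141, 1.330)
        # closed-form check against scipy's lognormal quantiles
        assert lognorm.ppf(0.025, sigma, scale=np.exp(mu)) == pytest.approx(1.141, abs=1e-9)
        assert lognorm.ppf(0.975, sigma, scale=np.exp(mu)) == pytest.approx(1.330, abs=1e-9)
        rng = np.random.default_rng(1)
        draws = rng.lognormal(mu, sigma, size=200_000)
        assert np.quantile(draws, 0.025) == pytest.approx(1.141, abs=0.01)
        assert np.quantile(draws, 0.975) == pytest.approx(1.330, abs=0.01)

    def test_seeded_reproducibility(self, config):
        a = run_psa(config, iterations=20, seed=99)
        b = run_psa(config, iterations=20, seed=99)
        assert a.draws.equals(b.draws)

    def test_sampled_parameters_recorded_with_draws(self, config):
        res = run_psa(config, iterations=10)
        assert "param::trauma_effect.or" in res.draws.columns
        assert (res.draws["param::trauma_effect.or"] > 0).all()

    def test_mean_stable_as_iterations_double(self, config):
        a = run_psa(config, iterations=100, seed=5)
        b = run_psa(config, iterations=200, seed=5)
        col = "incremental_ZeroTolerance_direct"
        se = b.draws[col].std() / np.sqrt(len(b.draws))
        assert abs(a.draws[col].mean() - b.draws[col].mean()) < 2 * se + 1e-9

    def test_incremental_summary_brackets_point_estimate(self, config):
        res = run_psa(config, iterations=300)
        s = res.summary["incremental_ZeroTolerance_direct"]
        det = _zt_incremental(config)
        assert s["p2.5"] < det < s["p97.5"]
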