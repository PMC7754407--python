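"""Sensitivity analyses: one-way deterministic, exposure sweep, and PSA.

One-way deterministic sensitivity analysis (DSA) re-runs the full
pipeline with a single input set to its low then high value and ranks
inputs by the spread of the chosen outcome (tornado order). The exposure
sweep varies the fraction of children assumed to experience one
additional policy-related trauma from 0% to 100% in 10% increments.
Probabilistic sensitivity analysis (PSA) samples inputs jointly from
per-parameter distributions chosen by support — lognormal for the odds
ratio, gamma for costs, beta for probabilities — and reports the
empirical distribution of per-child and incremental costs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import (ConfigError, DSARangeCfg, ModelConfig, config_to_raw,
                     revalidate, set_config_path)
from .pipeline import evaluate_policies
from .scenarios import PolicyScenario

__all__ = ["one_way_dsa", "trauma_fraction_sweep", "run_psa", "PSAResult",
           "lognormal_from_ci", "tornado_plot"]


def _get_path(raw: dict, path: str):
    node = raw
    for part in path.split("."):
        if isinstance(node, list):
            node = node[int(part)]
        elif isinstance(node, dict) and part in node:
            node = node[part]
        else:
            raise ConfigError(f"config path not found: {path} (at {part!r})")
    return node


def _outcome(df: pd.DataFrame, outcome: str, scenario: str, perspective: str,
             horizon: int) -> float:
    sel = df[(df["scenario"] == scenario) & (df["perspective"] == perspective)
             & (df["horizon"] == horizon)]
    if sel.empty:
        raise ValueError(f"no result for {scenario}/{perspective}/{horizon}")
    col = "incremental" if outcome == "incremental" else "total"
    return float(sel[col].iloc[0])


def one_way_dsa(ranges, config: ModelConfig, outcome: str = "incremental",
                scenario: str = "ZeroTolerance", perspective: str = "direct",
                horizon: int = 5) -> pd.DataFrame:
    """One-way DSA over configured high-low ranges, in tornado order.

    For each parameter the full pipeline is re-run with only that
    parameter set to its low, then high, value; the spread is the
    absolute difference of the outcome between the two runs. Rows are
    sorted by spread descending. ``outcome`` is "incremental" or "total"
    for the given scenario/perspective/horizon.
    """
    raw = config_to_raw(config)
    base_df = evaluate_policies(config)
    base_val = _outcome(base_df, outcome, scenario, perspective, horizon)
    rows = []
    for rng in ranges:
        if not isinstance(rng, DSARangeCfg):
            rng = DSARangeCfg.model_validate(rng)
        base_param = _get_path(raw, rng.path)
        if not rng.low <= base_param <= rng.high:
            raise ConfigError(
                f"DSA range for {rng.path}: base value {base_param} outside "
                f"[{rng.low}, {rng.high}]")
        vals = {}
        for bound, value in (("low", rng.low), ("high", rng.high)):
            cfg_b = revalidate(set_config_path(raw, rng.path, value))
            vals[bound] = _outcome(evaluate_policies(cfg_b), outcome,
                                   scenario, perspective, horizon)
        rows.append({
            "parameter": rng.path, "base_value": base_param,
            "low_input": rng.low, "high_input": rng.high,
            "outcome_at_base": base_val,
            "outcome_at_low": vals["low"], "outcome_at_high": vals["high"],
            "spread": abs(vals["high"] - vals["low"]),
        })
    df = pd.DataFrame(rows)
    return df.sort_values("spread", ascending=False, kind="stable").reset_index(drop=True)


def trauma_fraction_sweep(config: ModelConfig, fractions=None,
                          horizon: int = 5) -> pd.DataFrame:
    """Incremental per-child cost as the exposed fraction rises 0% -> 100%.

    Each fraction defines a policy in which that share of children
    experiences one additional trauma; the incremental is taken against
    the 0% run. Because the starting distribution is linear in the
    mixture weight and cost accumulation is linear in the distribution,
    increments per step are exactly constant.
    """
    if fractions is None:
        fractions = np.round(np.arange(0.0, 1.0001, 0.1), 10)
    fractions = list(fractions)
    if any(f < 0 or f > 1 for f in fractions):
        raise ValueError("fractions must lie in [0, 1]")
    base = config.base_distribution()
    or_point = config.trauma_effect.or_point
    tm = config.to_transition_model()
    mort = config.to_mortality_table()
    inputs = config.to_cost_inputs()

    from .costs import accumulate_costs
    from .markov import run_trajectory
    from .scenarios import initial_distribution

    totals = {}
    for f in fractions:
        sc = PolicyScenario(f"sweep_{f:.1f}", float(f))
        init = initial_distribution(base, sc, or_point)
        traj = run_trajectory(init, tm, mort, config.start_age, horizon)
        totals[f] = {
            p: accumulate_costs(traj, inputs, p, config.discount_rate)[0]
            for p in ("direct", "societal")
        }
    ref = totals[fractions[0]] if fractions[0] == 0.0 else None
    if ref is None:
        sc0 = PolicyScenario("sweep_0", 0.0)
        traj0 = run_trajectory(initial_distribution(base, sc0, or_point),
                               tm, mort, config.start_age, horizon)
        ref = {p: accumulate_costs(traj0, inputs, p, config.discount_rate)[0]
               for p in ("direct", "societal")}
    return pd.DataFrame([
        {
            "fraction": f,
            "incremental_direct": totals[f]["direct"] - ref["direct"],
            "incremental_societal": totals[f]["societal"] - ref["societal"],
        }
        for f in fractions
    ])


def lognormal_from_ci(ci_low: float, ci_high: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given 2.5/97.5 percentiles."""
    if not 0 < ci_low <= ci_high:
        raise ValueError("require 0 < ci_low <= ci_high")
    z = norm.ppf(0.975)
    mu = (np.log(ci_low) + np.log(ci_high)) / 2.0
    sigma = (np.log(ci_high) - np.log(ci_low)) / (2.0 * z)
    return float(mu), float(sigma)


def _sample_parameter(rng: np.random.Generator, dist: str, params: dict, size: int) -> np.ndarray:
    if dist == "lognormal":
        if "ci_low" in params:
            mu, sigma = lognormal_from_ci(params["ci_low"], params["ci_high"])
        else:
            mu, sigma = params["mu"], params["sigma"]
        return rng.lognormal(mu, sigma, size=size)
    if dist == "gamma":
        mean, sd = params["mean"], params["sd"]
        if mean <= 0 or sd <= 0:
            raise ConfigError("gamma parameters need mean > 0 and sd > 0")
        shape = (mean / sd) ** 2
        scale = sd**2 / mean
        return rng.gamma(shape, scale, size=size)
    if dist == "beta":
        if "alpha" in params:
            a, b = params["alpha"], params["beta"]
        else:
            mean, n = params["mean"], params["n"]
            a, b = mean * n, (1 - mean) * n
        if a <= 0 or b <= 0:
            raise ConfigError("beta parameters must be positive")
        return rng.beta(a, b, size=size)
    raise ConfigError(f"unknown PSA distribution {dist!r}")


@dataclass
class PSAResult:
    """Raw PSA draws and summary statistics."""

    draws: pd.DataFrame
    summary: dict


def run_psa(config: ModelConfig, iterations: int | None = None,
            seed: int | None = None, horizon: int = 5) -> PSAResult:
    """Monte Carlo PSA: joint parameter sampling, full-pipeline evaluation.

    Each iteration draws every configured parameter from its distribution,
    re-runs the pipeline and records per-child totals and incrementals for
    every scenario and perspective at the given horizon. Degenerate
    specifications (no parameters) reproduce the deterministic result in
    every draw. Seeded and reproducible.
    """
    spec = config.psa
    iterations = spec.iterations if iterations is None else int(iterations)
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    raw = config_to_raw(config)
    raw["horizons"] = [int(horizon)]  # PSA evaluates a single horizon
    samples = {
        p.path: _sample_parameter(rng, p.dist, p.params, iterations)
        for p in spec.parameters
    }
    records = []
    for i in range(iterations):
        raw_i = raw
        for path, vals in samples.items():
            raw_i = set_config_path(raw_i, path, float(vals[i]))
        cfg_i = revalidate(raw_i)
        df = evaluate_policies(cfg_i)
        df = df[df["horizon"] == horizon]
        rec = {"iteration": i}
        for _, r in df.iterrows():
            key = f"{r['scenario']}_{r['perspective']}"
            rec[f"total_{key}"] = r["total"]
            rec[f"incremental_{key}"] = r["incremental"]
        for path, vals in samples.items():
            rec[f"param::{path}"] = vals[i]
        records.append(rec)
    draws = pd.DataFrame(records)
    outcome_cols = [c for c in draws.columns
                    if c.startswith(("total_", "incremental_"))]
    summary = {
        col: {
            "mean": float(draws[col].mean()),
            "p2.5": float(draws[col].quantile(0.025)),
            "p97.5": float(draws[col].quantile(0.975)),
        }
        for col in outcome_cols
    }
    return PSAResult(draws=draws, summary=summary)


def tornado_plot(dsa_table: pd.DataFrame, path, title: str = "One-way sensitivity") -> None:
    """Optional tornado diagram (cosmetic; the CSV is the tested surface)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = dsa_table.iloc[::-1]
    fig, ax = plt.subplots(figsize=(8, 0.5 * len(df) + 1.5))
    base = df["outcome_at_base"].iloc[0]
    for i, (_, r) in enumerate(df.iterrows()):
        lo, hi = sorted((r["outcome_at_low"], r["outcome_at_high"]))
        ax.barh(i, hi - lo, left=lo, color="#4878d0", edgecolor="black")
    ax.axvline(base, color="black", lw=1)
    ax.set_yticks(range(len(df)), df["parameter"])
    ax.set_xlabel("outcome (2018 USD)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
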