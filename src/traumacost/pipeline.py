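"""End-to-end evaluation and report writing.

``evaluate_policies`` runs the deterministic core for one configuration:
baseline severity distribution -> per-policy starting distribution
(odds-ratio shift on the exposed fraction) -> Markov trajectory ->
per-child cost accumulation per perspective and horizon -> incrementals
versus the reference policy -> cohort budget impact. ``run_full_analysis``
adds the sensitivity analyses and writes the full result bundle (CSV
reports, JSON metadata, manifest with content hashes) to a run directory.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import ModelConfig
from .costs import accumulate_costs, compare_scenarios, scale_to_cohort
from .markov import run_trajectory
from .scenarios import initial_distribution

__all__ = ["evaluate_policies", "policy_table", "run_full_analysis", "RunBundle"]

REFERENCE_SCENARIO = "NoDetention"
PERSPECTIVES = ("direct", "societal")


def evaluate_policies(config: ModelConfig, or_value: float | None = None) -> pd.DataFrame:
    """Per-child totals and incrementals for every policy/perspective/horizon.

    ``or_value`` overrides the per-trauma odds ratio (used for CI-bound
    and PSA runs); by default the config's point estimate is used.
    Returns a tidy frame with columns scenario, perspective, horizon,
    total, incremental.
    """
    base = config.base_distribution()
    effect_or = config.trauma_effect.or_point if or_value is None else float(or_value)
    tm = config.to_transition_model()
    mort = config.to_mortality_table()
    inputs = config.to_cost_inputs()
    scenarios = config.to_scenarios()

    rows = []
    for horizon in config.horizons:
        trajectories = {}
        for sc in scenarios:
            init = initial_distribution(base, sc, effect_or)
            trajectories[sc.name] = run_trajectory(init, tm, mort, config.start_age, horizon)
        for perspective in PERSPECTIVES:
            totals = {
                name: accumulate_costs(traj, inputs, perspective, config.discount_rate)[0]
                for name, traj in trajectories.items()
            }
            inc = compare_scenarios(totals, REFERENCE_SCENARIO)
            for name in totals:
                rows.append({
                    "scenario": name, "perspective": perspective, "horizon": horizon,
                    "total": totals[name], "incremental": inc[name],
                })
    return pd.DataFrame(rows)


def policy_table(config: ModelConfig, with_ci: bool = True) -> pd.DataFrame:
    """Published-style cost table: per-child totals, CI bounds, cohort figures.

    One row per scenario x perspective x horizon with the per-child total,
    the incremental versus the reference policy (with bounds from re-running
    the pipeline at the odds-ratio CI limits when ``with_ci``), and the
    whole-dollar incremental budget impact for each configured cohort.
    """
    point = evaluate_policies(config)
    frames = {"point": point}
    if with_ci:
        frames["low"] = evaluate_policies(config, or_value=config.trauma_effect.ci_low)
        frames["high"] = evaluate_policies(config, or_value=config.trauma_effect.ci_high)
    cohorts = config.to_cohort_specs()
    rows = []
    for _, r in point.iterrows():
        key = (point["scenario"] == r["scenario"]) & \
              (point["perspective"] == r["perspective"]) & (point["horizon"] == r["horizon"])
        row = {
            "scenario": r["scenario"], "perspective": r["perspective"],
            "horizon": int(r["horizon"]),
            "per_child_total": round(r["total"]),
            "per_child_incremental": round(r["incremental"]),
        }
        if with_ci:
            for bound in ("low", "high"):
                b = frames[bound][key].iloc[0]
                row[f"per_child_total_{bound}"] = round(b["total"])
                row[f"per_child_incremental_{bound}"] = round(b["incremental"])
        for cohort in cohorts:
            row[f"incremental_{cohort.label}"] = scale_to_cohort(
                round(r["incremental"]), cohort)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RunBundle:
    """All artifacts of one full analysis run."""

    outdir: Path
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)
    manifest: dict[str, str] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_analysis(config: ModelConfig, outdir: str | Path,
                      psa_iterations: int | None = None) -> RunBundle:
    """Run the full pipeline and write the result bundle to ``outdir``.

    Writes: the policy cost table, the prevalence table, the tornado
    (one-way DSA) table, the exposure-fraction sweep, the PSA summary and
    draws, and a JSON metadata file; every output is listed with a sha256
    content hash in ``manifest.json``. Deterministic given the config
    (all stochastic stages are seeded from it).
    """
    from .sensitivity import one_way_dsa, run_psa, trauma_fraction_sweep

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = RunBundle(outdir=outdir)

    tables = bundle.tables
    tables["policy_costs"] = policy_table(config)
    tables["prevalence"] = config.prevalence_table().to_report_frame()
    horizon = config.horizons[0]
    tables["tornado_direct"] = one_way_dsa(
        config.dsa_ranges, config, outcome="total",
        scenario="ZeroTolerance", perspective="direct", horizon=horizon)
    tables["tornado_societal"] = one_way_dsa(
        config.dsa_ranges, config, outcome="total",
        scenario="ZeroTolerance", perspective="societal", horizon=horizon)
    tables["sweep"] = trauma_fraction_sweep(config=config, horizon=horizon)
    psa = run_psa(config, iterations=psa_iterations, horizon=horizon)
    tables["psa_draws"] = psa.draws

    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=name == "prevalence")

    placeholder_inputs = sorted(
        k for k, v in config.provenance.items() if v != "study")
    bundle.metadata = {
        "package_version": __version__,
        "python_version": platform.python_version(),
        "seeds": {"generator": config.generator.seed, "psa": config.psa.seed},
        "horizons": list(config.horizons),
        "discount_rate": config.discount_rate,
        "currency_note": config.costs.currency_note,
        "placeholder_inputs": placeholder_inputs,
        "psa_summary": psa.summary,
    }
    (outdir / "metadata.json").write_text(json.dumps(bundle.metadata, indent=2, sort_keys=True))
    (outdir / "config_used.json").write_text(
        json.dumps(config.model_dump(by_alias=True), indent=2, sort_keys=True, default=str))

    for path in sorted(outdir.iterdir()):
        if path.name != "manifest.json" and path.is_file():
            bundle.manifest[path.name] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2, sort_keys=True))
    return bundle
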