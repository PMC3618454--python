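"""End-to-end analysis: simulate -> extract -> fit -> turning -> transfer.

One master seed determines every stochastic stage.  The report directory
contains, per condition, the trajectories and encounter events, the pooled
and per-agent movement-length model comparisons, log-binning and
rank/frequency data, the encounter/baseline turning profiles with their test,
and the two cross-environment transfer experiments, plus a summary JSON
stamped with the configuration hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import encounter_response, environment, heavytail_fit, path_transfer
from .environment import Arena
from .errors import SchemaError
from .synthetic_agents import AgentConfig, SimulatedTrial, simulate_cohort
from .trajectory import MovementSample, movement_lengths, write_trajectories

logger = logging.getLogger("forage")

_FLOAT_FMT = "%.6f"


@dataclass
class AnalysisConfig:
    """Configuration of a full analysis run (YAML round-trippable)."""

    seed: int = 0
    out_dir: str = "forage_report"
    arena_radius: float = environment.DEFAULT_RADIUS
    n_items: int = environment.DEFAULT_N_ITEMS
    n_patches: int = environment.DEFAULT_N_PATCHES
    items_per_patch: int = environment.DEFAULT_ITEMS_PER_PATCH
    patch_radius: float = environment.DEFAULT_PATCH_RADIUS
    detection_radius: float = environment.DEFAULT_DETECTION_RADIUS
    n_agents: int = 16
    trials_per_agent: int = 5
    stop_at: int = 90
    dispersed_strategy: str = "levy"
    patched_strategy: str = "ars"
    agent_overrides: dict = field(default_factory=dict)
    collinearity_tol: float = 1e-6
    #: analysis lower cutoff for length fits; lengths below it (e.g. movement
    #: fragments created by fence reflections) are discarded before fitting.
    #: None fits the full sample with a = min(length).
    fit_lower_cutoff: Optional[float] = 1.0
    gof_bins: int = 20
    log_bin_base: float = 2.0
    turning_bin_width: float = 1.0
    turning_max_distance: float = 20.0
    n_perm: int = 999
    transfer_n_sim: int = 100

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = sorted(set(data) - known)
        if bad:
            raise SchemaError(f"unknown configuration keys: {bad}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _env_generator(config: AnalysisConfig, mode: str):
    arena = Arena(radius=config.arena_radius)
    if mode == "dispersed":
        return lambda s: environment.generate_dispersed(arena, config.n_items, seed=s)
    return lambda s: environment.generate_patched(
        arena, config.n_patches, config.items_per_patch, config.patch_radius, seed=s
    )


def _agent_config(config: AnalysisConfig, strategy: str) -> AgentConfig:
    return AgentConfig(
        strategy=strategy,
        detection_radius=config.detection_radius,
        stop_at=config.stop_at,
        **config.agent_overrides,
    )


def _events_frame(trials: list[SimulatedTrial]) -> pd.DataFrame:
    rows = []
    for t in trials:
        for e in t.events:
            rows.append(
                {
                    "agent_id": t.trajectory.agent_id,
                    "trial_id": t.trajectory.trial_id,
                    "item_id": e.item_id,
                    "x": e.position[0],
                    "y": e.position[1],
                    "arc_length": e.arc_length,
                    "vertex_index": e.vertex_index,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["agent_id", "trial_id", "item_id", "x", "y", "arc_length",
                 "vertex_index"],
    )


def _fit_tables(trials: list[SimulatedTrial], config: AnalysisConfig,
                out: Path, label: str) -> dict:
    """Aggregated and per-agent model comparisons (Table 1/2 layout)."""
    samples = [movement_lengths(t.trajectory, config.collinearity_tol) for t in trials]
    if config.fit_lower_cutoff is not None:
        samples = [
            MovementSample(s.lengths[s.lengths >= config.fit_lower_cutoff], s.labels)
            for s in samples
        ]
    pooled = MovementSample.pool(samples)
    fits = heavytail_fit.fit_all(pooled)
    comp = heavytail_fit.compare_models(fits)
    gof = heavytail_fit.g_test(pooled, fits[comp.best_model], config.gof_bins)
    # %.6g keeps astronomically large evidence ratios in scientific notation
    comp.to_frame().to_csv(out / f"model_comparison_{label}.csv", index=False,
                           float_format="%.6g")
    # per-agent comparisons: pool each agent's trials
    by_agent: dict[str, list[MovementSample]] = {}
    for t, s in zip(trials, samples):
        by_agent.setdefault(t.trajectory.agent_id, []).append(s)
    rows = []
    for agent in sorted(by_agent):
        sample = MovementSample.pool(by_agent[agent])
        agent_fits = heavytail_fit.fit_all(sample)
        agent_comp = heavytail_fit.compare_models(agent_fits)
        agent_gof = heavytail_fit.g_test(
            sample, agent_fits[agent_comp.best_model], config.gof_bins
        )
        rows.append(
            {
                "agent_id": agent,
                "n": len(sample),
                "best_model": agent_comp.best_model,
                "best_mu_or_lam": list(agent_fits[agent_comp.best_model].params.values())[0],
                "gof_p": agent_gof.p_value,
            }
        )
    per_agent = pd.DataFrame(rows)
    per_agent.to_csv(out / f"per_agent_fits_{label}.csv", index=False,
                     float_format=_FLOAT_FMT)
    proportions = {
        m: float((per_agent["best_model"] == m).mean())
        for m in heavytail_fit.MODELS
    }
    logbin = heavytail_fit.log_bin_slope(pooled, base=config.log_bin_base)
    # rank/frequency data: count of lengths >= x at each observed x
    x = np.sort(pooled.lengths)
    pd.DataFrame({"length": x, "n_geq": np.arange(len(x), 0, -1)}).to_csv(
        out / f"rank_frequency_{label}.csv", index=False, float_format=_FLOAT_FMT
    )
    return {
        "n": len(pooled),
        "best_model": comp.best_model,
        "evidence_ratios": {k: float(v) for k, v in comp.evidence_ratios.items()},
        "gof": {"G": gof.G, "df": gof.df, "p": gof.p_value},
        "proportion_best_by_model": proportions,
        "log_bin_slope": logbin.slope,
        "log_bin_stderr": logbin.stderr,
    }


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run the full pipeline and write the report bundle; returns the summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(config.seed)
    seeds = {name: int(master.integers(2**31)) for name in
             ("dispersed", "patched", "baseline_d", "baseline_p",
              "transfer_dp", "transfer_pd", "tests")}
    summary: dict = {"config_hash": config.config_hash, "seed": config.seed}
    arena = Arena(radius=config.arena_radius)
    cohorts: dict[str, list[SimulatedTrial]] = {}
    for mode, strategy in (
        ("dispersed", config.dispersed_strategy),
        ("patched", config.patched_strategy),
    ):
        t0 = time.perf_counter()
        trials = simulate_cohort(
            config.n_agents,
            config.trials_per_agent,
            _agent_config(config, strategy),
            _env_generator(config, mode),
            seed=seeds[mode],
            arena=arena,
        )
        cohorts[mode] = trials
        write_trajectories([t.trajectory for t in trials],
                           out / f"trajectories_{mode}.csv")
        _events_frame(trials).to_csv(out / f"events_{mode}.csv", index=False,
                                     float_format=_FLOAT_FMT)
        summary[mode] = _fit_tables(trials, config, out, mode)
        summary[mode]["strategy"] = strategy
        logger.info("condition %s simulated+fitted in %.1fs", mode,
                    time.perf_counter() - t0)

    # turning profiles vs. baseline, per condition
    for mode, bl_seed in (("dispersed", "baseline_d"), ("patched", "baseline_p")):
        trials = cohorts[mode]
        prof = encounter_response.turning_profile(
            trials, config.turning_bin_width, config.turning_max_distance,
            condition=f"experiment {mode}",
        )
        base = encounter_response.baseline_profile(
            trials, seed=seeds[bl_seed], bin_width=config.turning_bin_width,
            max_distance=config.turning_max_distance, condition=f"random {mode}",
        )
        pd.concat([prof.to_frame(), base.to_frame()]).to_csv(
            out / f"turning_profile_{mode}.csv", index=False, float_format=_FLOAT_FMT
        )
        test = encounter_response.compare_profiles(
            prof, base, method="permutation", n_perm=config.n_perm,
            seed=seeds["tests"],
        )
        anova = encounter_response.compare_profiles(
            prof, base, method="rm_anova", seed=seeds["tests"]
        )
        summary[f"turning_{mode}"] = {
            "mean_difference_deg": test.mean_difference,
            "permutation_p": test.p_value,
            "rm_anova_F": anova.statistic,
            "rm_anova_p": anova.p_value,
        }

    # path transfer in both directions
    for src, dst, key in (("dispersed", "patched", "transfer_dp"),
                          ("patched", "dispersed", "transfer_pd")):
        native_ref = np.array(
            [len(t.events) / (t.trajectory.path_length / 100.0) for t in cohorts[dst]]
        )
        res = path_transfer.transfer_experiment(
            cohorts[src],
            _env_generator(config, dst),
            n_sim=config.transfer_n_sim,
            seed=seeds[key],
            detection_radius=config.detection_radius,
            reference=native_ref,
            arena=arena,
        )
        res.to_frame().to_csv(out / f"{key}.csv", index=False,
                              float_format=_FLOAT_FMT)
        summary[key] = {
            "difference_mean": res.difference_mean,
            "difference_sd": res.difference_sd,
            "t": res.t_statistic,
            "p": res.p_value,
            "p_permutation": res.p_permutation,
        }

    config.to_yaml(out / "config.yaml")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
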