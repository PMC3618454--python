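"""Synthetic forager agents with the statistical structure the analysis assumes.

Two reference strategies:

* a resource-blind walker whose movement lengths are i.i.d. draws from a
  truncated power law (``levy``) or truncated exponential (``brownian``) and
  whose turns are drawn from a fixed low-dispersion distribution regardless of
  encounter history — i.e. a stationary-increment movement process; and
* an encounter-sensitive area-restricted-search walker (``ars``) that moves
  like the extensive walker until it collects an item, then switches to an
  intensive mode (short movements, wide uniform turns) until it has travelled
  a give-up distance D without a further encounter.

Trials follow the default foraging protocol: a circular 110 m arena, destructive
collection at 0.75 m, and termination once 90 items are collected (or at a
step cap).  The fence reflects the heading specularly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np

from .distributions import TruncatedExponential, TruncatedPareto
from .environment import (
    DEFAULT_DETECTION_RADIUS,
    Arena,
    EncounterEvent,
    ResourceMap,
    segment_entries,
)
from .trajectory import Trajectory

STRATEGIES = ("levy", "brownian", "ars")


@dataclass
class AgentConfig:
    """Parameters of a simulated forager.

    ``mu`` and ``length_bounds`` (a, b) define the truncated power law from
    which extensive movement lengths are drawn; ``brownian_rate`` replaces it
    for the Brownian strategy.  ``extensive_turn_sd`` (degrees) is the normal
    spread of turns between extensive movements; in intensive mode turns are
    uniform over +/- ``intensive_turn_range`` and movement lengths are short
    exponential excursions of scale ``intensive_length_scale`` above the lower
    cutoff.  ``intensive_distance`` D is the give-up distance: travelled
    distance without an encounter after which the walker reverts to extensive
    search.
    """

    strategy: str = "levy"
    mu: float = 2.0
    length_bounds: tuple[float, float] = (1.0, 110.0)
    brownian_rate: float = 0.2
    extensive_turn_sd: float = 20.0
    intensive_turn_range: float = 75.0
    intensive_distance: float = 20.0
    intensive_length_scale: float = 1.0
    detection_radius: float = DEFAULT_DETECTION_RADIUS
    step_cap: int = 100_000
    stop_at: int = 90
    start: str = "center"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        a, b = self.length_bounds
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not (a > 0 and b > a):
            raise ValueError("length bounds must satisfy 0 < a < b")
        if self.intensive_distance < 0:
            raise ValueError("give-up distance must be non-negative")
        if self.stop_at < 1:
            raise ValueError("collection target must be at least 1")
        if self.step_cap < 1:
            raise ValueError("step cap must be at least 1")


@dataclass
class SimulatedTrial:
    """One simulated foraging trial: path, encounters, and how it ended."""

    trajectory: Trajectory
    events: list
    terminated_by: str  # "target_reached" | "step_cap"

    @property
    def n_collected(self) -> int:
        return len(self.events)


def _wrap_angle(theta: float) -> float:
    return (theta + np.pi) % (2.0 * np.pi) - np.pi


def _fence_distance(pos: np.ndarray, direction: np.ndarray, center: np.ndarray,
                    radius: float) -> float:
    """Distance along ``direction`` from ``pos`` to the arena fence."""
    rel = pos - center
    pd_ = float(rel @ direction)
    disc = pd_ * pd_ + radius * radius - float(rel @ rel)
    return max(-pd_ + np.sqrt(max(disc, 0.0)), 0.0)


def simulate_trial(config: AgentConfig, env: ResourceMap,
                   arena: Optional[Arena] = None,
                   rng: Optional[np.random.Generator] = None) -> SimulatedTrial:
    """Run one trial of the configured walker in ``env``.

    The environment's collected flags are reset at the start and updated in
    place (destructive foraging within the trial).
    """
    arena = arena or env.arena
    rng = np.random.default_rng(config.seed) if rng is None else rng
    a, b = config.length_bounds
    ext_len = (
        TruncatedExponential(config.brownian_rate, a, b)
        if config.strategy == "brownian"
        else TruncatedPareto(config.mu, a, b)
    )
    center = np.asarray(arena.center, dtype=float)
    pos = center.copy() if config.start == "center" else np.asarray(config.start, float)
    heading = float(rng.uniform(0.0, 2.0 * np.pi))
    ars = config.strategy == "ars"
    # ARS reacts to an encounter only for a positive give-up distance; D = 0
    # degenerates exactly to the extensive-only (resource-blind) walker.
    react = ars and config.intensive_distance > 0

    env.reset_collected()
    vertices = [pos.copy()]
    events: list[EncounterEvent] = []
    arc = 0.0
    mode = "extensive"
    last_enc_arc = -np.inf
    terminated_by = "step_cap"
    r_d = config.detection_radius
    target = config.stop_at

    for _ in range(config.step_cap):
        if mode == "extensive":
            heading = _wrap_angle(heading + np.radians(rng.normal(0.0, config.extensive_turn_sd)))
            length = float(ext_len.ppf(rng.uniform()))
        else:
            heading = _wrap_angle(
                heading + np.radians(rng.uniform(-config.intensive_turn_range,
                                                 config.intensive_turn_range))
            )
            length = min(a + rng.exponential(config.intensive_length_scale), b)
        remaining = length
        while remaining > 1e-12:
            direction = np.array([np.cos(heading), np.sin(heading)])
            t_fence = _fence_distance(pos, direction, center, arena.radius)
            seg = min(remaining, t_fence)
            if seg <= 1e-12:
                # pointing outward while on the fence: reflect and retry
                normal = (pos - center) / arena.radius
                direction = direction - 2.0 * float(direction @ normal) * normal
                heading = float(np.arctan2(direction[1], direction[0]))
                continue
            new = pos + seg * direction
            # encounter detection over the swept sub-segment
            live = np.nonzero(~env.collected)[0]
            truncate_at: Optional[float] = None
            if len(live):
                idx, t_entry = segment_entries(pos, new, env.positions[live], r_d)
                for k_i, t in zip(idx, t_entry):
                    if react and truncate_at is not None and t > truncate_at:
                        break
                    item = int(live[k_i])
                    env.collected[item] = True
                    events.append(
                        EncounterEvent(
                            item_id=int(env.item_ids[item]),
                            position=tuple(env.positions[item]),
                            arc_length=arc + float(t),
                            vertex_index=len(vertices) - 1,
                        )
                    )
                    if react and truncate_at is None:
                        truncate_at = float(t)
                    if len(events) >= target:
                        break
            if react and truncate_at is not None and truncate_at < seg:
                # the walker stops at the first encounter and responds
                new = pos + truncate_at * direction
                seg = truncate_at
                remaining = 0.0
            if seg > 1e-12:
                vertices.append(new.copy())
                arc += seg
                pos = new
                remaining -= seg
            if ars and events and events[-1].arc_length > last_enc_arc:
                last_enc_arc = events[-1].arc_length
                if react:
                    mode = "intensive"
            if mode == "intensive" and arc - last_enc_arc > config.intensive_distance:
                mode = "extensive"
            if len(events) >= target:
                remaining = 0.0
                break
            if remaining > 1e-12:
                # fence hit: specular reflection of the heading
                normal = (pos - center) / arena.radius
                direction = np.array([np.cos(heading), np.sin(heading)])
                direction = direction - 2.0 * float(direction @ normal) * normal
                heading = float(np.arctan2(direction[1], direction[0]))
        if len(events) >= target:
            terminated_by = "target_reached"
            break

    if len(vertices) < 2:
        vertices.append(pos + np.array([1e-9, 0.0]))
    traj = Trajectory(np.asarray(vertices), arena=arena)
    return SimulatedTrial(traj, events, terminated_by)


def simulate_levy(config: AgentConfig, env: ResourceMap,
                  arena: Optional[Arena] = None,
                  rng: Optional[np.random.Generator] = None) -> SimulatedTrial:
    """Resource-blind truncated-Levy trial (requires ``strategy='levy'``)."""
    if config.strategy != "levy":
        raise ValueError("simulate_levy requires strategy='levy'")
    return simulate_trial(config, env, arena, rng)


def simulate_ars(config: AgentConfig, env: ResourceMap,
                 arena: Optional[Arena] = None,
                 rng: Optional[np.random.Generator] = None) -> SimulatedTrial:
    """Area-restricted-search trial (requires ``strategy='ars'``)."""
    if config.strategy != "ars":
        raise ValueError("simulate_ars requires strategy='ars'")
    return simulate_trial(config, env, arena, rng)


def simulate_cohort(n_agents: int, trials_per_agent: int, config: AgentConfig,
                    env_generator: Callable[[int], ResourceMap],
                    seed: Optional[int] = None,
                    arena: Optional[Arena] = None) -> list[SimulatedTrial]:
    """Simulate a cohort: fresh environment per trial, labels per agent.

    ``env_generator`` maps an integer seed to a fresh :class:`ResourceMap`
    (destructive collection resets between trials because each trial gets its
    own layout, so destructive collection resets naturally).
    """
    if n_agents < 1 or trials_per_agent < 1:
        raise ValueError("cohort counts must be at least 1")
    master = np.random.default_rng(seed)
    trials: list[SimulatedTrial] = []
    for i in range(n_agents):
        for j in range(trials_per_agent):
            env = env_generator(int(master.integers(2**31)))
            trial_rng = np.random.default_rng(int(master.integers(2**31)))
            trial = simulate_trial(replace(config, seed=None), env, arena, trial_rng)
            trial.trajectory.agent_id = f"A{i:02d}"
            trial.trajectory.trial_id = j
            trials.append(trial)
    return trials
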