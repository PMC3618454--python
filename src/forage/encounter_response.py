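"""Turning response after resource encounters versus a random-location baseline.

Area-restricted search predicts that turning sharpens just after a resource
encounter.  The analysis bins every turn by its along-path distance after an
anchor point — either an actual encounter or a random location sampled
uniformly by arc length along the same trajectories — averages within agents
first (trials pooled per agent), and compares per-agent mean turning over a
short post-anchor window between the two anchor types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyProfileError
from .synthetic_agents import SimulatedTrial
from .trajectory import Trajectory, turning_angles

TrialLike = Union[SimulatedTrial, tuple]

DEFAULT_BIN_WIDTH = 1.0
DEFAULT_MAX_DISTANCE = 20.0
#: Post-anchor window (m) summarized per agent for the primary contrast.
DEFAULT_TEST_WINDOW = (0.0, 5.0)


@dataclass
class TurningProfile:
    """Mean absolute turning angle by distance after anchor points."""

    bin_edges: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    per_agent: np.ndarray  # (n_agents, n_bins); NaN where an agent has no turn
    agent_ids: list
    condition: str = ""

    @property
    def n_agents(self) -> int:
        return len(self.agent_ids)

    def agent_window_means(self, window: tuple[float, float] = DEFAULT_TEST_WINDOW,
                           ) -> np.ndarray:
        """Per-agent mean turning over bins fully inside ``window``."""
        lo, hi = window
        sel = (self.bin_edges[:-1] >= lo - 1e-9) & (self.bin_edges[1:] <= hi + 1e-9)
        if not sel.any():
            raise ValueError("window contains no complete bins")
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.per_agent[:, sel], axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "mean_deg": self.mean,
                "sem_deg": self.sem,
                "condition": self.condition,
            }
        )


@dataclass
class ProfileComparison:
    """Result of testing two turning profiles against each other."""

    statistic: float
    df: tuple
    p_value: float
    method: str
    paired: bool
    mean_difference: float


def _trial_parts(trial: TrialLike) -> tuple[Trajectory, list]:
    if isinstance(trial, SimulatedTrial):
        return trial.trajectory, trial.events
    traj, events = trial
    return traj, list(events)


def _accumulate(trials: Sequence[TrialLike], anchors_per_trial: Sequence[np.ndarray],
                bin_width: float, max_distance: float,
                condition: str) -> TurningProfile:
    n_bins = int(np.ceil(max_distance / bin_width))
    edges = bin_width * np.arange(n_bins + 1)
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    for trial, anchors in zip(trials, anchors_per_trial):
        traj, _ = _trial_parts(trial)
        agent = traj.agent_id
        if agent not in sums:
            sums[agent] = np.zeros(n_bins)
            counts[agent] = np.zeros(n_bins)
        anchors = np.asarray(anchors, dtype=float)
        if len(anchors) == 0:
            continue
        turns = turning_angles(traj)
        if len(turns) == 0:
            continue
        delta = turns.arc_positions[:, None] - anchors[None, :]
        mask = (delta > 0) & (delta <= max_distance)
        t_idx, a_idx = np.nonzero(mask)
        bins = np.minimum((delta[t_idx, a_idx] / bin_width).astype(int), n_bins - 1)
        np.add.at(sums[agent], bins, turns.angles[t_idx])
        np.add.at(counts[agent], bins, 1.0)
    agent_ids = sorted(sums)
    per_agent = np.full((len(agent_ids), n_bins), np.nan)
    for i, agent in enumerate(agent_ids):
        has = counts[agent] > 0
        per_agent[i, has] = sums[agent][has] / counts[agent][has]
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        mean = np.nanmean(per_agent, axis=0)
        n_valid = np.sum(~np.isnan(per_agent), axis=0)
        sd = np.nanstd(per_agent, axis=0, ddof=1)
    sem = np.where(n_valid > 1, sd / np.sqrt(np.maximum(n_valid, 1)), np.nan)
    return TurningProfile(edges, mean, sem, per_agent, agent_ids, condition)


def turning_profile(trials: Sequence[TrialLike],
                    bin_width: float = DEFAULT_BIN_WIDTH,
                    max_distance: float = DEFAULT_MAX_DISTANCE,
                    condition: str = "experiment") -> TurningProfile:
    """Turning as a function of distance after actual encounters."""
    if bin_width <= 0 or max_distance <= 0:
        raise ValueError("bin width and max distance must be positive")
    anchors = []
    total = 0
    for trial in trials:
        _, events = _trial_parts(trial)
        arcs = np.array([e.arc_length for e in events])
        anchors.append(arcs)
        total += len(arcs)
    if total == 0:
        raise EmptyProfileError("no encounters in any trial")
    return _accumulate(trials, anchors, bin_width, max_distance, condition)


def baseline_profile(trials: Sequence[TrialLike],
                     n_anchors_per_trial: Optional[int] = None,
                     seed: Optional[int] = None,
                     bin_width: float = DEFAULT_BIN_WIDTH,
                     max_distance: float = DEFAULT_MAX_DISTANCE,
                     condition: str = "random") -> TurningProfile:
    """Turning after random locations sampled uniformly along each path.

    By default each trial receives as many random anchors as it had actual
    encounters, equalizing statistical weight between the two anchor types.
    """
    if bin_width <= 0 or max_distance <= 0:
        raise ValueError("bin width and max distance must be positive")
    rng = np.random.default_rng(seed)
    anchors = []
    total = 0
    for trial in trials:
        traj, events = _trial_parts(trial)
        if traj.path_length <= 0:
            raise ValueError("cannot place anchors on a zero-length path")
        n = len(events) if n_anchors_per_trial is None else int(n_anchors_per_trial)
        if n_anchors_per_trial is not None and n < 1:
            raise ValueError("need at least one anchor per trial")
        arcs = rng.uniform(0.0, traj.path_length, size=n)
        anchors.append(np.sort(arcs))
        total += n
    if total == 0:
        raise EmptyProfileError("no anchors generated for any trial")
    return _accumulate(trials, anchors, bin_width, max_distance, condition)


def compare_profiles(profile_a: TurningProfile, profile_b: TurningProfile,
                     method: str = "permutation", n_perm: int = 999,
                     seed: Optional[int] = None,
                     window: tuple[float, float] = DEFAULT_TEST_WINDOW,
                     alternative: str = "two-sided") -> ProfileComparison:
    """Test whether post-anchor turning differs between two profiles.

    The unit of analysis is the agent: each agent contributes one mean turning
    angle over ``window``.  When both profiles cover the same agents (e.g.
    encounter vs. baseline anchors on the same cohort) the contrast is
    within-subject (paired); otherwise it is between-cohort.

    ``method='rm_anova'`` gives the F statistic of a one-way repeated-measures
    (paired) or between-groups ANOVA with two levels; ``method='permutation'``
    exchanges condition labels (within agents when paired, across agents
    otherwise) and reports a p-value for the mean difference A - B.
    ``alternative`` applies to the permutation test: ``'two-sided'``,
    ``'greater'`` (A elevated over B, the area-restricted-search prediction),
    or ``'less'``.
    """
    if not np.allclose(profile_a.bin_edges, profile_b.bin_edges):
        raise ValueError("profiles have mismatched bin structure")
    a = profile_a.agent_window_means(window)
    b = profile_b.agent_window_means(window)
    paired = profile_a.agent_ids == profile_b.agent_ids
    rng = np.random.default_rng(seed)
    if paired:
        ok = ~(np.isnan(a) | np.isnan(b))
        d = a[ok] - b[ok]
        n = len(d)
        if n < 2:
            raise ValueError("need at least 2 agents with data for a paired test")
        mean_diff = float(np.mean(d))
        if method == "rm_anova":
            var = float(np.var(d, ddof=1))
            if var == 0.0:
                F, p = 0.0 if mean_diff == 0.0 else np.inf, 1.0 if mean_diff == 0.0 else 0.0
            else:
                F = n * mean_diff**2 / var
                p = float(stats.f.sf(F, 1, n - 1))
            return ProfileComparison(float(F), (1, n - 1), p, method, True, mean_diff)
        if method == "permutation":
            signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
            perm = (signs * d).mean(axis=1)
            p = _perm_pvalue(perm, mean_diff, alternative, n_perm)
            return ProfileComparison(mean_diff, (n,), p, method, True, mean_diff)
        raise ValueError(f"unknown method {method!r}")
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 agents per cohort")
    mean_diff = float(np.mean(a) - np.mean(b))
    if method == "rm_anova":
        F, p = stats.f_oneway(a, b)
        return ProfileComparison(float(F), (1, len(a) + len(b) - 2), float(p),
                                 method, False, mean_diff)
    if method == "permutation":
        pooled = np.concatenate([a, b])
        n_a = len(a)
        perm = np.empty(n_perm)
        for i in range(n_perm):
            rng.shuffle(pooled)
            perm[i] = pooled[:n_a].mean() - pooled[n_a:].mean()
        p = _perm_pvalue(perm, mean_diff, alternative, n_perm)
        return ProfileComparison(mean_diff, (len(a), len(b)), p, method, False,
                                 mean_diff)
    raise ValueError(f"unknown method {method!r}")


def _perm_pvalue(perm: np.ndarray, observed: float, alternative: str,
                 n_perm: int) -> float:
    if alternative == "two-sided":
        hits = np.sum(np.abs(perm) >= abs(observed) - 1e-12)
    elif alternative == "greater":
        hits = np.sum(perm >= observed - 1e-12)
    elif alternative == "less":
        hits = np.sum(perm <= observed + 1e-12)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float((1 + hits) / (n_perm + 1))
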