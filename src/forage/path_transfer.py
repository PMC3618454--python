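"""Cross-environment path-transfer experiment.

To ask whether paths are adapted to the resource layout that produced them,
each path is replayed — as a pure geometric object, with no behavioral
feedback — in freshly generated environments of the *other* layout, after a
rigid rotation about the arena center by a uniformly random angle (randomizing
the initial heading while keeping the path inside the circular fence).
Performance is the number of items destructively encountered per 100 m of
path; the per-path transferred performance is averaged over ``n_sim``
rotations and compared with the native performance of paths generated in the
target layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .environment import DEFAULT_DETECTION_RADIUS, Arena, ResourceMap
from .synthetic_agents import SimulatedTrial
from .trajectory import Trajectory

PathLike = Union[SimulatedTrial, tuple]


def rotate_path(trajectory: Trajectory, angle_deg: float,
                pivot: Optional[Sequence[float]] = None) -> Trajectory:
    """Rigid rotation of a path about ``pivot`` (default: arena center).

    Rotation about the arena center is an isometry of the arena, so rotated
    paths stay inside the fence; movement lengths and turning angles are
    preserved exactly.
    """
    if pivot is None:
        pivot = trajectory.arena.center if trajectory.arena is not None else (0.0, 0.0)
    pivot = np.asarray(pivot, dtype=float)
    theta = np.radians(angle_deg)
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    verts = (trajectory.vertices - pivot) @ rot.T + pivot
    return trajectory.transformed(verts)


def replay_performance(trajectory: Trajectory, env: ResourceMap,
                       detection_radius: float = DEFAULT_DETECTION_RADIUS,
                       per_100m: bool = True) -> float:
    """Items destructively encountered along a replayed path.

    The environment's collected flags are reset first; each item counts at
    most once regardless of how often the path revisits it.  With
    ``per_100m`` (default) the count is normalized to items per 100 m of path
    length, making paths of different lengths comparable.
    """
    length = trajectory.path_length
    if length <= 0:
        raise ValueError("cannot replay a zero-length path")
    env.reset_collected()
    if env.n_items == 0:
        return 0.0
    verts = trajectory.vertices
    p = verts[:-1]
    q = verts[1:]
    d = q - p
    seg_len = np.hypot(d[:, 0], d[:, 1])
    ok = seg_len > 0
    p, q, d, seg_len = p[ok], q[ok], d[ok], seg_len[ok]
    uh = d / seg_len[:, None]
    pts = env.positions
    r2 = detection_radius**2 + 1e-12
    hit = np.zeros(env.n_items, dtype=bool)
    # chunk over segments to bound the (n_seg x n_items) distance matrix
    chunk = max(1, int(4_000_000 // max(env.n_items, 1)))
    for s in range(0, len(p), chunk):
        e = s + chunk
        w = pts[None, :, :] - p[s:e, None, :]  # (m, n, 2)
        proj = np.einsum("mni,mi->mn", w, uh[s:e])
        tc = np.clip(proj, 0.0, seg_len[s:e, None])
        d2 = np.einsum("mni,mni->mn", w, w) - 2.0 * tc * proj + tc**2
        hit |= (d2 <= r2).any(axis=0)
    env.collected[hit] = True
    count = float(hit.sum())
    return count / (length / 100.0) if per_100m else count


@dataclass
class TransferResult:
    """Per-path and cohort-level outcome of a transfer experiment."""

    path_ids: list
    native: np.ndarray
    transferred_mean: np.ndarray
    transferred_sd: np.ndarray
    n_sim: int
    #: per-path native minus mean transferred performance
    difference: np.ndarray
    difference_mean: float
    difference_sd: float
    t_statistic: Optional[float] = None
    t_df: Optional[int] = None
    p_value: Optional[float] = None
    p_permutation: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "path_id": self.path_ids,
                "native_perf": self.native,
                "transferred_mean": self.transferred_mean,
                "transferred_sd": self.transferred_sd,
                "difference": self.difference,
            }
        )

    def by_agent(self) -> pd.DataFrame:
        """Per-agent means over trials (path ids are ``agent/trial``).

        Agents, not individual trials, are the unit of analysis: each agent's
        native and transferred performances are averaged over its pooled
        trials before any cross-cohort test.
        """
        df = self.to_frame()
        df["agent_id"] = [p.split("/")[0] for p in self.path_ids]
        return (
            df.groupby("agent_id")[["native_perf", "transferred_mean", "difference"]]
            .mean()
            .reset_index()
        )


def _path_and_native(item: PathLike, detection_radius: float) -> tuple[Trajectory, float]:
    if isinstance(item, SimulatedTrial):
        length = item.trajectory.path_length
        return item.trajectory, len(item.events) / (length / 100.0)
    traj, native = item
    return traj, float(native)


def transfer_experiment(paths: Sequence[PathLike],
                        env_generator: Callable[[int], ResourceMap],
                        n_sim: int = 100,
                        seed: Optional[int] = None,
                        detection_radius: float = DEFAULT_DETECTION_RADIUS,
                        reference: Optional[np.ndarray] = None,
                        arena: Optional[Arena] = None,
                        fixed_angle: Optional[float] = None) -> TransferResult:
    """Replay each path ``n_sim`` times in freshly generated environments.

    Each replay rotates the path about the arena center by a uniformly random
    angle in [0, 360) (or by ``fixed_angle``, useful for self-transfer checks)
    and regenerates the target-layout environment, as layouts were random per
    trial.  ``reference`` — native performances of a cohort generated in the
    target layout — enables the cross-cohort comparison (Welch t-test plus a
    label-permutation alternative on the per-path means).
    """
    if len(paths) == 0:
        raise ValueError("empty path cohort")
    if n_sim < 1:
        raise ValueError("n_sim must be at least 1")
    rng = np.random.default_rng(seed)
    ids, native, t_mean, t_sd = [], [], [], []
    for item in paths:
        traj, nat = _path_and_native(item, detection_radius)
        pivot = (arena or traj.arena or Arena()).center
        perfs = np.empty(n_sim)
        for s in range(n_sim):
            angle = (
                float(fixed_angle)
                if fixed_angle is not None
                else float(rng.uniform(0.0, 360.0))
            )
            env = env_generator(int(rng.integers(2**31)))
            rotated = rotate_path(traj, angle, pivot=pivot)
            perfs[s] = replay_performance(rotated, env, detection_radius)
        ids.append(f"{traj.agent_id}/{traj.trial_id}")
        native.append(nat)
        t_mean.append(float(perfs.mean()))
        t_sd.append(float(perfs.std(ddof=1)) if n_sim > 1 else 0.0)
    native = np.asarray(native)
    t_mean = np.asarray(t_mean)
    diff = native - t_mean
    result = TransferResult(
        path_ids=ids,
        native=native,
        transferred_mean=t_mean,
        transferred_sd=np.asarray(t_sd),
        n_sim=n_sim,
        difference=diff,
        difference_mean=float(diff.mean()),
        difference_sd=float(diff.std(ddof=1)) if len(diff) > 1 else 0.0,
    )
    if reference is not None:
        reference = np.asarray(reference, dtype=float)
        t, p = stats.ttest_ind(t_mean, reference, equal_var=False)
        result.t_statistic = float(t)
        result.t_df = len(t_mean) + len(reference) - 2
        result.p_value = float(p)
        pooled = np.concatenate([t_mean, reference])
        n_a = len(t_mean)
        obs = abs(t_mean.mean() - reference.mean())
        n_perm = 999
        perm = np.empty(n_perm)
        for i in range(n_perm):
            rng.shuffle(pooled)
            perm[i] = abs(pooled[:n_a].mean() - pooled[n_a:].mean())
        result.p_permutation = float((1 + np.sum(perm >= obs - 1e-12)) / (n_perm + 1))
    return result
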