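"""Polyline path model and extraction of movement statistics.

A forager that can either move forward or turn (but not both) produces a
polyline; the distance travelled between two consecutive turns is a *movement
length* and the absolute heading change at a turn is a *turning angle*.  These
two sequences are the raw material for all downstream distribution fitting and
encounter-response analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .environment import Arena
from .errors import FormatError

#: Interior vertices turning by no more than this (degrees) are treated as
#: collinear and merged when extracting movement lengths.
DEFAULT_COLLINEARITY_TOL = 1e-6


@dataclass
class Trajectory:
    """An ordered polyline path of one agent in one trial."""

    vertices: np.ndarray
    agent_id: str = "agent0"
    trial_id: int = 0
    arena: Optional[Arena] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        if len(v) < 2:
            raise ValueError("a trajectory needs at least 2 vertices")
        # normalization: drop consecutive duplicates
        keep = np.ones(len(v), dtype=bool)
        keep[1:] = np.hypot(*(v[1:] - v[:-1]).T) > 1e-12
        v = v[keep]
        if len(v) < 2:
            raise ValueError("trajectory degenerate after removing duplicate vertices")
        if self.arena is not None and not self.arena.contains(v, tol=1e-6).all():
            raise ValueError("trajectory leaves the arena")
        self.vertices = v

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def segment_lengths(self) -> np.ndarray:
        d = np.diff(self.vertices, axis=0)
        return np.hypot(d[:, 0], d[:, 1])

    @property
    def cum_lengths(self) -> np.ndarray:
        """Arc length at each vertex (0 at the start)."""
        return np.concatenate([[0.0], np.cumsum(self.segment_lengths)])

    @property
    def path_length(self) -> float:
        return float(self.segment_lengths.sum())

    def transformed(self, vertices: np.ndarray) -> "Trajectory":
        return Trajectory(vertices, self.agent_id, self.trial_id, self.arena)


@dataclass
class MovementSample:
    """Positive movement lengths (m), possibly pooled across trials/agents."""

    lengths: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float).ravel()
        if len(self.lengths) and not (self.lengths > 0).all():
            raise ValueError("movement lengths must be positive")

    def __len__(self) -> int:
        return len(self.lengths)

    @classmethod
    def pool(cls, samples: Iterable["MovementSample"]) -> "MovementSample":
        samples = list(samples)
        lengths = (
            np.concatenate([s.lengths for s in samples]) if samples else np.empty(0)
        )
        labels: list = []
        for s in samples:
            labels.extend(s.labels)
        return cls(lengths, labels)


@dataclass
class TurnSequence:
    """Absolute turning angles (degrees, in [0, 180]) with arc positions."""

    angles: np.ndarray
    arc_positions: np.ndarray

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float).ravel()
        self.arc_positions = np.asarray(self.arc_positions, dtype=float).ravel()

    def __len__(self) -> int:
        return len(self.angles)


def turning_angles(trajectory: Trajectory) -> TurnSequence:
    """Absolute heading change at every interior vertex, in degrees.

    Paths with fewer than three vertices have no interior vertex and yield an
    empty sequence.
    """
    v = trajectory.vertices
    if len(v) < 3:
        return TurnSequence(np.empty(0), np.empty(0))
    d = np.diff(v, axis=0)
    headings = np.arctan2(d[:, 1], d[:, 0])
    dtheta = np.diff(headings)
    dtheta = (dtheta + np.pi) % (2.0 * np.pi) - np.pi
    angles = np.degrees(np.abs(dtheta))
    return TurnSequence(angles, trajectory.cum_lengths[1:-1])


def movement_lengths(trajectory: Trajectory,
                     collinearity_tol: float = DEFAULT_COLLINEARITY_TOL) -> MovementSample:
    """Distances travelled between consecutive turns.

    Interior vertices whose turning angle does not exceed ``collinearity_tol``
    (degrees) are merged into the surrounding movement.  The path start and end
    act as turn delimiters, so a two-vertex path yields a single length.
    Lengths are travelled (arc) distances between surviving turn vertices, so
    their sum always equals the total path length.
    """
    v = trajectory.vertices
    if len(v) < 2:
        raise ValueError("a trajectory needs at least 2 vertices")
    cum = trajectory.cum_lengths
    if len(v) == 2:
        idx = np.array([0, 1])
    else:
        turns = turning_angles(trajectory).angles
        interior = np.nonzero(turns > collinearity_tol)[0] + 1
        idx = np.concatenate([[0], interior, [len(v) - 1]])
    lengths = np.diff(cum[idx])
    lengths = lengths[lengths > 0]
    return MovementSample(lengths, labels=[(trajectory.agent_id, trajectory.trial_id)])


# ---------------------------------------------------------------------- I/O

_COLUMNS = ["agent_id", "trial_id", "step", "x", "y"]


def write_trajectories(trajectories: Sequence[Trajectory], path) -> None:
    """Write paths as CSV with columns agent_id, trial_id, step, x, y."""
    frames = []
    for t in trajectories:
        frames.append(
            pd.DataFrame(
                {
                    "agent_id": t.agent_id,
                    "trial_id": t.trial_id,
                    "step": np.arange(t.n_vertices),
                    "x": t.vertices[:, 0],
                    "y": t.vertices[:, 1],
                }
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=_COLUMNS)
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_trajectories(path, arena: Optional[Arena] = None) -> list[Trajectory]:
    """Read paths from CSV; step indices must increase within each trial."""
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns: {missing}")
    out: list[Trajectory] = []
    if not len(df):
        return out
    for (agent, trial), grp in df.groupby(["agent_id", "trial_id"], sort=True):
        steps = grp["step"].to_numpy()
        bad = np.nonzero(np.diff(steps) <= 0)[0]
        if len(bad):
            row = grp.index[bad[0] + 1]
            raise FormatError(
                f"non-monotone step index at row {row} "
                f"(agent {agent}, trial {trial})"
            )
        out.append(
            Trajectory(
                grp[["x", "y"]].to_numpy(),
                agent_id=str(agent),
                trial_id=int(trial),
                arena=arena,
            )
        )
    return out
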