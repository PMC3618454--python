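"""Circular foraging arena, resource distributions, and encounter detection.

The modeled system is a fenced circular meadow in which a forager searches for
point resources.  Items are laid out either *dispersed* (independently and
uniformly over the disc) or *patched* (non-overlapping circular patches, items
uniform within each patch).  Foraging is destructive: an item is collected the
first time the path sweeps within the detection radius of it and is never
replaced within a trial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import PackingError

if TYPE_CHECKING:  # pragma: no cover
    from .trajectory import Trajectory

#: Default arena radius (m).
DEFAULT_RADIUS = 110.0
#: Total item count in both resource layouts.
DEFAULT_N_ITEMS = 1440
#: Patch layout: 24 patches of 60 items each, patch radius 8.65 m.
DEFAULT_N_PATCHES = 24
DEFAULT_ITEMS_PER_PATCH = 60
DEFAULT_PATCH_RADIUS = 8.65
#: Distance at which an item is detected and collected (m).
DEFAULT_DETECTION_RADIUS = 0.75


@dataclass(frozen=True)
class Arena:
    """Circular fenced arena.

    Parameters
    ----------
    radius
        Arena radius in meters (default 110 m).
    center
        Arena center in world coordinates.
    """

    radius: float = DEFAULT_RADIUS
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"arena radius must be positive, got {self.radius}")

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Boolean mask: which points lie inside the arena (with tolerance)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        c = np.asarray(self.center, dtype=float)
        return np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1]) <= self.radius + tol


@dataclass(frozen=True)
class EncounterEvent:
    """A destructive resource encounter along a path.

    ``arc_length`` is the cumulative distance travelled when the swept path
    first came within the detection radius of the item.
    """

    item_id: int
    position: tuple[float, float]
    arc_length: float
    vertex_index: int


@dataclass
class ResourceMap:
    """Item positions, optional patch structure, and collected flags."""

    positions: np.ndarray
    arena: Arena = field(default_factory=Arena)
    item_ids: Optional[np.ndarray] = None
    patch_centers: Optional[np.ndarray] = None
    patch_assignment: Optional[np.ndarray] = None
    patch_radius: Optional[float] = None
    collected: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        n = len(self.positions)
        if self.item_ids is None:
            self.item_ids = np.arange(n)
        else:
            self.item_ids = np.asarray(self.item_ids, dtype=int)
            if len(np.unique(self.item_ids)) != n:
                raise ValueError("item ids must be unique")
        if self.collected is None:
            self.collected = np.zeros(n, dtype=bool)
        else:
            self.collected = np.asarray(self.collected, dtype=bool)
        if n and not self.arena.contains(self.positions, tol=1e-6).all():
            raise ValueError("all items must lie inside the arena")
        if self.patch_centers is not None:
            self.patch_centers = np.asarray(self.patch_centers, dtype=float).reshape(-1, 2)
            if self.patch_assignment is None:
                raise ValueError("patched map requires a patch assignment")
            self.patch_assignment = np.asarray(self.patch_assignment, dtype=int)
            if self.patch_radius is not None and n:
                d = np.linalg.norm(
                    self.positions - self.patch_centers[self.patch_assignment], axis=1
                )
                if not (d <= self.patch_radius + 1e-6).all():
                    raise ValueError("item outside its assigned patch")

    @property
    def n_items(self) -> int:
        return len(self.positions)

    @property
    def n_collected(self) -> int:
        return int(self.collected.sum())

    @property
    def is_patched(self) -> bool:
        return self.patch_centers is not None

    def reset_collected(self) -> None:
        self.collected[:] = False

    def copy(self) -> "ResourceMap":
        return ResourceMap(
            positions=self.positions.copy(),
            arena=self.arena,
            item_ids=self.item_ids.copy(),
            patch_centers=None if self.patch_centers is None else self.patch_centers.copy(),
            patch_assignment=None
            if self.patch_assignment is None
            else self.patch_assignment.copy(),
            patch_radius=self.patch_radius,
            collected=self.collected.copy(),
        )

    # ---------------------------------------------------------------- I/O

    def to_frame(self) -> pd.DataFrame:
        patch = (
            self.patch_assignment
            if self.patch_assignment is not None
            else np.full(self.n_items, np.nan)
        )
        return pd.DataFrame(
            {
                "item_id": self.item_ids,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "patch_id": patch,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path, arena: Optional[Arena] = None,
                 patch_centers=None, patch_radius: Optional[float] = None) -> "ResourceMap":
        df = pd.read_csv(path)
        patch = None
        if "patch_id" in df.columns and df["patch_id"].notna().all() and len(df):
            patch = df["patch_id"].to_numpy(dtype=int)
        return cls(
            positions=df[["x", "y"]].to_numpy(),
            arena=arena or Arena(),
            item_ids=df["item_id"].to_numpy(dtype=int),
            patch_centers=patch_centers,
            patch_assignment=patch if patch_centers is not None else None,
            patch_radius=patch_radius,
        )

    def to_json(self, path) -> None:
        payload = {
            "arena": {"radius": self.arena.radius, "center": list(self.arena.center)},
            "patch_radius": self.patch_radius,
            "patch_centers": None
            if self.patch_centers is None
            else self.patch_centers.tolist(),
            "items": [
                {
                    "item_id": int(i),
                    "x": float(x),
                    "y": float(y),
                    "patch_id": None if self.patch_assignment is None else int(p),
                }
                for i, (x, y), p in zip(
                    self.item_ids,
                    self.positions,
                    self.patch_assignment
                    if self.patch_assignment is not None
                    else np.zeros(self.n_items, dtype=int),
                )
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ResourceMap":
        with open(path) as fh:
            payload = json.load(fh)
        arena = Arena(
            radius=payload["arena"]["radius"], center=tuple(payload["arena"]["center"])
        )
        items = payload["items"]
        centers = payload["patch_centers"]
        assignment = (
            np.array([it["patch_id"] for it in items], dtype=int)
            if centers is not None
            else None
        )
        return cls(
            positions=np.array([[it["x"], it["y"]] for it in items]),
            arena=arena,
            item_ids=np.array([it["item_id"] for it in items], dtype=int),
            patch_centers=None if centers is None else np.asarray(centers),
            patch_assignment=assignment,
            patch_radius=payload["patch_radius"],
        )


# ------------------------------------------------------------------ builders


def _uniform_disc(rng: np.random.Generator, n: int, radius: float,
                  center: Sequence[float]) -> np.ndarray:
    """Area-uniform points in a disc (radius via sqrt transform)."""
    r = radius * np.sqrt(rng.uniform(size=n))
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)]) + np.asarray(center, float)


def generate_dispersed(arena: Arena = Arena(), n_items: int = DEFAULT_N_ITEMS,
                       seed: Optional[int] = None) -> ResourceMap:
    """Items i.i.d. uniform over the arena disc (dispersed condition)."""
    if n_items < 0:
        raise ValueError(f"n_items must be non-negative, got {n_items}")
    rng = np.random.default_rng(seed)
    return ResourceMap(
        positions=_uniform_disc(rng, n_items, arena.radius, arena.center).reshape(-1, 2),
        arena=arena,
    )


def generate_patched(arena: Arena = Arena(), n_patches: int = DEFAULT_N_PATCHES,
                     items_per_patch: int = DEFAULT_ITEMS_PER_PATCH,
                     patch_radius: float = DEFAULT_PATCH_RADIUS,
                     seed: Optional[int] = None,
                     max_attempts: int = 1_000_000) -> ResourceMap:
    """Non-overlapping circular patches with uniform items (patched condition).

    Patch centers are sampled uniformly over the disc of radius
    ``R - patch_radius`` (so every patch lies fully inside the fence) and
    accepted only if at least ``2 * patch_radius`` from every accepted center,
    which keeps patch discs pairwise disjoint.  Rejection sampling raises
    :class:`PackingError` once ``max_attempts`` candidates have been drawn.
    """
    if n_patches < 0 or items_per_patch < 0:
        raise ValueError("counts must be non-negative")
    if patch_radius <= 0 or patch_radius >= arena.radius:
        raise ValueError("patch radius must be in (0, arena radius)")
    rng = np.random.default_rng(seed)
    c = np.asarray(arena.center, dtype=float)
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n_patches:
        if attempts >= max_attempts:
            raise PackingError(
                f"placed {len(centers)}/{n_patches} patch centers "
                f"in {max_attempts} attempts"
            )
        cand = _uniform_disc(rng, 1, arena.radius - patch_radius, c)[0]
        attempts += 1
        if all(np.linalg.norm(cand - p) >= 2.0 * patch_radius for p in centers):
            centers.append(cand)
    center_arr = np.asarray(centers).reshape(-1, 2)
    positions = np.concatenate(
        [_uniform_disc(rng, items_per_patch, patch_radius, ctr) for ctr in center_arr]
    ) if n_patches else np.empty((0, 2))
    assignment = np.repeat(np.arange(n_patches), items_per_patch)
    return ResourceMap(
        positions=positions,
        arena=arena,
        patch_centers=center_arr,
        patch_assignment=assignment,
        patch_radius=patch_radius,
    )


# ------------------------------------------------------- encounter detection


def segment_entries(p: np.ndarray, q: np.ndarray, points: np.ndarray,
                    radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Indices and along-segment entry distances of points swept by p->q.

    For each point within ``radius`` of the closed segment, the entry distance
    is the smallest ``t`` in ``[0, |q-p|]`` at which the moving forager is
    within ``radius`` of the point.  Indices are returned sorted by entry
    distance with index as tie-break.
    """
    u = q - p
    seg_len = float(np.hypot(*u))
    if seg_len == 0.0 or len(points) == 0:
        return np.empty(0, dtype=int), np.empty(0)
    uh = u / seg_len
    w = points - p
    proj = w @ uh
    d2 = np.einsum("ij,ij->i", w, w)
    perp2 = np.maximum(d2 - proj**2, 0.0)
    tc = np.clip(proj, 0.0, seg_len)
    close2 = d2 - 2.0 * tc * proj + tc**2
    hit = close2 <= radius**2 + 1e-12
    idx = np.nonzero(hit)[0]
    if len(idx) == 0:
        return idx, np.empty(0)
    s = np.sqrt(np.maximum(radius**2 - perp2[idx], 0.0))
    t_entry = np.clip(proj[idx] - s, 0.0, seg_len)
    order = np.lexsort((idx, t_entry))
    return idx[order], t_entry[order]


def detect_encounters(trajectory: "Trajectory", resource_map: ResourceMap,
                      detection_radius: float = DEFAULT_DETECTION_RADIUS,
                      stop_after: Optional[int] = None) -> list[EncounterEvent]:
    """Destructive first-pass encounters of a path with uncollected items.

    Walks the polyline segment by segment; an uncollected item is collected at
    the earliest arc length at which the swept segment comes within
    ``detection_radius`` of it, and is never re-detected.  ``resource_map``'s
    collected flags are updated in place.  ``stop_after`` optionally caps the
    number of new events (used for trials that end at a collection target).
    """
    if detection_radius <= 0:
        raise ValueError("detection radius must be positive")
    verts = trajectory.vertices
    if len(verts) < 2:
        raise ValueError("trajectory needs at least 2 vertices")
    events: list[EncounterEvent] = []
    arc = 0.0
    for j in range(len(verts) - 1):
        p, q = verts[j], verts[j + 1]
        seg_len = float(np.hypot(*(q - p)))
        if seg_len == 0.0:
            continue
        live = np.nonzero(~resource_map.collected)[0]
        if len(live):
            idx, t_entry = segment_entries(p, q, resource_map.positions[live], detection_radius)
            for k, t in zip(idx, t_entry):
                item = int(live[k])
                resource_map.collected[item] = True
                events.append(
                    EncounterEvent(
                        item_id=int(resource_map.item_ids[item]),
                        position=tuple(resource_map.positions[item]),
                        arc_length=arc + float(t),
                        vertex_index=j,
                    )
                )
                if stop_after is not None and len(events) >= stop_after:
                    return events
        arc += seg_len
    return events
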