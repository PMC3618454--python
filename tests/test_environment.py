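"""Resource-map construction and destructive encounter detection."""

import itertools

import numpy as np
import pytest

from forage import (
    Arena,
    ResourceMap,
    Trajectory,
    detect_encounters,
    generate_dispersed,
    generate_patched,
)
from forage.errors import PackingError

from conftest import rotate


class TestDispersed:
    def test_count_and_containment(self, arena):
        m = generate_dispersed(arena, 1440, seed=1)
        assert m.n_items == 1440
        assert np.hypot(*m.positions.T).max() <= arena.radius

    def test_reproducible_and_empty(self, arena):
        a = generate_dispersed(arena, 100, seed=7)
        b = generate_dispersed(arena, 100, seed=7)
        assert np.array_equal(a.positions, b.positions)
        assert generate_dispersed(arena, 0, seed=1).n_items == 0

    def test_negative_count_rejected(self, arena):
        with pytest.raises(ValueError):
            generate_dispersed(arena, -1, seed=1)

    def test_area_uniform(self, arena):
        # for uniform points on a disc, E[r^2] = R^2/2
        m = generate_dispersed(arena, 100_000, seed=1)
        msd = np.mean(np.hypot(*m.positions.T) ** 2)
        assert msd == pytest.approx(arena.radius**2 / 2, rel=0.01)

    def test_containment_across_seeds(self, arena):
        for seed in range(100):
            m = generate_dispersed(arena, 50, seed=seed)
            assert arena.contains(m.positions).all()


class TestPatched:
    def test_default_layout(self, patched_env):
        assert patched_env.n_items == 1440
        assert len(patched_env.patch_centers) == 24
        d = np.linalg.norm(
            patched_env.positions
            - patched_env.patch_centers[patched_env.patch_assignment],
            axis=1,
        )
        assert d.max() <= 8.65

    def test_single_patch(self, arena):
        m = generate_patched(arena, 1, 60, 8.65, seed=1)
        assert m.n_items == 60
        assert np.linalg.norm(m.positions - m.patch_centers[0], axis=1).max() <= 8.65

    def test_non_overlap_min_center_distance(self, arena):
        m = generate_patched(arena, 24, 60, 8.65, seed=2)
        dmin = min(
            np.linalg.norm(p - q)
            for p, q in itertools.combinations(m.patch_centers, 2)
        )
        assert dmin >= 2 * 8.65

    def test_patches_inside_fence(self, arena):
        for seed in range(30):
            m = generate_patched(arena, seed=seed)
            r = np.hypot(*(m.patch_centers - np.asarray(arena.center)).T)
            assert (r <= arena.radius - m.patch_radius + 1e-9).all()
            assert arena.contains(m.positions).all()

    def test_infeasible_packing_raises(self, arena):
        with pytest.raises(PackingError):
            generate_patched(arena, 50, 1, 20.0, seed=1, max_attempts=2000)


class TestDetectEncounters:
    def _line_map(self, arena, points):
        return ResourceMap(np.asarray(points, dtype=float), arena=arena)

    def test_perpendicular_within_radius(self, arena):
        traj = Trajectory([[0, 0], [10, 0]])
        m = self._line_map(arena, [[5.0, 0.5]])
        events = detect_encounters(traj, m, 0.75)
        assert len(events) == 1
        # entry where the sweep first reaches 0.75 m: 5 - sqrt(0.75^2-0.5^2)
        assert events[0].arc_length == pytest.approx(5 - np.sqrt(0.75**2 - 0.5**2))

    def test_outside_radius_missed(self, arena):
        traj = Trajectory([[0, 0], [10, 0]])
        m = self._line_map(arena, [[5.0, 0.8]])
        assert detect_encounters(traj, m, 0.75) == []

    def test_destructive_single_detection_on_revisit(self, arena):
        traj = Trajectory([[0, 0], [10, 0], [10, 3], [0, 3], [0, 0], [10, 0]])
        m = self._line_map(arena, [[5.0, 0.5]])
        events = detect_encounters(traj, m, 0.75)
        assert len(events) == 1
        assert events[0].vertex_index == 0

    def test_events_sorted_and_flags_match(self, arena, dispersed_env):
        rng = np.random.default_rng(3)
        verts = rng.uniform(-60, 60, size=(40, 2))
        events = detect_encounters(Trajectory(verts), dispersed_env, 0.75)
        arcs = [e.arc_length for e in events]
        assert arcs == sorted(arcs)
        assert dispersed_env.n_collected == len(events)
        ids = [e.item_id for e in events]
        assert len(set(ids)) == len(ids)

    def test_rotation_equivariance(self, arena):
        rng = np.random.default_rng(5)
        verts = rng.uniform(-50, 50, size=(20, 2))
        pts = rng.uniform(-60, 60, size=(200, 2))
        base = detect_encounters(Trajectory(verts), self._line_map(arena, pts), 0.75)
        rot = detect_encounters(
            Trajectory(rotate(verts, 123.0)),
            self._line_map(arena, rotate(pts, 123.0)),
            0.75,
        )
        assert [e.item_id for e in base] == [e.item_id for e in rot]
        np.testing.assert_allclose(
            [e.arc_length for e in base], [e.arc_length for e in rot], atol=1e-9
        )


class TestSerialization:
    def test_csv_round_trip(self, tmp_path, patched_env):
        path = tmp_path / "map.csv"
        patched_env.to_csv(path)
        loaded = ResourceMap.from_csv(
            path,
            arena=patched_env.arena,
            patch_centers=patched_env.patch_centers,
            patch_radius=patched_env.patch_radius,
        )
        np.testing.assert_allclose(loaded.positions, patched_env.positions, atol=1e-5)
        assert np.array_equal(loaded.patch_assignment, patched_env.patch_assignment)

    def test_json_round_trip(self, tmp_path, patched_env):
        path = tmp_path / "map.json"
        patched_env.to_json(path)
        loaded = ResourceMap.from_json(path)
        np.testing.assert_allclose(loaded.positions, patched_env.positions)
        assert loaded.arena.radius == patched_env.arena.radius
        assert loaded.patch_radius == patched_env.patch_radius

    def test_invariant_enforcement(self, arena):
        with pytest.raises(ValueError):
            ResourceMap(np.array([[200.0, 0.0]]), arena=arena)
        with pytest.raises(ValueError):
            ResourceMap(
                np.array([[0.0, 0.0], [1.0, 0.0]]),
                arena=arena,
                item_ids=np.array([1, 1]),
            )
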