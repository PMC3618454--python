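"""Walker construction: determinism, termination, resource blindness vs. ARS."""

import numpy as np
import pytest

from forage import (
    AgentConfig,
    Arena,
    MovementSample,
    fit_powerlaw_bounded,
    generate_dispersed,
    generate_patched,
    movement_lengths,
    simulate_ars,
    simulate_cohort,
    simulate_levy,
    simulate_trial,
)


class TestConfigValidation:
    def test_bad_bounds(self):
        with pytest.raises(ValueError):
            AgentConfig(length_bounds=(2.0, 1.0))
        with pytest.raises(ValueError):
            AgentConfig(length_bounds=(0.0, 1.0))

    def test_bad_strategy_and_targets(self):
        with pytest.raises(ValueError):
            AgentConfig(strategy="teleport")
        with pytest.raises(ValueError):
            AgentConfig(stop_at=0)

    def test_strategy_guards(self, arena, dispersed_env):
        with pytest.raises(ValueError):
            simulate_levy(AgentConfig(strategy="ars"), dispersed_env)
        with pytest.raises(ValueError):
            simulate_ars(AgentConfig(strategy="levy"), dispersed_env)


class TestTrialContract:
    def test_determinism(self, arena):
        cfg = AgentConfig(strategy="levy", seed=5)
        t1 = simulate_levy(cfg, generate_dispersed(arena, seed=3))
        t2 = simulate_levy(cfg, generate_dispersed(arena, seed=3))
        assert np.array_equal(t1.trajectory.vertices, t2.trajectory.vertices)
        assert [e.item_id for e in t1.events] == [e.item_id for e in t2.events]

    def test_target_reached_exact_count(self, arena, dispersed_env):
        trial = simulate_levy(AgentConfig(strategy="levy", seed=1), dispersed_env)
        assert trial.terminated_by == "target_reached"
        assert trial.n_collected == 90
        assert dispersed_env.n_collected == 90

    def test_step_cap_in_empty_environment(self, arena):
        env = generate_dispersed(arena, 0, seed=1)
        trial = simulate_levy(
            AgentConfig(strategy="levy", step_cap=50, seed=2), env
        )
        assert trial.terminated_by == "step_cap"
        assert trial.n_collected == 0

    def test_path_stays_inside_arena(self, arena, dispersed_env):
        trial = simulate_levy(AgentConfig(strategy="levy", seed=9), dispersed_env)
        assert arena.contains(trial.trajectory.vertices, tol=1e-6).all()

    def test_events_near_path(self, arena, patched_env):
        trial = simulate_ars(AgentConfig(strategy="ars", seed=4), patched_env)
        verts = trial.trajectory.vertices
        for e in trial.events:
            pos = np.asarray(e.position)
            w = verts[:-1] - pos
            d = verts[1:] - verts[:-1]
            seg_len = np.hypot(d[:, 0], d[:, 1])
            ok = seg_len > 0
            uh = d[ok] / seg_len[ok, None]
            proj = -np.einsum("ij,ij->i", w[ok], uh)
            tc = np.clip(proj, 0, seg_len[ok])
            closest = verts[:-1][ok] + tc[:, None] * uh
            assert np.hypot(*(closest - pos).T).min() <= 0.75 + 1e-9


class TestLevyStatistics:
    def test_pooled_length_recovery(self, arena):
        """Bounded power-law MLE on pooled path lengths recovers the generative mu."""
        gen = lambda s: generate_dispersed(arena, seed=s)
        cohort = simulate_cohort(
            2, 5, AgentConfig(strategy="levy", mu=2.0), gen, seed=0, arena=arena
        )
        pooled = MovementSample.pool(
            [movement_lengths(t.trajectory) for t in cohort]
        )
        # fence reflections split a few movements below the sampler's cutoff;
        # the fit applies to lengths at or above it
        x = pooled.lengths[pooled.lengths >= 1.0]
        assert len(x) > 2_000
        fit = fit_powerlaw_bounded(x, a=1.0, b=110.0)
        assert fit.params["mu"] == pytest.approx(2.0, abs=0.1)


class TestArsBehavior:
    def test_degenerate_give_up_equals_levy(self, arena):
        """D = 0 makes the ARS walker draw-for-draw identical to the blind walker."""
        rng_a = np.random.default_rng(33)
        rng_b = np.random.default_rng(33)
        env_a = generate_patched(arena, seed=5)
        env_b = generate_patched(arena, seed=5)
        ars = simulate_trial(
            AgentConfig(strategy="ars", intensive_distance=0.0), env_a, rng=rng_a
        )
        levy = simulate_trial(AgentConfig(strategy="levy"), env_b, rng=rng_b)
        assert np.array_equal(ars.trajectory.vertices, levy.trajectory.vertices)

    def test_ars_outforages_levy_in_patches(self, arena):
        """Per path length, ARS collects at least as much as the blind walker."""
        rates = {"ars": [], "levy": []}
        for s in range(50):
            for strat in ("ars", "levy"):
                env = generate_patched(arena, seed=700 + s)
                trial = simulate_trial(
                    AgentConfig(strategy=strat), env,
                    rng=np.random.default_rng(800 + s),
                )
                rates[strat].append(
                    trial.n_collected / (trial.trajectory.path_length / 100.0)
                )
        assert np.mean(rates["ars"]) >= np.mean(rates["levy"])


class TestCohort:
    def test_labels_and_counts(self, arena):
        gen = lambda s: generate_dispersed(arena, 200, seed=s)
        cfg = AgentConfig(strategy="levy", stop_at=5)
        cohort = simulate_cohort(16, 5, cfg, gen, seed=3, arena=arena)
        assert len(cohort) == 80
        agents = {t.trajectory.agent_id for t in cohort}
        assert len(agents) == 16
        assert all(t.terminated_by in {"target_reached", "step_cap"} for t in cohort)

    def test_single_trial_and_determinism(self, arena):
        gen = lambda s: generate_dispersed(arena, 200, seed=s)
        cfg = AgentConfig(strategy="levy", stop_at=5)
        c1 = simulate_cohort(1, 1, cfg, gen, seed=9, arena=arena)
        c2 = simulate_cohort(1, 1, cfg, gen, seed=9, arena=arena)
        assert len(c1) == 1
        assert np.array_equal(
            c1[0].trajectory.vertices, c2[0].trajectory.vertices
        )

    def test_invalid_counts(self, arena):
        gen = lambda s: generate_dispersed(arena, 10, seed=s)
        with pytest.raises(ValueError):
            simulate_cohort(0, 1, AgentConfig(), gen)
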