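"""Integrator and social-force composition tests."""

import numpy as np
import pytest

import schoolsim as ss
from schoolsim.simulate import AgentState, compose_social_force


def two_agent_params(**kw):
    base = dict(n_individuals=2, sigma_v=0.0, sigma_phi=0.0, seed=0)
    base.update(kw)
    return ss.ModelParams(**base)


class TestStep:
    def test_free_streaming(self):
        # all forces off: x advances by v dt, v unchanged
        p = two_agent_params(k_rep=0.0, k_att=0.0, mu=0.0, tau_v=np.inf)
        state = AgentState(np.array([[0.0, 0.0], [10.0, 0.0]]),
                           np.array([[3.0, 4.0], [-1.0, 2.0]]))
        new, acc = ss.step(state, p, np.random.default_rng(0))
        assert np.allclose(new.velocities, state.velocities)
        assert np.allclose(new.positions,
                           state.positions + state.velocities * p.dt)
        assert np.allclose(acc, 0.0)

    def test_friction_step_decrement(self):
        # speed 12: one explicit Euler step loses 0.625 * dt
        p = two_agent_params(k_rep=0.0, k_att=0.0, mu=0.0)
        state = AgentState(np.array([[0.0, 0.0], [1e5, 0.0]]),
                           np.array([[12.0, 0.0], [11.0, 0.0]]))
        new, _ = ss.step(state, p, np.random.default_rng(0))
        assert np.linalg.norm(new.velocities[0]) == pytest.approx(
            12.0 - 0.625 * p.dt)

    def test_seeded_trajectories_bitwise_identical(self):
        p = ss.ModelParams(n_individuals=8, seed=3)
        a = ss.simulate(p, 50)
        b = ss.simulate(p, 50)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.accelerations, b.accelerations)


class TestClosedFormLimits:
    def test_speed_relaxes_monotonically_to_v0(self):
        p = two_agent_params(k_rep=0.0, k_att=0.0, mu=0.0)
        init = AgentState(np.array([[0.0, 0.0], [1e5, 0.0]]),
                          np.array([[22.0, 0.0], [11.0, 0.0]]))
        traj = ss.simulate(p, 500, init=init,
                           rng=np.random.default_rng(0))
        speeds = traj.speeds[:, 0]
        assert np.all(np.diff(speeds) < 0)
        assert speeds[-1] == pytest.approx(p.v0, rel=1e-2)
        # relaxation time constant recovered within 1%
        tau_hat = ss.estimation.relaxation_time(p)
        assert tau_hat == pytest.approx(p.tau_v, rel=0.01)

    def test_pair_alignment_decay_rate_is_two_mu(self):
        mu_hat = ss.estimation.alignment_constant()
        assert mu_hat == pytest.approx(1.5, rel=0.01)

    def test_pair_spring_released_from_rest_oscillates_about_d0(self):
        p = two_agent_params(mu=0.0, tau_v=np.inf, d0=5.8)
        d_init = 9.0
        init = AgentState(np.array([[0.0, 0.0], [d_init, 0.0]]),
                          np.zeros((2, 2)))
        # initial acceleration magnitude is k_att |d - d0| per agent
        _, acc = ss.step(init.copy(), p, np.random.default_rng(0))
        assert np.linalg.norm(acc[0]) == pytest.approx(
            p.k_att * abs(d_init - p.d0), rel=1e-9)
        traj = ss.simulate(p, 4000, init=init,
                           rng=np.random.default_rng(0))
        sep = np.linalg.norm(traj.positions[:, 0] - traj.positions[:, 1],
                             axis=1)
        assert sep.min() < p.d0 < sep.max()
        # oscillation: the pair distance keeps re-crossing d0
        crossings = np.sum(np.diff(np.sign(sep - p.d0)) != 0)
        assert crossings >= 4


class TestComposeSocialForce:
    def test_two_agents_single_neighbor_weight_one(self):
        p = two_agent_params()
        state = AgentState(np.array([[0.0, 0.0], [8.0, 0.0]]),
                           np.array([[11.0, 0.0], [9.0, 2.0]]))
        g = ss.voronoi_adjacency(state.positions)
        fb = compose_social_force(state, g, p)
        expected = (ss.attraction_repulsion_force(
            state.positions[0], state.positions[1], p)
            + ss.alignment_force(state.velocities[0],
                                 state.velocities[1], p))
        assert np.allclose(fb.social[0], expected)

    def test_selective_fastest_agent_feels_no_social_force(self):
        p = ss.ModelParams(n_individuals=4, variant="selective")
        pos = np.array([[0, 0], [5, 0], [0, 5], [5, 5.0]])
        vel = np.array([[14.0, 0], [10.0, 0], [9.0, 0], [8.0, 0]])
        state = AgentState(pos, vel)
        fb = compose_social_force(state, ss.voronoi_adjacency(pos), p)
        assert np.allclose(fb.social[0], 0.0)

    def test_selective_single_faster_neighbor_gets_full_pairwise_force(self):
        p = ss.ModelParams(n_individuals=4, variant="selective")
        pos = np.array([[0, 0], [5, 0], [0, 5], [5, 5.0]])
        vel = np.array([[10.0, 0], [12.0, 0], [9.0, 0], [8.0, 0]])
        state = AgentState(pos, vel)
        fb = compose_social_force(state, ss.voronoi_adjacency(pos), p)
        expected = (ss.attraction_repulsion_force(pos[0], pos[1], p)
                    + ss.alignment_force(vel[0], vel[1], p))
        assert np.allclose(fb.social[0], expected)

    def test_selective_ignores_all_slower_neighbors(self, rng):
        p = ss.ModelParams(n_individuals=10, variant="selective")
        pos = rng.uniform(0, 30, (10, 2))
        vel = rng.uniform(5, 15, (10, 2))
        state = AgentState(pos, vel)
        g = ss.voronoi_adjacency(pos)
        sets = ss.interacting_sets(state, g, p)
        speed = np.linalg.norm(vel, axis=1)
        for i in range(10):
            for j in np.nonzero(sets[i])[0]:
                assert speed[j] > speed[i]
                assert g.adjacency[i, j]

    def test_nearest_only_variant_uses_single_neighbor(self, rng):
        p = ss.ModelParams(n_individuals=8, variant="nearest_only")
        pos = rng.uniform(0, 30, (8, 2))
        state = AgentState(pos, np.full((8, 2), 7.0))
        g = ss.voronoi_adjacency(pos)
        sets = ss.interacting_sets(state, g, p)
        assert np.array_equal(sets.sum(1), np.ones(8))
        assert np.array_equal(sets.argmax(1), g.nearest)


class TestSimulateEnsemble:
    def test_standard_school_orders(self, short_standard_run):
        pol = np.mean([ss.polarization(v)
                       for v in short_standard_run.velocities[::10]])
        assert pol > 0.8

    def test_no_alignment_strong_angular_noise_stays_disordered(self):
        # mu = 0 with strong heading noise: polarization matches the
        # null of independent headings, E|sum of N unit vectors|/N
        n = 12
        p = ss.ModelParams(n_individuals=n, mu=0.0, k_rep=0.0, k_att=0.0,
                           sigma_phi=12.0, seed=4)
        traj = ss.simulate(p, 4000, 1000)
        pol = np.array([ss.polarization(v) for v in traj.velocities[::5]])
        rng = np.random.default_rng(0)
        null_draws = np.abs(np.exp(
            1j * rng.uniform(0, 2 * np.pi, (4000, n))).mean(1))
        assert abs(pol.mean() - null_draws.mean()) < 3 * null_draws.std()

    def test_transient_discard_and_frame_count(self):
        p = ss.ModelParams(n_individuals=5, seed=1)
        traj = ss.simulate(p, 300, 50)
        assert traj.n_frames == 250
        assert traj.metadata["n_transient"] == 50
        with pytest.raises(ValueError):
            ss.simulate(p, 100, 100)

    def test_recorded_acceleration_is_velocity_increment_rate(self):
        p = ss.ModelParams(n_individuals=6, seed=8)
        traj = ss.simulate(p, 40)
        dv = np.diff(traj.velocities, axis=0) / p.dt
        assert np.allclose(traj.accelerations[:-1], dv, atol=1e-9)

    def test_initial_state_matches_target_scales(self):
        p = ss.ModelParams(seed=0)
        state = ss.initial_state(p, np.random.default_rng(2))
        speeds = np.linalg.norm(state.velocities, axis=1)
        assert np.allclose(speeds, p.v0)
        dnn = ss.mean_nn_distance(state.positions)
        assert 0.3 * p.d0 < dnn < 3.0 * p.d0


class TestPersistentRandomVariant:
    def test_social_forces_switched_off_while_active(self):
        p = ss.ModelParams(
            n_individuals=6, variant="persistent_random", seed=2,
            persistent=ss.PersistentRandomParams(rate=5.0, amplitude=3.0,
                                                 duration=0.3))
        rng = np.random.default_rng(2)
        state = ss.initial_state(p, rng)
        saw_active = False
        for _ in range(300):
            from schoolsim.simulate import total_deterministic_force
            fb = total_deterministic_force(state, p, rng)
            active = state.persistent.active | (
                np.linalg.norm(fb.persistent, axis=1) > 0)
            if active.any():
                saw_active = True
                assert np.allclose(fb.attraction_repulsion[active], 0.0)
                assert np.allclose(fb.alignment[active], 0.0)
            state, _ = ss.step(state, p, rng)
        assert saw_active
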