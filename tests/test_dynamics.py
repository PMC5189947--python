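"""Unit tests for the SDE samplers: drifts, integration, stationary-law
oracles, and the offset (positivity) transformation."""

import numpy as np
import pytest

from eisampler.dynamics import (
    NetworkState,
    SimulationProtocol,
    apply_offset,
    drift_hamiltonian,
    drift_hamiltonian_pure,
    drift_langevin,
    drift_z,
    drift_z_pure,
    linearized_drift_matrix,
    simulate,
    simulate_batch,
    stationary_covariance_lyapunov,
    stationary_covariance_target,
)
from eisampler.gsm import (
    input_current,
    posterior_u,
    sample_stimulus,
    total_energy,
)


class TestProtocolValidation:
    def test_defaults_valid(self):
        p = SimulationProtocol()
        assert p.mode == "hamiltonian"

    def test_invalid_settings_raise(self):
        with pytest.raises(ValueError):
            SimulationProtocol(mode="gibbs")
        with pytest.raises(ValueError):
            SimulationProtocol(mode="hamiltonian_fixed_z")  # needs z_fixed
        with pytest.raises(ValueError):
            SimulationProtocol(dt=1e-3)  # too coarse for tau = 10 ms
        with pytest.raises(ValueError):
            SimulationProtocol(t_post=0.0)
        with pytest.raises(ValueError):
            SimulationProtocol(z_gen=-1.0)
        with pytest.raises(ValueError):
            SimulationProtocol(record_every=0)

    def test_state_validation(self):
        with pytest.raises(ValueError):
            NetworkState(u=np.zeros(2), v=np.zeros(2), z=-0.1, v_z=0.0)
        with pytest.raises(ValueError):
            NetworkState(u=np.array([np.nan, 0.0]), v=np.zeros(2), z=1.0, v_z=0.0)


class TestDrifts:
    def test_fixed_point_of_the_ei_drift(self, small_model, rng):
        # At u = u_bar(z), v = B u, v_z = z, I_z-balanced z, all drifts
        # vanish except noise: the posterior mode is the deterministic
        # fixed point.
        gsm, net = small_model
        x = sample_stimulus(gsm, 1.0, rng).x
        # Solve for the joint (u, z) stationary point by iterating the two
        # conditional balance equations.
        z = 1.0
        for _ in range(200):
            u = posterior_u(gsm, x, z).mean
            Au = gsm.A @ u
            z = float(Au @ x / (Au @ Au + gsm.sigma_x_sq))
        st = NetworkState(u=u, v=net.B @ u, z=z, v_z=z)
        du, dv = drift_hamiltonian(st, net, gsm, x)
        dz, dvz = drift_z(st, net, gsm, x)
        assert np.max(np.abs(du)) < 1e-6
        assert np.max(np.abs(dv)) < 1e-6
        assert abs(dz) < 1e-6 and abs(dvz) < 1e-6

    def test_langevin_drift_is_scaled_input_current(self, small_model, rng):
        gsm, net = small_model
        x = sample_stimulus(gsm, 1.0, rng).x
        u = rng.standard_normal(gsm.n_features)
        st = NetworkState(u=u, v=np.zeros_like(u), z=0.7, v_z=0.0)
        expected = input_current(gsm, u, 0.7, x) / net.tau_L
        assert drift_langevin(st, net, gsm, x) == pytest.approx(expected)

    def test_full_drift_is_pure_plus_friction(self, small_model, rng):
        # The EI drift decomposes into the energy-conserving component plus
        # tau/tau_L-scaled friction terms; check the decomposition on u.
        gsm, net = small_model
        x = sample_stimulus(gsm, 1.0, rng).x
        u = rng.standard_normal(gsm.n_features)
        v = rng.standard_normal(gsm.n_features)
        st = NetworkState(u=u, v=v, z=0.9, v_z=1.1)
        du_full, _ = drift_hamiltonian(st, net, gsm, x)
        du_pure, _ = drift_hamiltonian_pure(st, net, gsm, x)
        r = net.tau / net.tau_L
        Iin = input_current(gsm, u, 0.9, x)
        friction = (-r * (net.M @ net.B) @ u + r * net.M @ v + r * Iin) / net.tau
        assert du_full == pytest.approx(du_pure + friction)

    def test_energy_conservation_improves_with_dt(self, small_model, rng):
        # Noise-free pure Hamiltonian flow: energy drift halves with dt
        # (first-order integrator), so the flow conserves energy in the
        # continuum limit.
        gsm, net = small_model
        x = sample_stimulus(gsm, 1.0, rng).x
        drifts = []
        for dt in (2e-5, 1e-5, 5e-6):
            u = np.full(gsm.n_features, 0.4)
            v = u.copy()
            z, v_z = 1.0, 1.0
            e0 = total_energy(gsm, net, u, v, z, v_z, x)
            for _ in range(int(0.02 / dt)):
                st = NetworkState(u=u, v=v, z=max(z, 1e-12), v_z=v_z)
                du, dv = drift_hamiltonian_pure(st, net, gsm, x)
                dz, dvz = drift_z_pure(st, net, gsm, x)
                u, v = u + du * dt, v + dv * dt
                z, v_z = z + dz * dt, v_z + dvz * dt
            drifts.append(abs(total_energy(gsm, net, u, v, z, v_z, x) - e0))
        assert drifts[0] > drifts[1] > drifts[2]
        assert drifts[2] < 0.5 * drifts[0]


class TestSimulate:
    def test_trajectory_shapes_and_times(self, small_model):
        gsm, net = small_model
        p = SimulationProtocol(t_pre=0.05, t_post=0.1, noise_seed=7)
        traj = simulate(p, net, gsm)
        assert traj.u_t.shape == (len(traj.times), gsm.n_features)
        assert traj.times[0] == pytest.approx(-0.05)
        assert traj.times[-1] == pytest.approx(0.1)
        assert traj.times[traj.onset_index] >= 0.0
        assert traj.fs == pytest.approx(2000.0)

    def test_determinism(self, small_model):
        gsm, net = small_model
        p = SimulationProtocol(t_pre=0.0, t_post=0.05, noise_seed=11)
        t1 = simulate(p, net, gsm)
        t2 = simulate(p, net, gsm)
        assert np.array_equal(t1.u_t, t2.u_t)
        assert np.array_equal(t1.z_t, t2.z_t)

    def test_seeds_differ(self, small_model):
        gsm, net = small_model
        a = simulate(SimulationProtocol(t_pre=0.0, t_post=0.05, noise_seed=1),
                     net, gsm)
        b = simulate(SimulationProtocol(t_pre=0.0, t_post=0.05, noise_seed=2),
                     net, gsm)
        assert not np.array_equal(a.u_t, b.u_t)

    def test_z_stays_nonnegative(self, small_model):
        gsm, net = small_model
        p = SimulationProtocol(t_pre=0.0, t_post=0.5, z_gen=0.0, noise_seed=3)
        traj = simulate(p, net, gsm)
        assert traj.z_t.min() >= 0.0

    def test_langevin_has_no_momenta(self, small_model):
        gsm, net = small_model
        p = SimulationProtocol(t_pre=0.0, t_post=0.05, mode="langevin")
        traj = simulate(p, net, gsm)
        assert traj.v_t is None and traj.v_z_t is None

    def test_fixed_z_is_clamped(self, small_model):
        gsm, net = small_model
        p = SimulationProtocol(t_pre=0.0, t_post=0.05,
                               mode="hamiltonian_fixed_z", z_fixed=1.3)
        traj = simulate(p, net, gsm)
        assert np.all(traj.z_t == 1.3)

    def test_batch_matches_singleton(self, small_model, rng):
        # A batch of identical stimuli with one shared noise seed still
        # differs per row (independent noise), but shapes and times align.
        gsm, net = small_model
        x = sample_stimulus(gsm, 1.0, rng).x
        X = np.tile(x, (3, 1))
        p = SimulationProtocol(t_pre=0.0, t_post=0.05, noise_seed=5)
        res = simulate_batch(p, net, gsm, X, X, record=("u", "z"))
        assert res["u"].shape == (len(res["times"]), 3, gsm.n_features)
        assert res["z"].shape == (len(res["times"]), 3)
        assert not np.array_equal(res["u"][:, 0], res["u"][:, 1])

    def test_batch_shape_mismatch_raises(self, small_model):
        gsm, net = small_model
        p = SimulationProtocol(t_pre=0.0, t_post=0.05)
        with pytest.raises(ValueError):
            simulate_batch(p, net, gsm, np.zeros((2, gsm.n_pixels)),
                           np.zeros((3, gsm.n_pixels)))


class TestStationaryOracles:
    def test_lyapunov_solution_equals_block_target(self, model, rng):
        # The analytic stationary covariance of the fixed-z OU system
        # solves the Lyapunov equation exactly.
        gsm, net = model
        x = sample_stimulus(gsm, 1.0, rng).x
        post = posterior_u(gsm, x, 1.0)
        target = stationary_covariance_target(net, post.cov)
        lyap = stationary_covariance_lyapunov(net, np.linalg.inv(post.cov))
        assert np.allclose(target, lyap, atol=1e-8 * np.abs(target).max())

    def test_drift_matrix_matches_drift_functions(self, model, rng):
        # F (du, dv) reproduces the nonlinear drift at fixed z measured
        # around the posterior mean.
        gsm, net = model
        x = sample_stimulus(gsm, 1.0, rng).x
        post = posterior_u(gsm, x, 1.0)
        F = linearized_drift_matrix(net, np.linalg.inv(post.cov))
        u = post.mean + 0.1 * rng.standard_normal(net.n)
        v = net.B @ post.mean + 0.1 * rng.standard_normal(net.n)
        st = NetworkState(u=u, v=v, z=1.0, v_z=1.0)
        du, dv = drift_hamiltonian(st, net, gsm, x)
        delta = np.concatenate([u - post.mean, v - net.B @ post.mean])
        pred = F @ delta
        assert du == pytest.approx(pred[: net.n], rel=1e-8, abs=1e-8)
        assert dv == pytest.approx(pred[net.n :], rel=1e-8, abs=1e-8)

    def test_drift_matrix_is_stable(self, model, rng):
        gsm, net = model
        x = sample_stimulus(gsm, 1.0, rng).x
        post = posterior_u(gsm, x, 1.0)
        F = linearized_drift_matrix(net, np.linalg.inv(post.cov))
        assert np.linalg.eigvals(F).real.max() < 0


class TestOffsetModel:
    def test_offset_shifts_posterior_mean_only(self, small_model, rng):
        gsm, _ = small_model
        b = np.full(gsm.n_features, 2.5)
        off = apply_offset(gsm, b)
        x = sample_stimulus(gsm, 1.0, rng).x
        base = posterior_u(gsm, x, 1.0)
        shifted = off.posterior_u(x, 1.0)
        assert shifted.mean == pytest.approx(base.mean + b)
        assert shifted.cov == pytest.approx(base.cov)

    def test_offset_leaves_dynamics_invariant(self, small_model, rng):
        # The input current at u + b under the offset model equals the
        # current at u under the base model.
        gsm, _ = small_model
        b = np.full(gsm.n_features, 2.5)
        off = apply_offset(gsm, b)
        x = sample_stimulus(gsm, 1.0, rng).x
        u = rng.standard_normal(gsm.n_features)
        assert off.input_current(u + b, 1.0, x) == pytest.approx(
            input_current(gsm, u, 1.0, x)
        )

    def test_offset_validation(self, small_model):
        gsm, _ = small_model
        with pytest.raises(ValueError):
            apply_offset(gsm, np.zeros(gsm.n_features + 1))
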