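"""Brownian propagation: displacement statistics, quaternion hygiene,
anisotropic body-frame diffusion, loop ordering guarantees."""

import numpy as np
import pytest

from ridsim.molecules import HydroParams, define_molecule_type
from ridsim.observables import Trajectory, msd, record_trajectory, rotational_correlation
from ridsim.propagation import (
    IntegratorSettings,
    Simulation,
    propagate_step,
    quat_multiply,
    quat_to_matrix,
    random_quaternions,
)

SETTINGS = IntegratorSettings(dt=0.01, temperature=293.15, seed=0)


class TestPropagateStep:
    def test_vanishing_dt_leaves_state_unchanged(self):
        mt = define_molecule_type("T", [[0, 0, 0]], [1.0], diffusion_constant=0.3)
        rng = np.random.default_rng(0)
        tiny = IntegratorSettings(dt=1e-18)
        pos, quat = propagate_step([1.0, 2, 3], [1.0, 0, 0, 0],
                                   np.zeros(3), np.zeros(3), mt, tiny, rng)
        np.testing.assert_allclose(pos, [1.0, 2, 3], atol=1e-8)
        np.testing.assert_allclose(quat, [1.0, 0, 0, 0], atol=1e-8)

    def test_displacement_variance_2_d_dt(self):
        mt = define_molecule_type("T", [[0, 0, 0]], [1.0], diffusion_constant=0.25)
        rng = np.random.default_rng(1)
        n = 100_000
        disp = np.empty((n, 3))
        for i in range(n):
            pos, _ = propagate_step(np.zeros(3), [1.0, 0, 0, 0],
                                    np.zeros(3), np.zeros(3), mt, SETTINGS, rng)
            disp[i] = pos
        expected = 2 * 0.25 * SETTINGS.dt
        var = disp.var(axis=0)
        se = expected * np.sqrt(2.0 / n)
        assert np.all(np.abs(var - expected) < 3.5 * se)
        assert np.abs(disp.mean(axis=0)).max() < 3 * np.sqrt(expected / n)

    def test_drift_follows_mobility_times_force(self):
        mt = define_molecule_type("T", [[0, 0, 0]], [1.0], diffusion_constant=0.25)
        rng = np.random.default_rng(2)
        n = 40_000
        force = np.array([50.0, 0.0, 0.0])
        disp = np.empty(n)
        for i in range(n):
            pos, _ = propagate_step(np.zeros(3), [1.0, 0, 0, 0],
                                    force, np.zeros(3), mt, SETTINGS, rng)
            disp[i] = pos[0]
        expected = 0.25 * 50.0 / SETTINGS.kT * SETTINGS.dt
        se = np.sqrt(2 * 0.25 * SETTINGS.dt / n)
        assert disp.mean() == pytest.approx(expected, abs=3 * se)

    def test_non_finite_force_raises(self):
        mt = define_molecule_type("T", [[0, 0, 0]], [1.0], diffusion_constant=0.25)
        with pytest.raises(FloatingPointError):
            propagate_step(np.zeros(3), [1.0, 0, 0, 0],
                           np.array([np.nan, 0, 0]), np.zeros(3), mt,
                           SETTINGS, np.random.default_rng(0))


class TestQuaternions:
    def test_norm_preserved_under_long_run(self):
        sim = Simulation(box=[20.0] * 3, dt=0.05, seed=3)
        sim.register_species(define_molecule_type(
            "T", [[0, 0, 0]], [0.8], diffusion_constant=0.2))
        rng = np.random.default_rng(0)
        sim.add_molecules("T", rng.uniform(0, 20, size=(50, 3)),
                          quaternions=random_quaternions(rng, 50))
        sim.run(500)
        norms = np.linalg.norm(sim.quat[: sim.n], axis=1)
        assert np.abs(norms - 1.0).max() < 1e-9

    def test_quat_multiply_matches_matrix_product(self, rng):
        q1 = random_quaternions(rng, 10)
        q2 = random_quaternions(rng, 10)
        q12 = quat_multiply(q1, q2)
        np.testing.assert_allclose(
            quat_to_matrix(q12),
            np.einsum("nij,njk->nik", quat_to_matrix(q1), quat_to_matrix(q2)),
            atol=1e-12,
        )


class TestAnisotropicDiffusion:
    @pytest.fixture(scope="class")
    @staticmethod
    def rod():
        # three-bead rod: distinct axial and transverse mobilities
        return define_molecule_type(
            "rod", [[-2.0, 0, 0], [0.0, 0, 0], [2.0, 0, 0]], [1.0, 1.0, 1.0],
            params=HydroParams())

    def test_short_time_body_frame_msd_slopes(self, rod):
        # per-axis displacement variance in the body frame = 2 D_ii dt
        rng = np.random.default_rng(4)
        settings = IntegratorSettings(dt=0.02)
        n = 60_000
        disp_b = np.empty((n, 3))
        quats = random_quaternions(rng, n)
        for i in range(n):
            R = quat_to_matrix(quats[i])
            pos, _ = propagate_step(np.zeros(3), quats[i], np.zeros(3),
                                    np.zeros(3), rod, settings, rng)
            disp_b[i] = R.T @ pos
        var = disp_b.var(axis=0)
        expected = 2 * np.diag(rod.D_tt) * settings.dt
        se = expected * np.sqrt(2.0 / n)
        assert np.all(np.abs(var - expected) < 3.5 * se)
        assert expected[0] > expected[1]  # axial faster than transverse

    def test_long_time_msd_recovers_trace_average(self, rod):
        sim = Simulation(box=[200.0] * 3, dt=0.05, seed=5)
        sim.register_species(rod)
        rng = np.random.default_rng(5)
        sim.add_molecules("rod", rng.uniform(0, 200, size=(400, 3)),
                          quaternions=random_quaternions(rng, 400))
        traj = Trajectory()
        sim.run(400, callback=record_trajectory(traj), callback_every=4)
        lags, m, e = msd(traj, "rod", lags=[10, 20, 30, 40, 50])
        slope = np.sum(m * lags) / np.sum(lags**2)
        se = np.sqrt(np.sum((e * lags) ** 2)) / np.sum(lags**2)
        assert abs(slope - 6 * rod.D_scalar) < 3 * se

    def test_isotropic_rotor_correlation_decay(self):
        mt = define_molecule_type("S", [[0, 0, 0]], [1.0], diffusion_constant=0.2)
        d_r = mt.D_rot_scalar
        sim = Simulation(box=[50.0] * 3, dt=0.02, seed=6)
        sim.register_species(mt)
        rng = np.random.default_rng(6)
        sim.add_molecules("S", rng.uniform(0, 50, size=(500, 3)),
                          quaternions=random_quaternions(rng, 500))
        traj = Trajectory()
        sim.run(250, callback=record_trajectory(traj), callback_every=5)
        lags, p, e = rotational_correlation(traj, "S", lags=[1, 2, 3, 4, 6, 8])
        expected = np.exp(-6 * d_r * lags)
        assert np.all(np.abs(p - expected) < 3.5 * np.maximum(e, 1e-4))


class TestSimulationLoop:
    def test_molecule_count_conserved_without_reactions(self):
        sim = Simulation(box=[15.0] * 3, dt=0.1, seed=7)
        sim.register_species(define_molecule_type(
            "T", [[0, 0, 0]], [1.0], diffusion_constant=0.3))
        rng = np.random.default_rng(7)
        sim.add_molecules("T", rng.uniform(0, 15, size=(80, 3)))
        for _ in range(300):
            sim.step()
            assert sim.n == 80

    def test_fixed_seed_bit_identical_trajectories(self):
        def run(seed):
            sim = Simulation(box=[15.0] * 3, dt=0.1, seed=seed)
            sim.register_species(define_molecule_type(
                "T", [[0, 0, 0]], [1.0], diffusion_constant=0.3))
            sim.add_molecules(
                "T", np.random.default_rng(0).uniform(0, 15, size=(40, 3)))
            sim.run(100)
            return sim.pos[: sim.n].copy(), sim.quat[: sim.n].copy()
        p1, q1 = run(11)
        p2, q2 = run(11)
        assert np.array_equal(p1, p2) and np.array_equal(q1, q2)

    def test_free_diffusion_reduction_with_potentials_off(self):
        # no potentials/reactions: step() reduces to free diffusion with the
        # same noise stream
        seed = 13
        sim = Simulation(box=[30.0] * 3, dt=0.1, seed=seed)
        mt = define_molecule_type("T", [[0, 0, 0]], [1.0], diffusion_constant=0.3)
        sim.register_species(mt)
        start = np.array([[15.0, 15.0, 15.0]])
        sim.add_molecules("T", start)
        sim.run(50)
        end_sim = sim.unwrapped_positions()[0]
        rng = np.random.Generator(np.random.Philox(seed))
        pos = start[0].copy()
        quat = np.array([1.0, 0, 0, 0])
        settings = IntegratorSettings(dt=0.1)
        for _ in range(50):
            # same draw order as the loop: translation then rotation
            pos = pos + np.sqrt(2 * 0.3 * 0.1) * rng.standard_normal(3)
            lr = np.linalg.cholesky(2 * mt.D_rr * 0.1)
            rng.standard_normal(3)  # rotation noise consumed
        np.testing.assert_allclose(end_sim, pos, atol=1e-12)
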