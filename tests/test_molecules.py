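"""Rigid-bead diffusion tensors: Stokes-Einstein closure, frame
covariance, and agreement with an independent supermatrix oracle."""

import numpy as np
import pytest

from ridsim.constants import KB
from ridsim.molecules import (
    HydroParams,
    compute_diffusion_tensor,
    define_molecule_type,
)

PARAMS = HydroParams(temperature=293.15)


def _oracle_diffusion(positions, radii, params):
    """Independent rigid-bead reduction: full RPY supermatrix inverted and
    contracted with the explicit 3N x 6 rigid-body kinematic matrix."""
    positions = np.asarray(positions, dtype=float)
    radii = np.asarray(radii, dtype=float)
    eta = params.viscosity
    n = len(radii)
    mob = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(n):
            if i == j:
                mob[3 * i:3 * i + 3, 3 * j:3 * j + 3] = np.eye(3) / (6 * np.pi * eta * radii[i])
                continue
            rv = positions[j] - positions[i]
            r = np.linalg.norm(rv)
            e = np.outer(rv, rv) / r**2
            a, b = radii[i], radii[j]
            if r >= a + b:
                blk = (
                    (np.eye(3) + e)
                    + (a**2 + b**2) / r**2 * (np.eye(3) / 3.0 - e)
                ) / (8 * np.pi * eta * r)
            else:
                blk = (
                    ((16 * r**3 * (a + b) - ((a - b) ** 2 + 3 * r**2) ** 2)
                     / (32 * r**3)) * np.eye(3)
                    + (3 * ((a - b) ** 2 - r**2) ** 2 / (32 * r**3)) * e
                ) / (6 * np.pi * eta * a * b)
            mob[3 * i:3 * i + 3, 3 * j:3 * j + 3] = blk
    xi = np.linalg.inv(mob)
    # kinematic map u = P [v; omega]
    P = np.zeros((3 * n, 6))
    for i in range(n):
        P[3 * i:3 * i + 3, :3] = np.eye(3)
        x, y, z = positions[i]
        P[3 * i:3 * i + 3, 3:] = -np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    xi6 = P.T @ xi @ P
    xi6[3:, 3:] += 8 * np.pi * eta * np.sum(radii**3) * np.eye(3)
    d6 = params.kT * np.linalg.inv(xi6)
    return d6[:3, :3], d6[3:, 3:], d6[:3, 3:]


class TestStokesEinstein:
    def test_single_sphere_translation_six_digits(self):
        d_tt, _, _, _ = compute_diffusion_tensor([[0, 0, 0]], [1.3], PARAMS)
        expected = PARAMS.kT / (6 * np.pi * PARAMS.viscosity * 1.3)
        assert d_tt == pytest.approx(expected * np.eye(3), rel=1e-9)

    def test_single_sphere_rotation_six_digits(self):
        _, d_rr, _, _ = compute_diffusion_tensor([[0, 0, 0]], [0.8], PARAMS)
        expected = PARAMS.kT / (8 * np.pi * PARAMS.viscosity * 0.8**3)
        assert d_rr == pytest.approx(expected * np.eye(3), rel=1e-9)

    def test_off_center_sphere_cod_at_bead_center(self):
        _, _, d_tr, cod = compute_diffusion_tensor([[1.0, -2.0, 0.5]], [1.0], PARAMS)
        assert cod == pytest.approx([1.0, -2.0, 0.5], abs=1e-9)
        assert np.abs(d_tr).max() < 1e-12


class TestFrameCovariance:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_tensors_rotate_covariantly(self, seed):
        rng = np.random.default_rng(seed)
        beads = rng.normal(scale=2.0, size=(4, 3))
        radii = rng.uniform(0.5, 1.5, size=4)
        # random rotation via QR
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        d_tt, d_rr, _, cod = compute_diffusion_tensor(beads, radii, PARAMS)
        d_tt2, d_rr2, _, cod2 = compute_diffusion_tensor(beads @ q.T, radii, PARAMS)
        np.testing.assert_allclose(q @ d_tt @ q.T, d_tt2, atol=1e-12)
        np.testing.assert_allclose(q @ d_rr @ q.T, d_rr2, atol=1e-12)
        np.testing.assert_allclose(q @ cod, cod2, atol=1e-9)

    def test_positive_definite(self, rng):
        for _ in range(5):
            beads = rng.normal(scale=3.0, size=(3, 3))
            radii = rng.uniform(0.3, 2.0, size=3)
            d_tt, d_rr, _, _ = compute_diffusion_tensor(beads, radii, PARAMS)
            assert np.linalg.eigvalsh(d_tt).min() > 0
            assert np.linalg.eigvalsh(d_rr).min() > 0


class TestAgainstOracle:
    def test_touching_dumbbell_eigenvalues(self):
        beads = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        radii = np.array([1.0, 1.0])
        d_tt, d_rr, _, cod = compute_diffusion_tensor(beads, radii, PARAMS)
        o_tt, o_rr, _ = _oracle_diffusion(beads - cod, radii, PARAMS)
        np.testing.assert_allclose(
            np.linalg.eigvalsh(d_tt), np.linalg.eigvalsh(o_tt), rtol=1e-10)
        np.testing.assert_allclose(
            np.linalg.eigvalsh(d_rr), np.linalg.eigvalsh(o_rr), rtol=1e-10)

    def test_asymmetric_dumbbell_full_tensors(self):
        beads = np.array([[0.0, 0, 0], [3.0, 0, 0.5]])
        radii = np.array([1.0, 2.0])
        d_tt, d_rr, d_tr, cod = compute_diffusion_tensor(beads, radii, PARAMS)
        o_tt, o_rr, o_tr = _oracle_diffusion(beads - cod, radii, PARAMS)
        np.testing.assert_allclose(d_tt, o_tt, atol=1e-12)
        np.testing.assert_allclose(d_rr, o_rr, atol=1e-12)
        np.testing.assert_allclose(d_tr, o_tr, atol=1e-12)
        # coupling is symmetric at the center of diffusion
        assert np.abs(d_tr - d_tr.T).max() < 1e-12

    def test_three_bead_rod_axial_exceeds_transverse(self):
        beads = np.array([[-2.0, 0, 0], [0.0, 0, 0], [2.0, 0, 0]])
        radii = np.ones(3)
        d_tt, _, _, cod = compute_diffusion_tensor(beads, radii, PARAMS)
        assert d_tt[0, 0] > d_tt[1, 1]
        assert d_tt[1, 1] == pytest.approx(d_tt[2, 2], rel=1e-9)
        o_tt, _, _ = _oracle_diffusion(beads - cod, radii, PARAMS)
        np.testing.assert_allclose(d_tt, o_tt, atol=1e-12)

    def test_symmetric_body_cod_at_geometric_center(self):
        beads = np.array([[-1.5, 0, 0], [1.5, 0, 0]])
        _, _, _, cod = compute_diffusion_tensor(beads, [1.0, 1.0], PARAMS)
        assert cod == pytest.approx([0.0, 0.0, 0.0], abs=1e-9)


class TestDefineMoleculeType:
    def test_recentered_on_center_of_diffusion(self):
        mt = define_molecule_type("M", [[0.0, 0, 0], [3.0, 0, 0]], [1.0, 2.0],
                                  params=PARAMS)
        # body frame origin is the center of diffusion
        d_tt, d_rr, d_tr, cod = compute_diffusion_tensor(
            mt.bead_positions, mt.bead_radii, PARAMS)
        assert cod == pytest.approx([0.0, 0.0, 0.0], abs=1e-9)
        assert mt.D_scalar == pytest.approx(np.trace(mt.D_tt) / 3.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            define_molecule_type("M", np.empty((0, 3)), [])
        with pytest.raises(ValueError):
            define_molecule_type("M", [[0, 0, 0]], [-1.0])

    def test_coincident_beads_rejected(self):
        with pytest.raises(ValueError):
            compute_diffusion_tensor([[0, 0, 0], [0, 0, 0]], [1.0, 1.0], PARAMS)

    def test_patches_attached_in_body_frame(self):
        mt = define_molecule_type(
            "M", [[0.0, 0, 0]], [1.0], patches=[((0.0, 0.0, 1.0), "site")])
        assert mt.n_particles == 2
        assert mt.particle_types == ["M", "site"]
        np.testing.assert_allclose(mt.particle_positions[1], [0, 0, 1.0])
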