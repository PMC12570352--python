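"""Rigid bead molecule types and their hydrodynamic diffusion tensors.

A molecule is a rigid arrangement of spherical beads (plus optional
massless interaction patches).  Its Brownian motion is governed by 3x3
translational and rotational diffusion tensors computed from bead-level
hydrodynamics:

1.  Assemble the 3N x 3N translational mobility supermatrix from pairwise
    Rotne-Prager-Yamakawa (RPY) tensors for unequal bead radii, using the
    regularized overlap form of Zuk et al. for overlapping beads.
2.  Invert it to the friction supermatrix and contract with the rigid-body
    kinematic map to the 6x6 friction tensor at the chosen origin, adding
    the rotational volume correction 8 pi eta a_i^3 per bead.
3.  Invert to the 6x6 diffusion tensor D = k_B T Xi^-1 and shift the
    origin to the center of diffusion, the unique point where the
    symmetric part of the translation-rotation coupling vanishes.

For a single bead this closes onto Stokes-Einstein:
``D_tt = kT/(6 pi eta a) I`` and ``D_rr = kT/(8 pi eta a^3) I``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE, KB, WATER_VISCOSITY

__all__ = [
    "HydroParams",
    "MoleculeType",
    "define_molecule_type",
    "compute_diffusion_tensor",
    "rpy_mobility_matrix",
]


@dataclass(frozen=True)
class HydroParams:
    """Solvent parameters for the hydrodynamic tensor computation.

    viscosity is in kJ ns/(mol nm^3); 1 mPa s = 0.60221 in these units.
    """

    temperature: float = DEFAULT_TEMPERATURE
    viscosity: float = WATER_VISCOSITY

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")

    @property
    def kT(self) -> float:
        return KB * self.temperature


def _skew(r: np.ndarray) -> np.ndarray:
    x, y, z = r
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


def _rpy_block(r_vec: np.ndarray, a_i: float, a_j: float, eta: float) -> np.ndarray:
    """Pairwise RPY mobility block for beads of radii a_i, a_j.

    Uses the far-field RPY form for r >= a_i + a_j and the Zuk et al.
    regularization for overlapping beads.
    """
    r = float(np.linalg.norm(r_vec))
    if r < 1e-12:
        raise ValueError("coincident beads give a singular hydrodynamic supermatrix")
    rhat = r_vec / r
    outer = np.outer(rhat, rhat)
    eye = np.eye(3)
    if r >= a_i + a_j:
        c = 1.0 / (8.0 * np.pi * eta * r)
        a2 = (a_i**2 + a_j**2) / r**2
        return c * ((1.0 + a2 / 3.0) * eye + (1.0 - a2) * outer)
    # overlap (assumes r > |a_i - a_j|; a bead fully inside another is rejected)
    if r <= abs(a_i - a_j):
        raise ValueError("bead fully contained in another; geometry is degenerate")
    c = 1.0 / (6.0 * np.pi * eta * a_i * a_j)
    diff2 = (a_i - a_j) ** 2
    ci = (16.0 * r**3 * (a_i + a_j) - (diff2 + 3.0 * r**2) ** 2) / (32.0 * r**3)
    co = 3.0 * (diff2 - r**2) ** 2 / (32.0 * r**3)
    return c * (ci * eye + co * outer)


def rpy_mobility_matrix(
    positions: np.ndarray, radii: np.ndarray, eta: float
) -> np.ndarray:
    """3N x 3N translational RPY mobility supermatrix."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float).ravel()
    n = len(radii)
    mob = np.zeros((3 * n, 3 * n))
    for i in range(n):
        mob[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] = np.eye(3) / (
            6.0 * np.pi * eta * radii[i]
        )
        for j in range(i + 1, n):
            blk = _rpy_block(positions[j] - positions[i], radii[i], radii[j], eta)
            mob[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = blk
            mob[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = blk.T
    return mob


def _rigid_friction(positions, radii, eta):
    """6x6 rigid-body friction tensor at the coordinate origin."""
    n = len(radii)
    xi = np.linalg.inv(rpy_mobility_matrix(positions, radii, eta))
    xi_tt = np.zeros((3, 3))
    xi_tr = np.zeros((3, 3))
    xi_rt = np.zeros((3, 3))
    xi_rr = np.zeros((3, 3))
    skews = [_skew(p) for p in positions]
    for i in range(n):
        Ai = skews[i]
        for j in range(n):
            b = xi[3 * i : 3 * i + 3, 3 * j : 3 * j + 3]
            xi_tt += b
            xi_tr -= b @ skews[j]
            xi_rt += Ai @ b
            xi_rr -= Ai @ b @ skews[j]
    # rotational volume correction: each bead's own rotational resistance
    xi_rr += 8.0 * np.pi * eta * float(np.sum(radii**3)) * np.eye(3)
    out = np.zeros((6, 6))
    out[:3, :3] = xi_tt
    out[:3, 3:] = xi_tr
    out[3:, :3] = xi_rt
    out[3:, 3:] = xi_rr
    return out


def _diffusion_at_origin(positions, radii, params):
    xi6 = _rigid_friction(positions, radii, params.viscosity)
    d6 = params.kT * np.linalg.inv(xi6)
    # symmetrize against roundoff
    d6 = 0.5 * (d6 + d6.T)
    return d6[:3, :3], d6[3:, 3:], d6[:3, 3:]


def _center_of_diffusion(d_rr: np.ndarray, d_tr: np.ndarray) -> np.ndarray:
    """Origin shift to the center of diffusion.

    The center of diffusion is the point where the translation-rotation
    coupling block of the diffusion tensor becomes symmetric (its
    antisymmetric part vanishes); for any symmetric body it coincides
    with the geometric center.
    """
    m = np.trace(d_rr) * np.eye(3) - d_rr
    anti = d_tr - d_tr.T
    b = np.array([anti[2, 1], anti[0, 2], anti[1, 0]])
    return np.linalg.solve(m, b)


def compute_diffusion_tensor(
    beads, radii, params: HydroParams | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Diffusion tensors of a rigid bead assembly at its center of diffusion.

    Parameters
    ----------
    beads : (N, 3) array
        Bead centers in nm (any body-fixed frame).
    radii : (N,) array
        Bead hydrodynamic radii in nm.
    params : HydroParams
        Temperature and solvent viscosity.

    Returns
    -------
    (D_tt, D_rr, D_tr, center_of_diffusion)
        3x3 tensors in nm^2/ns, nm^2/ns... D_rr in 1/ns and D_tr in
        nm/ns... evaluated at the center of diffusion, which is returned
        in the input frame.
    """
    params = params or HydroParams()
    beads = np.asarray(beads, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float).ravel()
    if len(beads) == 0:
        raise ValueError("at least one bead is required")
    if np.any(radii <= 0):
        raise ValueError("bead radii must be positive")
    if len(beads) != len(radii):
        raise ValueError("beads and radii length mismatch")
    _, d_rr, d_tr = _diffusion_at_origin(beads, radii, params)
    cod = _center_of_diffusion(d_rr, d_tr)
    d_tt, d_rr, d_tr = _diffusion_at_origin(beads - cod, radii, params)
    return d_tt, d_rr, d_tr, cod


@dataclass
class MoleculeType:
    """Immutable rigid-bead molecule definition.

    Coordinates are stored in the body frame with the origin at the
    center of diffusion.  ``particle_types`` and ``particle_positions``
    enumerate the interaction/reaction sites: all beads first, then any
    patches.
    """

    name: str
    bead_positions: np.ndarray  # (Nb, 3), body frame, origin = center of diffusion
    bead_radii: np.ndarray  # (Nb,)
    particle_positions: np.ndarray  # (Np, 3) beads + patches
    particle_types: list[str]
    D_tt: np.ndarray
    D_rr: np.ndarray
    D_tr: np.ndarray
    center_of_diffusion: np.ndarray  # in the original input frame
    surface_bound: bool = False
    params: HydroParams = field(default_factory=HydroParams)

    @property
    def D_scalar(self) -> float:
        """Scalar translational diffusion coefficient Tr(D_tt)/3 in nm^2/ns."""
        return float(np.trace(self.D_tt)) / 3.0

    @property
    def D_rot_scalar(self) -> float:
        return float(np.trace(self.D_rr)) / 3.0

    @property
    def n_particles(self) -> int:
        return len(self.particle_types)

    @property
    def radius(self) -> float:
        """Circumscribing radius (nm) used for placement and cutoffs."""
        return float(
            np.max(np.linalg.norm(self.bead_positions, axis=1) + self.bead_radii)
        )

    @property
    def is_isotropic(self) -> bool:
        """Single centered bead: orientation propagation can be skipped
        unless the type carries off-center particles."""
        return len(self.bead_radii) == 1 and self.n_particles == 1

    def world_particles(self, position: np.ndarray, quat: np.ndarray) -> np.ndarray:
        from .propagation import quat_to_matrix

        return position + self.particle_positions @ quat_to_matrix(quat).T


def define_molecule_type(
    name: str,
    beads,
    radii,
    particle_types=None,
    patches=None,
    params: HydroParams | None = None,
    surface_bound: bool = False,
    diffusion_constant: float | None = None,
) -> MoleculeType:
    """Build a MoleculeType, computing its tensors and recentring on the
    center of diffusion.

    Parameters
    ----------
    beads, radii : arrays
        Bead centers (nm) and radii (nm).
    particle_types : list of str, optional
        Particle (interaction-site) type name per bead; defaults to the
        molecule name for every bead.
    patches : list of (position, type name), optional
        Extra interaction/reaction sites rigidly attached to the body.
    diffusion_constant : float, optional
        Override: isotropic D (nm^2/ns) used instead of the hydrodynamic
        computation (single-bead types only), with the rotational tensor
        from Stokes-Einstein at the matching hydrodynamic radius.
    """
    params = params or HydroParams()
    beads = np.atleast_2d(np.asarray(beads, dtype=float))
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    if beads.size == 0:
        raise ValueError("at least one bead is required")
    if np.any(radii <= 0):
        raise ValueError("bead radii must be positive")
    if diffusion_constant is not None:
        if len(radii) != 1:
            raise ValueError("diffusion_constant override requires a single bead")
        cod = beads[0].copy()
        d_tt = diffusion_constant * np.eye(3)
        # rotational D from the hydrodynamic radius implied by the override
        a_eff = params.kT / (6.0 * np.pi * params.viscosity * diffusion_constant)
        d_rr = params.kT / (8.0 * np.pi * params.viscosity * a_eff**3) * np.eye(3)
        d_tr = np.zeros((3, 3))
    else:
        d_tt, d_rr, d_tr, cod = compute_diffusion_tensor(beads, radii, params)
    body = beads - cod
    if particle_types is None:
        particle_types = [name] * len(radii)
    ppos = [p for p in body]
    ptypes = list(particle_types)
    if patches:
        for pos, ptype in patches:
            ppos.append(np.asarray(pos, dtype=float) - cod)
            ptypes.append(ptype)
    return MoleculeType(
        name=name,
        bead_positions=body,
        bead_radii=radii,
        particle_positions=np.array(ppos),
        particle_types=ptypes,
        D_tt=d_tt,
        D_rr=d_rr,
        D_tr=d_tr,
        center_of_diffusion=cod,
        surface_bound=surface_bound,
        params=params,
    )
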