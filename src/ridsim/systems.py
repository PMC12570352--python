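"""Ready-made validation systems and mesh fixtures.

Every builder is a pure function of its arguments (including the seed),
so validation runs are reproducible.  The defaults encode the reference
study conditions used throughout the test suite:

- hard-sphere fluid: 1 nm diameter particles at packing fraction
  eta = 0.3 interacting by harmonic repulsion, D = 0.0859 nm^2/ns;
- NPT variant: same fluid with the Berendsen barostat targeting
  P0 = 10 kJ/(mol nm^3), switched on at 0.5 ns, dt = 0.1 ns;
- surface diffusion: non-interacting walkers ray-marched on an icosphere
  with D = 43 nm^2/us = 0.043 nm^2/ns;
- bimolecular benchmark: A + B <-> C with radii 1.5 / 3.0 / 3.12 nm,
  fusion radius 4.5 nm, association rate 0.001 /ns and dissociation
  5e-5 /ns at total density 0.00341 nm^-3;
- multi-path system: two-bead molecules A(a1,a2) and B(b1,b2) with four
  fusion paths over different particle pairs producing C or D, plus the
  back-reaction C -> A + B.
"""

from __future__ import annotations

import numpy as np

from .barostat import BarostatParams
from .constants import KB, DEFAULT_TEMPERATURE
from .mesh import CompartmentMesh, build_mesh
from .molecules import HydroParams, define_molecule_type
from .placement import mc_pack_dense, poisson_disc_volume, sample_surface
from .potentials import HarmonicRepulsion
from .propagation import Simulation
from .reactions import BiChannel, BiPath, UniChannel, UniPath

__all__ = [
    "cube_mesh",
    "icosphere_mesh",
    "hard_sphere_fluid",
    "hard_sphere_npt",
    "surface_diffusion_system",
    "ab_fusion_system",
    "multipath_two_bead_system",
]

#: Diffusion coefficient used by the hard-sphere validation runs (nm^2/ns).
HS_DIFFUSION = 0.0859
#: Hard-sphere diameter (nm).
HS_SIGMA = 1.0


def cube_mesh(edge: float = 1.0, center=(0.0, 0.0, 0.0)) -> CompartmentMesh:
    """Axis-aligned cube as 12 triangles with outward winding."""
    import trimesh

    box = trimesh.creation.box(extents=[edge] * 3)
    return build_mesh(np.asarray(box.vertices) + np.asarray(center, dtype=float),
                      np.asarray(box.faces))


def icosphere_mesh(subdivisions: int = 3, radius: float = 50.0,
                   center=(0.0, 0.0, 0.0)) -> CompartmentMesh:
    """Icosphere (subdivided icosahedron) compartment."""
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return build_mesh(np.asarray(ico.vertices) + np.asarray(center, dtype=float),
                      np.asarray(ico.faces))


def hard_sphere_fluid(n: int = 400, eta: float = 0.3, k: float = 20000.0,
                      dt: float = 4e-4, seed: int = 0,
                      D: float = HS_DIFFUSION,
                      temperature: float = DEFAULT_TEMPERATURE) -> Simulation:
    """Harmonic-repulsion approximation of a hard-sphere fluid at packing
    fraction ``eta`` in a periodic cubic box.

    The spring constant default makes the Barker-Henderson effective
    diameter ~0.986 sigma at 293 K, so hard-sphere theory applies with
    only a small softness correction; dt must satisfy
    D k dt / kT << 1 for a stable overdamped spring step.
    """
    v_sphere = np.pi / 6.0 * HS_SIGMA**3
    L = (n * v_sphere / eta) ** (1.0 / 3.0)
    sim = Simulation(box=[L, L, L], dt=dt, seed=seed, boundary="periodic",
                     temperature=temperature)
    sphere = define_molecule_type("HS", [[0.0, 0.0, 0.0]], [HS_SIGMA / 2.0],
                                  diffusion_constant=D)
    sim.register_species(sphere)
    sim.forcefield.set_pair("HS", "HS", HarmonicRepulsion(k=k, sigma=HS_SIGMA))
    pos, info = mc_pack_dense([L, L, L], np.full(n, HS_SIGMA / 2.0), seed=seed)
    if not info["converged"]:
        raise RuntimeError(f"could not pack {n} spheres at eta={eta}: {info}")
    sim.add_molecules("HS", pos)
    return sim


def hard_sphere_npt(n: int = 400, eta: float = 0.3, k: float = 100.0,
                    dt: float = 0.1, seed: int = 0,
                    P0: float = 10.0, tau_P: float = 2.5,
                    start_time: float = 0.5) -> Simulation:
    """Hard-sphere-like fluid in the NPT ensemble: the Berendsen barostat
    (target P0, coupling tau_P) activates at ``start_time`` ns."""
    sim = hard_sphere_fluid(n=n, eta=eta, k=k, dt=dt, seed=seed)
    sim.barostat = BarostatParams(P0=P0, tau_P=tau_P, start_time=start_time)
    return sim


def surface_diffusion_system(n_walkers: int = 1000, D: float = 0.043,
                             radius: float = 150.0, subdivisions: int = 3,
                             dt: float = 10.0, seed: int = 0) -> Simulation:
    """Non-interacting surface molecules ray-marched on an icosphere.

    D defaults to 0.043 nm^2/ns (= 43 nm^2/us); the box is sized to
    enclose the mesh.
    """
    mesh = icosphere_mesh(subdivisions=subdivisions, radius=radius,
                          center=(1.5 * radius,) * 3)
    L = 3.0 * radius
    sim = Simulation(box=[L, L, L], dt=dt, seed=seed, boundary="periodic",
                     mesh=mesh)
    walker = define_molecule_type("W", [[0.0, 0.0, 0.0]], [1.0],
                                  diffusion_constant=D, surface_bound=True)
    sim.register_species(walker)
    pos, tri = sample_surface(mesh, n_walkers, seed=seed)
    sim.add_molecules("W", pos, triangles=tri)
    return sim


def _sphere_species(name: str, radius: float, D: float | None = None,
                    params: HydroParams | None = None):
    return define_molecule_type(name, [[0.0, 0.0, 0.0]], [radius],
                                params=params, diffusion_constant=D)


def ab_fusion_system(n_a: int = 150, n_b: int = 150, n_c: int = 0,
                     box_l: float | None = None,
                     k_fusion: float = 0.001, k_fission: float = 5e-5,
                     R_react: float = 4.5, dt: float = 0.1, seed: int = 0,
                     repulsion_k: float = 0.0,
                     rho_tot: float = 0.00341) -> Simulation:
    """A + B <-> C benchmark (radii 1.5, 3.0, 3.12 nm).

    With ``repulsion_k = 0`` the species are ideal diffusers and, in the
    reaction-limited regime, the kinetics match the mass-action ODE with
    rates converted through k_macro.  ``repulsion_k > 0`` adds the
    harmonic excluded-volume interaction with sigma = r_i + r_j.
    """
    n_tot = n_a + n_b + n_c
    if box_l is None:
        box_l = (n_tot / rho_tot) ** (1.0 / 3.0)
    sim = Simulation(box=[box_l] * 3, dt=dt, seed=seed, boundary="periodic")
    radii = {"A": 1.5, "B": 3.0, "C": 3.12}
    for name, r in radii.items():
        sim.register_species(_sphere_species(name, r))
    if repulsion_k > 0:
        for x in radii:
            for y in radii:
                if x <= y:
                    sim.forcefield.set_pair(
                        x, y, HarmonicRepulsion(repulsion_k, radii[x] + radii[y])
                    )
    sim.reactions.add_bi(BiChannel(
        educts=("A", "B"),
        paths=[BiPath("fusion", rate=k_fusion, R_react=R_react, products=("C",))],
    ))
    if k_fission > 0:
        sim.reactions.add_uni(UniChannel(
            educt="C",
            paths=[UniPath("fission", rate=k_fission, products=("A", "B"),
                           radius=R_react)],
        ))
    rng = np.random.default_rng(seed)
    for name, count in (("A", n_a), ("B", n_b), ("C", n_c)):
        sim.add_molecules(name, rng.uniform(0.0, box_l, size=(count, 3)))
    return sim


def multipath_two_bead_system(n_a: int = 120, n_b: int = 120,
                              box_l: float = 75.0, dt: float = 0.1,
                              seed: int = 0,
                              rates=(0.002, 0.002, 0.002, 0.002),
                              radii=(3.0, 3.0, 3.0, 3.0),
                              k_back: float = 5e-5,
                              repulsion_k: float = 0.0) -> Simulation:
    """Two-bead molecules A(a1,a2) and B(b1,b2) with four fusion paths.

    Paths (following the reaction graph of the reference system):
      1. A(a1) + B(b1) -> C   2. A(a1) + B(b1) -> D
      3. A(a1) + B(b2) -> C   4. A(a2) + B(b2) -> C
    plus the fission C -> A + B.  C and D are single spheres.
    """
    sim = Simulation(box=[box_l] * 3, dt=dt, seed=seed, boundary="periodic")
    bead_r = 1.0
    sep = 2.0  # bead center separation within a molecule
    half = sep / 2.0
    A = define_molecule_type(
        "A", [[-half, 0, 0], [half, 0, 0]], [bead_r, bead_r],
        particle_types=["a1", "a2"],
    )
    B = define_molecule_type(
        "B", [[-half, 0, 0], [half, 0, 0]], [bead_r, bead_r],
        particle_types=["b1", "b2"],
    )
    sim.register_species(A)
    sim.register_species(B)
    sim.register_species(_sphere_species("C", 1.26))
    sim.register_species(_sphere_species("D", 1.26))
    k1, k2, k3, k4 = rates
    R1, R2, R3, R4 = radii
    sim.reactions.add_bi(BiChannel(("a1", "b1"), [
        BiPath("fusion", rate=k1, R_react=R1, products=("C",)),
        BiPath("fusion", rate=k2, R_react=R2, products=("D",)),
    ]))
    sim.reactions.add_bi(BiChannel(("a1", "b2"), [
        BiPath("fusion", rate=k3, R_react=R3, products=("C",)),
    ]))
    sim.reactions.add_bi(BiChannel(("a2", "b2"), [
        BiPath("fusion", rate=k4, R_react=R4, products=("C",)),
    ]))
    if k_back > 0:
        sim.reactions.add_uni(UniChannel("C", [
            UniPath("fission", rate=k_back, products=("A", "B"), radius=max(radii)),
        ]))
    if repulsion_k > 0:
        for pa in ("a1", "a2"):
            for pb in ("b1", "b2"):
                sim.forcefield.set_pair(pa, pb,
                                        HarmonicRepulsion(repulsion_k, 2 * bead_r))
    rng = np.random.default_rng(seed)
    from .propagation import random_quaternions

    for name, count in (("A", n_a), ("B", n_b)):
        pos = rng.uniform(0.0, box_l, size=(count, 3))
        sim.add_molecules(name, pos, quaternions=random_quaternions(rng, count))
    return sim
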