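"""Declarative YAML configuration: schema, validation, and run driver.

A configuration file describes a complete model: box and boundary,
molecule types (bead coordinates, radii, patches or a direct diffusion
constant), pair potentials, reaction channels, placement blocks,
integrator/barostat/output settings and the seed.  The schema is
validated with pydantic before any state is allocated; validation errors
report the JSON-pointer-style path of the offending field.

``run_config`` executes a validated configuration deterministically
(same seed, same outputs) and writes the trajectory (HDF5 + CSV + XYZ),
an event log, observables and a provenance record.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from .barostat import BarostatParams
from .constants import DEFAULT_TEMPERATURE
from .mesh import load_obj
from .molecules import HydroParams, define_molecule_type
from .observables import Trajectory, record_trajectory
from .placement import poisson_disc_volume, sample_surface
from .potentials import (
    ContinuousSquareWell,
    HarmonicRepulsion,
    PseudoHardSphere,
    WeakPiecewiseHarmonic,
)
from .propagation import Simulation, random_quaternions
from .reactions import BiChannel, BiPath, UniChannel, UniPath
from . import trajectory as trajio

__all__ = ["SimulationConfig", "load_config", "build_simulation", "run_config",
           "ConfigError"]


class ConfigError(ValueError):
    pass


class UnitsSection(BaseModel):
    length: Literal["nm"] = "nm"
    time: Literal["ns"] = "ns"
    energy: Literal["kJ/mol"] = "kJ/mol"


class BoxSection(BaseModel):
    lengths: list[float] = Field(min_length=3, max_length=3)
    boundary: Literal["periodic", "repulsive", "fixed_concentration"] = "periodic"
    concentrations: dict[str, float] = Field(default_factory=dict)


class SpeciesSection(BaseModel):
    beads: Optional[list[list[float]]] = None  # [[x,y,z],...]
    radii: Optional[list[float]] = None
    particle_types: Optional[list[str]] = None
    patches: Optional[list[dict]] = None  # {position: [x,y,z], type: name}
    diffusion_constant: Optional[float] = None  # nm^2/ns (single bead only)
    radius: Optional[float] = None  # shorthand for a single centered bead
    surface_bound: bool = False
    mesh_collision: Optional[Literal["reflect", "contact"]] = None

    @model_validator(mode="after")
    def _check(self):
        if self.radius is None and (self.beads is None or self.radii is None):
            raise ValueError("species needs either 'radius' or 'beads'+'radii'")
        return self


class PotentialSection(BaseModel):
    pair: list[str] = Field(min_length=2, max_length=2)  # particle type names
    kind: Literal["harmonic_repulsion", "weak_piecewise_harmonic", "csw", "phs"]
    k: Optional[float] = None
    sigma: Optional[float] = None
    depth: Optional[float] = None
    cutoff: Optional[float] = None
    eps: Optional[float] = None
    r_w: Optional[float] = None
    alpha: Optional[float] = None


class ReactionPathSection(BaseModel):
    kind: str
    rate: float = Field(ge=0.0)
    products: list[str] = Field(default_factory=list)
    radius: float = 0.0
    n_products: int = 1
    bond_k: float = 0.0
    unbind_rate: float = 0.0


class ReactionSection(BaseModel):
    educts: list[str] = Field(min_length=1, max_length=2)
    level: Literal["molecule", "particle"] = "molecule"
    paths: list[ReactionPathSection] = Field(min_length=1)


class PlacementSection(BaseModel):
    species: str
    count: int = Field(gt=0)
    method: Literal["uniform", "poisson_disc", "surface"] = "uniform"
    face_group: Optional[str] = None
    min_distance: float = 0.0


class IntegratorSection(BaseModel):
    dt: float = Field(gt=0.0)
    steps: int = Field(gt=0)
    temperature: float = DEFAULT_TEMPERATURE


class BarostatSection(BaseModel):
    P0: float
    tau_P: float = Field(gt=0.0)
    start_time: float = 0.0


class OutputSection(BaseModel):
    every: int = Field(default=1, gt=0)
    directory: str = "out"
    formats: list[Literal["hdf5", "csv", "xyz"]] = Field(
        default_factory=lambda: ["hdf5", "csv"])


class SimulationConfig(BaseModel):
    units: UnitsSection = Field(default_factory=UnitsSection)
    box: BoxSection
    species: dict[str, SpeciesSection]
    potentials: list[PotentialSection] = Field(default_factory=list)
    reactions: list[ReactionSection] = Field(default_factory=list)
    placement: list[PlacementSection] = Field(default_factory=list)
    integrator: IntegratorSection
    barostat: Optional[BarostatSection] = None
    mesh_file: Optional[str] = None
    output: OutputSection = Field(default_factory=OutputSection)
    seed: int = 0

    @model_validator(mode="after")
    def _cross_references(self):
        known_particles = set()
        for name, sp in self.species.items():
            if sp.particle_types:
                known_particles.update(sp.particle_types)
            else:
                known_particles.add(name)
            if sp.patches:
                known_particles.update(p["type"] for p in sp.patches)
        for r in self.reactions:
            for p in r.paths:
                for prod in p.products:
                    if prod not in self.species and prod not in known_particles:
                        raise ValueError(
                            f"reaction product {prod!r} is not a defined species "
                            "or particle type")
        for pl in self.placement:
            if pl.species not in self.species:
                raise ValueError(f"placement species {pl.species!r} undefined")
        return self


def load_config(path) -> tuple[SimulationConfig, str]:
    """Parse and validate a YAML config; returns (config, raw text)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    try:
        return SimulationConfig.model_validate(data), text
    except ValidationError as err:
        msgs = []
        for e in err.errors():
            ptr = "/" + "/".join(str(x) for x in e["loc"])
            msgs.append(f"{ptr}: {e['msg']}")
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(msgs)) from err


def _build_potential(p: PotentialSection):
    if p.kind == "harmonic_repulsion":
        return HarmonicRepulsion(k=p.k, sigma=p.sigma)
    if p.kind == "weak_piecewise_harmonic":
        return WeakPiecewiseHarmonic(k=p.k, sigma=p.sigma, depth=p.depth, rc=p.cutoff)
    if p.kind == "csw":
        return ContinuousSquareWell(eps=p.eps, r_w=p.r_w, alpha=p.alpha, rc=p.cutoff)
    return PseudoHardSphere(eps=p.eps, sigma=p.sigma)


def build_simulation(cfg: SimulationConfig, base_dir: Path | str = ".") -> Simulation:
    mesh = None
    if cfg.mesh_file:
        mesh = load_obj(Path(base_dir) / cfg.mesh_file)
    sim = Simulation(
        box=cfg.box.lengths,
        dt=cfg.integrator.dt,
        seed=cfg.seed,
        boundary=cfg.box.boundary,
        temperature=cfg.integrator.temperature,
        mesh=mesh,
        concentrations=cfg.box.concentrations,
        barostat=BarostatParams(**cfg.barostat.model_dump()) if cfg.barostat else None,
    )
    params = HydroParams(temperature=cfg.integrator.temperature)
    for name, sp in cfg.species.items():
        if sp.radius is not None:
            beads, radii = [[0.0, 0.0, 0.0]], [sp.radius]
        else:
            beads, radii = sp.beads, sp.radii
        patches = None
        if sp.patches:
            patches = [(p["position"], p["type"]) for p in sp.patches]
        mtype = define_molecule_type(
            name, beads, radii, particle_types=sp.particle_types, patches=patches,
            params=params, surface_bound=sp.surface_bound,
            diffusion_constant=sp.diffusion_constant,
        )
        sim.register_species(mtype, mesh_collision=sp.mesh_collision)
    for p in cfg.potentials:
        sim.forcefield.set_pair(p.pair[0], p.pair[1], _build_potential(p))
    for r in cfg.reactions:
        if len(r.educts) == 1:
            sim.reactions.add_uni(UniChannel(
                educt=r.educts[0], level=r.level,
                paths=[UniPath(kind=p.kind, rate=p.rate, products=tuple(p.products),
                               radius=p.radius, n_products=p.n_products)
                       for p in r.paths],
            ))
        else:
            sim.reactions.add_bi(BiChannel(
                educts=(r.educts[0], r.educts[1]), level=r.level,
                paths=[BiPath(kind=p.kind, rate=p.rate, R_react=p.radius,
                              products=tuple(p.products), bond_k=p.bond_k,
                              unbind_rate=p.unbind_rate)
                       for p in r.paths],
            ))
    rng = np.random.default_rng(cfg.seed)
    box = np.asarray(cfg.box.lengths)
    for pl in cfg.placement:
        sp = cfg.species[pl.species]
        if pl.method == "surface":
            if mesh is None:
                raise ConfigError("surface placement requires a mesh_file")
            pos, tri = sample_surface(mesh, pl.count,
                                      min_distance=pl.min_distance,
                                      face_group=pl.face_group,
                                      seed=int(rng.integers(2**31)))
            sim.add_molecules(pl.species, pos, triangles=tri)
        elif pl.method == "poisson_disc":
            r = sp.radius if sp.radius is not None else max(sp.radii)
            pos, _ = poisson_disc_volume(box, r, seed=int(rng.integers(2**31)),
                                         max_n=pl.count, mesh=mesh)
            sim.add_molecules(pl.species, pos[: pl.count],
                              quaternions=random_quaternions(rng, min(len(pos), pl.count)))
        else:
            pos = rng.uniform(0.0, box, size=(pl.count, 3))
            sim.add_molecules(pl.species, pos,
                              quaternions=random_quaternions(rng, pl.count))
    return sim


def run_config(path, out_dir=None, overrides: dict | None = None,
               steps: int | None = None, seed: int | None = None) -> dict:
    """Run a configuration file end to end; returns a result summary."""
    cfg, text = load_config(path)
    if seed is not None:
        cfg.seed = seed
    if steps is not None:
        cfg.integrator.steps = steps
    if overrides:
        data = yaml.safe_load(text)
        for key, value in overrides.items():
            node = data
            parts = key.split(".")
            for p in parts[:-1]:
                node = node[p]
            node[parts[-1]] = yaml.safe_load(str(value))
        cfg = SimulationConfig.model_validate(data)
        if seed is not None:
            cfg.seed = seed
        if steps is not None:
            cfg.integrator.steps = steps
    out = Path(out_dir) if out_dir is not None else Path("out")
    out.mkdir(parents=True, exist_ok=True)
    sim = build_simulation(cfg, base_dir=Path(path).parent)
    traj = Trajectory()
    output = cfg.output
    sim.run(cfg.integrator.steps, callback=record_trajectory(traj),
            callback_every=output.every)
    if "hdf5" in output.formats:
        trajio.write_hdf5(traj, out / "trajectory.h5")
    if "csv" in output.formats:
        trajio.write_csv(traj, out / "trajectory.csv")
    trajio.write_xyz(traj, out / "trajectory.xyz")
    with open(out / "events.jsonl", "w") as fh:
        for ev in sim.event_log:
            fh.write(json.dumps([ev[0], ev[1], *map(int, ev[2:])]) + "\n")
    trajio.write_provenance(out / "provenance.json", text, cfg.seed)
    trajio.write_observable_csv(out / "pressure.csv", {
        "time": np.asarray(traj.times),
        "pressure": np.asarray(traj.pressures),
    })
    return {
        "frames": traj.n_frames,
        "final_counts": sim.counts(),
        "n_events": len(sim.event_log),
        "out_dir": str(out),
    }
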