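"""Brownian-dynamics propagation and the main simulation loop.

Molecules follow overdamped (Brownian) rigid-body dynamics.  Each step
the translational update is taken in the body frame,

    dx_b = (D_tt F_b / k_B T) dt + xi,     xi ~ N(0, 2 D_tt dt),

rotated to the world frame, and the orientational update is a body-frame
rotation vector with drift (D_rr T_b / k_B T) dt and covariance
2 D_rr dt, applied by quaternion multiplication and renormalization
(first-order Euler-Maruyama; translation-rotation coupling is neglected
by default).

One simulation step performs, in order:

1.  position/orientation update of every molecule, including boundary
    handling (wrap, mirror reflection, or outflux removal) and mesh
    collision response;
2.  one sweep over the neighbor-list particle pairs that both
    accumulates forces/torques/virial and fills the reaction event list
    with Doi-scheme bimolecular events;
3.  unimolecular timers are checked and due events appended;
4.  events execute in uniformly random order; an event whose educt was
    consumed (or already reacted) this step is invalidated.  Forces are
    not recomputed after reactions - products feel forces from the next
    step's sweep - except binding bonds, whose force is evaluated at
    execution time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .barostat import BarostatParams, berendsen_mu
from .boundaries import (
    BoundarySpec,
    fixed_conc_influx,
    minimum_image,
    reflect_box,
    wrap_positions,
)
from .constants import KB, DEFAULT_TEMPERATURE
from .mesh import CompartmentMesh, ray_trace_reflect, surface_ray_march
from .molecules import MoleculeType
from .neighbors import build_hgrid, collect_pairs
from .potentials import ForceField
from .reactions import ReactionRegistry, sample_next_reaction_time
from .state import ReactionList

__all__ = [
    "IntegratorSettings",
    "Simulation",
    "propagate_step",
    "quat_to_matrix",
    "quat_multiply",
    "random_quaternions",
]

VOID_PARTICLE = "void"  # inert particle type used by particle-level decay


# -- quaternion helpers (scalar-first convention) -------------------------


def quat_multiply(q1, q2):
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    w1, x1, y1, z1 = np.moveaxis(q1, -1, 0)
    w2, x2, y2, z2 = np.moveaxis(q2, -1, 0)
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def quat_to_matrix(q):
    """Rotation matrix (or batch thereof) from unit quaternion(s)."""
    q = np.asarray(q, dtype=float)
    w, x, y, z = np.moveaxis(q, -1, 0)
    m = np.empty(q.shape[:-1] + (3, 3))
    m[..., 0, 0] = 1 - 2 * (y * y + z * z)
    m[..., 0, 1] = 2 * (x * y - z * w)
    m[..., 0, 2] = 2 * (x * z + y * w)
    m[..., 1, 0] = 2 * (x * y + z * w)
    m[..., 1, 1] = 1 - 2 * (x * x + z * z)
    m[..., 1, 2] = 2 * (y * z - x * w)
    m[..., 2, 0] = 2 * (x * z - y * w)
    m[..., 2, 1] = 2 * (y * z + x * w)
    m[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return m


def rotvec_to_quat(phi):
    """Unit quaternion(s) from rotation vector(s)."""
    phi = np.asarray(phi, dtype=float)
    angle = np.linalg.norm(phi, axis=-1, keepdims=True)
    small = angle < 1e-12
    axis = np.where(small, 0.0, phi / np.where(small, 1.0, angle))
    half = 0.5 * angle[..., 0]
    q = np.empty(phi.shape[:-1] + (4,))
    q[..., 0] = np.cos(half)
    q[..., 1:] = axis * np.sin(half)[..., None]
    return q


def random_quaternions(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniformly distributed unit quaternions (Shoemake's method)."""
    u1, u2, u3 = rng.random((3, n))
    a, b = np.sqrt(1 - u1), np.sqrt(u1)
    return np.stack(
        [
            a * np.sin(2 * np.pi * u2),
            a * np.cos(2 * np.pi * u2),
            b * np.sin(2 * np.pi * u3),
            b * np.cos(2 * np.pi * u3),
        ],
        axis=1,
    )


@dataclass
class IntegratorSettings:
    dt: float  # ns
    temperature: float = DEFAULT_TEMPERATURE
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def kT(self) -> float:
        return KB * self.temperature


def propagate_step(position, quaternion, force, torque, mtype: MoleculeType,
                   settings: IntegratorSettings, rng: np.random.Generator):
    """One free Brownian step of a single rigid bead molecule.

    Returns (position, quaternion); the quaternion is renormalized.
    """
    position = np.asarray(position, dtype=float)
    force = np.asarray(force, dtype=float)
    torque = np.asarray(torque, dtype=float)
    if not (np.all(np.isfinite(force)) and np.all(np.isfinite(torque))):
        raise FloatingPointError("non-finite force/torque in propagation")
    dt = settings.dt
    kT = settings.kT
    R = quat_to_matrix(quaternion)
    lt = np.linalg.cholesky(2.0 * mtype.D_tt * dt)
    lr = np.linalg.cholesky(2.0 * mtype.D_rr * dt)
    f_b = R.T @ force
    dx_b = mtype.D_tt @ f_b / kT * dt + lt @ rng.standard_normal(3)
    t_b = R.T @ torque
    dphi_b = mtype.D_rr @ t_b / kT * dt + lr @ rng.standard_normal(3)
    q = quat_multiply(quaternion, rotvec_to_quat(dphi_b))
    q = q / np.linalg.norm(q)
    return position + R @ dx_b, q


class _TypeTable:
    """Registered molecule types, particle types and derived cutoffs."""

    def __init__(self):
        self.types: list[MoleculeType] = []
        self.by_name: dict[str, int] = {}
        self.ptype_names: list[str] = [VOID_PARTICLE]
        self.ptype_ids: dict[str, int] = {VOID_PARTICLE: 0}

    def add(self, mtype: MoleculeType) -> int:
        if mtype.name in self.by_name:
            raise ValueError(f"molecule type {mtype.name!r} already defined")
        tid = len(self.types)
        self.types.append(mtype)
        self.by_name[mtype.name] = tid
        for p in mtype.particle_types:
            if p not in self.ptype_ids:
                self.ptype_ids[p] = len(self.ptype_names)
                self.ptype_names.append(p)
        return tid

    def __getitem__(self, tid: int) -> MoleculeType:
        return self.types[tid]

    def particle_type_ids(self, mtype: MoleculeType) -> np.ndarray:
        return np.array([self.ptype_ids[p] for p in mtype.particle_types], dtype=np.int64)


class Simulation:
    """A reaction-interaction-diffusion system in a rectangular box."""

    def __init__(self, box, dt, seed=0, boundary: str = "periodic",
                 temperature: float = DEFAULT_TEMPERATURE,
                 mesh: CompartmentMesh | None = None,
                 concentrations: dict[str, float] | None = None,
                 barostat: BarostatParams | None = None):
        self.boundary = BoundarySpec(kind=boundary, box=np.asarray(box, dtype=float),
                                     concentrations=concentrations or {})
        self.settings = IntegratorSettings(dt=dt, temperature=temperature, seed=seed)
        self.rng = np.random.Generator(np.random.Philox(seed))
        self.mesh = mesh
        self.barostat = barostat
        self.forcefield = ForceField()
        self.reactions = ReactionRegistry()
        self.table = _TypeTable()
        self.time = 0.0
        self.step_count = 0
        # molecule storage (tightly packed, pop-and-swap; ids never reused)
        self._cap = 64
        self.n = 0
        self._next_id = 0
        self.ids = np.zeros(self._cap, dtype=np.int64)
        self.type_id = np.zeros(self._cap, dtype=np.int64)
        self.pos = np.zeros((self._cap, 3))
        self.image = np.zeros((self._cap, 3), dtype=np.int64)
        self.quat = np.zeros((self._cap, 4))
        self.force = np.zeros((self._cap, 3))
        self.torque = np.zeros((self._cap, 3))
        self.next_event = np.full(self._cap, np.inf)
        self.tri = np.full(self._cap, -1, dtype=np.int64)
        self._loc: dict[int, int] = {}
        self._ptype_override: dict[int, np.ndarray] = {}
        self.bonds: dict[tuple, dict] = {}  # ((id,slot),(id,slot)) -> {k, r0}
        self.potential_energy = 0.0
        self.pair_virial = 0.0
        self.pressure = float("nan")
        self.event_log: list[tuple] = []
        self._mesh_collision: dict[str, str] = {}  # type name -> reflect|contact
        self._mesh_contact_k = 100.0
        self._cutoff_cache: np.ndarray | None = None

    # -- model definition -------------------------------------------
    @property
    def box(self) -> np.ndarray:
        return self.boundary.box

    @property
    def dt(self) -> float:
        return self.settings.dt

    @property
    def kT(self) -> float:
        return self.settings.kT

    def register_species(self, mtype: MoleculeType, mesh_collision: str | None = None):
        tid = self.table.add(mtype)
        if mesh_collision is not None:
            if mesh_collision not in ("reflect", "contact"):
                raise ValueError("mesh_collision must be 'reflect' or 'contact'")
            self._mesh_collision[mtype.name] = mesh_collision
        self._cutoff_cache = None
        return tid

    def species(self, name: str) -> MoleculeType:
        return self.table[self.table.by_name[name]]

    # -- molecule bookkeeping ----------------------------------------
    def _ensure_capacity(self, extra: int):
        need = self.n + extra
        if need <= self._cap:
            return
        while self._cap < need:
            self._cap *= 2
        for name in ("ids", "type_id", "tri"):
            arr = getattr(self, name)
            new = np.zeros(self._cap, dtype=arr.dtype)
            new[: self.n] = arr[: self.n]
            setattr(self, name, new)
        for name in ("pos", "image", "quat", "force", "torque"):
            arr = getattr(self, name)
            new = np.zeros((self._cap,) + arr.shape[1:], dtype=arr.dtype)
            new[: self.n] = arr[: self.n]
            setattr(self, name, new)
        new = np.full(self._cap, np.inf)
        new[: self.n] = self.next_event[: self.n]
        self.next_event = new

    def add_molecule(self, type_name: str, position, quaternion=None,
                     triangle: int = -1) -> int:
        tid = self.table.by_name[type_name]
        self._ensure_capacity(1)
        i = self.n
        mol_id = self._next_id
        self._next_id += 1
        self.ids[i] = mol_id
        self.type_id[i] = tid
        self.pos[i] = position
        self.image[i] = 0
        self.quat[i] = quaternion if quaternion is not None else (1.0, 0.0, 0.0, 0.0)
        self.force[i] = 0.0
        self.torque[i] = 0.0
        self.tri[i] = triangle
        self.next_event[i] = self.time + self._draw_lifetime(tid, mol_id)
        self._loc[mol_id] = i
        self.n += 1
        return mol_id

    def add_molecules(self, type_name: str, positions, quaternions=None,
                      triangles=None) -> list[int]:
        positions = np.atleast_2d(positions)
        out = []
        for k, p in enumerate(positions):
            q = None if quaternions is None else quaternions[k]
            t = -1 if triangles is None else int(triangles[k])
            out.append(self.add_molecule(type_name, p, q, t))
        return out

    def remove_molecule(self, mol_id: int):
        i = self._loc.pop(mol_id)
        last = self.n - 1
        if i != last:
            for name in ("ids", "type_id", "pos", "image", "quat", "force",
                         "torque", "next_event", "tri"):
                arr = getattr(self, name)
                arr[i] = arr[last]
            self._loc[int(self.ids[i])] = i
        self.n = last
        self._ptype_override.pop(mol_id, None)
        # drop bonds involving this molecule
        dead = [key for key in self.bonds if key[0][0] == mol_id or key[1][0] == mol_id]
        for key in dead:
            del self.bonds[key]

    def index_of(self, mol_id: int) -> int:
        return self._loc[mol_id]

    def alive(self, mol_id: int) -> bool:
        return mol_id in self._loc

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for tid in range(len(self.table.types)):
            out[self.table[tid].name] = int(np.sum(self.type_id[: self.n] == tid))
        return out

    def unwrapped_positions(self) -> np.ndarray:
        return self.pos[: self.n] + self.image[: self.n] * self.box

    # -- unimolecular scheduling ------------------------------------
    def _uni_options(self, tid: int, mol_id: int):
        """All (rate, channel, path, particle_slot) open to a molecule."""
        mtype = self.table[tid]
        opts = []
        ch = self.reactions.uni.get(mtype.name)
        if ch is not None and ch.level == "molecule":
            for p in ch.paths:
                if p.rate > 0:
                    opts.append((p.rate, ch, p, -1))
        ptypes = self._particle_type_names(tid, mol_id)
        for slot, pname in enumerate(ptypes):
            pch = self.reactions.uni.get(pname)
            if pch is not None and pch.level == "particle":
                for p in pch.paths:
                    if p.rate > 0:
                        opts.append((p.rate, pch, p, slot))
        return opts

    def _particle_type_names(self, tid: int, mol_id: int) -> list[str]:
        if mol_id in self._ptype_override:
            return [self.table.ptype_names[j] for j in self._ptype_override[mol_id]]
        return self.table[tid].particle_types

    def _draw_lifetime(self, tid: int, mol_id: int) -> float:
        k_t = sum(o[0] for o in self._uni_options(tid, mol_id))
        return sample_next_reaction_time(k_t, self.rng)

    def reschedule(self, mol_id: int):
        i = self._loc[mol_id]
        self.next_event[i] = self.time + self._draw_lifetime(int(self.type_id[i]), mol_id)

    # -- particle expansion ------------------------------------------
    def _expand_particles(self):
        """World-frame particle arrays (pos, ptype id, molecule index,
        body offset)."""
        n = self.n
        chunks_pos, chunks_t, chunks_m, chunks_off = [], [], [], []
        tids = self.type_id[:n]
        for tid in np.unique(tids):
            mtype = self.table[int(tid)]
            idx = np.flatnonzero(tids == tid)
            k = mtype.n_particles
            base_pt = self.table.particle_type_ids(mtype)
            if k == 1 and np.allclose(mtype.particle_positions[0], 0.0):
                chunks_pos.append(self.pos[idx])
                chunks_t.append(np.broadcast_to(base_pt, (len(idx), 1)).reshape(-1))
                chunks_m.append(idx)
                chunks_off.append(np.zeros((len(idx), 3)))
                continue
            R = quat_to_matrix(self.quat[idx])  # (m,3,3)
            off = np.einsum("mij,kj->mki", R, mtype.particle_positions)  # (m,k,3)
            chunks_pos.append((self.pos[idx][:, None, :] + off).reshape(-1, 3))
            pt = np.broadcast_to(base_pt, (len(idx), k)).copy()
            for row, i in enumerate(idx):
                ov = self._ptype_override.get(int(self.ids[i]))
                if ov is not None:
                    pt[row] = ov
            chunks_t.append(pt.reshape(-1))
            chunks_m.append(np.repeat(idx, k))
            chunks_off.append(off.reshape(-1, 3))
        if not chunks_pos:
            return (np.empty((0, 3)), np.empty(0, dtype=np.int64),
                    np.empty(0, dtype=np.int64), np.empty((0, 3)))
        return (np.vstack(chunks_pos), np.concatenate(chunks_t),
                np.concatenate(chunks_m), np.vstack(chunks_off))

    def _particle_cutoffs(self) -> np.ndarray:
        """Per-particle-type cutoff diameter covering potentials and
        reaction radii."""
        if self._cutoff_cache is None:
            names = self.table.ptype_names
            cut = np.zeros(len(names))
            for k, name in enumerate(names):
                cut[k] = max(
                    self.forcefield.max_cutoff_for(name),
                    self.reactions.max_reaction_radius_for(name),
                )
            self._cutoff_cache = cut
        return self._cutoff_cache

    def invalidate_cutoffs(self):
        self._cutoff_cache = None

    # -- force / reaction sweep --------------------------------------
    def sweep(self) -> ReactionList:
        """Pair sweep: fills forces, torques, virial, potential energy,
        pressure, and returns the bimolecular event list."""
        n = self.n
        self.force[:n] = 0.0
        self.torque[:n] = 0.0
        self.potential_energy = 0.0
        self.pair_virial = 0.0
        events = ReactionList()
        ppos, ptid, pmol, poff = self._expand_particles()
        cut_table = self._particle_cutoffs()
        pcut = cut_table[ptid]
        active = pcut > 0.0
        have_pairs = bool(np.any(active)) and len(ppos) > 1
        if have_pairs:
            sub = np.flatnonzero(active)
            periodic = self.boundary.kind == "periodic"
            grid = build_hgrid(ppos[sub], pcut[sub], self.box, periodic=periodic)
            gi, gj, gd, gr = collect_pairs(grid)
            gi, gj = sub[gi], sub[gj]
            # exclude intramolecular pairs
            keep = pmol[gi] != pmol[gj]
            gi, gj, gd, gr = gi[keep], gj[keep], gd[keep], gr[keep]
            self._pair_forces_and_reactions(events, gi, gj, gd, gr,
                                            ppos, ptid, pmol, poff)
        self._bond_forces(ppos, pmol, poff)
        self.pressure = (self.n * self.kT + self.pair_virial / 3.0) / self.boundary.volume
        return events

    def _pair_forces_and_reactions(self, events, gi, gj, gd, gr,
                                   ppos, ptid, pmol, poff):
        names = self.table.ptype_names
        ti, tj = ptid[gi], ptid[gj]
        key = np.minimum(ti, tj) * len(names) + np.maximum(ti, tj)
        order = np.argsort(key, kind="stable")
        bounds = np.flatnonzero(np.diff(key[order], prepend=-1))
        dt = self.dt
        for b0, b1 in zip(bounds, list(bounds[1:]) + [len(order)]):
            sel = order[b0:b1]
            a_id, b_id = int(ti[sel[0]]), int(tj[sel[0]])
            na, nb = names[min(a_id, b_id)], names[max(a_id, b_id)]
            pot = self.forcefield.get_pair(na, nb)
            r = gr[sel]
            if pot is not None:
                inr = r < pot.cutoff
                if np.any(inr):
                    s = sel[inr]
                    u, du = pot.u_and_du(r[inr])
                    self.potential_energy += float(np.sum(u))
                    rhat = gd[s] / gr[s][:, None]
                    fj = -du[:, None] * rhat  # force on particle j
                    mi, mj = pmol[gi[s]], pmol[gj[s]]
                    np.add.at(self.force, mj, fj)
                    np.add.at(self.force, mi, -fj)
                    np.add.at(self.torque, mj, np.cross(poff[gj[s]], fj))
                    np.add.at(self.torque, mi, np.cross(poff[gi[s]], -fj))
                    # molecular virial: molecule-center separation . pair force
                    dmol = gd[s] - poff[gj[s]] + poff[gi[s]]
                    self.pair_virial += float(np.einsum("ij,ij->", dmol, fj))
            # bimolecular reactions on this particle-type pair
            channels = self.reactions.bi_for(na, nb)
            if not channels:
                continue
            radii = [p.R_react for ch in channels for p in ch.paths]
            rmax = max(radii)
            cand = sel[r < rmax]
            if len(cand) == 0:
                continue
            ksum = np.zeros(len(cand))
            for ch in channels:
                for p in ch.paths:
                    ksum += np.where(gr[cand] < p.R_react, p.rate, 0.0)
            pfire = 1.0 - np.exp(-ksum * dt)
            fire = self.rng.random(len(cand)) < pfire
            for c in cand[fire]:
                rdist = gr[c]
                opts = [
                    (p.rate, ch, p)
                    for ch in channels
                    for p in ch.paths
                    if rdist < p.R_react
                ]
                rates = np.array([o[0] for o in opts])
                pick = opts[int(self.rng.choice(len(opts), p=rates / rates.sum()))]
                _, ch, path = pick
                mi, mj = int(pmol[gi[c]]), int(pmol[gj[c]])
                # orient educts so the first channel educt name comes first
                if names[int(ptid[gi[c]])] == ch.educts[0]:
                    first, second = mi, mj
                    pfirst, psecond = int(gi[c]), int(gj[c])
                else:
                    first, second = mj, mi
                    pfirst, psecond = int(gj[c]), int(gi[c])
                payload = {
                    "type": "bi",
                    "channel": ch,
                    "path": path,
                    "mid_first": int(self.ids[first]),
                    "mid_second": int(self.ids[second]),
                    "slot_first": int(pfirst - np.flatnonzero(pmol == first)[0]),
                    "slot_second": int(psecond - np.flatnonzero(pmol == second)[0]),
                }
                events.add(payload, (int(self.ids[first]), int(self.ids[second])))

    def _bond_forces(self, ppos, pmol, poff):
        if not self.bonds:
            return
        for (ka, kb), bond in self.bonds.items():
            ia = self._loc.get(ka[0])
            ib = self._loc.get(kb[0])
            if ia is None or ib is None:
                continue
            pa = self._particle_world(ia, ka[1])
            pb = self._particle_world(ib, kb[1])
            d = pb - pa
            if self.boundary.kind == "periodic":
                d = minimum_image(d, self.box)
            r = float(np.linalg.norm(d))
            if r < 1e-12:
                continue
            fmag = -bond["k"] * (r - bond["r0"])  # force on b along +d
            fb = fmag * d / r
            self.force[ib] += fb
            self.force[ia] -= fb
            offa = self._particle_offset(ia, ka[1])
            offb = self._particle_offset(ib, kb[1])
            self.torque[ib] += np.cross(offb, fb)
            self.torque[ia] += np.cross(offa, -fb)
            self.potential_energy += 0.5 * bond["k"] * (r - bond["r0"]) ** 2
            dmol = d - offb + offa
            self.pair_virial += float(dmol @ fb)

    def _particle_offset(self, i: int, slot: int) -> np.ndarray:
        mtype = self.table[int(self.type_id[i])]
        R = quat_to_matrix(self.quat[i])
        return R @ mtype.particle_positions[slot]

    def _particle_world(self, i: int, slot: int) -> np.ndarray:
        return self.pos[i] + self._particle_offset(i, slot)

    # -- propagation --------------------------------------------------
    def _propagate(self):
        n = self.n
        if n == 0:
            return
        dt = self.dt
        kT = self.kT
        tids = self.type_id[:n]
        order = np.argsort(self.ids[:n], kind="stable")
        for tid in np.unique(tids):
            mtype = self.table[int(tid)]
            idx = order[np.flatnonzero(tids[order] == tid)]
            if mtype.surface_bound:
                self._propagate_surface(idx, mtype)
                continue
            m = len(idx)
            if mtype.is_isotropic and abs(
                mtype.D_tt[0, 0] - mtype.D_tt[1, 1]
            ) < 1e-15:
                D = mtype.D_tt[0, 0]
                dx = (
                    D * self.force[idx] / kT * dt
                    + np.sqrt(2.0 * D * dt) * self.rng.standard_normal((m, 3))
                )
            else:
                R = quat_to_matrix(self.quat[idx])
                lt = np.linalg.cholesky(2.0 * mtype.D_tt * dt)
                f_b = np.einsum("nji,nj->ni", R, self.force[idx])
                dx_b = f_b @ mtype.D_tt.T / kT * dt + self.rng.standard_normal(
                    (m, 3)
                ) @ lt.T
                dx = np.einsum("nij,nj->ni", R, dx_b)
            # rotational update (skipped for perfectly isotropic tracers
            # would lose orientation statistics; always propagate)
            lr = np.linalg.cholesky(2.0 * mtype.D_rr * dt)
            Rm = quat_to_matrix(self.quat[idx])
            t_b = np.einsum("nji,nj->ni", Rm, self.torque[idx])
            dphi = t_b @ mtype.D_rr.T / kT * dt + self.rng.standard_normal(
                (len(idx), 3)
            ) @ lr.T
            dq = rotvec_to_quat(dphi)
            q = quat_multiply(self.quat[idx], dq)
            self.quat[idx] = q / np.linalg.norm(q, axis=1, keepdims=True)
            self._apply_displacement(idx, dx, mtype)

    def _apply_displacement(self, idx, dx, mtype):
        mode = self._mesh_collision.get(mtype.name)
        if self.mesh is not None and mode == "reflect":
            for row, i in enumerate(idx):
                newp, _ = ray_trace_reflect(self.pos[i], dx[row], self.mesh)
                self.pos[i] = newp
        else:
            self.pos[idx] += dx

    def _propagate_surface(self, idx, mtype):
        if self.mesh is None:
            raise RuntimeError("surface-bound species require a compartment mesh")
        dt = self.dt
        D = mtype.D_scalar  # in-plane scalar diffusion coefficient
        sigma = np.sqrt(2.0 * D * dt)
        xi = self.rng.standard_normal((len(idx), 2)) * sigma
        for row, i in enumerate(idx):
            tri = int(self.tri[i])
            nrm = self.mesh.normals[tri]
            # tangent basis
            t1 = np.cross(nrm, [1.0, 0.0, 0.0])
            if np.linalg.norm(t1) < 1e-6:
                t1 = np.cross(nrm, [0.0, 1.0, 0.0])
            t1 /= np.linalg.norm(t1)
            t2 = np.cross(nrm, t1)
            disp = xi[row, 0] * t1 + xi[row, 1] * t2
            f_plane = self.force[i] - (self.force[i] @ nrm) * nrm
            disp = disp + D * f_plane / self.kT * dt
            pos, tri, dq = surface_ray_march(self.pos[i], tri, disp, self.mesh)
            self.pos[i] = pos
            self.tri[i] = tri
            q = quat_multiply(dq, self.quat[i])
            self.quat[i] = q / np.linalg.norm(q)

    # -- boundary handling -------------------------------------------
    def _apply_boundary(self):
        n = self.n
        kind = self.boundary.kind
        if n and kind == "periodic":
            wrapped, shift = wrap_positions(self.pos[:n], self.box)
            self.pos[:n] = wrapped
            self.image[:n] += shift
        elif n and kind == "repulsive":
            self.pos[:n] = reflect_box(self.pos[:n], self.box)
        elif kind == "fixed_concentration":
            outside = np.flatnonzero(
                np.any((self.pos[:n] < 0) | (self.pos[:n] >= self.box), axis=1)
            )
            for mol_id in self.ids[outside].tolist():
                self.event_log.append((self.time, "outflux", mol_id))
                self.remove_molecule(mol_id)
            for name, tid in self.table.by_name.items():
                mtype = self.table[tid]
                pos = fixed_conc_influx(
                    self.boundary, name, mtype.D_scalar, self.dt, self.rng,
                    surface=mtype.surface_bound,
                )
                if len(pos):
                    quats = random_quaternions(self.rng, len(pos))
                    new = self.add_molecules(name, pos, quats)
                    for mol_id in new:
                        self.event_log.append((self.time, "influx", mol_id))

    # -- reaction execution -------------------------------------------
    def _collect_due_unimolecular(self, events: ReactionList):
        due = np.flatnonzero(self.next_event[: self.n] <= self.time)
        for i in due:
            mol_id = int(self.ids[i])
            events.add({"type": "uni", "mid": mol_id}, (mol_id,))

    def _execute_events(self, events: ReactionList):
        while len(events):
            payload, educts = events.pop_random(self.rng)
            if not all(self.alive(e) for e in educts):
                continue
            consumed = self._execute_one(payload)
            for e in educts:
                events.clear_for_educt(e)
            for e in consumed:
                events.clear_for_educt(e)

    def _execute_one(self, payload) -> list[int]:
        """Execute a single event; returns molecule ids consumed/reacted."""
        if payload["type"] == "uni":
            return self._execute_uni(payload["mid"])
        return self._execute_bi(payload)

    def _execute_uni(self, mol_id: int) -> list[int]:
        i = self._loc[mol_id]
        tid = int(self.type_id[i])
        opts = self._uni_options(tid, mol_id)
        if not opts:
            self.next_event[i] = np.inf
            return []
        rates = np.array([o[0] for o in opts])
        rate, ch, path, slot = opts[int(self.rng.choice(len(opts), p=rates / rates.sum()))]
        kind = path.kind
        self.event_log.append((self.time, kind, mol_id))
        if ch.level == "particle":
            return self._execute_uni_particle(mol_id, path, slot)
        if kind == "decay":
            self.remove_molecule(mol_id)
            return [mol_id]
        if kind == "conversion":
            self._convert_molecule(mol_id, path.products[0])
            return [mol_id]
        if kind == "fission":
            pos = self.pos[i].copy()
            q = self.quat[i].copy()
            self.remove_molecule(mol_id)
            u = self._random_unit()
            r = path.radius
            self.add_molecule(path.products[0], pos - 0.5 * r * u, q)
            self.add_molecule(path.products[1], pos + 0.5 * r * u, q)
            return [mol_id]
        if kind == "production":
            pos = self.pos[i]
            for _ in range(path.n_products):
                u = self._random_unit()
                self.add_molecule(path.products[0], pos + path.radius * u)
            self.reschedule(mol_id)
            return [mol_id]
        raise ValueError(f"kind {kind!r} not valid at molecule level")

    def _execute_uni_particle(self, mol_id: int, path, slot: int) -> list[int]:
        i = self._loc[mol_id]
        tid = int(self.type_id[i])
        kind = path.kind
        if kind == "release":
            ppos = self._particle_world(i, slot)
            u = self._random_unit()
            self.add_molecule(path.products[0], ppos + path.radius * u)
            if len(path.products) > 1:
                self._retype_particle(mol_id, slot, path.products[1])
            self.reschedule(mol_id)
            return [mol_id]
        if kind == "decay":
            self._retype_particle(mol_id, slot, VOID_PARTICLE)
            return [mol_id]
        if kind == "conversion":
            self._retype_particle(mol_id, slot, path.products[0])
            return [mol_id]
        raise ValueError(f"kind {kind!r} not valid at particle level")

    def _execute_bi(self, payload) -> list[int]:
        path = payload["path"]
        ch = payload["channel"]
        kind = path.kind
        mid1, mid2 = payload["mid_first"], payload["mid_second"]
        i1, i2 = self._loc[mid1], self._loc[mid2]
        self.event_log.append((self.time, kind, mid1, mid2))
        if kind == "fusion":
            p1 = self._particle_world(i1, payload["slot_first"])
            p2 = self._particle_world(i2, payload["slot_second"])
            d = p2 - p1
            if self.boundary.kind == "periodic":
                d = minimum_image(d, self.box)
            mid_pos = p1 + 0.5 * d
            q = self.quat[i1].copy()
            self.remove_molecule(mid1)
            self.remove_molecule(mid2)
            self.add_molecule(path.products[0], mid_pos, q)
            return [mid1, mid2]
        if kind == "enzymatic":
            # first educt is the substrate, second the enzyme
            self._convert_molecule(mid1, path.products[0])
            return [mid1, mid2]
        if kind == "binding":
            key = ((mid1, payload["slot_first"]), (mid2, payload["slot_second"]))
            if key not in self.bonds:
                p1 = self._particle_world(i1, payload["slot_first"])
                p2 = self._particle_world(i2, payload["slot_second"])
                d = p2 - p1
                if self.boundary.kind == "periodic":
                    d = minimum_image(d, self.box)
                r0 = float(np.linalg.norm(d))
                self.bonds[key] = {"k": path.bond_k, "r0": r0,
                                   "unbind_rate": path.unbind_rate}
                # bond force evaluated at execution time
                if r0 > 1e-12:
                    fb = -path.bond_k * (r0 - r0) * d / r0  # zero at formation
                    self.force[i2] += fb
                    self.force[i1] -= fb
            return [mid1, mid2]
        raise ValueError(f"unknown bimolecular kind {kind!r}")

    def _convert_molecule(self, mol_id: int, new_type: str):
        i = self._loc[mol_id]
        self.type_id[i] = self.table.by_name[new_type]
        self._ptype_override.pop(mol_id, None)
        self.reschedule(mol_id)

    def _retype_particle(self, mol_id: int, slot: int, new_ptype: str):
        i = self._loc[mol_id]
        tid = int(self.type_id[i])
        ov = self._ptype_override.get(mol_id)
        if ov is None:
            ov = self.table.particle_type_ids(self.table[tid]).copy()
        if new_ptype not in self.table.ptype_ids:
            self.table.ptype_ids[new_ptype] = len(self.table.ptype_names)
            self.table.ptype_names.append(new_ptype)
            self.invalidate_cutoffs()
        ov[slot] = self.table.ptype_ids[new_ptype]
        self._ptype_override[mol_id] = ov
        self.reschedule(mol_id)

    def _random_unit(self) -> np.ndarray:
        v = self.rng.standard_normal(3)
        return v / np.linalg.norm(v)

    # -- bond dissociation --------------------------------------------
    def _bond_unbinding(self):
        if not self.bonds:
            return
        dt = self.dt
        dead = []
        for key, bond in self.bonds.items():
            kr = bond.get("unbind_rate", 0.0)
            if kr > 0 and self.rng.random() < 1.0 - np.exp(-kr * dt):
                dead.append(key)
        for key in dead:
            self.event_log.append((self.time, "unbinding", key[0][0], key[1][0]))
            del self.bonds[key]

    # -- main loop -----------------------------------------------------
    def initialize_forces(self):
        """Evaluate the initial force field (events from this sweep are
        discarded: reactions begin with the first step)."""
        self.sweep()

    def step(self):
        """Advance the system by one time step."""
        self._propagate()
        self._apply_boundary()
        events = self.sweep()
        self.time += self.dt
        self._collect_due_unimolecular(events)
        self._execute_events(events)
        self._bond_unbinding()
        if self.barostat is not None and self.time >= self.barostat.start_time:
            mu = berendsen_mu(self.pressure, self.barostat, self.dt)
            self.pos[: self.n] *= mu
            self.boundary.box = self.box * mu
        self.step_count += 1

    def run(self, n_steps: int, callback=None, callback_every: int = 1):
        self.initialize_forces()
        if callback is not None:
            callback(self)
        for s in range(n_steps):
            self.step()
            if callback is not None and (s + 1) % callback_every == 0:
                callback(self)
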