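"""Validation observables: MSD, rotational correlation, RDF, traces.

The mean squared displacement is the time- and ensemble-averaged

    MSD(tau) = < |x(t + tau) - x(t)|^2 >

computed on periodically unwrapped coordinates; free isotropic diffusion
gives slope 6 D (3-D volume species) or 4 D (surface species, short
lags).

The rotational time correlation of a body axis n is

    P(tau) = (3/2) < (n(t + tau) . n(t))^2 > - 1/2,

which decays as exp(-6 D_r tau) for an isotropic rotor (the single-
exponential limit of the anisotropic multi-exponential theory); it is
invariant under n -> -n.

The radial distribution function g(r) is the shell-normalized pair
histogram in a periodic box; g -> 1 at large separations for a fluid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .propagation import quat_to_matrix

__all__ = ["Trajectory", "record_trajectory", "msd", "rotational_correlation", "rdf"]


@dataclass
class Trajectory:
    """In-memory trajectory: per-frame molecule records.

    ``positions`` are unwrapped (suitable for MSD); ``wrapped`` are the
    in-box coordinates (suitable for RDF).
    """

    times: list[float] = field(default_factory=list)
    ids: list[np.ndarray] = field(default_factory=list)
    type_names: list[np.ndarray] = field(default_factory=list)
    positions: list[np.ndarray] = field(default_factory=list)
    wrapped: list[np.ndarray] = field(default_factory=list)
    quaternions: list[np.ndarray] = field(default_factory=list)
    boxes: list[np.ndarray] = field(default_factory=list)
    pressures: list[float] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def append_frame(self, sim):
        n = sim.n
        self.times.append(sim.time)
        self.ids.append(sim.ids[:n].copy())
        names = np.array([sim.table[int(t)].name for t in sim.type_id[:n]])
        self.type_names.append(names)
        self.positions.append(sim.unwrapped_positions())
        self.wrapped.append(sim.pos[:n].copy())
        self.quaternions.append(sim.quat[:n].copy())
        self.boxes.append(sim.box.copy())
        self.pressures.append(sim.pressure)

    def counts(self, species: str) -> np.ndarray:
        return np.array([int(np.sum(t == species)) for t in self.type_names])


def record_trajectory(traj: Trajectory):
    """Callback for ``Simulation.run`` appending every invoked frame."""

    def cb(sim):
        traj.append_frame(sim)

    return cb


def _species_tracks(traj: Trajectory, species: str | None):
    """ids x frames arrays of positions (and quaternions) for molecules
    present in every frame."""
    if traj.n_frames < 2:
        raise ValueError("at least two frames required")
    common = set(traj.ids[0].tolist())
    for ids in traj.ids[1:]:
        common &= set(ids.tolist())
    if species is not None:
        sel = traj.ids[0][traj.type_names[0] == species]
        if len(sel) == 0:
            raise KeyError(f"no molecules of species {species!r} in frame 0")
        common &= set(sel.tolist())
    common = np.array(sorted(common))
    if len(common) == 0:
        raise ValueError("no molecule persists through all frames")
    pos = np.empty((traj.n_frames, len(common), 3))
    quat = np.empty((traj.n_frames, len(common), 4))
    for f in range(traj.n_frames):
        order = {int(i): k for k, i in enumerate(traj.ids[f])}
        rows = np.array([order[int(i)] for i in common])
        pos[f] = traj.positions[f][rows]
        quat[f] = traj.quaternions[f][rows]
    return common, pos, quat


def msd(traj: Trajectory, species: str | None = None, lags=None):
    """Time- and ensemble-averaged MSD per frame lag.

    Returns ``(lag_times, msd_values, standard_errors)``; standard
    errors are over molecules (each molecule's time-averaged MSD is one
    sample).
    """
    _, pos, _ = _species_tracks(traj, species)
    nf = pos.shape[0]
    if lags is None:
        lags = np.arange(1, min(nf, 64))
    lags = np.asarray(lags, dtype=int)
    times = np.asarray(traj.times)
    out = np.empty(len(lags))
    err = np.empty(len(lags))
    for k, lag in enumerate(lags):
        d = pos[lag:] - pos[:-lag]
        sq = np.einsum("fmd,fmd->fm", d, d)
        per_mol = sq.mean(axis=0)
        out[k] = per_mol.mean()
        err[k] = per_mol.std(ddof=1) / np.sqrt(len(per_mol)) if len(per_mol) > 1 else 0.0
    return times[lags] - times[0], out, err


def rotational_correlation(traj: Trajectory, species: str | None = None,
                           axis=(0.0, 0.0, 1.0), lags=None):
    """P(tau) = 3/2 <(n(t+tau).n(t))^2> - 1/2 for the chosen body axis."""
    _, _, quat = _species_tracks(traj, species)
    nf = quat.shape[0]
    if lags is None:
        lags = np.arange(1, min(nf, 64))
    lags = np.asarray(lags, dtype=int)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    R = quat_to_matrix(quat.reshape(-1, 4)).reshape(nf, -1, 3, 3)
    n = np.einsum("fmij,j->fmi", R, axis)
    times = np.asarray(traj.times)
    out = np.empty(len(lags))
    err = np.empty(len(lags))
    for k, lag in enumerate(lags):
        dots = np.einsum("fmi,fmi->fm", n[lag:], n[:-lag])
        p = 1.5 * (dots**2) - 0.5
        per_mol = p.mean(axis=0)
        out[k] = per_mol.mean()
        err[k] = per_mol.std(ddof=1) / np.sqrt(len(per_mol)) if len(per_mol) > 1 else 0.0
    return times[lags] - times[0], out, err


def rdf(traj: Trajectory, species_pair=None, bin_width: float = 0.05,
        r_max: float | None = None, frame_stride: int = 1):
    """Radial distribution function from the wrapped frames.

    ``species_pair`` is (name_a, name_b) or None for all molecules.
    Requires a periodic box; r_max defaults to (just under) box/2.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    box = traj.boxes[0]
    if r_max is None:
        r_max = float(np.min(box)) / 2.0 * 0.999
    if r_max > np.min(box) / 2.0 + 1e-12:
        raise ValueError("r_max exceeds half the box")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist = np.zeros(len(edges) - 1)
    norm_frames = 0
    n_a_tot = n_b_tot = 0.0
    for f in range(0, traj.n_frames, frame_stride):
        pos = traj.wrapped[f]
        names = traj.type_names[f]
        box = traj.boxes[f]
        if species_pair is None:
            pa = pb = pos
            same = True
        else:
            a, b = species_pair
            pa = pos[names == a]
            pb = pos[names == b]
            same = a == b
        empty = (len(pa) < 2) if same else (len(pa) == 0 or len(pb) == 0)
        if empty:
            continue
        if same:
            ii, jj = np.triu_indices(len(pa), 1)
            d = pa[jj] - pa[ii]
        else:
            d = (pb[None, :, :] - pa[:, None, :]).reshape(-1, 3)
        d -= box * np.round(d / box)
        r = np.linalg.norm(d, axis=1)
        hist += np.histogram(r, bins=edges)[0] * (2.0 if same else 1.0)
        n_a_tot += len(pa)
        n_b_tot += len(pb)
        norm_frames += 1
    if norm_frames == 0:
        raise ValueError("no frames with the requested species")
    vol = float(np.prod(box))
    n_a = n_a_tot / norm_frames
    n_b = n_b_tot / norm_frames
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    cross = species_pair is not None and species_pair[0] != species_pair[1]
    rho_pairs = (n_a * n_b / vol) if cross else (n_a * (n_a - 1) / vol)
    g = hist / norm_frames / (shell * rho_pairs)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return centers, g
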