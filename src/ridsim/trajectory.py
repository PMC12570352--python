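"""Trajectory and observable persistence.

The native container is HDF5: one group per frame with position and
quaternion datasets plus molecule ids/types, the box, time and pressure.
A plain-CSV fallback and an XYZ export (for generic molecular viewers)
are provided, along with a provenance record (config hash, package
versions, seed) so runs can be traced back to their inputs.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np

from .observables import Trajectory

__all__ = [
    "write_hdf5",
    "read_hdf5",
    "write_csv",
    "write_xyz",
    "write_observable_csv",
    "provenance_record",
]


def write_hdf5(traj: Trajectory, path):
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["n_frames"] = traj.n_frames
        for f in range(traj.n_frames):
            g = fh.create_group(f"frames/{f:06d}")
            g.attrs["time"] = traj.times[f]
            g.attrs["pressure"] = traj.pressures[f]
            g.create_dataset("box", data=traj.boxes[f])
            g.create_dataset("ids", data=traj.ids[f])
            g.create_dataset("types", data=np.char.encode(
                traj.type_names[f].astype(str), "utf-8"))
            g.create_dataset("position", data=traj.positions[f])
            g.create_dataset("wrapped", data=traj.wrapped[f])
            g.create_dataset("quaternion", data=traj.quaternions[f])


def read_hdf5(path) -> Trajectory:
    import h5py

    traj = Trajectory()
    with h5py.File(path, "r") as fh:
        frames = sorted(fh["frames"].keys())
        for f in frames:
            g = fh[f"frames/{f}"]
            traj.times.append(float(g.attrs["time"]))
            traj.pressures.append(float(g.attrs["pressure"]))
            traj.boxes.append(g["box"][...])
            traj.ids.append(g["ids"][...])
            traj.type_names.append(
                np.char.decode(g["types"][...], "utf-8"))
            traj.positions.append(g["position"][...])
            traj.wrapped.append(g["wrapped"][...])
            traj.quaternions.append(g["quaternion"][...])
    return traj


def write_csv(traj: Trajectory, path):
    """Long-format CSV: frame, time, id, type, x, y, z, qw, qx, qy, qz."""
    with open(path, "w") as fh:
        fh.write("frame,time,id,type,x,y,z,qw,qx,qy,qz\n")
        for f in range(traj.n_frames):
            t = traj.times[f]
            for k in range(len(traj.ids[f])):
                p = traj.positions[f][k]
                q = traj.quaternions[f][k]
                fh.write(
                    f"{f},{t:.9g},{traj.ids[f][k]},{traj.type_names[f][k]},"
                    f"{p[0]:.9g},{p[1]:.9g},{p[2]:.9g},"
                    f"{q[0]:.9g},{q[1]:.9g},{q[2]:.9g},{q[3]:.9g}\n"
                )


def write_xyz(traj: Trajectory, path):
    """Multi-frame XYZ (element column = molecule type name)."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            n = len(traj.ids[f])
            fh.write(f"{n}\ntime={traj.times[f]:.9g}\n")
            for k in range(n):
                p = traj.wrapped[f][k]
                fh.write(f"{traj.type_names[f][k]} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


def write_observable_csv(path, columns: dict[str, np.ndarray]):
    """Tabular observable output (e.g. lag, value, standard error)."""
    keys = list(columns)
    arrs = [np.asarray(columns[k]).ravel() for k in keys]
    with open(path, "w") as fh:
        fh.write(",".join(keys) + "\n")
        for row in zip(*arrs):
            fh.write(",".join(f"{v:.9g}" for v in row) + "\n")


def provenance_record(config_text: str | None, seed: int) -> dict:
    import numpy
    import scipy

    from . import __version__

    rec = {
        "package": "ridsim",
        "version": __version__,
        "seed": int(seed),
        "python": platform.python_version(),
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
    }
    if config_text is not None:
        rec["config_sha256"] = hashlib.sha256(config_text.encode()).hexdigest()
    return rec


def write_provenance(path, config_text: str | None, seed: int):
    Path(path).write_text(json.dumps(provenance_record(config_text, seed), indent=2))
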