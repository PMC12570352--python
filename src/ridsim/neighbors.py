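"""Linked-cell lists and the hierarchical grid for polydisperse cutoffs.

A classical linked-cell list needs cells at least as large as the largest
pair cutoff, which is wasteful when particle sizes span an order of
magnitude.  The hierarchical grid assigns every particle to a level by
its cutoff diameter; each level keeps its own cell list with cells sized
to that level's largest cutoff.  Pairs are found by a same-level
nearest-neighbor sweep plus a cross-level sweep in which only the
smaller-cell levels are scanned from each coarser particle (Newton's
third law: each unordered pair is produced exactly once).

The pair cutoff obeys the mixing rule ``cutoff_ij = (c_i + c_j)/2`` with
``c_i`` the per-particle cutoff *diameter* (for excluded volume this is
``2 r_i`` so that ``cutoff_ij = r_i + r_j``).

With all cutoffs equal the structure degenerates to a single-level
linked-cell list.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["HierarchicalGrid", "build_hgrid", "collect_pairs", "brute_force_pairs"]

_MAX_LEVELS = 8


@njit(cache=True)
def _sweep(pos, cut, box, periodic, lvl, n_levels, lvl_cut, ncells, cell_size, lvl_off, head, nxt):
    n = pos.shape[0]
    cap = max(64, 8 * n)
    out_i = np.empty(cap, dtype=np.int64)
    out_j = np.empty(cap, dtype=np.int64)
    out_d = np.empty((cap, 3), dtype=np.float64)
    out_r = np.empty(cap, dtype=np.float64)
    cnt = 0
    for i in range(n):
        li = lvl[i]
        for lf in range(li, n_levels):
            same = lf == li
            radius = 0.5 * (cut[i] + lvl_cut[lf])
            # cell index range on level lf covering the search sphere
            lo = np.empty(3, dtype=np.int64)
            span = np.empty(3, dtype=np.int64)
            for d in range(3):
                nc = ncells[lf, d]
                cs = cell_size[lf, d]
                a = int(np.floor((pos[i, d] - radius) / cs))
                b = int(np.floor((pos[i, d] + radius) / cs))
                if periodic:
                    s = b - a + 1
                    if s > nc:
                        s = nc
                    lo[d] = a % nc
                    span[d] = s
                else:
                    if a < 0:
                        a = 0
                    if b > nc - 1:
                        b = nc - 1
                    lo[d] = a
                    span[d] = b - a + 1 if b >= a else 0
            for ox in range(span[0]):
                cx = (lo[0] + ox) % ncells[lf, 0] if periodic else lo[0] + ox
                for oy in range(span[1]):
                    cy = (lo[1] + oy) % ncells[lf, 1] if periodic else lo[1] + oy
                    for oz in range(span[2]):
                        cz = (lo[2] + oz) % ncells[lf, 2] if periodic else lo[2] + oz
                        cell = (cx * ncells[lf, 1] + cy) * ncells[lf, 2] + cz
                        j = head[lvl_off[lf] + cell]
                        while j != -1:
                            if (not same) or (j > i):
                                dx = pos[j, 0] - pos[i, 0]
                                dy = pos[j, 1] - pos[i, 1]
                                dz = pos[j, 2] - pos[i, 2]
                                if periodic:
                                    dx -= box[0] * np.round(dx / box[0])
                                    dy -= box[1] * np.round(dy / box[1])
                                    dz -= box[2] * np.round(dz / box[2])
                                r2 = dx * dx + dy * dy + dz * dz
                                rc = 0.5 * (cut[i] + cut[j])
                                if r2 < rc * rc:
                                    if cnt == cap:
                                        cap *= 2
                                        tmp_i = np.empty(cap, dtype=np.int64)
                                        tmp_j = np.empty(cap, dtype=np.int64)
                                        tmp_d = np.empty((cap, 3), dtype=np.float64)
                                        tmp_r = np.empty(cap, dtype=np.float64)
                                        tmp_i[:cnt] = out_i[:cnt]
                                        tmp_j[:cnt] = out_j[:cnt]
                                        tmp_d[:cnt] = out_d[:cnt]
                                        tmp_r[:cnt] = out_r[:cnt]
                                        out_i, out_j = tmp_i, tmp_j
                                        out_d, out_r = tmp_d, tmp_r
                                    out_i[cnt] = i
                                    out_j[cnt] = j
                                    out_d[cnt, 0] = dx
                                    out_d[cnt, 1] = dy
                                    out_d[cnt, 2] = dz
                                    out_r[cnt] = np.sqrt(r2)
                                    cnt += 1
                            j = nxt[j]
    return out_i[:cnt], out_j[:cnt], out_d[:cnt], out_r[:cnt]


@njit(cache=True)
def _bin_particles(pos, box, periodic, lvl, n_levels, ncells, cell_size, lvl_off, total_cells):
    n = pos.shape[0]
    head = np.full(total_cells, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        l = lvl[i]
        cidx = 0
        for d in range(3):
            x = pos[i, d]
            if periodic:
                x = x % box[d]
            c = int(np.floor(x / cell_size[l, d]))
            if c < 0:
                c = 0
            if c > ncells[l, d] - 1:
                c = ncells[l, d] - 1
            cidx = cidx * ncells[l, d] + c
        cell = lvl_off[l] + cidx
        nxt[i] = head[cell]
        head[cell] = i
    return head, nxt


class HierarchicalGrid:
    """Per-cutoff-level linked-cell structure over one configuration."""

    def __init__(self, positions, cutoffs, box, periodic, lvl, lvl_cut, ncells,
                 cell_size, lvl_off, head, nxt):
        self.positions = positions
        self.cutoffs = cutoffs
        self.box = box
        self.periodic = periodic
        self.particle_level = lvl
        self.level_cutoffs = lvl_cut  # per-level max cutoff diameter (nm)
        self._ncells = ncells
        self._cell_size = cell_size
        self._lvl_off = lvl_off
        self._head = head
        self._nxt = nxt

    @property
    def n_levels(self) -> int:
        return len(self.level_cutoffs)

    @property
    def cell_sizes(self) -> np.ndarray:
        return self._cell_size


def _assign_levels(cutoffs: np.ndarray, max_levels: int = _MAX_LEVELS):
    uniq = np.unique(cutoffs)[::-1]  # descending
    if len(uniq) <= max_levels:
        edges = uniq
        lvl = np.searchsorted(-edges, -cutoffs)  # exact match index
        lvl = np.array([int(np.where(uniq == c)[0][0]) for c in cutoffs], dtype=np.int64)
        return lvl, uniq.astype(float)
    # geometric binning: max_levels bins between max and min cutoff
    cmax, cmin = float(uniq[0]), float(uniq[-1])
    bounds = cmax * (cmin / cmax) ** (np.arange(1, max_levels + 1) / max_levels)
    lvl = np.empty(len(cutoffs), dtype=np.int64)
    lvl_cut = np.zeros(max_levels)
    for k, c in enumerate(cutoffs):
        l = int(np.searchsorted(-bounds, -c))
        l = min(l, max_levels - 1)
        lvl[k] = l
        lvl_cut[l] = max(lvl_cut[l], c)
    # a level's nominal cutoff must cover every particle binned into it
    for l in range(max_levels):
        if lvl_cut[l] == 0.0:
            lvl_cut[l] = bounds[l - 1] if l > 0 else cmax
    return lvl, lvl_cut


def build_hgrid(positions, cutoffs, box, periodic: bool = True,
                max_levels: int = _MAX_LEVELS) -> HierarchicalGrid:
    """Bin particles into the hierarchical grid.

    ``cutoffs`` are per-particle cutoff diameters (nm).  Raises a
    ValueError when any cutoff exceeds half the box in some dimension.
    """
    positions = np.ascontiguousarray(positions, dtype=float).reshape(-1, 3)
    cutoffs = np.ascontiguousarray(cutoffs, dtype=float).ravel()
    box = np.asarray(box, dtype=float).ravel()
    if np.any(box <= 0):
        raise ValueError("box lengths must be positive")
    if len(cutoffs) and np.any(cutoffs <= 0):
        raise ValueError("cutoffs must be positive")
    if len(cutoffs) and periodic and np.any(cutoffs > np.min(box) / 2 + 1e-12):
        raise ValueError("a cutoff exceeds half the box; minimum image breaks down")
    if len(cutoffs) == 0:
        lvl = np.empty(0, dtype=np.int64)
        lvl_cut = np.array([1.0])
    else:
        lvl, lvl_cut = _assign_levels(cutoffs, max_levels)
    n_levels = len(lvl_cut)
    ncells = np.empty((n_levels, 3), dtype=np.int64)
    cell_size = np.empty((n_levels, 3))
    lvl_off = np.empty(n_levels, dtype=np.int64)
    off = 0
    for l in range(n_levels):
        for d in range(3):
            nc = max(1, int(np.floor(box[d] / lvl_cut[l])))
            ncells[l, d] = nc
            cell_size[l, d] = box[d] / nc
        lvl_off[l] = off
        off += int(np.prod(ncells[l]))
    head, nxt = _bin_particles(
        positions, box, periodic, lvl, n_levels, ncells, cell_size, lvl_off, off
    )
    return HierarchicalGrid(positions, cutoffs, box, periodic, lvl, lvl_cut,
                            ncells, cell_size, lvl_off, head, nxt)


def collect_pairs(hgrid: HierarchicalGrid):
    """All unordered pairs with ``r_ij < (c_i + c_j)/2``, each exactly once.

    Returns ``(i, j, dvec, r)`` with ``dvec = pos[j] - pos[i]`` under the
    minimum image convention for periodic boxes.
    """
    if len(hgrid.cutoffs) == 0:
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64),
                np.empty((0, 3)), np.empty(0))
    return _sweep(
        hgrid.positions, hgrid.cutoffs, hgrid.box, hgrid.periodic,
        hgrid.particle_level, hgrid.n_levels, hgrid.level_cutoffs,
        hgrid._ncells, hgrid._cell_size, hgrid._lvl_off, hgrid._head, hgrid._nxt,
    )


def brute_force_pairs(positions, cutoffs, box, periodic: bool = True):
    """O(N^2) reference pair list (oracle for the grid sweep)."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    cutoffs = np.asarray(cutoffs, dtype=float).ravel()
    box = np.asarray(box, dtype=float).ravel()
    n = len(cutoffs)
    ii, jj = np.triu_indices(n, 1)
    d = positions[jj] - positions[ii]
    if periodic:
        d -= box * np.round(d / box)
    r = np.linalg.norm(d, axis=1)
    rc = 0.5 * (cutoffs[ii] + cutoffs[jj])
    keep = r < rc
    return ii[keep], jj[keep], d[keep], r[keep]
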