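"""Pairwise interaction potentials, force accumulation and virial pressure.

Every potential exposes the two-function contract ``u_and_du(r)`` ->
``(U, dU/dr)`` (vectorized over numpy arrays of distances) plus a
``cutoff`` beyond which both vanish; custom potentials only need to
implement that contract.

Built-in kinds:

``HarmonicRepulsion``
    U(r) = k/2 (r - sigma)^2 for r <= sigma, else 0.  The workhorse
    excluded-volume potential; C^1 at sigma by construction.

``WeakPiecewiseHarmonic``
    Short-range harmonic repulsion glued to a harmonic attractive well
    (depth d) that returns to zero with continuous U and dU/dr at the
    cutoff.

``ContinuousSquareWell``
    U(r) = -eps/2 [1 - tanh((r - r_w)/alpha)]: a smoothed square well.

``PseudoHardSphere``
    Cut-shifted Mie 50-49 potential: a steep, continuous stand-in for a
    hard core.

Forces on beads are mapped to a net force and torque per molecule about
its center of diffusion, and the pair virial is accumulated with
molecule-center separation vectors (the rigid-body convention required
for the Brownian virial pressure).
"""

from __future__ import annotations

import numpy as np

from .constants import KB

__all__ = [
    "PairPotential",
    "HarmonicRepulsion",
    "WeakPiecewiseHarmonic",
    "ContinuousSquareWell",
    "PseudoHardSphere",
    "ForceField",
    "evaluate_pair",
    "virial_pressure",
]


class PairPotential:
    """Base class: subclasses define ``cutoff`` and ``u_and_du``."""

    cutoff: float = 0.0

    def u_and_du(self, r):
        raise NotImplementedError

    def __call__(self, r):
        r = np.asarray(r, dtype=float)
        if np.any(r < 0):
            raise ValueError("pair distance must be non-negative")
        return self.u_and_du(r)


class HarmonicRepulsion(PairPotential):
    def __init__(self, k: float, sigma: float):
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        self.k = float(k)
        self.sigma = float(sigma)
        self.cutoff = self.sigma

    def u_and_du(self, r):
        r = np.asarray(r, dtype=float)
        overlap = np.minimum(r - self.sigma, 0.0)
        return 0.5 * self.k * overlap**2, self.k * overlap


class WeakPiecewiseHarmonic(PairPotential):
    """Harmonic repulsive core with a weak harmonic attractive well.

    Parameters: force constant ``k`` of the core, desired (contact)
    distance ``sigma``, well depth ``depth`` and interaction cutoff
    ``rc`` > sigma.
    """

    def __init__(self, k: float, sigma: float, depth: float, rc: float):
        if rc <= sigma:
            raise ValueError("cutoff must exceed sigma")
        self.k = float(k)
        self.sigma = float(sigma)
        self.depth = float(depth)
        self.cutoff = float(rc)
        self._half = 0.5 * (rc - sigma)

    def u_and_du(self, r):
        r = np.asarray(r, dtype=float)
        u = np.zeros_like(r)
        du = np.zeros_like(r)
        d, h, s, rc = self.depth, self._half, self.sigma, self.cutoff
        core = r < s
        u = np.where(core, 0.5 * self.k * (r - s) ** 2 - d, u)
        du = np.where(core, self.k * (r - s), du)
        mid = (r >= s) & (r < s + h)
        u = np.where(mid, 0.5 * d / h**2 * (r - s) ** 2 - d, u)
        du = np.where(mid, d / h**2 * (r - s), du)
        outer = (r >= s + h) & (r < rc)
        u = np.where(outer, -0.5 * d / h**2 * (r - rc) ** 2, u)
        du = np.where(outer, -d / h**2 * (r - rc), du)
        return u, du


class ContinuousSquareWell(PairPotential):
    def __init__(self, eps: float, r_w: float, alpha: float, rc: float | None = None):
        self.eps = float(eps)
        self.r_w = float(r_w)
        self.alpha = float(alpha)
        self.cutoff = float(rc) if rc is not None else self.r_w + 10.0 * self.alpha
        # cut-and-shift so U is exactly zero at (and beyond) the cutoff
        self._shift = -0.5 * self.eps * (1.0 - np.tanh((self.cutoff - self.r_w) / self.alpha))

    def u_and_du(self, r):
        r = np.asarray(r, dtype=float)
        t = np.tanh((r - self.r_w) / self.alpha)
        inside = r < self.cutoff
        u = np.where(inside, -0.5 * self.eps * (1.0 - t) - self._shift, 0.0)
        du = np.where(inside, 0.5 * self.eps / self.alpha * (1.0 - t**2), 0.0)
        return u, du


class PseudoHardSphere(PairPotential):
    """Cut-shifted Mie 50-49 potential; steeply repulsive, zero beyond
    (50/49) sigma."""

    _LR, _LA = 50.0, 49.0

    def __init__(self, eps: float, sigma: float):
        self.eps = float(eps)
        self.sigma = float(sigma)
        self.cutoff = (self._LR / self._LA) * self.sigma
        self._pref = self._LR * (self._LR / self._LA) ** self._LA * self.eps

    def u_and_du(self, r):
        r = np.asarray(r, dtype=float)
        rs = np.where(r > 0, r, np.nan)
        sr = self.sigma / rs
        inside = r < self.cutoff
        u = np.where(inside, self._pref * (sr**self._LR - sr**self._LA) + self.eps, 0.0)
        du = np.where(
            inside,
            self._pref * (-self._LR * sr**self._LR + self._LA * sr**self._LA) / rs,
            0.0,
        )
        return np.nan_to_num(u, posinf=np.inf), np.nan_to_num(du, neginf=-np.inf)


def evaluate_pair(pot: PairPotential, r):
    """(U, dU/dr) of ``pot`` at distance(s) ``r`` (nm)."""
    return pot(r)


class ForceField:
    """Per-particle-type-pair potential table (symmetric under swap)."""

    def __init__(self):
        self._table: dict[tuple[str, str], PairPotential] = {}

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set_pair(self, type_a: str, type_b: str, pot: PairPotential):
        self._table[self._key(type_a, type_b)] = pot

    def get_pair(self, type_a: str, type_b: str) -> PairPotential | None:
        return self._table.get(self._key(type_a, type_b))

    def items(self):
        return self._table.items()

    def max_cutoff_for(self, ptype: str) -> float:
        """Largest interaction cutoff involving particle type ``ptype``."""
        best = 0.0
        for (a, b), pot in self._table.items():
            if ptype in (a, b):
                best = max(best, pot.cutoff)
        return best

    def __len__(self):
        return len(self._table)


def virial_pressure(
    n_molecules: int,
    temperature: float,
    volume: float,
    pair_virial: float,
) -> float:
    """Virial pressure in kJ/(mol nm^3).

    P = (N k_B T + W/3) / V with W the accumulated molecular pair virial
    sum_pairs r_ij . F_ij referenced to molecule centers of diffusion.
    """
    if volume <= 0:
        raise ValueError("volume must be positive")
    return (n_molecules * KB * temperature + pair_virial / 3.0) / volume
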