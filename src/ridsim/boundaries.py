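"""Periodic, repulsive and fixed-concentration simulation-box boundaries.

Periodic boxes use the minimum image convention (half-open wrapping to
[-L/2, L/2) for separations, [0, L) for positions).  Repulsive boxes
mirror-reflect displacements at the box faces.  Fixed-concentration
boundaries couple the box to an unsimulated outside pool of
concentration C: molecules crossing the boundary are removed (outflux)
and new molecules are Poisson-injected (influx) at the rate a diffusive
flux from the pool would supply.

Influx statistics per species and time step::

    l_n   = sqrt(4 D dt / pi)          mean one-sided normal displacement
    N_hit = A * (l_n / 2) * C          expected boundary hits (Poisson rate)

and each inserted molecule is placed a normal depth ``sqrt(pi) l_n x``
inside the box, where the dimensionless depth x is drawn from the CDF

    P(x) = 1 - exp(-x^2) + sqrt(pi) x erfc(x)

(whose density is sqrt(pi) erfc(x) >= 0).  Surface-bound species use the
boundary edge length L in place of the area A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc

__all__ = [
    "BoundarySpec",
    "minimum_image",
    "wrap_positions",
    "mean_normal_distance",
    "expected_hits",
    "InfluxSampler",
    "fixed_conc_influx",
]


def minimum_image(d, box):
    """Wrap separation vector(s) ``d`` into [-L/2, L/2) per component."""
    d = np.asarray(d, dtype=float)
    box = np.asarray(box, dtype=float)
    return d - box * np.floor(d / box + 0.5)


def wrap_positions(pos, box):
    """Wrap absolute positions into [0, L); returns (wrapped, image_shift)."""
    pos = np.asarray(pos, dtype=float)
    shift = np.floor(pos / box).astype(np.int64)
    return pos - shift * box, shift


def mean_normal_distance(D: float, dt: float) -> float:
    """l_n = sqrt(4 D dt / pi): mean one-sided distance diffused normal to
    a plane in one time step (nm)."""
    return float(np.sqrt(4.0 * D * dt / np.pi))


def expected_hits(area: float, D: float, dt: float, conc: float) -> float:
    """Expected boundary crossings per step, N_hit = A (l_n/2) C."""
    return area * 0.5 * mean_normal_distance(D, dt) * conc


class InfluxSampler:
    """Samples the normalized insertion depth x from
    P(x) = 1 - exp(-x^2) + sqrt(pi) x erfc(x) by inverse transform on a
    precomputed monotone interpolant."""

    def __init__(self, x_max: float = 6.0, knots: int = 4096):
        x = np.linspace(0.0, x_max, knots)
        self._x = x
        self._cdf = self.cdf(x)
        # guard strict monotonicity for np.interp inversion
        self._cdf[-1] = 1.0

    @staticmethod
    def cdf(x):
        x = np.asarray(x, dtype=float)
        return 1.0 - np.exp(-(x**2)) + np.sqrt(np.pi) * x * erfc(x)

    @staticmethod
    def pdf(x):
        x = np.asarray(x, dtype=float)
        return np.sqrt(np.pi) * erfc(x)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        u = rng.random(n)
        return np.interp(u, self._cdf, self._x)


_DEPTH_SAMPLER = InfluxSampler()


@dataclass
class BoundarySpec:
    """Boundary condition of the rectangular simulation box."""

    kind: str = "periodic"  # periodic | repulsive | fixed_concentration
    box: np.ndarray = field(default_factory=lambda: np.array([50.0, 50.0, 50.0]))
    concentrations: dict[str, float] = field(default_factory=dict)  # nm^-3 (or nm^-2)

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=float).ravel()
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")
        if self.kind not in ("periodic", "repulsive", "fixed_concentration"):
            raise ValueError(f"unknown boundary kind {self.kind!r}")
        if any(c < 0 for c in self.concentrations.values()):
            raise ValueError("outside concentrations must be non-negative")

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    @property
    def area(self) -> float:
        lx, ly, lz = self.box
        return 2.0 * (lx * ly + ly * lz + lx * lz)


def fixed_conc_influx(spec: BoundarySpec, species_name: str, D: float, dt: float,
                      rng: np.random.Generator, surface: bool = False):
    """Draw this step's insertions for one species.

    Returns an (n, 3) array of positions inside the box.  The number of
    insertions is Poisson with rate N_hit; each is placed uniformly on a
    face (chosen by area) and displaced inward by sqrt(pi) l_n x with x
    from the depth CDF.
    """
    conc = spec.concentrations.get(species_name, 0.0)
    if conc <= 0.0 or D <= 0.0:
        return np.empty((0, 3))
    lx, ly, lz = spec.box
    if surface:
        # surface species travel on the box faces; the flux is through the
        # boundary edges of total length 4(lx+ly+lz)
        measure = 4.0 * (lx + ly + lz)
    else:
        measure = spec.area
    ln = mean_normal_distance(D, dt)
    n_hit = measure * 0.5 * ln * conc
    n = int(rng.poisson(n_hit))
    if n == 0:
        return np.empty((0, 3))
    # choose faces (+x,-x,+y,-y,+z,-z) by area
    face_areas = np.array([ly * lz, ly * lz, lx * lz, lx * lz, lx * ly, lx * ly])
    faces = rng.choice(6, size=n, p=face_areas / face_areas.sum())
    u = rng.random((n, 2))
    depth = np.sqrt(np.pi) * ln * _DEPTH_SAMPLER.sample(rng, n)
    pos = np.empty((n, 3))
    for k in range(n):
        axis = faces[k] // 2
        high = faces[k] % 2 == 0
        others = [d for d in range(3) if d != axis]
        pos[k, others[0]] = u[k, 0] * spec.box[others[0]]
        pos[k, others[1]] = u[k, 1] * spec.box[others[1]]
        pos[k, axis] = spec.box[axis] - depth[k] if high else depth[k]
    return pos


def reflect_box(pos, box):
    """Mirror positions back into [0, L] per component (repulsive box).

    Handles multiple folds for displacements larger than the box.
    """
    pos = np.asarray(pos, dtype=float)
    period = 2.0 * box
    folded = np.mod(pos, period)
    return np.where(folded > box, period - folded, folded)
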