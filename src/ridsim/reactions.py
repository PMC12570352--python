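"""Uni- and bimolecular reactions: channels, rate conversion, sampling.

Unimolecular channels (decay, fission, production, conversion, release)
are scheduled event-driven with the Gillespie direct method: each
molecule carries the time of its next reaction, drawn once from the
exponential lifetime distribution tau = ln(1/U)/k_t with k_t the summed
path rate, and re-drawn only when its channel set changes.  The path is
chosen with probability k_i/k_t.

Bimolecular channels (fusion, enzymatic, binding) follow the volume
reaction scheme of Doi: an educt pair within the reaction radius R_react
fires during a step of length dt with probability

    p = 1 - exp(-sum_i k_i dt)

summed over the paths whose radius covers the current pair distance.

Microscopic (per-encounter, 1/ns) and macroscopic (mass-action, nm^3/ns)
rates are interconverted through

    k_macro = 4 pi (D_A + D_B) [R - sqrt((D_A+D_B)/k) tanh(R sqrt(k/(D_A+D_B)))]

valid for lambda_AB = sqrt(4 (D_A + D_B) dt) << R; the k -> inf limit is
the diffusion-limited Smoluchowski rate 4 pi (D_A+D_B) R and the k -> 0
limit the reaction-limited (4/3) pi R^3 k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "UniPath",
    "UniChannel",
    "BiPath",
    "BiChannel",
    "ReactionRegistry",
    "lambda_AB",
    "k_macro",
    "solve_k_micro",
    "sample_next_reaction_time",
]

UNI_KINDS = ("decay", "fission", "production", "conversion", "release")
BI_KINDS = ("fusion", "enzymatic", "binding")


# -- rate conversion ------------------------------------------------------


def lambda_AB(D_A: float, D_B: float, dt: float) -> float:
    """Mean change of the pair distance per step, sqrt(4 (D_A+D_B) dt) (nm)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return float(np.sqrt(4.0 * (D_A + D_B) * dt))


def check_reaction_radius(R_react: float, D_A: float, D_B: float, dt: float):
    """Warn when molecules can jump past partners between evaluations."""
    lam = lambda_AB(D_A, D_B, dt)
    if lam > R_react:
        warnings.warn(
            f"displacement scale lambda_AB = {lam:.3g} nm exceeds the reaction "
            f"radius {R_react:.3g} nm; molecules may pass reaction partners "
            "between steps (reduce dt or enlarge R_react)",
            stacklevel=2,
        )


def k_macro(k: float, D_A: float, D_B: float, R: float) -> float:
    """Macroscopic mass-action rate (nm^3/ns) for microscopic rate ``k``
    (1/ns) inside radius ``R`` (nm)."""
    if R <= 0:
        raise ValueError("reaction radius must be positive")
    D = D_A + D_B
    if k <= 0:
        return 0.0
    if D <= 0:
        # no relative diffusion: purely local conversion inside the sphere
        return (4.0 / 3.0) * np.pi * R**3 * k
    s = np.sqrt(D / k)
    return float(4.0 * np.pi * D * (R - s * np.tanh(R / s)))


def solve_k_micro(k_mac: float, D_A: float, D_B: float, R: float,
                  rtol: float = 1e-12) -> float:
    """Invert ``k_macro`` for the microscopic rate by bracketed
    root-finding; requires k_mac below the Smoluchowski bound
    4 pi (D_A+D_B) R."""
    D = D_A + D_B
    bound = 4.0 * np.pi * D * R
    if k_mac <= 0:
        return 0.0
    if k_mac >= bound:
        raise ValueError(
            f"k_macro = {k_mac:.6g} exceeds the diffusion-limited bound "
            f"4 pi (D_A+D_B) R = {bound:.6g} nm^3/ns; no microscopic rate exists"
        )
    f = lambda log_k: k_macro(np.exp(log_k), D_A, D_B, R) - k_mac
    lo, hi = -40.0, 40.0
    while f(hi) < 0:
        hi += 20.0
        if hi > 400:
            raise RuntimeError("failed to bracket the microscopic rate")
    log_k = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    return float(np.exp(log_k))


def sample_next_reaction_time(k_t: float, rng: np.random.Generator) -> float:
    """Waiting time to the next reaction, tau = ln(1/U)/k_t (ns)."""
    if k_t <= 0:
        return np.inf
    u = rng.random()
    while u == 0.0:
        u = rng.random()
    return float(np.log(1.0 / u) / k_t)


# -- channel definitions --------------------------------------------------


@dataclass
class UniPath:
    kind: str  # decay | fission | production | conversion | release
    rate: float  # 1/ns
    products: tuple[str, ...] = ()
    radius: float = 0.0  # dissociation radius (nm) for fission/release
    n_products: int = 1  # production only

    def __post_init__(self):
        if self.kind not in UNI_KINDS:
            raise ValueError(f"unknown unimolecular kind {self.kind!r}")
        if self.rate < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class UniChannel:
    educt: str  # molecule type (or particle type for particle-level paths)
    paths: list[UniPath]
    level: str = "molecule"  # molecule | particle

    @property
    def k_total(self) -> float:
        return float(sum(p.rate for p in self.paths))

    def choose_path(self, rng: np.random.Generator) -> UniPath:
        rates = np.array([p.rate for p in self.paths])
        return self.paths[int(rng.choice(len(rates), p=rates / rates.sum()))]


@dataclass
class BiPath:
    kind: str  # fusion | enzymatic | binding
    rate: float  # 1/ns (microscopic)
    R_react: float  # nm
    products: tuple[str, ...] = ()
    bond_k: float = 0.0  # binding stiffness kJ/(mol nm^2)
    unbind_rate: float = 0.0  # 1/ns

    def __post_init__(self):
        if self.kind not in BI_KINDS:
            raise ValueError(f"unknown bimolecular kind {self.kind!r}")
        if self.R_react <= 0:
            raise ValueError("reaction radius must be positive")
        if self.rate < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class BiChannel:
    educts: tuple[str, str]  # particle-type pair carrying the distance
    paths: list[BiPath]
    level: str = "molecule"

    @property
    def max_radius(self) -> float:
        return max(p.R_react for p in self.paths)


@dataclass
class ReactionRegistry:
    """All reaction channels of a model, keyed by educt type(s)."""

    uni: dict[str, UniChannel] = field(default_factory=dict)
    bi: dict[tuple[str, str], list[BiChannel]] = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add_uni(self, channel: UniChannel):
        self.uni[channel.educt] = channel

    def add_bi(self, channel: BiChannel):
        self.bi.setdefault(self._key(*channel.educts), []).append(channel)

    def bi_for(self, type_a: str, type_b: str) -> list[BiChannel]:
        return self.bi.get(self._key(type_a, type_b), [])

    def max_reaction_radius_for(self, ptype: str) -> float:
        best = 0.0
        for key, channels in self.bi.items():
            if ptype in key:
                best = max(best, max(c.max_radius for c in channels))
        return best

    def bi_probability(self, type_a: str, type_b: str, r: float, dt: float):
        """Doi firing probability for a pair at distance r, plus the
        applicable (channel, path) list."""
        applicable = []
        k_sum = 0.0
        for ch in self.bi_for(type_a, type_b):
            for p in ch.paths:
                if r < p.R_react:
                    applicable.append((ch, p))
                    k_sum += p.rate
        if k_sum <= 0.0:
            return 0.0, applicable
        return 1.0 - float(np.exp(-k_sum * dt)), applicable

    def to_graph(self) -> dict:
        """Reaction network as a JSON-serializable node/edge list."""
        nodes: set[str] = set()
        edges = []
        for educt, ch in self.uni.items():
            nodes.add(educt)
            for p in ch.paths:
                nodes.update(p.products)
                edges.append({
                    "educts": [educt],
                    "products": list(p.products),
                    "kind": p.kind,
                    "rate": p.rate,
                    "radius": p.radius,
                })
        for key, channels in self.bi.items():
            nodes.update(key)
            for ch in channels:
                for p in ch.paths:
                    nodes.update(p.products)
                    edges.append({
                        "educts": list(ch.educts),
                        "products": list(p.products),
                        "kind": p.kind,
                        "rate": p.rate,
                        "radius": p.R_react,
                    })
        return {"nodes": sorted(nodes), "edges": edges}
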