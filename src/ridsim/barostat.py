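"""Berendsen barostat for NPT runs.

The instantaneous virial pressure P is relaxed toward a target P0 by
rescaling the box and the molecule centers each step with

    mu = (1 - (dt / tau_P) (P0 - P))^(1/3)

so that P < P0 compresses the box (mu < 1, raising the pressure) and
P > P0 expands it.  Internal bead geometry is rigid and never scaled;
only the centers of diffusion move.  The scheme drives the system to the
target density efficiently but does not sample the exact NPT ensemble
(pressure fluctuations are underestimated), which is acceptable for
equilibration and density targeting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BarostatParams", "berendsen_mu", "berendsen_step"]


@dataclass
class BarostatParams:
    P0: float  # target pressure, kJ/(mol nm^3)
    tau_P: float  # coupling time constant, ns
    start_time: float = 0.0  # ns; barostat inactive before this
    mode: str = "isotropic"

    def __post_init__(self):
        if self.tau_P <= 0:
            raise ValueError("tau_P must be positive")
        if self.mode != "isotropic":
            raise ValueError("only isotropic pressure coupling is supported")


def berendsen_mu(P: float, params: BarostatParams, dt: float) -> float:
    """Isotropic scale factor mu for one step."""
    if dt >= params.tau_P:
        raise ValueError("tau_P must exceed the time step")
    arg = 1.0 - (dt / params.tau_P) * (params.P0 - P)
    if arg <= 0.0:
        raise FloatingPointError(
            "Berendsen scaling factor became non-positive; decrease dt/tau_P "
            "or start from a less stressed configuration"
        )
    return float(arg ** (1.0 / 3.0))


def berendsen_step(positions: np.ndarray, box: np.ndarray, P: float,
                   params: BarostatParams, dt: float):
    """Scale molecule centers and box by mu; returns (positions, box, mu)."""
    mu = berendsen_mu(P, params, dt)
    return positions * mu, box * mu, mu
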