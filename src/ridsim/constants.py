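"""Unit system and physical constants.

The package works in a molar unit system common in coarse-grained
biomolecular simulation: lengths in nm, times in ns, energies in kJ/mol.
Derived units: forces kJ/(mol nm), pressures kJ/(mol nm^3), diffusion
coefficients nm^2/ns, viscosities kJ ns/(mol nm^3).
"""

#: Boltzmann constant (gas constant per mole) in kJ/(mol K).
KB = 0.008314462

#: Default temperature in K.
DEFAULT_TEMPERATURE = 293.15

#: Conversion: 1 Pa s expressed in kJ ns/(mol nm^3).
#: 1 J s/m^3 * 6.02214076e20 (J -> kJ/mol) * 1e9 (s -> ns) / 1e27 (m^3 -> nm^3)
PA_S = 6.02214076e2

#: Dynamic viscosity of water at ~293 K (1.0 mPa s) in kJ ns/(mol nm^3).
#: Gives the physical Stokes-Einstein D ~ 0.215 nm^2/ns for a 1 nm radius
#: sphere at 293.15 K.
WATER_VISCOSITY = 1.0e-3 * PA_S


def thermal_energy(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """k_B T in kJ/mol."""
    return KB * temperature
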