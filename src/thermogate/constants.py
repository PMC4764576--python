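"""Physical constants, in the unit system used package-wide.

Energies are kcal/mol, temperatures kelvin, voltages millivolt at
interfaces (volts internally where Faraday's constant appears).
"""

#: Gas constant, kcal/(mol K).
R_KCAL: float = 1.9872e-3

#: Gas constant, J/(mol K) — used only inside the GHK flux factor.
R_J: float = 8.314462618

#: Faraday constant, C/mol.
FARADAY: float = 96485.33212

#: Boltzmann constant over elementary charge, V/K, so that
#: z*V / (KB_OVER_E * T) is dimensionless with V in volts.
KB_OVER_E: float = 8.617333262e-5

#: Conversion of a Celsius temperature to kelvin.
CELSIUS_OFFSET: float = 273.15


def celsius_to_kelvin(t_c: float) -> float:
    """Convert °C to K."""
    return t_c + CELSIUS_OFFSET


def kelvin_to_celsius(t_k: float) -> float:
    """Convert K to °C."""
    return t_k - CELSIUS_OFFSET
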