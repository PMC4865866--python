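"""Physical constants and unit conversions used throughout the package.

Energies are in meV, momentum transfers in nm^-1, temperatures in kelvin
unless a function states otherwise.
"""

import numpy as np

#: Reduced Planck constant, meV * s.
HBAR_MEV_S = 6.582119569e-13

#: Boltzmann constant, meV / K.
KB_MEV_PER_K = 8.617333262e-2

#: Converts a dispersion slope d(hbar*omega)/dQ in meV * nm into a phase
#: velocity in m/s:  v = E / (hbar * Q)  with Q in nm^-1.
MEV_NM_TO_M_PER_S = 1.0 / (HBAR_MEV_S * 1.0e9)  # ~1519.267

#: 0 degrees Celsius in kelvin.
CELSIUS_OFFSET = 273.15


def celsius_to_kelvin(temperature_c: float) -> float:
    """Convert a temperature from Celsius to kelvin."""
    t = float(temperature_c) + CELSIUS_OFFSET
    if t <= 0:
        raise ValueError(f"temperature {temperature_c} degC is at or below 0 K")
    return t


def thermal_energy_mev(temperature_k: float) -> float:
    """k_B * T in meV."""
    if temperature_k <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    return KB_MEV_PER_K * float(temperature_k)


def nm_inv_to_spacing_nm(q_nm_inv: float) -> float:
    """Real-space repeat distance 2*pi/Q in nm for a wavevector in nm^-1."""
    if q_nm_inv <= 0:
        raise ValueError("wavevector must be positive")
    return 2.0 * np.pi / float(q_nm_inv)
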