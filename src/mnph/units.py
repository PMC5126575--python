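"""Unit conversions used at I/O boundaries.

The package is strict SI internally (T, A/m, J, kg, m, s). Magnetometry
data is often reported in CGS (Oe for fields, emu/g for mass
magnetization); these helpers make the conversion explicit rather than
implicit in parsing code.
"""

import numpy as np

#: 1 Oe = 1000/(4π) A/m
OE_TO_AM = 1e3 / (4.0 * np.pi)

#: 1 emu/g = 1 A·m²/kg (numerically identical)
EMU_G_TO_AM2_KG = 1.0


def oersted_to_am(h_oe):
    """Convert a field from oersted to A/m."""
    return np.asarray(h_oe, dtype=float) * OE_TO_AM


def am_to_oersted(h_am):
    """Convert a field from A/m to oersted."""
    return np.asarray(h_am, dtype=float) / OE_TO_AM


def mT_to_T(b_mT):
    """Convert millitesla to tesla."""
    return np.asarray(b_mT, dtype=float) * 1e-3


def celsius_to_kelvin(t_C):
    """Convert °C to K."""
    return np.asarray(t_C, dtype=float) + 273.15


def kelvin_to_celsius(t_K):
    """Convert K to °C."""
    return np.asarray(t_K, dtype=float) - 273.15
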