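"""Unit conventions and conversions, centralized.

Grid coordinates and spacings are millimetres, conductivities S/m, injected
currents milliamperes, potentials volts.  Electric fields are reported in
V/m and activating functions in V/m^2, so every spatial derivative taken on
the mm grid passes through the conversions below exactly once.
"""

M_PER_MM = 1e-3
A_PER_MA = 1e-3

#: vacuum permittivity, F/m
EPSILON_0 = 8.8541878128e-12


def mm_to_m(x):
    return x * M_PER_MM


def ma_to_a(i):
    return i * A_PER_MA


def a_to_ma(i):
    return i / A_PER_MA
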