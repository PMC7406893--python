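"""Physical constants (SI) and the unit conversions used at the presentation layer.

Internally everything is SI except where a module documents otherwise
(membrane potentials in mV and time in ms inside the Hodgkin-Huxley module,
following that literature's convention).  Reported quantities use the units
conventional in the NV-sensing literature: electric fields in mV/m, magnetic
fields in nT, current densities in mA/m^2 and charge densities in C/m^3.
"""

ELEMENTARY_CHARGE = 1.602176634e-19  # C
BOLTZMANN = 1.380649e-23             # J/K
AVOGADRO = 6.02214076e23             # 1/mol
FARADAY = ELEMENTARY_CHARGE * AVOGADRO  # C/mol
EPS0 = 8.8541878128e-12              # F/m
MU0 = 1.25663706212e-6               # H/m

# presentation-unit conversions
V_PER_M_TO_MV_PER_M = 1.0e3
V_PER_CM_TO_MV_PER_M = 1.0e5
T_TO_NT = 1.0e9
A_PER_M2_TO_MA_PER_M2 = 1.0e3


def thermal_voltage(T: float) -> float:
    """k_B*T/e in volts."""
    return BOLTZMANN * T / ELEMENTARY_CHARGE
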