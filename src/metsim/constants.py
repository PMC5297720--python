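"""Physical constants and unit conversions used throughout the package.

All internal units: concentrations mol/L, gas pressures bar, energies kJ/mol,
potentials V vs SHE, time days, volumes L, current A, areas m2.
"""

R = 8.314e-3          # gas constant, kJ/mol/K
R_J = 8.314           # gas constant, J/mol/K
R_BAR = 0.08314       # gas constant, L*bar/mol/K
F = 96485.0           # Faraday constant, C/mol e-
T_REF = 298.15        # reference temperature, K
SECONDS_PER_DAY = 86400.0
P_TOTAL = 1.013       # default headspace total pressure, bar

#: SHE -> Ag/AgCl (3 M KCl) reference electrode offset, V.
#: E(vs Ag/AgCl) = E(vs SHE) - E_AGCL_VS_SHE
E_AGCL_VS_SHE = 0.197


def water_vapour_pressure(T: float = T_REF) -> float:
    """Saturation water vapour pressure in bar (Antoine, 1-100 C range)."""
    Tc = T - 273.15
    p_mmhg = 10.0 ** (8.07131 - 1730.63 / (233.426 + Tc))
    return p_mmhg * 1.01325 / 760.0
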