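"""Physical constants and unit conversions.

The package works in Å / ps / kcal/mol / K internally and converts to
reporting units (cm/s, mol/L) only at output boundaries.
"""

#: Boltzmann constant in kcal/(mol K).
KB_KCAL: float = 0.0019872041

#: Conversion factor from Å/ps to cm/s.
APS_TO_CMS: float = 1.0e4

#: Avogadro's number, 1/mol.
AVOGADRO: float = 6.02214076e23

#: Conversion from number density in 1/Å^3 to molarity in mol/L.
#: 1 Å^3 = 1e-27 L, so c[mol/L] = (count/Å^3) * 1e27 / N_A.
PER_A3_TO_MOLAR: float = 1.0e27 / AVOGADRO


def beta(temperature: float) -> float:
    """Inverse thermal energy 1/(k_B T) in mol/kcal."""
    return 1.0 / (KB_KCAL * temperature)
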