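"""Small unit conversions used when reporting exposure concentrations."""

#: Molar mass of atrazine (C8H14ClN5) in g/mol.
ATRAZINE_MOLAR_MASS = 215.68


def ug_per_l_to_micromolar(concentration_ug_per_l: float, molar_mass_g_per_mol: float) -> float:
    """Convert a mass concentration in ug/L to micromolar.

    1 ug/L = 1e-6 g/L, and dividing by the molar mass (g/mol) gives mol/L;
    multiplying by 1e6 expresses the result in umol/L (uM).  The two 1e6
    factors cancel, so numerically this is just concentration / molar mass.
    """
    if molar_mass_g_per_mol <= 0:
        raise ValueError("molar_mass_g_per_mol must be positive")
    return concentration_ug_per_l / molar_mass_g_per_mol
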