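"""Unit conventions and exact conversion helpers.

The internal unit system is: length µm, time s, amount mol. Concentrations
are carried in µM throughout the solver state (equilibrium values span
0.04–2000 µM, which keeps the nonlinear systems well scaled), while membrane
flux densities are expressed in mol s⁻¹ µm⁻², the unit the single-channel
models are parameterized in. The bridge between the two is the exact identity

    1 µM = 1e-21 mol / µm³

so a flux density j [mol s⁻¹ µm⁻²] applied on a patch of area A [µm²] into a
control volume V [µm³] changes the local concentration at a rate
j·A/(V·MOL_PER_UM3_PER_UM) [µM/s].
"""

# 1 µM expressed in mol/µm³ (1e-6 mol/L / (1e15 µm³/L)).
MOL_PER_UM3_PER_UM = 1e-21


def uM_to_mol_per_um3(c_uM: float) -> float:
    """Convert a concentration from µM to mol/µm³ (exact)."""
    return c_uM * MOL_PER_UM3_PER_UM


def mol_per_um3_to_uM(c: float) -> float:
    """Convert a concentration from mol/µm³ to µM (exact inverse)."""
    return c / MOL_PER_UM3_PER_UM


def nM(x: float) -> float:
    """Express a value given in nM in µM."""
    return x * 1e-3


def mM(x: float) -> float:
    """Express a value given in mM in µM."""
    return x * 1e3


def ms(x: float) -> float:
    """Express a value given in milliseconds in seconds."""
    return x * 1e-3


def nm_per_s(v_um_per_s: float) -> float:
    """Express a velocity given in µm/s in nm/s (for reporting)."""
    return v_um_per_s * 1e3
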