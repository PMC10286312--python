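"""Unit conventions and boundary conversions.

All internal computation uses molar water concentrations (µM), tissue
concentrations in µmol per kg wet weight (µmol/kg_MP for the
membrane-protein compartment), and time in days.  Mass-based water
concentrations (µg/L, ng/L) are converted at the package boundary using
the ligand's molar mass.
"""

from __future__ import annotations

#: Default ligand molar mass in g/mol.  A 50 µg/L thiacloprid solution is
#: equivalent to 200 nM, i.e. an effective molar mass of 250 g/mol.
DEFAULT_MOLAR_MASS = 250.0

#: Wet-to-dry weight conversion factor for Gammarus pulex tissue.
#: Exposed for convenience only; the package never applies it implicitly —
#: every tissue concentration is on a wet-weight basis.
WET_TO_DRY_FACTOR = 5.4


def ug_per_l_to_um(c_ug_l: float, molar_mass: float = DEFAULT_MOLAR_MASS) -> float:
    """Convert a water concentration from µg/L to µM."""
    if molar_mass <= 0:
        raise ValueError(f"molar_mass must be positive, got {molar_mass}")
    return c_ug_l / molar_mass


def um_to_ug_per_l(c_um: float, molar_mass: float = DEFAULT_MOLAR_MASS) -> float:
    """Convert a water concentration from µM to µg/L."""
    if molar_mass <= 0:
        raise ValueError(f"molar_mass must be positive, got {molar_mass}")
    return c_um * molar_mass


def ng_per_l_to_um(c_ng_l: float, molar_mass: float = DEFAULT_MOLAR_MASS) -> float:
    """Convert a water concentration from ng/L to µM."""
    return ug_per_l_to_um(c_ng_l / 1000.0, molar_mass)


def um_to_ng_per_l(c_um: float, molar_mass: float = DEFAULT_MOLAR_MASS) -> float:
    """Convert a water concentration from µM to ng/L."""
    return um_to_ug_per_l(c_um, molar_mass) * 1000.0


def nm_to_um(c_nm: float) -> float:
    """Convert nM to µM."""
    return c_nm / 1000.0
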