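"""Unit conventions and element data.

Internal units everywhere in the package:

* length      Å
* time        ps
* energy      kJ/mol
* force       nN (converted at the module boundary where needed)

so gradients are kJ/mol/Å and Hessians kJ/mol/Å².
"""

from __future__ import annotations

# 1 nN acting over 1 Å does 1e-19 J of work; times Avogadro -> 60.2214 kJ/mol.
NN_ANGSTROM_TO_KJ_PER_MOL: float = 60.2214

#: kJ/mol/Å per nN — the same constant read as a force conversion.
NN_TO_KJ_PER_MOL_PER_ANGSTROM: float = NN_ANGSTROM_TO_KJ_PER_MOL

KCAL_TO_KJ: float = 4.184

#: Covalent radii in Å (Cordero-type consensus values; high-spin value for Fe).
#: Used by bond detection with a configurable scale factor.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Sc": 1.70, "Ti": 1.60, "V": 1.53, "Cr": 1.39,
    "Mn": 1.61, "Fe": 1.52, "Co": 1.50, "Ni": 1.24, "Cu": 1.32, "Zn": 1.22,
    "Ga": 1.22, "Ge": 1.20, "As": 1.19, "Se": 1.20, "Br": 1.20, "Kr": 1.16,
    "Rb": 2.20, "Sr": 1.95, "Mo": 1.54, "Ru": 1.46, "Rh": 1.42, "Pd": 1.39,
    "Ag": 1.45, "Cd": 1.44, "In": 1.42, "Sn": 1.39, "Sb": 1.39, "Te": 1.38,
    "I": 1.39, "Xe": 1.40,
    "Cs": 2.44, "Ba": 2.15, "W": 1.62, "Pt": 1.36, "Au": 1.36, "Hg": 1.32,
    "Pb": 1.46,
}

#: All IUPAC element symbols, for validating parsed structures.
ELEMENT_SYMBOLS: frozenset[str] = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co
    Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te
    I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir
    Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No
    Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og""".split()
)


def normalize_element(symbol: str) -> str:
    """Map a free-form symbol ('FE', 'fe', 'Fe') onto its canonical form."""
    s = symbol.strip()
    if not s:
        raise ValueError("empty element symbol")
    canon = s[0].upper() + s[1:].lower()
    if canon not in ELEMENT_SYMBOLS:
        raise ValueError(f"unknown element symbol: {symbol!r}")
    return canon
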