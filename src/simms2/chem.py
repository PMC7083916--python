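"""Elemental compositions and monoisotopic mass bookkeeping.

Compositions are :class:`pyteomics.mass.Composition` objects (element ->
count mappings with element-wise ``+``/``-``); masses come from the NIST
atomic-mass table shipped with pyteomics.  All glycosaminoglycan residue
masses in this package are built from the handful of neutral building
blocks defined here.
"""

from __future__ import annotations

from pyteomics import mass as _pmass

Composition = _pmass.Composition

#: Mass of a proton in u, used for negative-mode [M - zH]^z- arithmetic.
PROTON = 1.00727646688

#: Monoisotopic mass of helium-4, the drift gas for all CCS values here.
HELIUM_MASS = 4.002602


def comp(formula: str) -> Composition:
    """Composition from a plain molecular formula such as ``"C6H8O6"``."""
    return Composition(formula=formula)


# In-chain residue compositions (free monosaccharide minus one water):
#   HexA    C6H8O6   uronic acid (GlcA or IdoA; identical composition)
#   dHexA   C6H6O5   4,5-unsaturated uronic acid from lyase digestion
#   HexN    C6H11NO4 glucosamine with a free amine
#   HexNAc  C8H13NO5 N-acetyl glucosamine
H2O = comp("H2O")
SO3 = comp("SO3")
ACETYL = comp("C2H2O")  # HexNAc - HexN
HEXA = comp("C6H8O6")
DELTA_HEXA = comp("C6H6O5")
HEXN = comp("C6H11NO4")
HEXNAC = HEXN + ACETYL

H2O_MASS = _pmass.calculate_mass(composition=H2O)
SO3_MASS = _pmass.calculate_mass(composition=SO3)


def monoisotopic_mass(composition: Composition) -> float:
    """Monoisotopic mass in Da of an elemental composition."""
    return _pmass.calculate_mass(composition=composition)


def average_mass(composition: Composition) -> float:
    """Average (chemical) mass in Da of an elemental composition."""
    return _pmass.calculate_mass(composition=composition, average=True)


def formula(composition: Composition) -> str:
    """Canonical Hill-ish formula string (C, H, then alphabetical)."""
    order = ["C", "H", "N", "O", "S"]
    parts = []
    for el in order:
        n = composition.get(el, 0)
        if n == 1:
            parts.append(el)
        elif n > 1:
            parts.append(f"{el}{n}")
    for el in sorted(composition):
        if el not in order and composition[el]:
            parts.append(f"{el}{composition[el]}")
    return "".join(parts)


def mz_from_neutral(neutral_mass: float, charge: int) -> float:
    """Negative-mode m/z of [M - zH]^z- for a neutral monoisotopic mass.

    Raises ``ValueError`` for a non-positive charge.
    """
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass - charge * PROTON) / charge


def neutral_from_mz(mz: float, charge: int) -> float:
    """Inverse of :func:`mz_from_neutral`."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return mz * charge + charge * PROTON


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative error of *observed* vs *theoretical* in ppm."""
    return (observed - theoretical) / theoretical * 1e6
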