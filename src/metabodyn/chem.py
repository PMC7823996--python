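"""Mass-spectrometric constants and small-molecule mass arithmetic.

Monoisotopic masses of elemental formulas are computed with pyteomics, which
carries the IUPAC atomic mass tables.
"""

from __future__ import annotations

import math

from pyteomics import mass as _ptmass

__all__ = [
    "PROTON_MASS",
    "C13_DELTA",
    "C13_ABUNDANCE",
    "FORMATE_ADDUCT_DELTA",
    "TUNE_MIX_POSITIVE",
    "TUNE_MIX_NEGATIVE",
    "monoisotopic_mass",
    "adduct_mz",
    "isotopologue_ratio",
]

#: Mass of a proton in Da (charge carrier for [M+H]+ / [M-H]- ions).
PROTON_MASS = 1.007276

#: Mass difference of one 13C substitution in Da.
C13_DELTA = 1.00335

#: Natural abundance of 13C.
C13_ABUNDANCE = 0.0107

#: [M+HCOO]- formate adduct: + HCOOH (46.005480) - proton (1.007276).
FORMATE_ADDUCT_DELTA = 44.998204

# Agilent ESI-L low-concentration tune mix ions commonly used as reference
# masses on QTOF instruments, restricted to the 20-1050 m/z scan range.
TUNE_MIX_POSITIVE = (118.0863, 322.0481, 622.0290, 922.0098)
TUNE_MIX_NEGATIVE = (112.9856, 301.9981, 601.9790, 1033.9881)


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic mass in Da of an elemental formula such as ``"C3H6O3"``.

    Raises
    ------
    ValueError
        If the formula contains an unknown element symbol or is malformed.
    """
    try:
        return float(_ptmass.calculate_mass(formula=formula))
    except Exception as exc:  # pyteomics raises its own hierarchy
        raise ValueError(f"cannot parse elemental formula {formula!r}: {exc}") from exc


def adduct_mz(neutral_mass: float, polarity: str) -> float:
    """m/z of the [M+H]+ (positive) or [M-H]- (negative) ion of a neutral mass."""
    if polarity == "+":
        return neutral_mass + PROTON_MASS
    if polarity == "-":
        return neutral_mass - PROTON_MASS
    raise ValueError(f"polarity must be '+' or '-', got {polarity!r}")


def isotopologue_ratio(n_carbons: int, k: int, p: float = C13_ABUNDANCE) -> float:
    """Expected intensity ratio I(M+k)/I(M) for a molecule with ``n_carbons``.

    Under a binomial model for 13C incorporation,
    I(M+k)/I(M) = C(n, k) * (p / (1 - p))**k.
    """
    if k < 0 or n_carbons < 0:
        raise ValueError("n_carbons and k must be non-negative")
    if k > n_carbons:
        return 0.0
    return math.comb(n_carbons, k) * (p / (1.0 - p)) ** k
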