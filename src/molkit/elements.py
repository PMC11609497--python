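"""Element lookup tables: atomic masses (amu) and Bondi van-der-Waals radii (nm).

PDB and XYZ files carry no masses, so masses are assigned from the element,
which is in turn inferred from the atom name when no element column exists.
Unknown elements get a default mass of 12.0 amu with a warning; unknown vdW
radii are an error at the point of use (SASA) rather than a silent default.
"""

from __future__ import annotations

import warnings

MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "Cl": 35.45, "Br": 79.904, "I": 126.904,
    "Na": 22.990, "K": 39.098, "Mg": 24.305, "Ca": 40.078, "Fe": 55.845,
    "Zn": 65.38, "Mn": 54.938, "Cu": 63.546, "Se": 78.971, "B": 10.81,
}

DEFAULT_MASS = 12.0

# Bondi (1964) radii in nm; ions use common tabulated values.
VDW_RADII: dict[str, float] = {
    "H": 0.120, "C": 0.170, "N": 0.155, "O": 0.152, "S": 0.180,
    "P": 0.180, "F": 0.147, "Cl": 0.175, "Br": 0.185, "I": 0.198,
    "Na": 0.227, "K": 0.275, "Mg": 0.173, "Zn": 0.139, "Se": 0.190,
    "Cu": 0.140, "Ca": 0.231,
}

# Names that are unambiguously two-letter elements when they stand alone.
_TWO_LETTER = {"CL", "BR", "NA", "MG", "FE", "ZN", "MN", "CU", "SE"}


def guess_element(name: str) -> str:
    """Infer an element symbol from an atom name's leading letters.

    ``CA`` is treated as an alpha carbon, not calcium; two-letter ion names
    (``CL``, ``NA``, ``MG`` ...) map to the ion element.
    """
    stripped = name.strip().lstrip("0123456789'\"*")
    if not stripped:
        return "X"
    upper = stripped.upper()
    if upper[:2] in _TWO_LETTER and (len(upper) == 2 or not upper[2:3].isalpha()):
        return upper[:2].capitalize()
    first = upper[0]
    return first if first.isalpha() else "X"


def mass_of(element: str) -> float:
    key = element.strip().capitalize()
    if key in MASSES:
        return MASSES[key]
    warnings.warn(f"unknown element {element!r}: using default mass {DEFAULT_MASS} amu")
    return DEFAULT_MASS


def vdw_radius_of(element: str) -> float | None:
    return VDW_RADII.get(element.strip().capitalize())
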