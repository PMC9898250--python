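"""Bundled per-element masses (amu) and van der Waals radii (Å).

Covers the elements that occur in transporter/membrane systems; pseudo-atoms
in synthetic systems default to carbon. Radii follow the Bondi set.
"""

from __future__ import annotations

ELEMENT_MASS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "MG": 24.305,
    "NA": 22.990,
    "CL": 35.45,
    "K": 39.098,
}

ELEMENT_VDW: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "S": 1.80,
    "MG": 1.73,
    "NA": 2.27,
    "CL": 1.75,
    "K": 2.75,
}


class ElementLookupError(KeyError):
    """Raised when mass or vdW radius is requested for an unknown element."""


def element_mass(element: str) -> float:
    try:
        return ELEMENT_MASS[element.upper()]
    except KeyError:
        raise ElementLookupError(f"no mass tabulated for element {element!r}") from None


def element_vdw(element: str) -> float:
    try:
        return ELEMENT_VDW[element.upper()]
    except KeyError:
        raise ElementLookupError(f"no vdW radius tabulated for element {element!r}") from None


def guess_element(atom_name: str) -> str:
    """Guess the element from a PDB atom name (first alphabetic character,
    two-letter check for Mg/Na/Cl)."""
    stripped = atom_name.strip()
    two = stripped[:2].upper()
    if two in ("MG", "NA", "CL"):
        return two
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    raise ElementLookupError(f"cannot guess element from atom name {atom_name!r}")
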