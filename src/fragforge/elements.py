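"""Element data shared across the package.

Van der Waals radii follow Bondi's compilation (values in Angstrom). The
voxelizer and the density cutoff (1.75 * r) are element-aware; elements not
in the table fall back to the carbon radius, mirroring how unrecognised heavy
atoms are routed to the catch-all "other" grid channel.
"""

from __future__ import annotations

# Bondi-style vdW radii, Angstrom.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
    "B": 1.92,
    "Si": 2.10,
    "Se": 1.90,
    # common metals seen in binding sites; all land in the "other" channel
    "Fe": 2.00,
    "Zn": 1.39,
    "Mg": 1.73,
    "Ca": 2.31,
    "Mn": 2.00,
    "Na": 2.27,
    "K": 2.75,
    "Cu": 1.40,
    "Ni": 1.63,
    "Co": 2.00,
}

#: fallback radius for elements outside the table (carbon radius)
DEFAULT_RADIUS: float = VDW_RADII["C"]

#: elements the fixture generator draws receptor atoms from
RECEPTOR_ELEMENTS: tuple[str, ...] = ("C", "N", "O", "S", "P")


def vdw_radius(element: str) -> float:
    """Van der Waals radius in Angstrom; unknown elements get the C radius."""
    return VDW_RADII.get(element, DEFAULT_RADIUS)
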