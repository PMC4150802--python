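"""Residue templates for the four canonical ribonucleotides.

Connectivity (with hydrogens), rotatability flags, van der Waals radii,
backbone/glycosidic torsion definitions, Watson-Crick hydrogen-bond atoms,
and idealized planar base coordinates used by the synthetic fixture builder.

Rotatable bonds carry the usual backbone labels: alpha (P-O5'), beta
(O5'-C5'), gamma (C5'-C4'), epsilon (C3'-O3'), zeta (O3'-P of the next
residue) and chi (glycosidic).  delta is not an independent bond torsion
here; the ribose ring is a rigid body driven by the pucker coordinate tau.
The 2'-OH torsion is deliberately frozen into the ribose body so that the
degree-of-freedom count matches the backbone + glycosidic set.
"""

from __future__ import annotations

import numpy as np

from .geometry import rotation_matrix, unit

# --- element data -----------------------------------------------------------

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "H": 1.20}

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "U"}
BASE_TYPES = PURINES | PYRIMIDINES

# complementary WC partner
WC_PARTNER = {"A": "U", "U": "A", "G": "C", "C": "G"}

# --- sugar / backbone -------------------------------------------------------

SUGAR_ATOMS = [
    ("P", "P"), ("OP1", "O"), ("OP2", "O"),
    ("O5'", "O"), ("C5'", "C"), ("H5'", "H"), ("H5''", "H"),
    ("C4'", "C"), ("H4'", "H"), ("O4'", "O"),
    ("C3'", "C"), ("H3'", "H"), ("O3'", "O"),
    ("C2'", "C"), ("H2'", "H"), ("O2'", "O"), ("HO2'", "H"),
    ("C1'", "C"), ("H1'", "H"),
]

RING_ATOMS = ["O4'", "C1'", "C2'", "C3'", "C4'"]

# (name_i, name_j, rotatable)
SUGAR_BONDS = [
    ("P", "OP1", False), ("P", "OP2", False), ("P", "O5'", True),      # alpha
    ("O5'", "C5'", True),                                              # beta
    ("C5'", "H5'", False), ("C5'", "H5''", False),
    ("C5'", "C4'", True),                                              # gamma
    ("C4'", "H4'", False), ("C4'", "O4'", False), ("C4'", "C3'", False),
    ("O4'", "C1'", False),
    ("C1'", "H1'", False), ("C1'", "C2'", False),
    ("C2'", "H2'", False), ("C2'", "O2'", False), ("O2'", "HO2'", False),
    ("C2'", "C3'", False),
    ("C3'", "H3'", False), ("C3'", "O3'", True),                       # epsilon
]

# terminal decorations
FIVE_PRIME_OH = [("HO5'", "H")]          # replaces P, OP1, OP2
FIVE_PRIME_OH_BONDS = [("O5'", "HO5'", False)]
THREE_PRIME_OH = [("HO3'", "H")]
THREE_PRIME_OH_BONDS = [("O3'", "HO3'", False)]
FIVE_PRIME_OP3 = [("OP3", "O")]          # optional third phosphate oxygen
FIVE_PRIME_OP3_BONDS = [("P", "OP3", False)]

# --- bases ------------------------------------------------------------------

BASE_ATOMS = {
    "A": [("N9", "N"), ("C8", "C"), ("H8", "H"), ("N7", "N"), ("C5", "C"),
          ("C6", "C"), ("N6", "N"), ("H61", "H"), ("H62", "H"), ("N1", "N"),
          ("C2", "C"), ("H2", "H"), ("N3", "N"), ("C4", "C")],
    "G": [("N9", "N"), ("C8", "C"), ("H8", "H"), ("N7", "N"), ("C5", "C"),
          ("C6", "C"), ("O6", "O"), ("N1", "N"), ("H1", "H"), ("C2", "C"),
          ("N2", "N"), ("H21", "H"), ("H22", "H"), ("N3", "N"), ("C4", "C")],
    "C": [("N1", "N"), ("C2", "C"), ("O2", "O"), ("N3", "N"), ("C4", "C"),
          ("N4", "N"), ("H41", "H"), ("H42", "H"), ("C5", "C"), ("H5", "H"),
          ("C6", "C"), ("H6", "H")],
    "U": [("N1", "N"), ("C2", "C"), ("O2", "O"), ("N3", "N"), ("H3", "H"),
          ("C4", "C"), ("O4", "O"), ("C5", "C"), ("H5", "H"),
          ("C6", "C"), ("H6", "H")],
}

_PURINE_RING_BONDS = [
    ("N1", "C2"), ("C2", "N3"), ("N3", "C4"), ("C4", "C5"), ("C5", "C6"),
    ("C6", "N1"), ("C5", "N7"), ("N7", "C8"), ("C8", "N9"), ("N9", "C4"),
]
_PYRIMIDINE_RING_BONDS = [
    ("N1", "C2"), ("C2", "N3"), ("N3", "C4"), ("C4", "C5"), ("C5", "C6"),
    ("C6", "N1"),
]

BASE_BONDS = {
    "A": _PURINE_RING_BONDS + [
        ("C8", "H8"), ("C6", "N6"), ("N6", "H61"), ("N6", "H62"), ("C2", "H2")],
    "G": _PURINE_RING_BONDS + [
        ("C8", "H8"), ("C6", "O6"), ("N1", "H1"),
        ("C2", "N2"), ("N2", "H21"), ("N2", "H22")],
    "C": _PYRIMIDINE_RING_BONDS + [
        ("C2", "O2"), ("C4", "N4"), ("N4", "H41"), ("N4", "H42"),
        ("C5", "H5"), ("C6", "H6")],
    "U": _PYRIMIDINE_RING_BONDS + [
        ("C2", "O2"), ("N3", "H3"), ("C4", "O4"), ("C5", "H5"), ("C6", "H6")],
}

GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "U": "N1"}
# ring neighbors of the glycosidic nitrogen (for the C1' exterior bisector)
GLYC_RING_NEIGHBORS = {"A": ("C4", "C8"), "G": ("C4", "C8"),
                       "C": ("C2", "C6"), "U": ("C2", "C6")}
# chi = O4'-C1'-N9-C4 (purines) / O4'-C1'-N1-C2 (pyrimidines)
CHI_REF_ATOM = {"A": "C4", "G": "C4", "C": "C2", "U": "C2"}


def glycosidic_bond(base: str):
    return ("C1'", GLYCOSIDIC_N[base])


def base_atom_names(base: str):
    return [n for n, _ in BASE_ATOMS[base]]


# --- torsion quadruples (IUPAC) --------------------------------------------
# entries: label -> (quadruple of (residue offset, atom name)) where offset is
# relative to the residue owning the torsion.
TORSION_DEFS = {
    "alpha":   (((-1, "O3'"), (0, "P"), (0, "O5'"), (0, "C5'"))),
    "beta":    (((0, "P"), (0, "O5'"), (0, "C5'"), (0, "C4'"))),
    "gamma":   (((0, "O5'"), (0, "C5'"), (0, "C4'"), (0, "C3'"))),
    "delta":   (((0, "C5'"), (0, "C4'"), (0, "C3'"), (0, "O3'"))),
    "epsilon": (((0, "C4'"), (0, "C3'"), (0, "O3'"), (1, "P"))),
    "zeta":    (((0, "C3'"), (0, "O3'"), (1, "P"), (1, "O5'"))),
}

# rotatable backbone bond -> label (both atoms in the same residue unless zeta)
BOND_LABELS = {
    ("P", "O5'"): "alpha",
    ("O5'", "C5'"): "beta",
    ("C5'", "C4'"): "gamma",
    ("C3'", "O3'"): "epsilon",
}
INTER_BOND = ("O3'", "P")  # residue i -> i+1, label zeta


# --- Watson-Crick hydrogen bonds -------------------------------------------
# Canonical central WC hydrogen bond per pair class, as
# (donor residue letter, donor heavy atom, hydrogen, acceptor residue letter,
#  acceptor atom).  AU: U(N3)-H3 ... A(N1).  GC: G(N1)-H1 ... C(N3).
WC_HBONDS = {
    "AU": ("U", "N3", "H3", "A", "N1"),
    "GC": ("G", "N1", "H1", "C", "N3"),
}


# --- idealized planar base geometry ----------------------------------------

_RING_BOND = 1.385       # aromatic ring bond length (regular-polygon idealization)
_C_N_EXO = 1.34          # C-N exocyclic (amino)
_C_O_EXO = 1.23          # C=O exocyclic
_N_H = 1.01
_C_H = 1.08
_C1P_N = 1.47            # glycosidic bond length


def _regular_polygon(n, side):
    r = side / (2.0 * np.sin(np.pi / n))
    ang = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([r * np.cos(ang), r * np.sin(ang), np.zeros(n)])


def _exo(center, ring_atom, length):
    """Place an exocyclic substituent radially outward from the ring center."""
    d = unit(ring_atom - center)
    return ring_atom + length * d


def ideal_base_coords(base: str) -> dict:
    """Idealized planar coordinates (z=0 plane) for one base, keyed by name.

    Rings are regular polygons; substituents sit on the exterior bisector.
    The geometry is an internally consistent idealization, not a fiber
    average; Watson-Crick placement is calibrated downstream.
    """
    coords = {}
    hexagon = _regular_polygon(6, _RING_BOND)
    hex_names = ["N1", "C2", "N3", "C4", "C5", "C6"]
    center6 = hexagon.mean(axis=0)
    for name, p in zip(hex_names, hexagon):
        coords[name] = p

    if base in PURINES:
        # fuse a regular pentagon on the C4-C5 edge, on the outside
        c4, c5 = coords["C4"], coords["C5"]
        mid = 0.5 * (c4 + c5)
        out = unit(mid - center6)
        edge = c5 - c4
        r5 = _RING_BOND / (2.0 * np.sin(np.pi / 5.0))
        apothem = r5 * np.cos(np.pi / 5.0)
        center5 = mid + out * apothem
        # pentagon vertices: rotate c4 about center5 by multiples of 72 deg,
        # choosing the rotation sense that starts from C4 toward C5.
        Rz = rotation_matrix(np.array([0.0, 0.0, 1.0]), -2.0 * np.pi / 5.0)
        v = c4 - center5
        pent = [c4]
        for _ in range(4):
            v = v @ Rz.T
            pent.append(center5 + v)
        if np.linalg.norm(pent[1] - c5) > 1e-6:  # wrong sense; flip
            Rz = rotation_matrix(np.array([0.0, 0.0, 1.0]), 2.0 * np.pi / 5.0)
            v = c4 - center5
            pent = [c4]
            for _ in range(4):
                v = v @ Rz.T
                pent.append(center5 + v)
        # pent order: C4, C5, N7, C8, N9
        coords["N7"], coords["C8"], coords["N9"] = pent[2], pent[3], pent[4]
        coords["H8"] = _exo(center5, coords["C8"], _C_H)
        if base == "A":
            coords["N6"] = _exo(center6, coords["C6"], _C_N_EXO)
            coords["H2"] = _exo(center6, coords["C2"], _C_H)
            _amino_hydrogens(coords, "C6", "N6", "H61", "H62")
        else:  # G
            coords["O6"] = _exo(center6, coords["C6"], _C_O_EXO)
            coords["H1"] = _exo(center6, coords["N1"], _N_H)
            coords["N2"] = _exo(center6, coords["C2"], _C_N_EXO)
            _amino_hydrogens(coords, "C2", "N2", "H21", "H22")
    else:
        coords["O2"] = _exo(center6, coords["C2"], _C_O_EXO)
        coords["H5"] = _exo(center6, coords["C5"], _C_H)
        coords["H6"] = _exo(center6, coords["C6"], _C_H)
        if base == "C":
            coords["N4"] = _exo(center6, coords["C4"], _C_N_EXO)
            _amino_hydrogens(coords, "C4", "N4", "H41", "H42")
        else:  # U
            coords["H3"] = _exo(center6, coords["N3"], _N_H)
            coords["O4"] = _exo(center6, coords["C4"], _C_O_EXO)
    return coords


def _amino_hydrogens(coords, parent, n_name, h1, h2):
    """Two in-plane amino hydrogens at +-120 deg from the parent->N bond."""
    n = coords[n_name]
    d = unit(n - coords[parent])
    z = np.array([0.0, 0.0, 1.0])
    for name, sgn in ((h1, 1.0), (h2, -1.0)):
        R = rotation_matrix(z, sgn * 2.0 * np.pi / 3.0)
        coords[name] = n + _N_H * (-(d @ R.T))
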