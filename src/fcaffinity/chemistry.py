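"""Chemical reference data shared across the package.

Fixed tables: van der Waals radii, atomic solvation parameters,
hydrogen-bond donor/acceptor atoms, salt-bridge charged-group atoms,
the hydrophilic residue set, and ideal side-chain internal coordinates
used for template-based mutagenesis.

All geometry is heavy-atom only: crystal structures of antibody
complexes rarely resolve hydrogens, so every distance criterion in this
package is defined between heavy atoms.
"""

from __future__ import annotations

# --- amino-acid codes -------------------------------------------------

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
CANONICAL_AA = frozenset(AA1_TO_3)

# --- van der Waals radii (Å), Bondi-like ------------------------------

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
VDW_DEFAULT = 1.70


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), VDW_DEFAULT)


# --- atomic solvation parameters (kcal / (mol Å²)) --------------------
# Eisenberg & McLachlan-style constants: apolar atoms favour burial,
# polar atoms favour exposure.  Energy of an atom = ASP(element) × SASA.

SOLVATION_ASP = {"C": 0.016, "N": -0.006, "O": -0.006, "S": 0.021}

# --- hydrogen-bond donor / acceptor heavy atoms -----------------------
# Backbone N is a donor (except proline); backbone O an acceptor.
# Side-chain entries list heavy atoms only; sulfur is excluded.

HB_DONORS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "ASN": ("ND2",), "GLN": ("NE2",), "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2"),
    "TRP": ("NE1",),
}
HB_ACCEPTORS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "ASN": ("OD1",), "GLN": ("OE1",),
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"),
}

# --- salt-bridge charged-group atoms ----------------------------------

NEGATIVE_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
POSITIVE_ATOMS = {
    "LYS": ("NZ",),
    "ARG": ("NH1", "NH2", "NE"),
    "HIS": ("ND1", "NE2"),
}

# --- hydrophilic residues (1-letter) ----------------------------------
# Cys and Trp are borderline and deliberately excluded.

HYDROPHILIC = frozenset("STNQYHKRDE")

# --- ideal side-chain internal coordinates ----------------------------
# Each side-chain heavy atom beyond CB is defined by a z-matrix row
#   (name, (a, b, c), bond, angle, torsion)
# placed so that |c-atom| = bond, angle(b, c, atom) = angle and
# dihedral(a, b, c, atom) = torsion.  A torsion may be numeric (fixed)
# or ("chiN", offset) meaning the variable chi angle plus a constant.
# CB itself is placed from the N-CA-C frame (see mutator.build_side_chain).

_c = lambda n, off=0.0: (f"chi{n}", off)  # noqa: E731

SIDE_CHAIN_ZMAT: dict[str, list[tuple]] = {
    "GLY": [],
    "ALA": [],
    "SER": [("OG", ("N", "CA", "CB"), 1.42, 110.8, _c(1))],
    "CYS": [("SG", ("N", "CA", "CB"), 1.81, 113.8, _c(1))],
    "THR": [("OG1", ("N", "CA", "CB"), 1.43, 109.6, _c(1)),
            ("CG2", ("N", "CA", "CB"), 1.52, 110.5, _c(1, -120.0))],
    "VAL": [("CG1", ("N", "CA", "CB"), 1.52, 110.5, _c(1)),
            ("CG2", ("N", "CA", "CB"), 1.52, 110.5, _c(1, 120.0))],
    "LEU": [("CG", ("N", "CA", "CB"), 1.53, 116.3, _c(1)),
            ("CD1", ("CA", "CB", "CG"), 1.52, 110.7, _c(2)),
            ("CD2", ("CA", "CB", "CG"), 1.52, 110.7, _c(2, 120.0))],
    "ILE": [("CG1", ("N", "CA", "CB"), 1.53, 110.4, _c(1)),
            ("CG2", ("N", "CA", "CB"), 1.52, 110.5, _c(1, -120.0)),
            ("CD1", ("CA", "CB", "CG1"), 1.51, 113.8, _c(2))],
    "MET": [("CG", ("N", "CA", "CB"), 1.52, 114.1, _c(1)),
            ("SD", ("CA", "CB", "CG"), 1.80, 112.7, _c(2)),
            ("CE", ("CB", "CG", "SD"), 1.79, 100.9, 180.0)],
    "PRO": [("CG", ("N", "CA", "CB"), 1.50, 104.5, 25.0),
            ("CD", ("CA", "CB", "CG"), 1.51, 106.1, -35.0)],
    "PHE": [("CG", ("N", "CA", "CB"), 1.50, 113.8, _c(1)),
            ("CD1", ("CA", "CB", "CG"), 1.39, 120.8, _c(2)),
            ("CD2", ("CA", "CB", "CG"), 1.39, 120.8, _c(2, 180.0)),
            ("CE1", ("CB", "CG", "CD1"), 1.39, 120.8, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.39, 120.8, 180.0),
            ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0)],
    "TYR": [("CG", ("N", "CA", "CB"), 1.51, 113.9, _c(1)),
            ("CD1", ("CA", "CB", "CG"), 1.39, 120.8, _c(2)),
            ("CD2", ("CA", "CB", "CG"), 1.39, 120.8, _c(2, 180.0)),
            ("CE1", ("CB", "CG", "CD1"), 1.39, 121.2, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.39, 121.2, 180.0),
            ("CZ", ("CG", "CD1", "CE1"), 1.38, 119.6, 0.0),
            ("OH", ("CD1", "CE1", "CZ"), 1.38, 119.9, 180.0)],
    "TRP": [("CG", ("N", "CA", "CB"), 1.50, 113.6, _c(1)),
            ("CD1", ("CA", "CB", "CG"), 1.37, 126.9, _c(2)),
            ("CD2", ("CA", "CB", "CG"), 1.43, 126.7, _c(2, 180.0)),
            ("NE1", ("CB", "CG", "CD1"), 1.38, 110.2, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.41, 107.2, 180.0),
            ("CE3", ("CD1", "CG", "CD2"), 1.40, 133.9, 180.0),
            ("CZ2", ("CG", "CD2", "CE2"), 1.40, 122.4, 180.0),
            ("CZ3", ("CG", "CD2", "CE3"), 1.39, 118.6, 180.0),
            ("CH2", ("CD2", "CE2", "CZ2"), 1.37, 117.5, 0.0)],
    "ASP": [("CG", ("N", "CA", "CB"), 1.52, 113.1, _c(1)),
            ("OD1", ("CA", "CB", "CG"), 1.25, 118.2, _c(2)),
            ("OD2", ("CA", "CB", "CG"), 1.25, 118.2, _c(2, 180.0))],
    "ASN": [("CG", ("N", "CA", "CB"), 1.52, 112.6, _c(1)),
            ("OD1", ("CA", "CB", "CG"), 1.23, 120.8, _c(2)),
            ("ND2", ("CA", "CB", "CG"), 1.33, 116.4, _c(2, 180.0))],
    "GLU": [("CG", ("N", "CA", "CB"), 1.52, 114.1, _c(1)),
            ("CD", ("CA", "CB", "CG"), 1.52, 112.6, _c(2)),
            ("OE1", ("CB", "CG", "CD"), 1.25, 118.2, 0.0),
            ("OE2", ("CB", "CG", "CD"), 1.25, 118.2, 180.0)],
    "GLN": [("CG", ("N", "CA", "CB"), 1.52, 114.1, _c(1)),
            ("CD", ("CA", "CB", "CG"), 1.52, 112.6, _c(2)),
            ("OE1", ("CB", "CG", "CD"), 1.23, 120.8, 0.0),
            ("NE2", ("CB", "CG", "CD"), 1.33, 116.4, 180.0)],
    "LYS": [("CG", ("N", "CA", "CB"), 1.52, 114.1, _c(1)),
            ("CD", ("CA", "CB", "CG"), 1.52, 111.3, _c(2)),
            ("CE", ("CB", "CG", "CD"), 1.52, 111.3, 180.0),
            ("NZ", ("CG", "CD", "CE"), 1.49, 111.9, 180.0)],
    "ARG": [("CG", ("N", "CA", "CB"), 1.52, 114.1, _c(1)),
            ("CD", ("CA", "CB", "CG"), 1.52, 111.3, _c(2)),
            ("NE", ("CB", "CG", "CD"), 1.46, 112.0, 180.0),
            ("CZ", ("CG", "CD", "NE"), 1.33, 124.2, 180.0),
            ("NH1", ("CD", "NE", "CZ"), 1.33, 120.0, 0.0),
            ("NH2", ("CD", "NE", "CZ"), 1.33, 120.0, 180.0)],
    "HIS": [("CG", ("N", "CA", "CB"), 1.50, 113.8, _c(1)),
            ("ND1", ("CA", "CB", "CG"), 1.38, 122.7, _c(2)),
            ("CD2", ("CA", "CB", "CG"), 1.36, 131.0, _c(2, 180.0)),
            ("CE1", ("CB", "CG", "ND1"), 1.32, 109.2, 180.0),
            ("NE2", ("CB", "CG", "CD2"), 1.37, 107.2, 180.0)],
}

del _c

# Chi angles that exist (and are scanned) per residue type.
SCANNED_CHIS: dict[str, tuple[str, ...]] = {}
for _aa, _rows in SIDE_CHAIN_ZMAT.items():
    _chis = []
    for _row in _rows:
        _t = _row[4]
        if isinstance(_t, tuple) and _t[1] == 0.0 and _t[0] not in _chis:
            _chis.append(_t[0])
    SCANNED_CHIS[_aa] = tuple(_chis)
del _aa, _rows, _chis, _row, _t


def element_of(atom_name: str) -> str:
    """Infer the element from a PDB heavy-atom name (protein atoms)."""
    for ch in atom_name.strip():
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")
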