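"""Single-rotamer side-chain templates built from idealized internal coordinates.

Each entry places one heavy atom from three previously placed atoms
(parent, grandparent, great-grandparent) with an idealized bond length,
bond angle and a fixed torsion — an all-anti "template rotamer" with
approximate ring geometry.  The templates provide chemically labelled
heavy atoms for contact, salt-bridge and ion-proximity analysis; they make
no claim of rotameric or ring-planarity accuracy.
"""

from __future__ import annotations

import numpy as np

from coassembler._geom import place_atom

# (atom, ref1, ref2, ref3, bond Å, angle deg, torsion deg) — torsion is
# ref3-ref2-ref1-atom; backbone atoms N, CA, C plus CB are placed elsewhere.
SIDECHAIN_TOPOLOGY: dict[str, list[tuple[str, str, str, str, float, float, float]]] = {
    "GLY": [],
    "ALA": [],
    "SER": [("OG", "CB", "CA", "N", 1.42, 110.8, -65.0)],
    "CYS": [("SG", "CB", "CA", "N", 1.81, 113.8, -65.0)],
    "THR": [("OG1", "CB", "CA", "N", 1.43, 109.5, -60.0),
            ("CG2", "CB", "CA", "N", 1.52, 110.5, 60.0)],
    "VAL": [("CG1", "CB", "CA", "N", 1.53, 110.8, 175.0),
            ("CG2", "CB", "CA", "N", 1.53, 110.8, -65.0)],
    "LEU": [("CG", "CB", "CA", "N", 1.53, 116.3, -65.0),
            ("CD1", "CG", "CB", "CA", 1.52, 110.7, 65.0),
            ("CD2", "CG", "CB", "CA", 1.52, 110.7, -175.0)],
    "ILE": [("CG1", "CB", "CA", "N", 1.53, 110.4, -60.0),
            ("CG2", "CB", "CA", "N", 1.53, 110.5, 170.0),
            ("CD1", "CG1", "CB", "CA", 1.52, 113.9, 170.0)],
    "MET": [("CG", "CB", "CA", "N", 1.52, 114.1, -65.0),
            ("SD", "CG", "CB", "CA", 1.80, 112.7, 180.0),
            ("CE", "SD", "CG", "CB", 1.79, 100.8, 180.0)],
    "PRO": [("CG", "CB", "CA", "N", 1.49, 104.5, 30.0),
            ("CD", "CG", "CB", "CA", 1.50, 106.1, -35.0)],
    "PHE": [("CG", "CB", "CA", "N", 1.50, 113.8, -65.0),
            ("CD1", "CG", "CB", "CA", 1.39, 120.8, 90.0),
            ("CD2", "CG", "CB", "CA", 1.39, 120.8, -90.0),
            ("CE1", "CD1", "CG", "CB", 1.39, 120.0, 180.0),
            ("CE2", "CD2", "CG", "CB", 1.39, 120.0, 180.0),
            ("CZ", "CE1", "CD1", "CG", 1.39, 120.0, 0.0)],
    "TYR": [("CG", "CB", "CA", "N", 1.51, 113.9, -65.0),
            ("CD1", "CG", "CB", "CA", 1.39, 120.8, 90.0),
            ("CD2", "CG", "CB", "CA", 1.39, 120.8, -90.0),
            ("CE1", "CD1", "CG", "CB", 1.39, 121.1, 180.0),
            ("CE2", "CD2", "CG", "CB", 1.39, 121.1, 180.0),
            ("CZ", "CE1", "CD1", "CG", 1.38, 119.5, 0.0),
            ("OH", "CZ", "CE1", "CD1", 1.38, 119.8, 180.0)],
    "TRP": [("CG", "CB", "CA", "N", 1.50, 113.6, -65.0),
            ("CD1", "CG", "CB", "CA", 1.37, 126.9, 90.0),
            ("CD2", "CG", "CB", "CA", 1.43, 126.6, -90.0),
            ("NE1", "CD1", "CG", "CB", 1.38, 110.2, 180.0),
            ("CE2", "NE1", "CD1", "CG", 1.37, 108.9, 0.0),
            ("CE3", "CD2", "CG", "CD1", 1.40, 133.9, 180.0),
            ("CZ2", "CE2", "NE1", "CD1", 1.40, 130.1, 180.0),
            ("CZ3", "CE3", "CD2", "CG", 1.39, 118.7, 180.0),
            ("CH2", "CZ2", "CE2", "NE1", 1.37, 117.5, 180.0)],
    "ASP": [("CG", "CB", "CA", "N", 1.52, 113.1, -65.0),
            ("OD1", "CG", "CB", "CA", 1.25, 118.2, -20.0),
            ("OD2", "CG", "CB", "CA", 1.25, 118.2, 160.0)],
    "GLU": [("CG", "CB", "CA", "N", 1.52, 114.2, -65.0),
            ("CD", "CG", "CB", "CA", 1.52, 112.6, 180.0),
            ("OE1", "CD", "CG", "CB", 1.25, 118.3, -20.0),
            ("OE2", "CD", "CG", "CB", 1.25, 118.3, 160.0)],
    "ASN": [("CG", "CB", "CA", "N", 1.52, 112.7, -65.0),
            ("OD1", "CG", "CB", "CA", 1.23, 120.8, -60.0),
            ("ND2", "CG", "CB", "CA", 1.33, 116.5, 120.0)],
    "GLN": [("CG", "CB", "CA", "N", 1.52, 114.2, -65.0),
            ("CD", "CG", "CB", "CA", 1.52, 112.6, 180.0),
            ("OE1", "CD", "CG", "CB", 1.23, 120.9, -60.0),
            ("NE2", "CD", "CG", "CB", 1.33, 116.4, 120.0)],
    "LYS": [("CG", "CB", "CA", "N", 1.52, 114.1, -65.0),
            ("CD", "CG", "CB", "CA", 1.52, 111.3, 180.0),
            ("CE", "CD", "CG", "CB", 1.52, 111.3, 180.0),
            ("NZ", "CE", "CD", "CG", 1.49, 111.9, 180.0)],
    "ARG": [("CG", "CB", "CA", "N", 1.52, 114.1, -65.0),
            ("CD", "CG", "CB", "CA", 1.52, 111.3, 180.0),
            ("NE", "CD", "CG", "CB", 1.46, 112.0, 180.0),
            ("CZ", "NE", "CD", "CG", 1.33, 124.2, 180.0),
            ("NH1", "CZ", "NE", "CD", 1.33, 120.0, 0.0),
            ("NH2", "CZ", "NE", "CD", 1.33, 120.0, 180.0)],
    "HIS": [("CG", "CB", "CA", "N", 1.49, 113.8, -65.0),
            ("ND1", "CG", "CB", "CA", 1.38, 122.7, 90.0),
            ("CD2", "CG", "CB", "CA", 1.36, 131.1, -90.0),
            ("CE1", "ND1", "CG", "CB", 1.32, 109.2, 180.0),
            ("NE2", "CD2", "CG", "CB", 1.37, 107.2, 180.0)],
}

# CB placement relative to the backbone frame; torsion C-N-CA-CB reproduces
# L-amino-acid chirality (verified against standard peptide geometry).
CB_INTERNAL = (1.53, 110.5, 122.5)


def build_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    bond, angle, torsion = CB_INTERNAL
    return place_atom(c, n, ca, bond, angle, torsion)


def build_sidechain(resname: str, n: np.ndarray, ca: np.ndarray,
                    c: np.ndarray) -> list[tuple[str, np.ndarray]]:
    """Heavy side-chain atoms (CB onward) for the template rotamer.

    Returns an ordered list of (atom_name, coordinate); empty for GLY.
    """
    resname = resname.upper()
    if resname not in SIDECHAIN_TOPOLOGY:
        raise KeyError(f"no side-chain template for residue {resname!r}")
    if resname == "GLY":
        return []
    placed: dict[str, np.ndarray] = {"N": np.asarray(n, float),
                                     "CA": np.asarray(ca, float),
                                     "C": np.asarray(c, float)}
    placed["CB"] = build_cb(placed["N"], placed["CA"], placed["C"])
    out = [("CB", placed["CB"])]
    for name, r1, r2, r3, bond, angle, torsion in SIDECHAIN_TOPOLOGY[resname]:
        coord = place_atom(placed[r3], placed[r2], placed[r1], bond, angle, torsion)
        placed[name] = coord
        out.append((name, coord))
    return out
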