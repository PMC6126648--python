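"""Standard protein geometry: ideal values, internal-coordinate atom placement.

Target bond lengths and angles follow the conventional restraint dictionaries
used in macromolecular refinement (Engh & Huber style values). Side-chain
internal coordinates are a compact canonical-rotamer topology used by the
synthetic-structure builder; ring closure for Pro/His/Phe/Tyr/Trp is
approximate (good enough for clash and density work, not a rotamer library).
"""

from __future__ import annotations

import math

import numpy as np

# Backbone bond targets (value Angstrom, sigma)
BOND_N_CA = (1.458, 0.019)
BOND_CA_C = (1.525, 0.021)
BOND_C_O = (1.231, 0.020)
BOND_C_N = (1.329, 0.014)  # peptide bond
BOND_CA_CB = (1.530, 0.020)

# Backbone angle targets (value degrees, sigma)
ANGLE_N_CA_C = (111.0, 2.7)
ANGLE_CA_C_O = (120.8, 1.7)
ANGLE_CA_C_N = (116.2, 2.0)
ANGLE_O_C_N = (123.0, 1.6)
ANGLE_C_N_CA = (121.7, 1.8)
ANGLE_N_CA_CB = (110.4, 1.5)
ANGLE_C_CA_CB = (110.5, 1.5)

OMEGA_SIGMA_DEG = 6.0
PLANE_SIGMA = 0.02  # Angstrom, out-of-plane deviation
CHIRAL_SIGMA = 0.20  # Angstrom^3

PEPTIDE_BOND_RANGE = (1.2, 1.5)  # C-N distance treated as a bond

ELEMENT_ELECTRONS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "S": 16, "SE": 34, "P": 15,
}


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D given chain A-B-C: |CD| = bond, angle(BCD), torsion(ABCD)."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        # collinear support: pick any perpendicular
        n = np.cross(bc, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(n) < 1e-9:
            n = np.cross(bc, np.array([0.0, 1.0, 0.0]))
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        -bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle in degrees, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return math.degrees(math.atan2(y, x))


def angle_deg(p0, p1, p2) -> float:
    v1 = p0 - p1
    v2 = p2 - p1
    c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def chiral_volume(center, p1, p2, p3) -> float:
    """Signed volume det[p1-c, p2-c, p3-c]; L-CA (N, C, CB) is positive."""
    return float(np.linalg.det(np.stack([p1 - center, p2 - center, p3 - center])))


# Improper torsion dihedral(C, N, CA, CB) for an L-amino acid (degrees)
CB_IMPROPER = 122.6


def _ideal_ca_chiral_target() -> float:
    ca = np.zeros(3)
    n = np.array([BOND_N_CA[0], 0.0, 0.0])
    th = math.radians(ANGLE_N_CA_C[0])
    c = BOND_CA_C[0] * np.array([math.cos(th), math.sin(th), 0.0])
    # CB below the N-CA-C plane for an L-amino acid
    cb = place_atom(c, n, ca, BOND_CA_CB[0], ANGLE_N_CA_CB[0], CB_IMPROPER)
    return chiral_volume(ca, n, c, cb)


CHIRAL_CA_TARGET = _ideal_ca_chiral_target()



MAIN_CHAIN_ATOMS = ("N", "CA", "C", "O")
# CB counts as main chain for clash adjudication
CLASH_MAIN_ATOMS = ("N", "CA", "C", "O", "CB", "OXT")

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "MSE": "M", "PHE": "F",
    "PRO": "P", "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y",
    "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items() if k != "MSE"}

# Side-chain topology: resname -> list of
# (atom, element, (ref_a, ref_b, ref_c), bond, angle, torsion)
# torsion strings "chi1".. resolve to the canonical value below; numeric offsets
# are written as e.g. ("chi1", 120.0).
_CHI = {"chi1": -65.0, "chi2": 180.0, "chi3": 180.0, "chi4": 180.0}


def _t(name, off=0.0):
    return _CHI[name] + off


SIDE_CHAIN_TOPOLOGY: dict[str, list[tuple]] = {
    "ALA": [],
    "GLY": [],
    "SER": [("OG", "O", ("N", "CA", "CB"), 1.417, 110.8, _t("chi1"))],
    "CYS": [("SG", "S", ("N", "CA", "CB"), 1.808, 114.4, _t("chi1"))],
    "THR": [("OG1", "O", ("N", "CA", "CB"), 1.433, 109.6, _t("chi1")),
            ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, _t("chi1", -120))],
    "VAL": [("CG1", "C", ("N", "CA", "CB"), 1.527, 110.5, _t("chi1", -110)),
            ("CG2", "C", ("N", "CA", "CB"), 1.527, 110.5, _t("chi1", 10))],
    "LEU": [("CG", "C", ("N", "CA", "CB"), 1.530, 116.3, _t("chi1")),
            ("CD1", "C", ("CA", "CB", "CG"), 1.521, 110.7, _t("chi2")),
            ("CD2", "C", ("CA", "CB", "CG"), 1.521, 110.7, _t("chi2", -120))],
    "ILE": [("CG1", "C", ("N", "CA", "CB"), 1.530, 110.4, _t("chi1")),
            ("CG2", "C", ("N", "CA", "CB"), 1.521, 110.5, _t("chi1", 120)),
            ("CD1", "C", ("CA", "CB", "CG1"), 1.513, 113.8, 170.0)],
    "MET": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, _t("chi1")),
            ("SD", "S", ("CA", "CB", "CG"), 1.803, 112.7, _t("chi2")),
            ("CE", "C", ("CB", "CG", "SD"), 1.791, 100.9, _t("chi3"))],
    "MSE": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, _t("chi1")),
            ("SE", "SE", ("CA", "CB", "CG"), 1.950, 112.7, _t("chi2")),
            ("CE", "C", ("CB", "CG", "SE"), 1.950, 100.9, _t("chi3"))],
    "PRO": [("CG", "C", ("N", "CA", "CB"), 1.492, 104.5, 30.0),
            ("CD", "C", ("CA", "CB", "CG"), 1.503, 106.1, -35.0)],
    "PHE": [("CG", "C", ("N", "CA", "CB"), 1.502, 113.8, _t("chi1")),
            ("CD1", "C", ("CA", "CB", "CG"), 1.384, 120.8, 90.0),
            ("CD2", "C", ("CA", "CB", "CG"), 1.384, 120.8, -90.0),
            ("CE1", "C", ("CB", "CG", "CD1"), 1.382, 120.8, 180.0),
            ("CE2", "C", ("CB", "CG", "CD2"), 1.382, 120.8, 180.0),
            ("CZ", "C", ("CG", "CD1", "CE1"), 1.382, 120.0, 0.0)],
    "TYR": [("CG", "C", ("N", "CA", "CB"), 1.502, 113.8, _t("chi1")),
            ("CD1", "C", ("CA", "CB", "CG"), 1.384, 120.8, 90.0),
            ("CD2", "C", ("CA", "CB", "CG"), 1.384, 120.8, -90.0),
            ("CE1", "C", ("CB", "CG", "CD1"), 1.382, 121.2, 180.0),
            ("CE2", "C", ("CB", "CG", "CD2"), 1.382, 121.2, 180.0),
            ("CZ", "C", ("CG", "CD1", "CE1"), 1.378, 119.6, 0.0),
            ("OH", "O", ("CD1", "CE1", "CZ"), 1.376, 119.9, 180.0)],
    "TRP": [("CG", "C", ("N", "CA", "CB"), 1.498, 113.6, _t("chi1")),
            ("CD1", "C", ("CA", "CB", "CG"), 1.365, 126.9, 90.0),
            ("CD2", "C", ("CA", "CB", "CG"), 1.433, 126.7, -90.0),
            ("NE1", "N", ("CB", "CG", "CD1"), 1.374, 110.2, 180.0),
            ("CE2", "C", ("CG", "CD1", "NE1"), 1.370, 108.9, 0.0),
            ("CE3", "C", ("CB", "CG", "CD2"), 1.398, 133.9, 0.0),
            ("CZ2", "C", ("CD1", "NE1", "CE2"), 1.394, 130.1, 180.0),
            ("CZ3", "C", ("CG", "CD2", "CE3"), 1.382, 118.8, 180.0),
            ("CH2", "C", ("CD2", "CE3", "CZ3"), 1.368, 121.2, 0.0)],
    "ASP": [("CG", "C", ("N", "CA", "CB"), 1.516, 113.0, _t("chi1")),
            ("OD1", "O", ("CA", "CB", "CG"), 1.249, 118.4, -15.0),
            ("OD2", "O", ("CA", "CB", "CG"), 1.249, 118.4, 165.0)],
    "ASN": [("CG", "C", ("N", "CA", "CB"), 1.516, 112.7, _t("chi1")),
            ("OD1", "O", ("CA", "CB", "CG"), 1.231, 120.8, -25.0),
            ("ND2", "N", ("CA", "CB", "CG"), 1.328, 116.4, 155.0)],
    "GLU": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, _t("chi1")),
            ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, _t("chi2")),
            ("OE1", "O", ("CB", "CG", "CD"), 1.249, 118.4, -10.0),
            ("OE2", "O", ("CB", "CG", "CD"), 1.249, 118.4, 170.0)],
    "GLN": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, _t("chi1")),
            ("CD", "C", ("CA", "CB", "CG"), 1.516, 112.6, _t("chi2")),
            ("OE1", "O", ("CB", "CG", "CD"), 1.231, 120.8, -10.0),
            ("NE2", "N", ("CB", "CG", "CD"), 1.328, 116.4, 170.0)],
    "LYS": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, _t("chi1")),
            ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, _t("chi2")),
            ("CE", "C", ("CB", "CG", "CD"), 1.508, 111.3, _t("chi3")),
            ("NZ", "N", ("CG", "CD", "CE"), 1.489, 111.9, _t("chi4"))],
    "ARG": [("CG", "C", ("N", "CA", "CB"), 1.520, 114.1, _t("chi1")),
            ("CD", "C", ("CA", "CB", "CG"), 1.520, 111.3, _t("chi2")),
            ("NE", "N", ("CB", "CG", "CD"), 1.461, 112.0, _t("chi3")),
            ("CZ", "C", ("CG", "CD", "NE"), 1.329, 124.2, 90.0),
            ("NH1", "N", ("CD", "NE", "CZ"), 1.326, 120.0, 0.0),
            ("NH2", "N", ("CD", "NE", "CZ"), 1.326, 120.0, 180.0)],
    "HIS": [("CG", "C", ("N", "CA", "CB"), 1.497, 113.8, _t("chi1")),
            ("ND1", "N", ("CA", "CB", "CG"), 1.371, 122.7, -75.0),
            ("CD2", "C", ("CA", "CB", "CG"), 1.356, 131.1, 105.0),
            ("CE1", "C", ("CB", "CG", "ND1"), 1.319, 109.0, 180.0),
            ("NE2", "N", ("CB", "CG", "CD2"), 1.374, 107.2, 180.0)],
}

# Chemically equivalent side-chain atom pairs swappable before superposition
# (administrative flips for Asp/Glu/Phe/Tyr)
DEFY_SWAPS = {
    "ASP": [("OD1", "OD2")],
    "GLU": [("OE1", "OE2")],
    "PHE": [("CD1", "CD2"), ("CE1", "CE2")],
    "TYR": [("CD1", "CD2"), ("CE1", "CE2")],
}
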