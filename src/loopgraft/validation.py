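"""Geometry filters and the Ramachandran Z score.

The Ramachandran score standardizes the mean log-odds of a fragment's
phi/psi angles against reference torsion distributions, one per residue
class (Gly, Pro, pre-Pro, Ile/Val, general).  The reference densities are a
smooth parametric mixture of wrapped Gaussians over the canonical basins,
discretized once on a fixed 4-degree grid at import time so scoring is
bit-for-bit reproducible.  Fragment Z combines per-residue standardized
scores: Z = sum(s_i - mu_class) / sqrt(sum(sigma_class^2)), which is the
standard-error normalization (a fragment drawn from the reference scores
~N(0, 1) regardless of length).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import geom
from .geom import (ANGLE_C_N_CA, ANGLE_CA_C_N, ANGLE_CA_C_O, ANGLE_N_CA_C,
                   ANGLE_O_C_N, BOND_C_N, BOND_C_O, BOND_CA_C, BOND_N_CA,
                   CHIRAL_CA_TARGET, CHIRAL_SIGMA, OMEGA_SIGMA_DEG,
                   PEPTIDE_BOND_RANGE, PLANE_SIGMA, angle_deg, chiral_volume,
                   dihedral)

# Filter thresholds (loops are rejected past these)
RMSZ_BOND_MAX = 1.2
RMSZ_ANGLE_MAX = 1.2
RMSZ_CHIR_MAX = 1.5
RMSZ_PLANE_MAX = 2.0
RMSZ_TORSION_MAX = 2.0
OMEGA_DEV_MAX = 30.0          # degrees from 0/180
RAMA_Z_POOR = -5.0
GRUBBS_SIGMA = 2.0


@dataclass
class GeometryScores:
    rmsz_bond: float
    rmsz_angle: float
    rmsz_chir: float
    rmsz_plane: float
    rmsz_torsion: float
    omega_devs: list[float] = field(default_factory=list)
    cis_flags: list[bool] = field(default_factory=list)
    cn_distances: list[float] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("rmsz_bond", "rmsz_angle", "rmsz_chir",
                 "rmsz_plane", "rmsz_torsion")}


def _rms(vals: list[float]) -> float:
    return float(np.sqrt(np.mean(np.square(vals)))) if vals else 0.0


def _plane_deviation_zs(points: np.ndarray) -> list[float]:
    centered = points - points.mean(0)
    _, _, vt = np.linalg.svd(centered)
    normal = vt[-1]
    return [float(abs(np.dot(p, normal)) / PLANE_SIGMA) for p in centered]


def geometry_scores(residues) -> GeometryScores:
    """Restraint RMSZ values over a contiguous backbone fragment.

    Bonds: N-CA, CA-C, C-O per residue plus the inter-residue C-N peptide
    bond; angles: the five backbone angles; chirality: the CA centre;
    planes: least-squares peptide-plane deviations; torsion: omega against
    the nearer of 0/180 degrees.
    """
    missing = []
    for r in residues:
        for name in ("N", "CA", "C", "O"):
            if r.atom(name) is None:
                missing.append(f"{r.type}{r.number}:{name}")
    if missing:
        raise ValueError("incomplete backbone: " + ", ".join(missing))
    zb, za, zc, zp, zt = [], [], [], [], []
    omega_devs, cis_flags, cn = [], [], []
    for r in residues:
        n, ca, c, o = (r.atom(x).pos for x in ("N", "CA", "C", "O"))
        zb.append((np.linalg.norm(ca - n) - BOND_N_CA[0]) / BOND_N_CA[1])
        zb.append((np.linalg.norm(c - ca) - BOND_CA_C[0]) / BOND_CA_C[1])
        zb.append((np.linalg.norm(o - c) - BOND_C_O[0]) / BOND_C_O[1])
        za.append((angle_deg(n, ca, c) - ANGLE_N_CA_C[0]) / ANGLE_N_CA_C[1])
        za.append((angle_deg(ca, c, o) - ANGLE_CA_C_O[0]) / ANGLE_CA_C_O[1])
        cb = r.atom("CB")
        if cb is not None:
            v = chiral_volume(ca, n, c, cb.pos)
            zc.append((v - CHIRAL_CA_TARGET) / CHIRAL_SIGMA)
    for r0, r1 in zip(residues, residues[1:]):
        ca0, c0, o0 = (r0.atom(x).pos for x in ("CA", "C", "O"))
        n1, ca1 = (r1.atom(x).pos for x in ("N", "CA"))
        d = float(np.linalg.norm(n1 - c0))
        cn.append(d)
        zb.append((d - BOND_C_N[0]) / BOND_C_N[1])
        za.append((angle_deg(ca0, c0, n1) - ANGLE_CA_C_N[0]) / ANGLE_CA_C_N[1])
        za.append((angle_deg(o0, c0, n1) - ANGLE_O_C_N[0]) / ANGLE_O_C_N[1])
        za.append((angle_deg(c0, n1, ca1) - ANGLE_C_N_CA[0]) / ANGLE_C_N_CA[1])
        om = dihedral(ca0, c0, n1, ca1)
        dev = min(abs(om), abs(180.0 - abs(om)))
        omega_devs.append(dev)
        cis_flags.append(abs(om) < 90.0)
        target = 0.0 if abs(om) < 90.0 else 180.0
        zdev = om - math.copysign(target, om) if target else om
        zt.append(zdev / OMEGA_SIGMA_DEG)
        zp.extend(_plane_deviation_zs(np.array([ca0, c0, o0, n1, ca1])))
    return GeometryScores(_rms(zb), _rms(za), _rms(zc), _rms(zp), _rms(zt),
                          omega_devs, cis_flags, cn)


def geometry_filter(scores: GeometryScores, converged: bool = True,
                    source_cis_flags: list[bool] | None = None
                    ) -> tuple[bool, str]:
    """Accept/reject a refined candidate on geometric criteria.

    Rejects: non-converged refinement; a broken peptide bond between
    consecutive residues; RMSZ past the bond/angle 1.2, chirality 1.5 or
    plane/torsion 2.0 limits; two or more sequential omega distortions
    (> 30 degrees from 0/180 — one is tolerated); any cis-peptide whose
    source homolog peptide is not also cis.
    """
    if not converged:
        return False, "not-converged"
    lo, hi = PEPTIDE_BOND_RANGE
    if any(not (lo <= d <= hi) for d in scores.cn_distances):
        return False, "broken-peptide-bond"
    if scores.rmsz_bond > RMSZ_BOND_MAX or scores.rmsz_angle > RMSZ_ANGLE_MAX:
        return False, "bad-bond-angle-rmsz"
    if scores.rmsz_chir > RMSZ_CHIR_MAX:
        return False, "bad-chirality-rmsz"
    if scores.rmsz_plane > RMSZ_PLANE_MAX or scores.rmsz_torsion > RMSZ_TORSION_MAX:
        return False, "bad-plane-torsion-rmsz"
    distorted = [d > OMEGA_DEV_MAX for d in scores.omega_devs]
    if any(a and b for a, b in zip(distorted, distorted[1:])):
        return False, "sequential-omega-distortions"
    if source_cis_flags is not None:
        for i, cis in enumerate(scores.cis_flags):
            src = source_cis_flags[i] if i < len(source_cis_flags) else False
            if cis and not src:
                return False, "cis-peptide-not-in-source"
    return True, ""


# ---------------------------------------------------------------------------
# Ramachandran reference distributions

RAMA_BIN_DEG = 4.0
_N_BINS = int(360 / RAMA_BIN_DEG)

# wrapped-Gaussian mixture components per residue class:
# (phi0, psi0, sigma_phi, sigma_psi, weight)
_RAMA_COMPONENTS: dict[str, list[tuple]] = {
    "general": [(-63, -43, 11, 11, 0.42), (-120, 130, 22, 25, 0.28),
                (-65, 147, 13, 13, 0.22), (57, 42, 11, 11, 0.08)],
    "gly": [(-63, -41, 13, 13, 0.25), (63, 41, 13, 13, 0.25),
            (-85, 170, 20, 20, 0.20), (85, -170, 20, 20, 0.20),
            (-175, 175, 25, 25, 0.10)],
    "pro": [(-63, -35, 10, 10, 0.45), (-65, 145, 10, 12, 0.55)],
    "prepro": [(-63, -43, 11, 11, 0.30), (-120, 125, 20, 22, 0.45),
               (-65, 147, 13, 13, 0.25)],
    "ileval": [(-63, -45, 10, 10, 0.35), (-115, 125, 18, 20, 0.45),
               (-65, 147, 12, 12, 0.20)],
}
#: mixing fraction of the uniform floor (keeps log-odds finite everywhere)
_UNIFORM_FLOOR = 0.005


def _wrap_diff(a: np.ndarray, b: float) -> np.ndarray:
    return (a - b + 180.0) % 360.0 - 180.0


def _build_tables():
    centers = -180.0 + RAMA_BIN_DEG * (np.arange(_N_BINS) + 0.5)
    phi, psi = np.meshgrid(centers, centers, indexing="ij")
    tables = {}
    for cls, comps in _RAMA_COMPONENTS.items():
        dens = np.zeros_like(phi)
        for p0, s0, sp, ss, w in comps:
            d = np.exp(-_wrap_diff(phi, p0) ** 2 / (2 * sp ** 2)
                       - _wrap_diff(psi, s0) ** 2 / (2 * ss ** 2))
            dens += w * d / d.sum()
        dens /= dens.sum()
        uniform = 1.0 / dens.size
        dens = (1 - _UNIFORM_FLOOR) * dens + _UNIFORM_FLOOR * uniform
        logodds = np.log(dens / uniform)
        mu = float(np.sum(dens * logodds))
        sd = float(np.sqrt(np.sum(dens * (logodds - mu) ** 2)))
        tables[cls] = {"prob": dens, "logodds": logodds, "mu": mu, "sd": sd}
    return tables


RAMA_TABLES = _build_tables()


def residue_class(restype: str, next_type: str | None) -> str:
    if restype == "PRO":
        return "pro"
    if next_type == "PRO":
        return "prepro"
    if restype == "GLY":
        return "gly"
    if restype in ("ILE", "VAL"):
        return "ileval"
    return "general"


def _bin_index(angle: float) -> int:
    i = int((angle + 180.0) // RAMA_BIN_DEG)
    return min(max(i, 0), _N_BINS - 1)


def rama_logodds(phi: float, psi: float, cls: str) -> float:
    t = RAMA_TABLES[cls]
    return float(t["logodds"][_bin_index(phi), _bin_index(psi)])


@dataclass
class RamaScore:
    per_residue: list[tuple[int, str, float, float, float]]  # (num, cls, phi, psi, logodds)
    z: float


def backbone_dihedrals(residues) -> list[tuple[float | None, float | None]]:
    """(phi, psi) per residue; None where a neighbor is absent/unbonded."""
    out = []
    for i, r in enumerate(residues):
        phi = psi = None
        n, ca, c = (r.atom(x) for x in ("N", "CA", "C"))
        if None in (n, ca, c):
            out.append((None, None))
            continue
        if i > 0:
            cp = residues[i - 1].atom("C")
            if cp is not None and np.linalg.norm(n.pos - cp.pos) < 2.5:
                phi = dihedral(cp.pos, n.pos, ca.pos, c.pos)
        if i + 1 < len(residues):
            nn = residues[i + 1].atom("N")
            if nn is not None and np.linalg.norm(nn.pos - c.pos) < 2.5:
                psi = dihedral(n.pos, ca.pos, c.pos, nn.pos)
        out.append((phi, psi))
    return out


def rama_z(residues) -> RamaScore:
    """Ramachandran Z of a contiguous fragment (or whole chain)."""
    dihedrals = backbone_dihedrals(residues)
    per = []
    num = 0.0
    var = 0.0
    for i, (r, (phi, psi)) in enumerate(zip(residues, dihedrals)):
        if phi is None or psi is None:
            continue
        nxt = residues[i + 1].type if i + 1 < len(residues) else None
        cls = residue_class(r.type, nxt)
        s = rama_logodds(phi, psi, cls)
        t = RAMA_TABLES[cls]
        num += s - t["mu"]
        var += t["sd"] ** 2
        per.append((r.number, cls, phi, psi, s))
    if not per:
        raise ValueError("no residue with defined phi/psi")
    return RamaScore(per, num / math.sqrt(var))


def rama_z_from_dihedrals(pairs: list[tuple[float, float]],
                          cls: str = "general") -> float:
    """Z for raw (phi, psi) pairs of a single residue class."""
    t = RAMA_TABLES[cls]
    s = [rama_logodds(phi, psi, cls) for phi, psi in pairs]
    return float((np.sum(np.asarray(s) - t["mu"])) /
                 math.sqrt(len(s) * t["sd"] ** 2))


def sample_reference_dihedrals(cls: str, n: int,
                               rng: np.random.Generator
                               ) -> list[tuple[float, float]]:
    """Draw (phi, psi) pairs from a class reference distribution."""
    t = RAMA_TABLES[cls]
    flat = t["prob"].ravel()
    idx = rng.choice(flat.size, size=n, p=flat / flat.sum())
    ii, jj = np.unravel_index(idx, t["prob"].shape)
    phi = -180.0 + RAMA_BIN_DEG * (ii + 0.5)
    psi = -180.0 + RAMA_BIN_DEG * (jj + 0.5)
    return list(zip(phi.tolist(), psi.tolist()))


def rama_outlier_filter(candidate_z: float, peer_zs: list[float],
                        source_zs: list[float]) -> tuple[bool, str]:
    """Grubbs-style 2-sigma negative-outlier comparison.

    Only candidates with poor Z (< -5) are examined; such a candidate is
    rejected when it lies more than two standard deviations below the mean
    of either the peer-candidate Z population or the source-loop Z
    population.  Populations smaller than 3 carry insufficient evidence and
    are skipped.
    """
    if not (candidate_z < RAMA_Z_POOR):
        return True, ""
    for name, pop in (("peers", peer_zs), ("sources", source_zs)):
        vals = [z for z in pop if np.isfinite(z)]
        if len(vals) < 3:
            continue
        mean = float(np.mean(vals))
        sd = float(np.std(vals))
        if sd <= 0:
            continue
        if (mean - candidate_z) / sd > GRUBBS_SIGMA:
            return False, f"rama-z-outlier-vs-{name}"
    return True, ""
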