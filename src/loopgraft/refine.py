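"""Simplified restrained real-space regularization of a grafted region.

Minimizes  E = w_geom * (bonds + angles + torsion tethers + omega +
chirality + Ramachandran) - w_map * sum of interpolated density at atom
centers, over the Cartesian coordinates of the region atoms, with an
L-BFGS-B quasi-Newton optimizer and analytic gradients throughout.
Planarity of the peptide unit is maintained by the omega tether together
with the three angle restraints around the carbonyl carbon; the validation
module still measures true least-squares plane deviations on the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import validation
from .geom import (ANGLE_C_N_CA, ANGLE_CA_C_N, ANGLE_CA_C_O, ANGLE_C_CA_CB,
                   ANGLE_N_CA_C, ANGLE_N_CA_CB, ANGLE_O_C_N, BOND_C_N,
                   BOND_C_O, BOND_CA_C, BOND_CA_CB, BOND_N_CA,
                   CHIRAL_CA_TARGET, CHIRAL_SIGMA, OMEGA_SIGMA_DEG,
                   SIDE_CHAIN_TOPOLOGY, dihedral)
from .density import MapGrid, interpolate_cubic
from .validation import RAMA_BIN_DEG, RAMA_TABLES, _N_BINS, residue_class

DEFAULT_W_GEOM = 1.0
DEFAULT_W_MAP = 3.0
DEFAULT_W_RAMA = 0.2
DEFAULT_TORSION_SIGMA = 8.0    # degrees, tether to start conformation
CONVERGENCE_TOL = 1e-3
MAX_ITER = 1500
GAP_CLOSE_TRIGGER = 1.6        # junction C-N beyond this gets the N moved
GAP_CLOSE_TARGET = 1.40


class NumericalRefinementError(RuntimeError):
    pass


@dataclass
class RefineRegion:
    """Contiguous mobile residues, plus optional frozen context residues.

    The frozen residues participate in bond/angle/torsion restraints (so
    the region stays covalently tethered to the rest of the model) but
    their coordinates are pinned during minimization."""
    residues: list                      # contiguous; all atoms mobile
    grid: MapGrid | None = None
    fixed_before: object = None         # Residue or None
    fixed_after: object = None


@dataclass
class RefineResult:
    converged: bool
    n_iter: int
    final_energy: float
    scores: validation.GeometryScores | None = None


# ---------------------------------------------------------------------------
# junction closing


def close_gap_pregame(prev_residue, first_loop_residue) -> bool:
    """Move the loop-edge backbone N into the junction gap when the C-N
    distance is too long for the minimizer to find the bond on its own.
    Returns True when a move was made."""
    c = prev_residue.atom("C")
    n = first_loop_residue.atom("N")
    if c is None or n is None:
        return False
    v = n.pos - c.pos
    d = float(np.linalg.norm(v))
    if d <= GAP_CLOSE_TRIGGER:
        return False
    n.pos = c.pos + v * (GAP_CLOSE_TARGET / d)
    return True


# ---------------------------------------------------------------------------
# restraint construction

_BACKBONE_BONDS = [("N", "CA", BOND_N_CA), ("CA", "C", BOND_CA_C),
                   ("C", "O", BOND_C_O), ("CA", "CB", BOND_CA_CB)]
_SIDE_BOND_SIGMA = 0.02
_SIDE_ANGLE_SIGMA = 2.5


@dataclass
class _Restraints:
    bonds: list = field(default_factory=list)      # (i, j, d0, sigma)
    angles: list = field(default_factory=list)     # (i, j, k, th0_deg, sigma)
    torsions: list = field(default_factory=list)   # (i, j, k, l, tau0, sigma)
    chirals: list = field(default_factory=list)    # (c, i, j, k, v0, sigma)
    ramas: list = field(default_factory=list)      # (cm1, n, ca, c, nn, cls)


def _build_restraints(residues, atom_index) -> _Restraints:
    rs = _Restraints()

    def idx(ri, name):
        return atom_index.get((ri, name))

    for ri, res in enumerate(residues):
        for a1, a2, (d0, sg) in _BACKBONE_BONDS:
            i, j = idx(ri, a1), idx(ri, a2)
            if i is not None and j is not None:
                rs.bonds.append((i, j, d0, sg))
        for tup in SIDE_CHAIN_TOPOLOGY.get(res.type, []):
            name, _el, (ra, rb, rc), bond, ang, _tor = tup
            i, j, k, l = (idx(ri, x) for x in (name, rc, rb, ra))
            if i is not None and j is not None:
                rs.bonds.append((i, j, bond, _SIDE_BOND_SIGMA))
                if k is not None:
                    rs.angles.append((k, j, i, ang, _SIDE_ANGLE_SIGMA))
                    if l is not None:
                        tau0 = None  # tethered below from start conformation
                        rs.torsions.append((l, k, j, i, tau0, DEFAULT_TORSION_SIGMA))
        for a1, a2, a3, (t0, sg) in [
                ("N", "CA", "C", ANGLE_N_CA_C), ("CA", "C", "O", ANGLE_CA_C_O),
                ("N", "CA", "CB", ANGLE_N_CA_CB),
                ("C", "CA", "CB", ANGLE_C_CA_CB)]:
            i, j, k = idx(ri, a1), idx(ri, a2), idx(ri, a3)
            if None not in (i, j, k):
                rs.angles.append((i, j, k, t0, sg))
        ii = [idx(ri, x) for x in ("CA", "N", "C", "CB")]
        if None not in ii:
            rs.chirals.append((*ii, CHIRAL_CA_TARGET, CHIRAL_SIGMA))
    for ri in range(len(residues) - 1):
        pairs = [("C", ri, "N", ri + 1, BOND_C_N)]
        for a1, r1, a2, r2, (d0, sg) in pairs:
            i, j = idx(r1, a1), idx(r2, a2)
            if i is not None and j is not None:
                rs.bonds.append((i, j, d0, sg))
        for (a1, r1), (a2, r2), (a3, r3), (t0, sg) in [
                (("CA", ri), ("C", ri), ("N", ri + 1), ANGLE_CA_C_N),
                (("O", ri), ("C", ri), ("N", ri + 1), ANGLE_O_C_N),
                (("C", ri), ("N", ri + 1), ("CA", ri + 1), ANGLE_C_N_CA)]:
            i, j, k = idx(r1, a1), idx(r2, a2), idx(r3, a3)
            if None not in (i, j, k):
                rs.angles.append((i, j, k, t0, sg))
        # omega: restrained to the nearer of 0/180 (cis kept cis)
        ii = [idx(ri, "CA"), idx(ri, "C"), idx(ri + 1, "N"), idx(ri + 1, "CA")]
        if None not in ii:
            rs.torsions.append((*ii, "omega", OMEGA_SIGMA_DEG))
        # carbonyl-O improper: O stays in the CA-C-N(i+1) plane
        ii = [idx(ri, "O"), idx(ri, "CA"), idx(ri, "C"), idx(ri + 1, "N")]
        if None not in ii:
            rs.torsions.append((*ii, 180.0, 3.0))
        # phi/psi tethers to the start conformation
        ii = [idx(ri, "C"), idx(ri + 1, "N"), idx(ri + 1, "CA"), idx(ri + 1, "C")]
        if None not in ii:
            rs.torsions.append((*ii, None, DEFAULT_TORSION_SIGMA))
        ii = [idx(ri, "N"), idx(ri, "CA"), idx(ri, "C"), idx(ri + 1, "N")]
        if None not in ii:
            rs.torsions.append((*ii, None, DEFAULT_TORSION_SIGMA))
    # Ramachandran: interior residues with full phi/psi support
    for ri in range(1, len(residues) - 1):
        ii = [atom_index.get((ri - 1, "C")), atom_index.get((ri, "N")),
              atom_index.get((ri, "CA")), atom_index.get((ri, "C")),
              atom_index.get((ri + 1, "N"))]
        if None not in ii:
            cls = residue_class(residues[ri].type, residues[ri + 1].type)
            rs.ramas.append((*ii, cls))
    return rs


# ---------------------------------------------------------------------------
# energy terms with analytic gradients (batched over restraints)


def _dihedral_and_grad(x, i, j, k, l):
    """Scalar dihedral (degrees) + per-atom gradients; None if degenerate."""
    b1 = x[j] - x[i]
    b2 = x[k] - x[j]
    b3 = x[l] - x[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    lb2 = np.linalg.norm(b2)
    n1sq = float(np.dot(n1, n1))
    n2sq = float(np.dot(n2, n2))
    if n1sq < 1e-12 or n2sq < 1e-12 or lb2 < 1e-9:
        return None
    m1 = np.cross(n1, b2 / lb2)
    phi = math.degrees(math.atan2(float(np.dot(m1, n2)), float(np.dot(n1, n2))))
    gi = lb2 / n1sq * n1
    gl = -lb2 / n2sq * n2
    c1 = float(np.dot(b1, b2)) / (lb2 * lb2)
    c2 = float(np.dot(b3, b2)) / (lb2 * lb2)
    gj = -gi - c1 * gi + c2 * gl
    gk = -gl - c2 * gl + c1 * gi
    return phi, (np.degrees(gi), np.degrees(gj), np.degrees(gk), np.degrees(gl))


def _wrap180(a):
    return (a + 180.0) % 360.0 - 180.0


class _BatchRestraints:
    """Index/target arrays for vectorized energy evaluation."""

    def __init__(self, rs: _Restraints, x0: np.ndarray):
        self.b_ij = np.array([(r[0], r[1]) for r in rs.bonds], dtype=int) \
            if rs.bonds else np.zeros((0, 2), dtype=int)
        self.b_d0 = np.array([r[2] for r in rs.bonds])
        self.b_sg = np.array([r[3] for r in rs.bonds])
        self.a_ijk = np.array([(i, j, k) for i, j, k, _, _ in rs.angles],
                              dtype=int) if rs.angles else np.zeros((0, 3), int)
        self.a_t0 = np.array([r[3] for r in rs.angles])
        self.a_sg = np.array([r[4] for r in rs.angles])
        self.t_ijkl = np.array([(i, j, k, l) for i, j, k, l, _, _ in
                                rs.torsions], dtype=int) \
            if rs.torsions else np.zeros((0, 4), int)
        self.t_sg = np.array([r[5] for r in rs.torsions])
        # tether targets resolved from the start conformation
        targets = []
        for (i, j, k, l, tau0, sg) in rs.torsions:
            res = _dihedral_and_grad(x0, i, j, k, l)
            start = res[0] if res is not None else 0.0
            if tau0 == "omega":
                targets.append(0.0 if abs(start) < 90.0 else 180.0)
            elif tau0 is None:
                targets.append(start)
            else:
                targets.append(float(tau0))
        self.t_t0 = np.array(targets)
        self.c_idx = np.array([(c, i, j, k) for c, i, j, k, _, _ in
                               rs.chirals], dtype=int) \
            if rs.chirals else np.zeros((0, 4), int)
        self.c_v0 = np.array([r[4] for r in rs.chirals])
        self.c_sg = np.array([r[5] for r in rs.chirals])
        self.ramas = rs.ramas


def _batch_dihedrals(x, idx4):
    """Vectorized dihedrals (deg) + gradients for an (n, 4) index array."""
    p1, p2, p3, p4 = (x[idx4[:, c]] for c in range(4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    lb2 = np.linalg.norm(b2, axis=1)
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    ok = (n1sq > 1e-12) & (n2sq > 1e-12) & (lb2 > 1e-9)
    n1sq = np.where(ok, n1sq, 1.0)
    n2sq = np.where(ok, n2sq, 1.0)
    lb2s = np.where(ok, lb2, 1.0)
    m1 = np.cross(n1, b2 / lb2s[:, None])
    y = np.einsum("ij,ij->i", m1, n2)
    xx = np.einsum("ij,ij->i", n1, n2)
    phi = np.degrees(np.arctan2(y, xx))
    gi = (lb2s / n1sq)[:, None] * n1
    gl = -(lb2s / n2sq)[:, None] * n2
    c1 = np.einsum("ij,ij->i", b1, b2) / lb2s ** 2
    c2 = np.einsum("ij,ij->i", b3, b2) / lb2s ** 2
    gj = -gi - c1[:, None] * gi + c2[:, None] * gl
    gk = -gl - c2[:, None] * gl + c1[:, None] * gi
    deg = 180.0 / np.pi
    return phi, (gi * deg, gj * deg, gk * deg, gl * deg), ok


def _accumulate(grad, idx, contrib):
    np.add.at(grad, idx, contrib)


def _energy_and_grad(x, br: _BatchRestraints, w_rama: float,
                     grad: np.ndarray) -> float:
    e = 0.0
    if len(br.b_ij):
        v = x[br.b_ij[:, 0]] - x[br.b_ij[:, 1]]
        d = np.linalg.norm(v, axis=1)
        z = (d - br.b_d0) / br.b_sg
        e += float(np.sum(z * z))
        pref = (2 * z / (br.b_sg * np.maximum(d, 1e-12)))[:, None] * v
        _accumulate(grad, br.b_ij[:, 0], pref)
        _accumulate(grad, br.b_ij[:, 1], -pref)
    if len(br.a_ijk):
        u = x[br.a_ijk[:, 0]] - x[br.a_ijk[:, 1]]
        v = x[br.a_ijk[:, 2]] - x[br.a_ijk[:, 1]]
        lu = np.maximum(np.linalg.norm(u, axis=1), 1e-9)
        lv = np.maximum(np.linalg.norm(v, axis=1), 1e-9)
        uh = u / lu[:, None]
        vh = v / lv[:, None]
        c = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
        th = np.degrees(np.arccos(c))
        sn = np.sqrt(np.maximum(1.0 - c * c, 1e-12))
        z = (th - br.a_t0) / br.a_sg
        e += float(np.sum(z * z))
        pref = 2 * z / br.a_sg * np.degrees(-1.0 / sn)
        gi = pref[:, None] * (vh - c[:, None] * uh) / lu[:, None]
        gk = pref[:, None] * (uh - c[:, None] * vh) / lv[:, None]
        _accumulate(grad, br.a_ijk[:, 0], gi)
        _accumulate(grad, br.a_ijk[:, 2], gk)
        _accumulate(grad, br.a_ijk[:, 1], -(gi + gk))
    if len(br.t_ijkl):
        phi, gs, ok = _batch_dihedrals(x, br.t_ijkl)
        dv = _wrap180(phi - br.t_t0)
        z = np.where(ok, dv / br.t_sg, 0.0)
        e += float(np.sum(z * z))
        pref = (2 * z / br.t_sg)[:, None]
        for col, g in enumerate(gs):
            _accumulate(grad, br.t_ijkl[:, col], pref * g)
    if len(br.c_idx):
        c0 = x[br.c_idx[:, 0]]
        a = x[br.c_idx[:, 1]] - c0
        b = x[br.c_idx[:, 2]] - c0
        d = x[br.c_idx[:, 3]] - c0
        bxd = np.cross(b, d)
        v = np.einsum("ij,ij->i", a, bxd)
        z = (v - br.c_v0) / br.c_sg
        e += float(np.sum(z * z))
        pref = (2 * z / br.c_sg)[:, None]
        ga = pref * bxd
        gb = pref * np.cross(d, a)
        gd = pref * np.cross(a, b)
        _accumulate(grad, br.c_idx[:, 1], ga)
        _accumulate(grad, br.c_idx[:, 2], gb)
        _accumulate(grad, br.c_idx[:, 3], gd)
        _accumulate(grad, br.c_idx[:, 0], -(ga + gb + gd))
    if w_rama > 0 and br.ramas:
        e += w_rama * _rama_energy(x, br.ramas, grad, w_rama)
    return e


def _rama_lookup_bilinear(cls, phi, psi):
    """Bilinear log-odds and d/dphi, d/dpsi (per degree)."""
    table = RAMA_TABLES[cls]["logodds"]
    u = (phi + 180.0) / RAMA_BIN_DEG - 0.5
    v = (psi + 180.0) / RAMA_BIN_DEG - 0.5
    i0 = int(np.floor(u))
    j0 = int(np.floor(v))
    fu = u - i0
    fv = v - j0
    q = [[table[(i0 + di) % _N_BINS, (j0 + dj) % _N_BINS]
          for dj in (0, 1)] for di in (0, 1)]
    val = (q[0][0] * (1 - fu) * (1 - fv) + q[1][0] * fu * (1 - fv)
           + q[0][1] * (1 - fu) * fv + q[1][1] * fu * fv)
    dval_du = ((q[1][0] - q[0][0]) * (1 - fv) + (q[1][1] - q[0][1]) * fv)
    dval_dv = ((q[0][1] - q[0][0]) * (1 - fu) + (q[1][1] - q[1][0]) * fu)
    return val, dval_du / RAMA_BIN_DEG, dval_dv / RAMA_BIN_DEG


def _rama_energy(x, ramas, grad, w):
    """-log-odds backbone-dihedral term; gradient is scaled by w in place,
    the returned energy is unscaled."""
    e = 0.0
    for cm1, n, ca, c, nn, cls in ramas:
        rphi = _dihedral_and_grad(x, cm1, n, ca, c)
        rpsi = _dihedral_and_grad(x, n, ca, c, nn)
        if rphi is None or rpsi is None:
            continue
        phi, gphi = rphi
        psi, gpsi = rpsi
        val, dphi, dpsi = _rama_lookup_bilinear(cls, phi, psi)
        e += -val
        for idx_, g in zip((cm1, n, ca, c), gphi):
            grad[idx_] += -w * dphi * g
        for idx_, g in zip((n, ca, c, nn), gpsi):
            grad[idx_] += -w * dpsi * g
    return e


def rsr_minimize(region: RefineRegion, max_iter: int = MAX_ITER,
                 tol: float = CONVERGENCE_TOL,
                 w_geom: float = DEFAULT_W_GEOM,
                 w_map: float = DEFAULT_W_MAP,
                 w_rama: float = DEFAULT_W_RAMA,
                 score_residues: slice | None = None) -> RefineResult:
    """Minimize restrained energy against the map; updates coordinates in
    place and reports RMSZ over ``score_residues`` (default: whole region),
    recomputed by the validation module on the output coordinates."""
    residues = list(region.residues)
    n_front = 0
    if region.fixed_before is not None:
        residues = [region.fixed_before] + residues
        n_front = 1
    if region.fixed_after is not None:
        residues = residues + [region.fixed_after]
    mobile_range = range(n_front, n_front + len(region.residues))
    atoms = []
    atom_index = {}
    mobile = []
    for ri, res in enumerate(residues):
        for a in res.atoms:
            if a.element == "H":
                continue
            atom_index[(ri, a.name)] = len(atoms)
            atoms.append(a)
            mobile.append(ri in mobile_range)
    if not atoms:
        raise ValueError("empty region")
    mobile = np.array(mobile)
    rs = _build_restraints(residues, atom_index)
    x0 = np.array([a.pos for a in atoms])
    br = _BatchRestraints(rs, x0)
    nat = len(atoms)
    bounds = None
    if not mobile.all():
        bounds = []
        for i in range(nat):
            for d in range(3):
                v = x0[i, d]
                bounds.append((v, v) if not mobile[i] else (None, None))

    def objective(flat):
        x = flat.reshape(nat, 3)
        grad = np.zeros_like(x)
        e = _energy_and_grad(x, br, w_rama, grad)
        e *= w_geom
        grad *= w_geom
        if region.grid is not None and w_map > 0:
            vals, gmap = interpolate_cubic(region.grid, x, gradient=True)
            e -= w_map * float(vals.sum())
            grad -= w_map * gmap
        if not np.isfinite(e):
            raise NumericalRefinementError("non-finite energy in refinement")
        return e, grad.ravel()

    res = minimize(objective, x0.ravel(), jac=True, method="L-BFGS-B",
                   bounds=bounds,
                   options={"maxiter": max_iter, "gtol": tol,
                            "ftol": 1e-12})
    xf = res.x.reshape(nat, 3)
    for a, p in zip(atoms, xf):
        a.pos = p.copy()
    _, gfinal = objective(res.x)
    gfinal = gfinal.reshape(nat, 3)
    gfinal[~mobile] = 0.0
    converged = bool(np.max(np.abs(gfinal)) < tol) or \
        (res.status == 0 and res.success)
    sl = score_residues or slice(None)
    scores = None
    try:
        scores = validation.geometry_scores(list(region.residues)[sl])
    except ValueError:
        pass
    return RefineResult(converged, int(res.nit), float(res.fun), scores)
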