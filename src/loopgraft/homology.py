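"""Homolog-to-target alignment around a gap and rigid-body superposition.

Anchor convention: five consecutive modeled residues are required on each
side of a gap; the residue directly adjacent to the gap on each side is
remodeled together with the loop, and the remaining eight residues are the
structural-alignment anchors.  Superposition uses the quaternion
(Horn) closed form; the RMSD it reports is over backbone atoms only.
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .geom import DEFY_SWAPS, MAIN_CHAIN_ATOMS
from .model_io import (LoopGap, Residue, SequenceRecord, StructureModel)

#: homologs below this whole-chain identity are never used
CHAIN_IDENTITY_FLOOR = 70.0
#: loop or anchor identity below this skips the homolog for that gap
WINDOW_IDENTITY_FLOOR = 50.0
#: alignments with backbone RMSD at/above this never yield a graft
ALIGN_RMSD_MAX = 2.0


class DegenerateGeometryError(ValueError):
    pass


@dataclass
class RigidTransform:
    rotation_quaternion: np.ndarray   # (w, x, y, z), unit norm
    translation: np.ndarray
    rmsd: float

    @property
    def matrix(self) -> np.ndarray:
        w, x, y, z = self.rotation_quaternion
        return np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.matrix.T + self.translation


@dataclass
class SequencePairing:
    """Residue-level pairing between a target construct and a homolog chain."""
    target_to_homolog: dict[int, int]      # construct position -> homolog polymer index
    identity_overall: float                # % identity over aligned columns

    def identity_over(self, target_seq: str, homolog_seq: str,
                      positions: range | list[int]) -> float:
        """Percent identity over the given target construct positions,
        computed on aligned columns only."""
        n, same = 0, 0
        for p in positions:
            h = self.target_to_homolog.get(p)
            if h is None:
                continue
            n += 1
            if target_seq[p].upper() == homolog_seq[h].upper():
                same += 1
        return 100.0 * same / n if n else 0.0


@dataclass
class HomologCandidateSource:
    homolog: StructureModel
    chain_id: str
    pairing: SequencePairing
    loop_identity: float
    anchor_identity: float
    loop_residues: list[Residue]          # gap + the two remodel residues
    alt: str = ""                         # alt-loc expanded into this source
    cis_flags: list[bool] = field(default_factory=list)
    source_rama_z: float = float("nan")
    label: str = ""


def _blosum_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.mode = "global"
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        al.target_end_gap_score = 0.0
        al.query_end_gap_score = 0.0
    return al


def align_homolog_sequence(target_seq: str, homolog_seq: str) -> SequencePairing:
    """Global Needleman-Wunsch (BLOSUM62, 11/1 affine) residue pairing.

    Results are memoized on the sequence pair (alignment is deterministic).
    """
    if not target_seq or not homolog_seq:
        raise ValueError("empty sequence")
    key = (target_seq.upper(), homolog_seq.upper())
    cached = _PAIRING_CACHE.get(key)
    if cached is not None:
        return cached
    pairing = _align_uncached(*key)
    if len(_PAIRING_CACHE) > 512:
        _PAIRING_CACHE.clear()
    _PAIRING_CACHE[key] = pairing
    return pairing


_PAIRING_CACHE: dict[tuple[str, str], "SequencePairing"] = {}


def _align_uncached(target_seq: str, homolog_seq: str) -> SequencePairing:
    aln = _blosum_aligner().align(target_seq.upper(), homolog_seq.upper())[0]
    mapping: dict[int, int] = {}
    n, same = 0, 0
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for k in range(t1 - t0):
            mapping[t0 + k] = q0 + k
            n += 1
            if target_seq[t0 + k].upper() == homolog_seq[q0 + k].upper():
                same += 1
    return SequencePairing(mapping, 100.0 * same / n if n else 0.0)


# ---------------------------------------------------------------------------
# Quaternion superposition


def superpose_quaternion(fixed: np.ndarray, moving: np.ndarray,
                         weights: np.ndarray | None = None,
                         rmsd_mask: np.ndarray | None = None) -> RigidTransform:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Closed-form quaternion solution: the optimal rotation is the eigenvector
    of the 4x4 key matrix built from the weighted covariance of the centered
    point sets, for its largest eigenvalue.  The rotation is always proper.
    ``rmsd_mask`` selects the pairs over which the reported RMSD is computed
    (backbone atoms, by convention); the fit itself uses all pairs.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape or fixed.ndim != 2 or fixed.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    n = fixed.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 point pairs")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    fc = (w[:, None] * fixed).sum(0) / wsum
    mc = (w[:, None] * moving).sum(0) / wsum
    P = moving - mc
    Q = fixed - fc
    # collinearity check via the rank of either centered set
    if np.linalg.matrix_rank(Q, tol=1e-8) < 2 or \
            np.linalg.matrix_rank(P, tol=1e-8) < 2:
        raise DegenerateGeometryError("degenerate (collinear/coincident) points")
    S = (w[:, None] * P).T @ Q  # 3x3 covariance, moving -> fixed
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    evals, evecs = np.linalg.eigh(K)
    q = evecs[:, -1]
    q /= np.linalg.norm(q)
    if q[0] < 0:
        q = -q
    tr = RigidTransform(q, np.zeros(3), 0.0)
    R = tr.matrix
    t = fc - R @ mc
    moved = moving @ R.T + t
    mask = np.ones(n, dtype=bool) if rmsd_mask is None else np.asarray(rmsd_mask)
    d2 = np.sum((moved[mask] - fixed[mask]) ** 2, axis=1)
    rmsd = float(np.sqrt(d2.mean())) if mask.any() else 0.0
    return RigidTransform(q, t, rmsd)


# ---------------------------------------------------------------------------
# Anchor preparation with DEFY flips


@dataclass
class AnchorSet:
    """The 8 alignment residues and the 2 remodeled gap-adjacent residues."""
    pre_anchor: list[int]     # construct positions, N-side, outermost first
    post_anchor: list[int]
    remodel_pair: tuple[int, int]

    @classmethod
    def around(cls, gap: LoopGap) -> "AnchorSet":
        pre = list(range(gap.start - 5, gap.start - 1))
        post = list(range(gap.end + 2, gap.end + 6))
        return cls(pre, post, (gap.start - 1, gap.end + 1))


def prepare_anchor_atoms(target_res: list[Residue], homolog_res: list[Residue]
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build paired (fixed, moving) coordinate arrays over the anchors.

    Backbone atoms (N, CA, C, O) are always paired; side-chain atoms are
    paired only for position pairs with identical residue type (a mutation
    crops the pairing to CB).  For Asp/Glu/Phe/Tyr, chemically equivalent
    atom labels are swapped (DEFY flip) whenever a provisional backbone-only
    superposition shows the swap reduces the summed squared distance.
    Returns (fixed, moving, backbone_mask).
    """
    if len(target_res) != len(homolog_res):
        raise ValueError("anchor residue lists differ in length")
    bb_fixed, bb_moving = [], []
    for tr, hr in zip(target_res, homolog_res):
        for name in MAIN_CHAIN_ATOMS:
            ta, ha = tr.atom(name), hr.atom(name)
            if ta is None or ha is None:
                raise ValueError(f"missing backbone atom {name} in anchors")
            bb_fixed.append(ta.pos)
            bb_moving.append(ha.pos)
    bb_fixed = np.array(bb_fixed)
    bb_moving = np.array(bb_moving)
    provisional = superpose_quaternion(bb_fixed, bb_moving)

    fixed = [*bb_fixed]
    moving = [*bb_moving]
    bb_mask = [True] * len(bb_fixed)
    for tr, hr in zip(target_res, homolog_res):
        if tr.type != hr.type:
            # mutation: side chain beyond CB excluded; CB kept when shared
            ta, ha = tr.atom("CB"), hr.atom("CB")
            if ta is not None and ha is not None:
                fixed.append(ta.pos)
                moving.append(ha.pos)
                bb_mask.append(False)
            continue
        swaps = dict(DEFY_SWAPS.get(tr.type, []))
        swap_names = set(swaps) | set(swaps.values())
        inv = {v: k for k, v in swaps.items()}
        names = [a.name for a in tr.atoms
                 if a.name not in MAIN_CHAIN_ATOMS and a.element != "H"
                 and hr.atom(a.name) is not None and a.alt in ("", "A")]
        plain = [n for n in names if n not in swap_names]
        for n in plain:
            fixed.append(tr.atom(n).pos)
            moving.append(hr.atom(n).pos)
            bb_mask.append(False)
        if swaps and all(n in names for pair in swaps.items() for n in pair):
            t_pts = np.array([tr.atom(n).pos for pair in swaps.items()
                              for n in pair])
            h_pts = np.array([hr.atom(n).pos for pair in swaps.items()
                              for n in pair])
            h_sw = np.array([hr.atom(inv.get(n, swaps.get(n, n))).pos
                             for pair in swaps.items() for n in pair])
            d_plain = np.sum((provisional.apply(h_pts) - t_pts) ** 2)
            d_swap = np.sum((provisional.apply(h_sw) - t_pts) ** 2)
            chosen = h_sw if d_swap < d_plain else h_pts
            for tp, hp in zip(t_pts, chosen):
                fixed.append(tp)
                moving.append(hp)
                bb_mask.append(False)
        elif swaps:
            for pair in swaps.items():
                for n in pair:
                    if n in names:
                        fixed.append(tr.atom(n).pos)
                        moving.append(hr.atom(n).pos)
                        bb_mask.append(False)
    return np.array(fixed), np.array(moving), np.array(bb_mask)


# ---------------------------------------------------------------------------
# Source collection


def _loop_alt_ids(residues: list[Residue]) -> list[str]:
    """Backbone alt-loc ids present in a prospective homolog loop; raises if
    alternates form multiple separate stretches (combinatorial case)."""
    alts = sorted({a.alt for r in residues for a in r.atoms
                   if a.alt and a.name in MAIN_CHAIN_ATOMS})
    if not alts:
        return [""]
    flagged = [i for i, r in enumerate(residues)
               if any(a.alt and a.name in MAIN_CHAIN_ATOMS for a in r.atoms)]
    stretches = 1
    for a, b in zip(flagged, flagged[1:]):
        if b - a > 1:
            stretches += 1
    if stretches > 1:
        raise ValueError("multiple alternate stretches")
    return alts


def _restrict_to_alt(res: Residue, alt: str) -> Residue:
    out = Residue(res.number, res.type, [], res.icode, res.het)
    for a in res.atoms:
        if a.alt in ("", alt):
            b = a.copy()
            b.alt = ""
            if out.atom(b.name) is None:
                out.atoms.append(b)
    return out


def collect_sources(gap: LoopGap, target_rec: SequenceRecord,
                    homologs: list[StructureModel],
                    rama_fn=None) -> list[HomologCandidateSource]:
    """Enumerate eligible homolog loop donors for one gap.

    A donor chain must pass the whole-chain identity floor, cover the loop
    plus all eight anchors with a complete backbone, and meet the 50% loop
    and anchor identity rules (single-residue loops are exempt from the loop
    rule).  Backbone alternates inside the donor loop become separate
    sources; donors with several disjoint alternate stretches are excluded.
    """
    target_seq = target_rec.letters.upper()
    anchors = AnchorSet.around(gap)
    loop_positions = list(range(gap.start, gap.end + 1))
    graft_positions = [anchors.remodel_pair[0], *loop_positions,
                       anchors.remodel_pair[1]]
    sources: list[HomologCandidateSource] = []
    for hi, hom in enumerate(homologs):
        for chain in hom.chains:
            poly = chain.polymer()
            if not poly:
                continue
            hseq = "".join(r.one_letter for r in poly)
            pairing = align_homolog_sequence(target_seq, hseq)
            if pairing.identity_overall < CHAIN_IDENTITY_FLOOR:
                continue
            needed = graft_positions + anchors.pre_anchor + anchors.post_anchor
            idx = [pairing.target_to_homolog.get(p) for p in needed]
            if any(i is None for i in idx):
                continue
            if not all(poly[i].main_chain_complete for i in idx):
                continue
            loop_identity = pairing.identity_over(
                target_seq, hseq, loop_positions)
            anchor_identity = pairing.identity_over(
                target_seq, hseq,
                anchors.pre_anchor + anchors.post_anchor)
            if anchor_identity < WINDOW_IDENTITY_FLOOR:
                continue
            if gap.length > 1 and loop_identity < WINDOW_IDENTITY_FLOOR:
                continue
            loop_res = [poly[pairing.target_to_homolog[p]]
                        for p in graft_positions]
            try:
                alt_ids = _loop_alt_ids(loop_res)
            except ValueError:
                continue
            for alt in alt_ids:
                res_alt = [_restrict_to_alt(r, alt) if alt else r.copy()
                           for r in loop_res]
                if not all(r.main_chain_present for r in res_alt):
                    continue
                cis = _cis_flags(res_alt)
                src = HomologCandidateSource(
                    hom, chain.id, pairing, loop_identity, anchor_identity,
                    res_alt, alt=alt,
                    cis_flags=cis,
                    label=f"homolog{hi}:{chain.id}" + (f":{alt}" if alt else ""))
                if rama_fn is not None:
                    try:
                        src.source_rama_z = float(rama_fn(res_alt))
                    except Exception:
                        pass
                sources.append(src)
    return sources


def _cis_flags(residues: list[Residue]) -> list[bool]:
    from .geom import dihedral
    flags = []
    for r0, r1 in zip(residues, residues[1:]):
        try:
            om = dihedral(r0.atom("CA").pos, r0.atom("C").pos,
                          r1.atom("N").pos, r1.atom("CA").pos)
            flags.append(abs(om) < 90.0)
        except AttributeError:
            flags.append(False)
    return flags
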