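"""Clash detection against the model (with symmetry copies) and the
importance-hierarchy adjudication.

Distance classes: heavy < 2.1 A, small < 2.6 A.  CB counts as a main-chain
atom for clash purposes because its position is fixed by the backbone.
Importance order: existing main chain and most ligands > existing side
chains > loop side chains > waters and near-zero-occupancy atoms.  Glycerol,
ethanol, 1,2-ethanediol and PEG-like polymers are the deletable exceptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geom import CLASH_MAIN_ATOMS
from .model_io import StructureModel, ZERO_OCC

HEAVY_CLASH = 2.1
SMALL_CLASH = 2.6
DISULFIDE_SG_MAX = 2.5
SYMMETRY_MARGIN = 5.0

#: residue codes deletable in favor of a loop main chain
EXCEPTION_LIGANDS = {"GOL", "EOH", "EDO", "PEG", "PGE", "PG4", "P6G",
                     "1PE", "2PE", "PE3", "PE4"}


@dataclass
class ClashReport:
    loop_atom: tuple            # (res_idx_in_candidate, atom name)
    other_atom: tuple           # (chain id, res number, res type, atom name)
    sym_id: int                 # 0 = identity image
    distance: float
    severity: str               # heavy | small
    loop_side: str              # main | side
    other_class: str            # main | side | water | exception_ligand |
                                # other_ligand | low_occ


@dataclass
class ClashDecision:
    verdict: str                              # keep | discard_candidate
    reason: str = ""
    delete_atoms: list[tuple] = field(default_factory=list)   # model atoms
    crop_loop_side_chains: list[int] = field(default_factory=list)

    def __post_init__(self):
        if self.verdict == "discard_candidate":
            assert not self.delete_atoms and not self.crop_loop_side_chains


def _disulfide_cys_sg(model: StructureModel) -> set[tuple]:
    """Keys of SG atoms participating in an S-S bridge (< 2.5 A)."""
    sgs = []
    for c in model.chains:
        for r in c.residues:
            if r.type == "CYS":
                a = r.atom("SG")
                if a is not None:
                    sgs.append(((c.id, r.number), a.pos))
    bridged = set()
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            if np.linalg.norm(sgs[i][1] - sgs[j][1]) < DISULFIDE_SG_MAX:
                bridged.add(sgs[i][0])
                bridged.add(sgs[j][0])
    return bridged


def _classify_other(chain, res, atom, bridged) -> str:
    if res.is_water:
        return "water"
    if atom.occ <= ZERO_OCC:
        return "low_occ"
    if res.type in EXCEPTION_LIGANDS:
        return "exception_ligand"
    from .geom import AA3_TO_1
    if res.type in AA3_TO_1:
        if atom.name in CLASH_MAIN_ATOMS and not (
                res.type == "CYS" and atom.name == "CB" and False):
            return "main"
        return "side"
    return "other_ligand"


def _symmetry_images(model: StructureModel, points: np.ndarray,
                     margin: float) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """(sym id, R_cart, t_cart) for images whose copies can come within
    ``margin`` of the candidate bounding box.  Identity (no shift) first."""
    import gemmi
    cell = gemmi.UnitCell(*model.cell)
    om = np.array(cell.orth.mat.tolist())
    fm = np.array(cell.frac.mat.tolist())
    lo = points.min(0) - margin
    hi = points.max(0) + margin
    images = []
    sym_id = 0
    degenerate_cell = cell.volume < 10.0
    for R_f, t_f in model.sym_ops:
        shifts = [np.zeros(3)] if degenerate_cell else [
            np.array([i, j, k])
            for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
        for shift in shifts:
            R_c = om @ R_f @ fm
            t_c = om @ (t_f + shift)
            is_identity = np.allclose(R_f, np.eye(3)) and \
                np.allclose(t_f + shift, 0)
            images.append((sym_id if not is_identity else 0,
                           R_c, t_c, is_identity))
            sym_id += 1
    out = []
    for sid, R_c, t_c, is_id in images:
        out.append((0 if is_id else sid, R_c, t_c))
    return out


def find_clashes(candidate, model: StructureModel,
                 exclude: set | None = None,
                 bonded: set | None = None,
                 use_symmetry: bool = True) -> list[ClashReport]:
    """All atom pairs under 2.6 A between candidate atoms and retained model
    atoms, including symmetry images.  ``exclude`` holds (chain, resnum)
    keys being replaced by the graft (never clash partners); ``bonded``
    holds ((cand_res_idx, cand_atom), (chain, resnum, atom)) pairs forming
    the covalent junctions, which are not clashes.  Hydrogens are ignored."""
    exclude = exclude or set()
    bonded = bonded or set()
    cand_atoms = []
    for ri, res in enumerate(candidate.residues):
        for a in res.atoms:
            if a.element == "H":
                continue
            side = "main" if a.name in CLASH_MAIN_ATOMS else "side"
            cand_atoms.append((ri, a.name, side, a.pos))
    if not cand_atoms:
        return []
    cand_pos = np.array([c[3] for c in cand_atoms])
    bridged = _disulfide_cys_sg(model)
    model_atoms = []
    for c in model.chains:
        for r in c.residues:
            if (c.id, r.number) in exclude:
                continue
            for a in r.atoms:
                if a.element == "H":
                    continue
                model_atoms.append((c, r, a))
    if not model_atoms:
        return []
    base_pos = np.array([a.pos for _, _, a in model_atoms])
    reports = []
    images = _symmetry_images(model, cand_pos, SYMMETRY_MARGIN) if use_symmetry \
        else [(0, np.eye(3), np.zeros(3))]
    lo = cand_pos.min(0) - SMALL_CLASH - SYMMETRY_MARGIN
    hi = cand_pos.max(0) + SMALL_CLASH + SYMMETRY_MARGIN
    tree_c = cKDTree(cand_pos)
    seen_pairs = set()
    for sid, R_c, t_c in images:
        pos = base_pos @ R_c.T + t_c
        inside = np.all((pos >= lo) & (pos <= hi), axis=1)
        if not inside.any():
            continue
        sub_idx = np.nonzero(inside)[0]
        pairs = tree_c.query_ball_point(pos[sub_idx], SMALL_CLASH)
        for local_i, cand_list in zip(sub_idx, pairs):
            ch, r, a = model_atoms[local_i]
            for cj in cand_list:
                d = float(np.linalg.norm(pos[local_i] - cand_pos[cj]))
                if d >= SMALL_CLASH:
                    continue
                if sid == 0:
                    key = (cj, local_i)
                    if key in seen_pairs:
                        continue
                    seen_pairs.add(key)
                ri, aname, side, _ = cand_atoms[cj]
                if sid == 0 and ((ri, aname),
                                 (ch.id, r.number, a.name)) in bonded:
                    continue
                other_cls = _classify_other(ch, r, a, bridged)
                reports.append(ClashReport(
                    (ri, aname), (ch.id, r.number, r.type, a.name), sid, d,
                    "heavy" if d < HEAVY_CLASH else "small",
                    side, other_cls))
    return reports


def adjudicate(reports: list[ClashReport],
               model: StructureModel | None = None) -> ClashDecision:
    """Apply the importance hierarchy to a clash report list.

    1. loop main chain vs existing main chain or non-exception ligand,
       heavy: discard the candidate;
    2. loop main chain vs exception ligand, heavy: delete the ligand;
    3. existing side chain vs loop backbone, heavy: delete that side chain —
       unless the side chain is a disulfide-bonded Cys, which vetoes the
       candidate;
    4. loop side chain heavy against any protein atom or non-water compound:
       crop the loop side chain from the gamma atom onward;
    5. waters and occupancy <= 0.01 atoms: deleted on any (small or heavy)
       clash with the loop.
    """
    bridged = _disulfide_cys_sg(model) if model is not None else set()
    delete_atoms: list[tuple] = []
    crops: set[int] = set()
    for rep in reports:
        if rep.severity == "heavy" and rep.loop_side == "main" and \
                rep.other_class in ("main", "other_ligand"):
            return ClashDecision("discard_candidate",
                                 reason="loop-main-vs-" + rep.other_class)
        if rep.severity == "heavy" and rep.loop_side == "main" and \
                rep.other_class == "side":
            key = (rep.other_atom[0], rep.other_atom[1])
            if rep.other_atom[2] == "CYS" and key in bridged:
                return ClashDecision("discard_candidate",
                                     reason="cysteine-bridge")
    for rep in reports:
        if rep.other_class in ("water", "low_occ"):
            delete_atoms.append(rep.other_atom)
            continue
        if rep.severity != "heavy":
            continue
        if rep.loop_side == "main" and rep.other_class == "exception_ligand":
            delete_atoms.append(rep.other_atom)
        elif rep.loop_side == "main" and rep.other_class == "side":
            delete_atoms.append(rep.other_atom)   # whole side chain, resolved later
        elif rep.loop_side == "side" and rep.other_class in (
                "main", "side", "exception_ligand", "other_ligand"):
            crops.add(rep.loop_atom[0])
    uniq = []
    for d in delete_atoms:
        if d not in uniq:
            uniq.append(d)
    return ClashDecision("keep", delete_atoms=uniq,
                         crop_loop_side_chains=sorted(crops))


def apply_decision(decision: ClashDecision, candidate,
                   model: StructureModel) -> list[tuple]:
    """Delete model atoms / crop loop side chains per the decision.
    Returns an undo list of (chain id, removed Residue copy) records."""
    from .geom import MAIN_CHAIN_ATOMS
    removed = []
    for chain_id, resnum, restype, atom_name in decision.delete_atoms:
        chain = model.chain(chain_id)
        for res in list(chain.residues):
            if res.number != resnum or res.type != restype:
                continue
            if res.is_water or restype in EXCEPTION_LIGANDS or \
                    all(a.occ <= ZERO_OCC for a in res.atoms):
                removed.append((chain_id, res.copy()))
                chain.residues.remove(res)
            else:
                # protein residue: drop side chain beyond CB
                removed.append((chain_id, res.copy()))
                res.atoms = [a for a in res.atoms
                             if a.name in CLASH_MAIN_ATOMS]
            break
    for ri in decision.crop_loop_side_chains:
        res = candidate.residues[ri]
        res.atoms = [a for a in res.atoms
                     if a.name in CLASH_MAIN_ATOMS]
    candidate.deletions.extend(removed)
    return removed


def restore_deletions(model: StructureModel, removed: list[tuple]) -> None:
    """Put back residues/side chains deleted to fit a now-discarded loop."""
    for chain_id, res in removed:
        chain = model.chain(chain_id)
        existing = next((r for r in chain.residues
                         if r.number == res.number and r.type == res.type
                         and r.icode == res.icode), None)
        if existing is None:
            chain.residues.append(res)
        else:
            existing.atoms = [a.copy() for a in res.atoms]
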