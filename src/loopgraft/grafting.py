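"""Transfer a homolog loop into the target model; candidate pool management.

A graft replaces the two gap-adjacent target residues (and any partially
modeled edge residue) with the transformed homolog residues, crops side
chains at mutated positions to CB, sets occupancies to 1.00, rescales B
factors by the ratio of model-average B factors, and converts MET/MSE to
match the target's prevailing methionine type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geom import AA1_TO_3, MAIN_CHAIN_ATOMS
from .homology import (AnchorSet, HomologCandidateSource, RigidTransform)
from .model_io import LoopGap, Residue, SequenceRecord, StructureModel

DEDUP_RMSD = 0.1
TOP_N_DEFAULT = 10


class CandidateConstructionError(ValueError):
    pass


@dataclass
class CandidateLoop:
    source: HomologCandidateSource | None
    residues: list[Residue]              # remodel-pair + loop + remodel-pair
    align_rmsd: float
    transform: RigidTransform | None
    gap: LoopGap
    state: str = "raw"
    reject_reason: str = ""
    rama_z: float = float("nan")
    loop_mean_density: float = float("nan")
    deletions: list = field(default_factory=list)

    @property
    def label(self) -> str:
        return self.source.label if self.source else "zero-occupancy"

    def backbone_coords(self) -> np.ndarray:
        pts = []
        for r in self.residues:
            for name in MAIN_CHAIN_ATOMS:
                a = r.atom(name)
                if a is not None:
                    pts.append(a.pos)
        return np.array(pts)

    def set_state(self, new: str, reason: str = ""):
        order = {"raw": 0, "refined": 1, "accepted": 2, "rejected": 2}
        if order[new] < order[self.state]:
            raise ValueError(f"state cannot move {self.state} -> {new}")
        self.state = new
        if reason:
            self.reject_reason = reason


def _prevailing_met_type(model: StructureModel) -> str:
    n_met = n_mse = 0
    for c in model.chains:
        for r in c.polymer():
            if r.type == "MET":
                n_met += 1
            elif r.type == "MSE":
                n_mse += 1
    return "MSE" if n_mse > n_met else "MET"


def _convert_met(res: Residue, target_type: str) -> None:
    if res.type == target_type or res.type not in ("MET", "MSE"):
        return
    res.type = target_type
    for a in res.atoms:
        if target_type == "MSE" and a.name == "SD":
            a.name, a.element = "SE", "SE"
        elif target_type == "MET" and a.name == "SE":
            a.name, a.element = "SD", "S"
    res.het = target_type == "MSE"


def _crop_to_cb(res: Residue) -> None:
    keep = set(MAIN_CHAIN_ATOMS) | {"CB"}
    res.atoms = [a for a in res.atoms if a.name in keep]


def graft_loop(model: StructureModel, gap: LoopGap,
               source: HomologCandidateSource, transform: RigidTransform,
               rec: SequenceRecord | None = None,
               align_rmsd_max: float = 2.0) -> CandidateLoop:
    """Build a candidate by transforming the donor residues into the target
    frame.  The caller is responsible for having verified anchors; this
    enforces the alignment-RMSD cutoff."""
    if transform.rmsd >= align_rmsd_max:
        raise CandidateConstructionError(
            f"alignment RMSD {transform.rmsd:.2f} at/above cutoff")
    anchors = AnchorSet.around(gap)
    positions = [anchors.remodel_pair[0],
                 *range(gap.start, gap.end + 1), anchors.remodel_pair[1]]
    if rec is not None:
        letters = "".join(rec.letters[p].upper() for p in positions)
    else:
        letters = _gap_target_letters(gap)
    target_types = [AA1_TO_3.get(ch, "ALA") for ch in letters]
    met_type = _prevailing_met_type(model)
    b_ratio = model.mean_protein_b() / source.homolog.mean_protein_b()
    grafted: list[Residue] = []
    for pos, want, hres in zip(positions, target_types, source.loop_residues):
        res = hres.copy()
        res.number = pos + 1  # construct numbering, 1-based
        res.icode = ""
        if want in ("MET", "MSE") and res.type in ("MET", "MSE"):
            _convert_met(res, met_type)
        elif res.type != want:
            got3 = res.type
            _crop_to_cb(res)
            res.type = want
            if want == "GLY":
                res.atoms = [a for a in res.atoms if a.name != "CB"]
            elif got3 == "GLY" and want != "GLY":
                pass  # CB completed later by side-chain building stages
        for a in res.atoms:
            a.pos = transform.apply(a.pos[None, :])[0]
            a.occ = 1.0
            a.b = a.b * b_ratio
            a.alt = ""
        grafted.append(res)
    return CandidateLoop(source, grafted, transform.rmsd, transform, gap)


def _gap_target_letters(gap: LoopGap) -> str:
    # remodel-pair letters are supplied by the pipeline via gap context; the
    # gap sequence covers the loop itself.  Callers fill edges from the
    # construct; here we require the extended sequence attribute when set.
    ext = getattr(gap, "extended_sequence", None)
    if ext is not None:
        return ext
    return "A" + gap.sequence + "A"


def zero_occupancy_candidate(model: StructureModel, gap: LoopGap,
                             rec: SequenceRecord) -> CandidateLoop:
    """Promote an existing zero-occupancy stretch to a regular candidate."""
    if not gap.zero_occupancy_modeled:
        raise ValueError("gap is not a zero-occupancy-modeled stretch")
    chain = model.chain(gap.chain_id)
    poly = chain.polymer()
    residues = []
    for pos in [gap.start - 1, *range(gap.start, gap.end + 1), gap.end + 1]:
        ri = rec.res_index[pos] if 0 <= pos < len(rec.res_index) else None
        if ri is None:
            raise ValueError("zero-occupancy stretch has unmapped edges")
        res = poly[ri].copy()
        for a in res.atoms:
            a.occ = 1.0
        residues.append(res)
    return CandidateLoop(None, residues, 0.0, None, gap)


def loop_backbone_rmsd(a: CandidateLoop, b: CandidateLoop) -> float:
    """Direct (superposition-free) backbone RMSD between two candidates,
    both already in the target frame."""
    pa, pb = a.backbone_coords(), b.backbone_coords()
    if pa.shape != pb.shape:
        return float("inf")
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))


def dedup_and_rank(cands: list[CandidateLoop],
                   top_n: int = TOP_N_DEFAULT) -> list[CandidateLoop]:
    """Remove near-duplicate conformations and keep the best-aligned few.

    For any pair closer than 0.1 A loop-backbone RMSD the candidate with the
    worse alignment RMSD is discarded; survivors are sorted by alignment
    RMSD (stable in input order on ties) and truncated to ``top_n``.
    """
    keep = [True] * len(cands)
    order = sorted(range(len(cands)), key=lambda i: (cands[i].align_rmsd, i))
    for oi, i in enumerate(order):
        if not keep[i]:
            continue
        for j in order[oi + 1:]:
            if keep[j] and loop_backbone_rmsd(cands[i], cands[j]) < DEDUP_RMSD:
                keep[j] = False
    survivors = [cands[i] for i in order if keep[i]]
    return survivors[:top_n]
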