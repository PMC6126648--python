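"""End-to-end loop completion: detect gaps, collect donors, graft, filter,
refine, score against the density and update the model.

The per-gap funnel is: donor collection -> anchor superposition (alignment
RMSD < 2.0 A) -> graft -> clash adjudication -> dedup/rank (top 10) ->
junction closing + restrained real-space refinement -> post-refinement
clash re-check -> geometry filters -> Ramachandran outlier filter ->
density-ratio acceptance (> 0.25) -> best mean loop density wins -> final
RSCC gate (>= 0.60) with restoration of any deletions when it fails.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import clash_rules, density, grafting, homology, refine, validation
from .density import (CONTROL_MIN_ATOMS, DENSITY_RATIO_MIN, MapGrid,
                      rscc, synthesize_map)
from .geom import MAIN_CHAIN_ATOMS
from .grafting import CandidateLoop, dedup_and_rank, graft_loop, \
    zero_occupancy_candidate
from .homology import AnchorSet, collect_sources, prepare_anchor_atoms, \
    superpose_quaternion
from .model_io import (LoopGap, SequenceRecord, StructureModel,
                       extract_case_coded_sequence, find_missing_loops,
                       write_fasta, write_structure)


@dataclass
class LoopwholeConfig:
    max_loop_length: int = 30
    align_rmsd_max: float = 2.0
    top_n: int = 10
    density_ratio_min: float = DENSITY_RATIO_MIN
    rscc_min_final: float = 0.60
    rscc_min_chain: float = 0.80
    refine_max_iter: int = refine.MAX_ITER
    refine_tol: float = refine.CONVERGENCE_TOL
    w_geom: float = refine.DEFAULT_W_GEOM
    w_map: float = refine.DEFAULT_W_MAP
    w_rama: float = refine.DEFAULT_W_RAMA
    calc_map_b_blur: float = 15.0
    detect_only: bool = False


@dataclass
class GapOutcome:
    gap: dict
    status: str                  # built | no-candidates | all-rejected | skipped
    chosen: str | None = None
    candidates: list[dict] = field(default_factory=list)
    density_report: dict | None = None
    deletions: list = field(default_factory=list)
    restored: bool = False


@dataclass
class RunReport:
    chain_rscc: dict = field(default_factory=dict)
    skipped_chains: list[str] = field(default_factory=list)
    gaps: list[GapOutcome] = field(default_factory=list)
    built: int = 0
    rejected: int = 0
    incomplete_side_chains: list = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "chain_rscc": self.chain_rscc,
            "skipped_chains": self.skipped_chains,
            "gaps": [asdict(g) for g in self.gaps],
            "built": self.built,
            "rejected": self.rejected,
            "incomplete_side_chains": self.incomplete_side_chains,
            "warnings": self.warnings,
        }


class MissingSequenceError(ValueError):
    pass


def chain_precheck_ok(cc: float, config: "LoopwholeConfig") -> bool:
    """Loop building is attempted in a chain only when its overall RSCC is
    at least the pre-check floor (0.80 by default)."""
    return bool(np.isfinite(cc) and cc >= config.rscc_min_chain)


def final_rscc_ok(cc: float, config: "LoopwholeConfig") -> bool:
    """A built loop is kept only when its RSCC against the map is at least
    the final floor (0.60 by default)."""
    return bool(np.isfinite(cc) and cc >= config.rscc_min_final)


def _chain_positions(model: StructureModel, chain_id: str) -> np.ndarray:
    return np.array([a.pos for c, r, a in model.all_atoms()
                     if c.id == chain_id and a.element != "H"])


def _control_positions(model: StructureModel, seqs: list[SequenceRecord],
                       homologs: list[StructureModel],
                       gap: LoopGap) -> np.ndarray:
    """Main-chain atoms of the target at positions ordered in all homologs;
    falls back to all non-loop main-chain atoms under 30 atoms."""
    excluded = set(range(gap.start - 1, gap.end + 2))
    pts = []
    for rec in seqs:
        chain = model.chain(rec.chain_id)
        poly = chain.polymer()
        always = []
        for p, ch in enumerate(rec.letters):
            if not ch.isupper() or rec.res_index[p] is None:
                continue
            if rec.chain_id == gap.chain_id and p in excluded:
                continue
            ok = True
            for hom in homologs:
                found = False
                for hchain in hom.chains:
                    hpoly = hchain.polymer()
                    if not hpoly:
                        continue
                    hseq = "".join(r.one_letter for r in hpoly)
                    pairing = homology.align_homolog_sequence(
                        rec.letters.upper(), hseq)
                    hidx = pairing.target_to_homolog.get(p)
                    if hidx is not None and hpoly[hidx].main_chain_complete:
                        found = True
                        break
                if not found:
                    ok = False
                    break
            if ok:
                always.append(p)
        for p in always:
            res = poly[rec.res_index[p]]
            for name in MAIN_CHAIN_ATOMS:
                a = res.atom(name)
                if a is not None:
                    pts.append(a.pos)
    if len(pts) < CONTROL_MIN_ATOMS:
        pts = []
        for rec in seqs:
            chain = model.chain(rec.chain_id)
            poly = chain.polymer()
            for p, ch in enumerate(rec.letters):
                if rec.res_index[p] is None:
                    continue
                if rec.chain_id == gap.chain_id and p in excluded:
                    continue
                res = poly[rec.res_index[p]]
                if not res.main_chain_complete:
                    continue
                for name in MAIN_CHAIN_ATOMS:
                    a = res.atom(name)
                    if a is not None:
                        pts.append(a.pos)
    return np.array(pts)


def _file_number_for(rec: SequenceRecord, chain, pos: int) -> int:
    """Target file numbering for a construct position, extrapolated from the
    nearest mapped residue."""
    poly = chain.polymer()
    for delta in range(len(rec.res_index)):
        for p in (pos - delta, pos + delta):
            if 0 <= p < len(rec.res_index) and rec.res_index[p] is not None:
                return poly[rec.res_index[p]].number + (pos - p)
    return pos + 1


def _junction_bonds(cand, work, gap, rec) -> set:
    """Covalent junction pairs between the candidate termini and the kept
    anchor residues (peptide bonds, not clashes)."""
    chain = work.chain(gap.chain_id)
    poly = chain.polymer()
    bonded = set()
    mc = ("N", "CA", "C", "O", "CB")
    p_before = gap.start - 2
    if 0 <= p_before < len(rec.res_index) and rec.res_index[p_before] is not None:
        num = poly[rec.res_index[p_before]].number
        for a1 in mc:
            for a2 in mc:
                bonded.add(((0, a1), (gap.chain_id, num, a2)))
    p_after = gap.end + 2
    if 0 <= p_after < len(rec.res_index) and rec.res_index[p_after] is not None:
        num = poly[rec.res_index[p_after]].number
        for a1 in mc:
            for a2 in mc:
                bonded.add(((len(cand.residues) - 1, a1),
                            (gap.chain_id, num, a2)))
    return bonded


def _evaluate_candidate(cand: CandidateLoop, model: StructureModel,
                        gap: LoopGap, rec: SequenceRecord,
                        obs_map: MapGrid | None,
                        config: LoopwholeConfig,
                        replaced_keys: set) -> dict:
    """Run one candidate through clash adjudication, refinement and the
    geometry filters, on a scratch copy of the model.  Returns a record;
    the candidate's residues are left refined in place when it survives."""
    record = {"label": cand.label, "align_rmsd": round(cand.align_rmsd, 4),
              "state": "raw", "reject": ""}
    work = model.copy()
    bonded = _junction_bonds(cand, work, gap, rec)
    reports = clash_rules.find_clashes(cand, work, exclude=replaced_keys,
                                       bonded=bonded)
    decision = clash_rules.adjudicate(reports, work)
    if decision.verdict == "discard_candidate":
        cand.set_state("rejected", "clash-discard:" + decision.reason)
        record.update(state="rejected", reject="clash-discard")
        return record
    removed = clash_rules.apply_decision(decision, cand, work)
    # refinement region: candidate plus one existing residue per side
    chain = work.chain(gap.chain_id)
    poly = chain.polymer()
    extra_before = rec.res_index[gap.start - 2] if gap.start >= 2 else None
    extra_after = rec.res_index[gap.end + 2] \
        if gap.end + 2 < len(rec.res_index) else None
    region_res = []
    if extra_before is not None:
        region_res.append(poly[extra_before].copy())
    region_res.extend(cand.residues)
    if extra_after is not None:
        region_res.append(poly[extra_after].copy())
    if extra_before is not None:
        refine.close_gap_pregame(region_res[0], region_res[1])
    if extra_after is not None:
        refine.close_gap_pregame(region_res[-2], region_res[-1])
    # frozen context keeps the region covalently tethered to the model
    fb = rec.res_index[gap.start - 3] if gap.start >= 3 else None
    fa = rec.res_index[gap.end + 3] \
        if gap.end + 3 < len(rec.res_index) else None
    region = refine.RefineRegion(
        region_res, obs_map,
        fixed_before=poly[fb].copy() if fb is not None else None,
        fixed_after=poly[fa].copy() if fa is not None else None)
    lo = 1 if extra_before is not None else 0
    hi = len(region_res) - (1 if extra_after is not None else 0)
    result = refine.rsr_minimize(
        region, max_iter=config.refine_max_iter, tol=config.refine_tol,
        w_geom=config.w_geom, w_map=config.w_map if obs_map is not None else 0,
        w_rama=config.w_rama, score_residues=slice(lo, hi))
    cand.set_state("refined")
    record["state"] = "refined"
    record["converged"] = result.converged
    # post-refinement clash re-check
    reports2 = clash_rules.find_clashes(cand, work, exclude=replaced_keys,
                                        bonded=bonded)
    decision2 = clash_rules.adjudicate(reports2, work)
    if decision2.verdict == "discard_candidate":
        cand.set_state("rejected", "clash-after-refine")
        record.update(state="rejected", reject="clash-discard")
        return record
    clash_rules.apply_decision(decision2, cand, work)
    scores = result.scores
    if scores is None:
        cand.set_state("rejected", "unscorable")
        record.update(state="rejected", reject="bad-geometry")
        return record
    src_cis = cand.source.cis_flags if cand.source else None
    ok, reason = validation.geometry_filter(scores, result.converged, src_cis)
    record["rmsz"] = scores.as_dict()
    if not ok:
        cand.set_state("rejected", reason)
        record.update(state="rejected", reject="bad-geometry",
                      reason=reason)
        return record
    try:
        cand.rama_z = validation.rama_z(cand.residues).z
    except ValueError:
        cand.rama_z = float("nan")
    record["rama_z"] = None if np.isnan(cand.rama_z) else round(cand.rama_z, 3)
    record["pending_deletions"] = [(cid, r.number, r.type)
                                   for cid, r in cand.deletions]
    return record


def run_loopwhole(model: StructureModel,
                  constructs: list[tuple[str, str]] | dict[str, str] | None,
                  homologs: list[StructureModel],
                  obs_map: MapGrid | None,
                  config: LoopwholeConfig | None = None
                  ) -> tuple[StructureModel, RunReport]:
    """Build missing loops in ``model`` from homolog donors and the map.

    Returns the updated model and a machine-readable run report.  The input
    model object is not modified.
    """
    config = config or LoopwholeConfig()
    report = RunReport()
    if not constructs:
        constructs = model.seqres or None
    if not constructs:
        raise MissingSequenceError(
            "loop building requires construct sequences (FASTA or SEQRES)")
    work = model.copy()
    seqs = extract_case_coded_sequence(work, constructs)

    # chain-level density pre-check
    allowed_chains = set()
    for rec in seqs:
        if obs_map is None:
            allowed_chains.add(rec.chain_id)
            continue
        sub = StructureModel([work.chain(rec.chain_id).copy()],
                             cell=work.cell)
        calc = synthesize_map(sub, b_blur=config.calc_map_b_blur,
                              cell=obs_map.cell, shape=obs_map.shape)
        try:
            cc, _ = rscc(_chain_positions(work, rec.chain_id), obs_map, calc)
        except ValueError:
            cc = float("nan")
        report.chain_rscc[rec.chain_id] = round(cc, 4) if np.isfinite(cc) \
            else None
        if not chain_precheck_ok(cc, config):
            report.skipped_chains.append(rec.chain_id)
            report.warnings.append(
                f"chain {rec.chain_id}: density fit below "
                f"{config.rscc_min_chain:.2f}; overall conformation "
                "unreliable, loops not attempted")
            continue
        allowed_chains.add(rec.chain_id)

    gaps = find_missing_loops(work, seqs, max_len=config.max_loop_length)
    if config.detect_only:
        for gap in gaps:
            report.gaps.append(GapOutcome(asdict(gap), "detected"))
        return work, report

    for gap in gaps:
        rec = next(r for r in seqs if r.chain_id == gap.chain_id)
        outcome = GapOutcome(asdict(gap), "no-candidates")
        report.gaps.append(outcome)
        if gap.skipped or gap.chain_id not in allowed_chains:
            outcome.status = "skipped"
            continue
        built = _process_gap(work, gap, rec, seqs, homologs, obs_map,
                             config, outcome)
        if built:
            report.built += 1
            # re-extract so later gaps see the updated completeness
            seqs = extract_case_coded_sequence(work, constructs)
        elif outcome.status != "no-candidates":
            report.rejected += 1

    # list residues with incomplete side chains (for downstream rebuilding)
    for c in work.chains:
        for r in c.polymer():
            from .geom import SIDE_CHAIN_TOPOLOGY
            want = {t[0] for t in SIDE_CHAIN_TOPOLOGY.get(r.type, [])}
            if r.type not in ("GLY",):
                want.add("CB")
            if want - r.atom_names():
                report.incomplete_side_chains.append(
                    (c.id, r.number, r.type))
    return work, report


def _process_gap(work: StructureModel, gap: LoopGap, rec: SequenceRecord,
                 seqs, homologs, obs_map, config: LoopwholeConfig,
                 outcome: GapOutcome) -> bool:
    chain = work.chain(gap.chain_id)
    poly = chain.polymer()
    anchors = AnchorSet.around(gap)
    replaced_positions = list(range(gap.start - 1, gap.end + 2))
    replaced_keys = set()
    for p in replaced_positions:
        ri = rec.res_index[p] if 0 <= p < len(rec.res_index) else None
        if ri is not None:
            replaced_keys.add((gap.chain_id, poly[ri].number))

    candidates: list[CandidateLoop] = []
    rama_fn = lambda residues: validation.rama_z(residues).z
    sources = collect_sources(gap, rec, homologs, rama_fn=rama_fn)
    for src in sources:
        t_res = [poly[rec.res_index[p]]
                 for p in anchors.pre_anchor + anchors.post_anchor]
        hpoly = src.homolog.chain(src.chain_id).polymer()
        h_res = [hpoly[src.pairing.target_to_homolog[p]]
                 for p in anchors.pre_anchor + anchors.post_anchor]
        try:
            fixed, moving, bb_mask = prepare_anchor_atoms(t_res, h_res)
            tr = superpose_quaternion(fixed, moving, rmsd_mask=bb_mask)
        except (ValueError, homology.DegenerateGeometryError):
            continue
        if tr.rmsd >= config.align_rmsd_max:
            outcome.candidates.append(
                {"label": src.label, "align_rmsd": round(tr.rmsd, 4),
                 "state": "rejected", "reject": "alignment-rmsd"})
            continue
        try:
            candidates.append(graft_loop(work, gap, src, tr, rec=rec,
                                         align_rmsd_max=config.align_rmsd_max))
        except grafting.CandidateConstructionError:
            continue
    if gap.zero_occupancy_modeled:
        try:
            candidates.append(zero_occupancy_candidate(work, gap, rec))
        except ValueError:
            pass
    if not candidates:
        outcome.status = "no-candidates"
        return False

    candidates = dedup_and_rank(candidates, top_n=config.top_n)
    survivors: list[CandidateLoop] = []
    for cand in candidates:
        rec_entry = _evaluate_candidate(cand, work, gap, rec, obs_map,
                                        config, replaced_keys)
        outcome.candidates.append(rec_entry)
        if cand.state != "rejected":
            survivors.append(cand)

    # Ramachandran Grubbs comparison across the pool
    source_zs = [c.source.source_rama_z for c in survivors
                 if c.source is not None]
    still = []
    for cand in survivors:
        peers = [c.rama_z for c in survivors if c is not cand]
        ok, reason = validation.rama_outlier_filter(
            cand.rama_z if np.isfinite(cand.rama_z) else 0.0,
            peers, source_zs)
        entry = next(e for e in outcome.candidates
                     if e["label"] == cand.label)
        if not ok:
            cand.set_state("rejected", reason)
            entry.update(state="rejected", reject="bad-geometry",
                         reason=reason)
        else:
            still.append(cand)
    survivors = still

    # density-ratio acceptance
    accepted: list[tuple[CandidateLoop, density.DensityFitReport]] = []
    control = _control_positions(work, seqs, homologs, gap) \
        if (obs_map is not None and survivors) else None
    for cand in survivors:
        entry = next(e for e in outcome.candidates
                     if e["label"] == cand.label)
        if obs_map is None:
            cand.loop_mean_density = 0.0
            accepted.append((cand, None))
            continue
        try:
            fit = density.density_ratio(cand.residues, control, obs_map,
                                        ratio_min=config.density_ratio_min)
        except ValueError:
            cand.set_state("rejected", "density-error")
            entry.update(state="rejected", reject="insufficient-density")
            continue
        entry["density_ratio"] = round(fit.ratio, 4)
        if fit.ratio <= config.density_ratio_min:
            cand.set_state("rejected", "density-ratio")
            prev = entry.get("reject", "")
            entry.update(state="rejected",
                         reject="both" if prev == "bad-geometry"
                         else "insufficient-density")
            continue
        cand.loop_mean_density = fit.loop_mean
        accepted.append((cand, fit))
    if not accepted:
        outcome.status = "all-rejected"
        return False

    best, best_fit = max(accepted, key=lambda cf: cf[0].loop_mean_density)
    for cand, _ in accepted:
        if cand is not best:
            cand.set_state("rejected", "better-candidate-available")

    snapshot = work.copy()
    _install_candidate(work, gap, rec, best)
    # final RSCC gate against the map with a calc map from the updated model
    if obs_map is not None:
        calc = synthesize_map(work, b_blur=config.calc_map_b_blur,
                              cell=obs_map.cell, shape=obs_map.shape)
        loop_pos = np.array([a.pos for r in best.residues for a in r.atoms])
        try:
            cc, rsr_val = rscc(loop_pos, obs_map, calc)
        except ValueError:
            cc, rsr_val = float("nan"), float("nan")
        fit_dict = {
            "loop_mean": best_fit.loop_mean if best_fit else None,
            "control_mean": best_fit.control_mean if best_fit else None,
            "ratio": best_fit.ratio if best_fit else None,
            "control_set_size": best_fit.control_set_size if best_fit else 0,
            "rscc": None if np.isnan(cc) else round(cc, 4),
            "rsr": None if np.isnan(rsr_val) else round(rsr_val, 4),
        }
        outcome.density_report = fit_dict
        if not final_rscc_ok(cc, config):
            # revert: restores waters/ligands deleted for this loop
            work.chains = snapshot.chains
            best.set_state("rejected", "low-final-rscc")
            entry = next(e for e in outcome.candidates
                         if e["label"] == best.label)
            entry.update(state="rejected", reject="insufficient-density",
                         reason="low-final-rscc")
            outcome.status = "all-rejected"
            outcome.restored = True
            return False
    best.set_state("accepted")
    entry = next(e for e in outcome.candidates if e["label"] == best.label)
    entry["state"] = "accepted"
    outcome.status = "built"
    outcome.chosen = best.label
    outcome.deletions = [(cid, r.number, r.type) for cid, r in best.deletions]
    return True


def _install_candidate(work: StructureModel, gap: LoopGap,
                       rec: SequenceRecord, cand: CandidateLoop) -> None:
    """Replace the gap region in the model with the candidate residues."""
    chain = work.chain(gap.chain_id)
    poly = chain.polymer()
    positions = list(range(gap.start - 1, gap.end + 2))
    # file numbering for the new residues, from the pre-edit mapping
    numbers = [_file_number_for(rec, chain, p) for p in positions]
    # insertion anchor: first kept residue after the gap
    anchor_res = None
    for p in range(gap.end + 2, len(rec.res_index)):
        ri = rec.res_index[p]
        if ri is not None:
            anchor_res = poly[ri]
            break
    # apply the candidate's pending model deletions (waters etc.)
    for cid, res in cand.deletions:
        target_chain = work.chain(cid)
        doomed = next((r for r in target_chain.residues
                       if r.number == res.number and r.type == res.type
                       and r.icode == res.icode), None)
        if doomed is not None:
            if doomed.is_water or doomed.het:
                target_chain.residues.remove(doomed)
            else:
                from .geom import CLASH_MAIN_ATOMS
                doomed.atoms = [a for a in doomed.atoms
                                if a.name in CLASH_MAIN_ATOMS]
    # remove replaced residues
    doomed_ids = set()
    for p in positions:
        ri = rec.res_index[p] if 0 <= p < len(rec.res_index) else None
        if ri is not None:
            doomed_ids.add(id(poly[ri]))
    chain.residues = [r for r in chain.residues if id(r) not in doomed_ids]
    new_res = []
    for num, res in zip(numbers, cand.residues):
        r = res.copy()
        r.number = num
        new_res.append(r)
    if anchor_res is not None:
        insert_at = next(i for i, r in enumerate(chain.residues)
                         if r is anchor_res)
    else:
        insert_at = len(chain.residues)
    chain.residues[insert_at:insert_at] = new_res


def finalize_outputs(model: StructureModel, report: RunReport,
                     constructs, outdir: str | Path,
                     basename: str = "loopgraft") -> dict[str, Path]:
    """Write the updated model (PDB + mmCIF), the case-coded FASTA, the JSON
    report and a per-loop summary table; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["pdb"] = outdir / f"{basename}.pdb"
    write_structure(model, paths["pdb"], dialect="pdb")
    paths["cif"] = outdir / f"{basename}.cif"
    write_structure(model, paths["cif"], dialect="mmcif")
    if constructs:
        seqs = extract_case_coded_sequence(model, constructs)
        paths["fasta"] = outdir / f"{basename}.fasta"
        write_fasta([(f"{basename}|chain_{s.chain_id}", s.letters)
                     for s in seqs], paths["fasta"])
    paths["report"] = outdir / f"{basename}_report.json"
    with open(paths["report"], "w") as fh:
        json.dump(report.as_dict(), fh, indent=1, default=str)
    paths["summary"] = outdir / f"{basename}_loops.tsv"
    with open(paths["summary"], "w") as fh:
        fh.write("chain\tstart\tend\tlength\tstatus\tchosen\tratio\trscc\n")
        for g in report.gaps:
            dr = g.density_report or {}
            fh.write("\t".join(str(x) for x in (
                g.gap["chain_id"], g.gap["start"] + 1, g.gap["end"] + 1,
                g.gap["end"] - g.gap["start"] + 1, g.status,
                g.chosen or "-", dr.get("ratio", "-"),
                dr.get("rscc", "-"))) + "\n")
    return paths
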