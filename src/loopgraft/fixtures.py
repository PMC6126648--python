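"""Synthetic-structure generator: ideal-geometry chains, gapped targets,
noisy homolog donors and matching density maps, all reproducible from a
single seed.

The builder follows a secondary-structure plan of (length, phi, psi)
segments, places backbones with ideal bond lengths and angles (trans
peptides), and attaches side chains at canonical single-rotamer internal
coordinates.  Targets are derived by deleting (or zero-occupying) a gap;
homologs are the same fold with seeded coordinate noise, mutations, a rigid
motion and a B-factor scale — the conditions the loop-transfer pipeline is
designed for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .density import MapGrid, synthesize_map, zero_out_sphere
from .geom import (AA1_TO_3, ANGLE_C_N_CA, ANGLE_CA_C_N, ANGLE_CA_C_O,
                   ANGLE_N_CA_C, ANGLE_N_CA_CB, BOND_C_N, BOND_C_O,
                   BOND_CA_C, BOND_CA_CB, BOND_N_CA, CB_IMPROPER,
                   SIDE_CHAIN_TOPOLOGY, place_atom)
from .model_io import AtomRecord, Chain, Residue, StructureModel

HELIX = (-63.0, -42.0)
STRAND = (-120.0, 130.0)
PPII = (-65.0, 147.0)

DEFAULT_B = 20.0
CELL_MARGIN = 9.0


@dataclass
class FixtureSpec:
    sequence: str = "ADKEVLSRAQGTFNELIKDYAGSTQVMRELHNAW"
    plan: list[tuple[int, float, float]] | None = None  # (count, phi, psi)
    gap_start: int = 14        # 0-based construct positions, inclusive
    gap_end: int = 17
    homolog_noise: float = 0.15
    homolog_mutations: int = 0
    homolog_b_scale: float = 1.5
    homolog_shift: float = 12.0
    n_homologs: int = 3
    map_b_blur: float = 15.0
    map_spacing: float = 0.7
    map_noise_snr: float = 0.0   # 0 = noiseless
    zero_map_over_gap: bool = False
    zero_occupancy_gap: bool = False
    seed: int = 0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def default_plan(n: int) -> list[tuple[int, float, float]]:
    """Helix - loop - strand alternation covering n residues."""
    plan = []
    left = n
    kinds = [(8, *HELIX), (4, *PPII), (8, *STRAND), (4, *PPII)]
    i = 0
    while left > 0:
        cnt, phi, psi = kinds[i % len(kinds)]
        cnt = min(cnt, left)
        plan.append((cnt, phi, psi))
        left -= cnt
        i += 1
    return plan


def _phi_psi_series(spec: FixtureSpec) -> list[tuple[float, float]]:
    plan = spec.plan or default_plan(len(spec.sequence))
    out = []
    for cnt, phi, psi in plan:
        out.extend([(phi, psi)] * cnt)
    return out[:len(spec.sequence)]


def build_side_chain(res: Residue) -> None:
    """Attach CB and the canonical-rotamer side chain to a backbone."""
    n, ca, c = (res.atom(x) for x in ("N", "CA", "C"))
    if None in (n, ca, c):
        return
    b = res.atom("O").b if res.atom("O") else DEFAULT_B
    if res.type != "GLY" and res.atom("CB") is None:
        cb = place_atom(c.pos, n.pos, ca.pos, BOND_CA_CB[0],
                        ANGLE_N_CA_CB[0], CB_IMPROPER)
        res.atoms.append(AtomRecord("CB", "C", cb, 1.0, b))
    for name, el, (ra, rb, rc), bond, ang, tor in \
            SIDE_CHAIN_TOPOLOGY.get(res.type, []):
        if res.atom(name) is not None:
            continue
        pa, pb, pc = (res.atom(x) for x in (ra, rb, rc))
        if None in (pa, pb, pc):
            continue
        pos = place_atom(pa.pos, pb.pos, pc.pos, bond, ang, tor)
        res.atoms.append(AtomRecord(name, el, pos, 1.0, b))


def build_ground_truth(spec: FixtureSpec) -> StructureModel:
    """Ideal-geometry model for the plan; single chain A, occupancies 1.0."""
    seq = spec.sequence.upper()
    series = _phi_psi_series(spec)
    residues: list[Residue] = []
    # seed the first residue
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA[0], 0.0, 0.0])
    th = np.radians(ANGLE_N_CA_C[0])
    c0 = ca0 + BOND_CA_C[0] * np.array([-np.cos(th), np.sin(th), 0.0])
    coords = [{"N": n0, "CA": ca0, "C": c0}]
    for i in range(1, len(seq)):
        prev = coords[-1]
        psi_prev = series[i - 1][1]
        phi = series[i][0]
        n = place_atom(prev["N"], prev["CA"], prev["C"],
                       BOND_C_N[0], ANGLE_CA_C_N[0], psi_prev)
        ca = place_atom(prev["CA"], prev["C"], n,
                        BOND_N_CA[0], ANGLE_C_N_CA[0], 180.0)
        c = place_atom(prev["C"], n, ca, BOND_CA_C[0], ANGLE_N_CA_C[0], phi)
        coords.append({"N": n, "CA": ca, "C": c})
    # carbonyl O in the peptide plane (terminal O from psi)
    for i, d in enumerate(coords):
        if i + 1 < len(coords):
            d["O"] = place_atom(coords[i + 1]["N"], d["CA"], d["C"],
                                BOND_C_O[0], ANGLE_CA_C_O[0], 180.0)
        else:
            d["O"] = place_atom(d["N"], d["CA"], d["C"],
                                BOND_C_O[0], ANGLE_CA_C_O[0],
                                series[i][1] + 180.0)
    for i, ch in enumerate(seq):
        rtype = AA1_TO_3.get(ch, "ALA")
        res = Residue(i + 1, rtype, [
            AtomRecord(nm, "N" if nm == "N" else ("O" if nm == "O" else "C"),
                       coords[i][nm], 1.0, DEFAULT_B)
            for nm in ("N", "CA", "C", "O")])
        build_side_chain(res)
        residues.append(res)
    model = StructureModel([Chain("A", residues)])
    _fit_cell(model)
    return model


def _fit_cell(model: StructureModel, margin: float = CELL_MARGIN) -> None:
    pts = np.array([a.pos for _, _, a in model.all_atoms()])
    lo = pts.min(0)
    shift = margin - lo
    for _, _, a in model.all_atoms():
        a.pos = a.pos + shift
    extent = pts.max(0) - lo + 2 * margin
    model.cell = (float(extent[0]), float(extent[1]), float(extent[2]),
                  90.0, 90.0, 90.0)


def mutate_residue(res: Residue, new_type: str) -> None:
    """Swap residue type and rebuild the side chain at the canonical
    rotamer (backbone untouched)."""
    keep = {"N", "CA", "C", "O"}
    res.atoms = [a for a in res.atoms if a.name in keep]
    res.type = new_type
    build_side_chain(res)


_MUTATION_POOL = "ASDLKETVQNRIF"


def derive_target_and_homologs(truth: StructureModel, spec: FixtureSpec
                               ) -> tuple[StructureModel,
                                          list[StructureModel], MapGrid]:
    """(target with gap, homolog donors, density map from the truth)."""
    rng = spec.rng()
    target = truth.copy()
    chain = target.chains[0]
    gap_res = [r for r in chain.residues
               if spec.gap_start <= r.number - 1 <= spec.gap_end]
    if spec.zero_occupancy_gap:
        for r in gap_res:
            for a in r.atoms:
                a.occ = 0.0
    else:
        for r in gap_res:
            chain.residues.remove(r)
    homologs = []
    for h in range(spec.n_homologs):
        hom = truth.copy()
        hchain = hom.chains[0]
        poly = hchain.polymer()
        # mutations away from the gap edges
        mutable = [r for r in poly
                   if not (spec.gap_start - 1 <= r.number - 1
                           <= spec.gap_end + 1)]
        k = min(spec.homolog_mutations, len(mutable))
        if k:
            for r in rng.choice(len(mutable), size=k, replace=False):
                res = mutable[int(r)]
                choices = [c for c in _MUTATION_POOL
                           if AA1_TO_3[c] != res.type]
                mutate_residue(res, AA1_TO_3[choices[int(
                    rng.integers(len(choices)))]])
        if spec.homolog_noise > 0:
            for _, _, a in hom.all_atoms():
                a.pos = a.pos + rng.normal(0.0, spec.homolog_noise, 3)
        # rigid motion: random rotation + shift
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        t = rng.normal(0.0, 1.0, 3)
        t = t / np.linalg.norm(t) * spec.homolog_shift
        for _, _, a in hom.all_atoms():
            a.pos = R @ a.pos + t
            a.b = a.b * spec.homolog_b_scale
        _fit_cell(hom)
        homologs.append(hom)
    grid = synthesize_map(truth, b_blur=spec.map_b_blur,
                          spacing=spec.map_spacing)
    if spec.map_noise_snr > 0:
        sd = grid.values.std() / spec.map_noise_snr
        grid.values = grid.values + rng.normal(0.0, sd, grid.values.shape)
    if spec.zero_map_over_gap:
        truth_chain = truth.chains[0]
        for r in truth_chain.residues:
            if spec.gap_start <= r.number - 1 <= spec.gap_end:
                for a in r.atoms:
                    zero_out_sphere(grid, a.pos, 3.0)
    return target, homologs, grid


def constructs_for(spec: FixtureSpec) -> list[tuple[str, str]]:
    return [("construct_A", spec.sequence.upper())]


def make_fixture(spec: FixtureSpec):
    """(truth, target, homologs, map, constructs) from one seeded spec."""
    truth = build_ground_truth(spec)
    target, homologs, grid = derive_target_and_homologs(truth, spec)
    return truth, target, homologs, grid, constructs_for(spec)
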