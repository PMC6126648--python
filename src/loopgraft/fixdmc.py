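"""Reconstruct 1-3 missing backbone atoms from peptide-plane geometry,
add C-terminal OXT atoms, and normalize occupancies.

The five atoms CA(i), C(i), O(i), N(i+1), CA(i+1) of a trans peptide unit
are coplanar with fixed internal geometry.  Whenever at least three of
them are present, an ideal planar template is rigidly fitted onto the
present atoms and the missing ones are copied from the fitted template.
Passes repeat until no further atom can be placed, so pairs and trios that
span neighboring planes resolve incrementally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geom import (ANGLE_C_N_CA, ANGLE_CA_C_N, ANGLE_CA_C_O, BOND_C_N,
                   BOND_CA_C, BOND_C_O, BOND_N_CA)
from .homology import superpose_quaternion
from .model_io import AtomRecord, Residue, StructureModel, SequenceRecord

PLANE_ATOMS = ("CA1", "C", "O", "N2", "CA2")
PLANE_FIT_TOL = 0.05
OXT_BOND = 1.25


def _ideal_plane_template() -> dict[str, np.ndarray]:
    """Ideal trans peptide plane in 2-D (z = 0)."""
    ca1 = np.zeros(3)
    c = np.array([BOND_CA_C[0], 0.0, 0.0])
    a_n = math.radians(180.0 - ANGLE_CA_C_N[0])
    n2 = c + BOND_C_N[0] * np.array([math.cos(a_n), math.sin(a_n), 0.0])
    a_o = math.radians(180.0 - ANGLE_CA_C_O[0])
    o = c + BOND_C_O[0] * np.array([math.cos(a_o), -math.sin(a_o), 0.0])
    # CA2 in plane, trans across the C-N bond (omega = 180)
    u = (c - n2) / np.linalg.norm(c - n2)
    th = math.radians(ANGLE_C_N_CA[0])
    perp = np.array([-u[1], u[0], 0.0])
    for sgn in (1.0, -1.0):
        ca2 = n2 + BOND_N_CA[0] * (math.cos(th) * u + sgn * math.sin(th) * perp)
        # omega: dihedral CA1-C-N2-CA2 should be 180
        from .geom import dihedral
        if abs(abs(dihedral(ca1, c, n2, ca2)) - 180.0) < 1.0:
            break
    return {"CA1": ca1, "C": c, "O": o, "N2": n2, "CA2": ca2}


_TEMPLATE = _ideal_plane_template()


@dataclass
class PlaneContext:
    """The five peptide-plane atoms; missing ones are None."""
    atoms: dict[str, np.ndarray | None]

    @property
    def present(self) -> list[str]:
        return [k for k in PLANE_ATOMS if self.atoms.get(k) is not None]

    @property
    def missing(self) -> list[str]:
        return [k for k in PLANE_ATOMS if self.atoms.get(k) is None]


class CannotReconstruct(Exception):
    pass


def reconstruct_missing(context: PlaneContext) -> dict[str, np.ndarray]:
    """Coordinates for the plane's missing atoms from the fitted template.

    Requires at least three present plane atoms; the result lies in the
    best-fit plane of the present atoms by construction.
    """
    present = context.present
    if len(present) < 3:
        raise CannotReconstruct(
            f"only {len(present)} plane atoms present (need >= 3)")
    fixed = np.array([context.atoms[k] for k in present])
    moving = np.array([_TEMPLATE[k] for k in present])
    tr = superpose_quaternion(fixed, moving)
    out = {}
    for k in context.missing:
        out[k] = tr.apply(_TEMPLATE[k][None, :])[0]
    return out


def _plane_context(res0: Residue, res1: Residue) -> PlaneContext:
    def pos(res, name):
        a = res.atom(name)
        return a.pos if a is not None else None
    return PlaneContext({
        "CA1": pos(res0, "CA"), "C": pos(res0, "C"), "O": pos(res0, "O"),
        "N2": pos(res1, "N"), "CA2": pos(res1, "CA"),
    })


_ATOM_ELEMENT = {"CA1": "C", "C": "C", "O": "O", "N2": "N", "CA2": "C"}
_ATOM_OWNER = {"CA1": (0, "CA"), "C": (0, "C"), "O": (0, "O"),
               "N2": (1, "N"), "CA2": (1, "CA")}


def fix_main_chain(model: StructureModel) -> dict:
    """Fill missing backbone atoms in all chains; returns counts by size.

    Iterates peptide planes; whenever a plane has >= 3 atoms, its missing
    atoms are rebuilt in place.  Repeated passes let reconstructions in one
    plane enable the next (pairs/trios spanning planes).  Existing atoms
    are never moved.
    """
    added_per_residue: dict[tuple, int] = {}
    changed = True
    n_pass = 0
    while changed and n_pass < 8:
        changed = False
        n_pass += 1
        for chain in model.chains:
            poly = chain.polymer()
            for r0, r1 in zip(poly, poly[1:]):
                if r1.number - r0.number != 1:
                    continue
                ctx = _plane_context(r0, r1)
                if not ctx.missing or len(ctx.present) < 3:
                    continue
                try:
                    coords = reconstruct_missing(ctx)
                except CannotReconstruct:
                    continue
                b_vals = []
                for k in ctx.present:
                    ridx, nm = _ATOM_OWNER[k]
                    b_vals.append((r0, r1)[ridx].atom(nm).b)
                b_ref = float(np.mean(b_vals))
                for key, pos in coords.items():
                    ridx, name = _ATOM_OWNER[key]
                    res = (r0, r1)[ridx]
                    if res.atom(name) is not None:
                        continue
                    res.atoms.append(AtomRecord(name, _ATOM_ELEMENT[key],
                                                pos, 1.0, b_ref))
                    added_per_residue[(chain.id, res.number, res.icode)] = \
                        added_per_residue.get(
                            (chain.id, res.number, res.icode), 0) + 1
                    changed = True
    counts = {"singles": 0, "pairs": 0, "trios": 0}
    for _, n in added_per_residue.items():
        if n == 1:
            counts["singles"] += 1
        elif n == 2:
            counts["pairs"] += 1
        elif n >= 3:
            counts["trios"] += 1
    counts["atoms_added"] = sum(added_per_residue.values())
    return counts


def add_oxt(model: StructureModel,
            constructs: list[tuple[str, str]] | dict[str, str] | None = None
            ) -> list[str]:
    """Add the terminal carboxylate OXT where the construct shows the chain
    is complete.  Returns the chain ids that received an OXT.

    Skipped with a warning-style empty result when no sequence source is
    available (construct FASTA or SEQRES): without it, the last modeled
    residue cannot be identified as the true C-terminus.
    """
    if constructs is None:
        constructs = model.seqres or None
    if not constructs:
        return []
    if isinstance(constructs, dict):
        constructs = list(constructs.items())
    from .model_io import map_chain_to_construct, UnmappedChainError
    done = []
    for chain in model.chains:
        poly = chain.polymer()
        if not poly:
            continue
        mapped = None
        for _, seq in constructs:
            try:
                mapped = map_chain_to_construct(chain, seq)
                break
            except UnmappedChainError:
                continue
        if mapped is None:
            continue
        # last construct position must be the last modeled residue
        if mapped[-1] is None:
            continue
        last = poly[mapped[-1]]
        if not last.main_chain_complete or last.atom("OXT") is not None:
            continue
        ca, c, o = (last.atom(x) for x in ("CA", "C", "O"))
        # OXT symmetric to O about the CA-C axis, in the carboxylate plane
        axis = (c.pos - ca.pos) / np.linalg.norm(c.pos - ca.pos)
        vo = o.pos - c.pos
        reflected = 2.0 * np.dot(vo, axis) * axis - vo
        oxt = c.pos + reflected / np.linalg.norm(reflected) * OXT_BOND
        last.atoms.append(AtomRecord("OXT", "O", oxt, 1.0, o.b))
        done.append(chain.id)
    return done


def reset_occupancies(model: StructureModel) -> int:
    """Reset protein atom occupancies to 1.0 where the residue has no
    alternates and the bonded neighbors are at full occupancy; the carbonyl
    O only needs its C at full occupancy.  Returns the number of resets."""
    n_reset = 0
    for chain in model.chains:
        poly = chain.polymer()
        for i, res in enumerate(poly):
            if res.het and res.type != "MSE":
                continue
            if res.has_alternates or any(a.alt for a in res.atoms):
                continue
            prev_res = poly[i - 1] if i > 0 else None
            next_res = poly[i + 1] if i + 1 < len(poly) else None

            def neighbor_full(r, name):
                if r is None:
                    return True
                a = r.atom(name)
                return a is None or a.occ >= 1.0

            for a in res.atoms:
                if a.occ >= 1.0:
                    continue
                if a.name == "O" or a.name == "OXT":
                    c = res.atom("C")
                    if c is not None and c.occ >= 1.0:
                        a.occ = 1.0
                        n_reset += 1
                    continue
                ok = False
                if a.name == "N":
                    ok = neighbor_full(res, "CA") and \
                        (prev_res is None or neighbor_full(prev_res, "C"))
                elif a.name == "CA":
                    ok = neighbor_full(res, "N") and neighbor_full(res, "C")
                elif a.name == "C":
                    ok = neighbor_full(res, "CA") and \
                        (next_res is None or neighbor_full(next_res, "N"))
                elif a.name == "CB":
                    ok = neighbor_full(res, "CA")
                else:
                    # side chain: both bonded neighbors (approximated by the
                    # residue's other side-chain/backbone atoms) full
                    others = [b for b in res.atoms if b is not a]
                    ok = all(b.occ >= 1.0 for b in others)
                if ok:
                    a.occ = 1.0
                    n_reset += 1
    return n_reset


def run_fixdmc(model: StructureModel,
               constructs=None, do_oxt: bool = True,
               do_occ_reset: bool = True) -> dict:
    """Full main-chain fixing pass; returns a summary dict."""
    counts = fix_main_chain(model)
    oxt_chains = add_oxt(model, constructs) if do_oxt else []
    n_reset = reset_occupancies(model) if do_occ_reset else 0
    return {**counts, "oxt_chains": oxt_chains, "occ_resets": n_reset}
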