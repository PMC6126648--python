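"""Structure/sequence data model, PDB + mmCIF I/O, and missing-loop detection.

The in-memory model is deliberately small: chains of residues of atoms, plus
cell and symmetry. File parsing and writing are delegated to gemmi; this
module owns the completeness bookkeeping that loop building needs (case-coded
sequences, anchors, zero-occupancy stretches, alternate-conformer flags).
"""

from __future__ import annotations

import warnings

import copy
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from Bio import Align

from .geom import AA3_TO_1, MAIN_CHAIN_ATOMS

#: occupancy at or below which an atom is treated as effectively unmodeled
ZERO_OCC = 0.01

WATER_NAMES = {"HOH", "WAT", "DOD"}


class ParseError(ValueError):
    pass


class UnmappedChainError(ValueError):
    pass


@dataclass
class AtomRecord:
    name: str
    element: str
    pos: np.ndarray
    occ: float = 1.0
    b: float = 20.0
    alt: str = ""

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float)
        if not self.name:
            raise ValueError("atom name must be nonempty")
        if not (0.0 <= self.occ <= 1.0):
            raise ValueError(f"occupancy {self.occ} outside [0, 1]")
        if self.b < 0:
            raise ValueError("negative B factor")

    def copy(self) -> "AtomRecord":
        return AtomRecord(self.name, self.element, self.pos.copy(),
                          self.occ, self.b, self.alt)


@dataclass
class Residue:
    number: int
    type: str
    atoms: list[AtomRecord] = field(default_factory=list)
    icode: str = ""
    het: bool = False

    def atom(self, name: str, alt: str | None = None) -> AtomRecord | None:
        """First atom with this name (optionally restricted to one alt-loc)."""
        for a in self.atoms:
            if a.name == name and (alt is None or a.alt in ("", alt)):
                return a
        return None

    def atom_names(self) -> set[str]:
        return {a.name for a in self.atoms}

    @property
    def one_letter(self) -> str:
        return AA3_TO_1.get(self.type, "X")

    @property
    def is_water(self) -> bool:
        return self.type in WATER_NAMES

    @property
    def has_alternates(self) -> bool:
        return any(a.alt not in ("", "A") for a in self.atoms) and \
            any(a.alt == "A" for a in self.atoms)

    def backbone_alternate_atoms(self) -> set[str]:
        """Main-chain atom names that occur in more than one alt-loc."""
        seen: dict[str, set[str]] = {}
        for a in self.atoms:
            if a.name in MAIN_CHAIN_ATOMS:
                seen.setdefault(a.name, set()).add(a.alt)
        return {n for n, alts in seen.items() if len(alts) > 1}

    @property
    def main_chain_complete(self) -> bool:
        """N, CA, C, O all present at occupancy above the zero-occ cutoff."""
        for name in MAIN_CHAIN_ATOMS:
            if not any(a.name == name and a.occ > ZERO_OCC for a in self.atoms):
                return False
        return True

    @property
    def main_chain_present(self) -> bool:
        """N, CA, C, O present regardless of occupancy."""
        names = self.atom_names()
        return all(n in names for n in MAIN_CHAIN_ATOMS)

    def mean_b(self) -> float:
        return float(np.mean([a.b for a in self.atoms])) if self.atoms else 0.0

    def copy(self) -> "Residue":
        return Residue(self.number, self.type, [a.copy() for a in self.atoms],
                       self.icode, self.het)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def polymer(self) -> list[Residue]:
        """Amino-acid residues (waters and non-peptide ligands excluded)."""
        return [r for r in self.residues
                if r.type in AA3_TO_1 and not r.is_water]

    def copy(self) -> "Chain":
        return Chain(self.id, [r.copy() for r in self.residues])


@dataclass
class StructureModel:
    chains: list[Chain] = field(default_factory=list)
    cell: tuple = (1.0, 1.0, 1.0, 90.0, 90.0, 90.0)
    sym_ops: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    spacegroup: str = "P 1"
    seqres: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        ids = [c.id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate chain ids")
        if not self.sym_ops:
            self.sym_ops = [(np.eye(3), np.zeros(3))]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(chain_id)

    def all_atoms(self):
        """Yield (chain, residue, atom) triples."""
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a

    def mean_protein_b(self) -> float:
        bs = [a.b for c in self.chains for r in c.polymer() for a in r.atoms]
        if not bs:
            raise ValueError("no protein atoms")
        return float(np.mean(bs))

    def copy(self) -> "StructureModel":
        return StructureModel(
            [c.copy() for c in self.chains], tuple(self.cell),
            [(R.copy(), t.copy()) for R, t in self.sym_ops],
            self.spacegroup, dict(self.seqres))


@dataclass
class SequenceRecord:
    """Case-coded construct sequence for one chain.

    ``letters[i]`` is uppercase when construct position ``i`` has a complete
    modeled backbone, lowercase otherwise.  ``res_index[i]`` is the index of
    the mapped residue in the chain's polymer list, or ``None`` if unmodeled.
    """
    chain_id: str
    letters: str
    res_index: list[int | None] = field(default_factory=list)

    def __len__(self):
        return len(self.letters)


@dataclass
class LoopGap:
    """One internal run of incompletely modeled construct positions."""
    chain_id: str
    start: int            # 0-based construct position, inclusive
    end: int              # inclusive
    sequence: str         # 1-letter construct codes over [start, end]
    n_anchor_before: int = 0
    n_anchor_after: int = 0
    zero_occupancy_modeled: bool = False
    ca_only_alternates_in_anchor: bool = False
    partial_edge_residue_before: bool = False
    partial_edge_residue_after: bool = False
    skipped: bool = False
    skip_reason: str = ""

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("empty gap")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# gemmi-backed file I/O


def _from_gemmi(st: gemmi.Structure) -> StructureModel:
    st.setup_entities()
    chains = []
    for gch in st[0]:
        residues = []
        for gres in gch:
            atoms = [AtomRecord(ga.name, ga.element.name.upper(),
                                np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                                min(max(ga.occ, 0.0), 1.0), max(ga.b_iso, 0.0),
                                ga.altloc if ga.altloc != "\x00" else "")
                     for ga in gres]
            residues.append(Residue(gres.seqid.num, gres.name, atoms,
                                    gres.seqid.icode.strip(),
                                    gres.het_flag == "H"))
        chains.append(Chain(gch.name, residues))
    cell = (st.cell.a, st.cell.b, st.cell.c,
            st.cell.alpha, st.cell.beta, st.cell.gamma)
    ops = []
    sg = gemmi.find_spacegroup_by_name(st.spacegroup_hm or "P 1")
    if sg is not None:
        for op in sg.operations():
            ops.append((np.array(op.rot, dtype=float) / op.DEN,
                        np.array(op.tran, dtype=float) / op.DEN))
    seqres: dict[str, str] = {}
    for ent in st.entities:
        if ent.entity_type == gemmi.EntityType.Polymer and ent.full_sequence:
            seq = "".join(AA3_TO_1.get(gemmi.Entity.first_mon(m), "X")
                          for m in ent.full_sequence)
            for sub in ent.subchains:
                ch = next((c.name for c in st[0] if any(
                    res.subchain == sub for res in c)), None)
                if ch:
                    seqres[ch] = seq
    return StructureModel(chains, cell, ops, st.spacegroup_hm or "P 1", seqres)


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(*model.cell)
    st.spacegroup_hm = model.spacegroup
    gm = gemmi.Model("1")
    for ch in model.chains:
        gch = gemmi.Chain(ch.id)
        for res in ch.residues:
            gres = gemmi.Residue()
            gres.name = res.type
            gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
            gres.het_flag = "H" if res.het else "A"
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element.capitalize())
                ga.pos = gemmi.Position(*a.pos)
                ga.occ = a.occ
                ga.b_iso = a.b
                if a.alt:
                    ga.altloc = a.alt
                gres.add_atom(ga)
            gch.add_residue(gres)
        gm.add_chain(gch)
    st.add_model(gm)
    st.setup_entities()
    return st


def read_structure(path: str | Path, dialect: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF coordinate file into a StructureModel."""
    path = Path(path)
    if dialect is None:
        dialect = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if dialect == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        elif dialect == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    except (RuntimeError, ValueError, IndexError) as exc:
        raise ParseError(f"cannot parse {path} as {dialect}: {exc}") from exc
    return _from_gemmi(st)


def write_structure(model: StructureModel, path: str | Path,
                    dialect: str | None = None) -> None:
    path = Path(path)
    if dialect is None:
        dialect = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    st = _to_gemmi(model)
    if dialect == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (header, sequence) pairs."""
    records = []
    header, seq = None, []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                records.append((header, "".join(seq)))
            header, seq = line[1:].strip(), []
        else:
            seq.append(line)
    if header is not None:
        records.append((header, "".join(seq)))
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Case-coded sequences and gap detection


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 2.0
    al.mismatch_score = -10.0
    al.open_gap_score = -2.0
    al.extend_gap_score = -0.1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        al.target_end_gap_score = 0.0
        al.query_end_gap_score = 0.0
    return al


def map_chain_to_construct(chain: Chain, construct: str) -> list[int | None]:
    """Map construct positions to polymer residue indices by global alignment.

    The modeled sequence must align to the construct without internal
    mismatches; missing stretches become gaps on the model side.
    """
    poly = chain.polymer()
    modeled = "".join(r.one_letter for r in poly)
    if not modeled:
        raise UnmappedChainError(f"chain {chain.id} has no protein residues")
    construct_up = construct.upper()
    aln = _aligner().align(construct_up, modeled)[0]
    res_index: list[int | None] = [None] * len(construct_up)
    n_mismatch = 0
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for k in range(t1 - t0):
            if construct_up[t0 + k] != modeled[q0 + k] and modeled[q0 + k] != "X":
                n_mismatch += 1
            res_index[t0 + k] = q0 + k
    n_mapped = sum(i is not None for i in res_index)
    if n_mapped < len(modeled) or n_mismatch > 0:
        raise UnmappedChainError(
            f"chain {chain.id} does not map cleanly onto the construct "
            f"({len(modeled) - n_mapped} unaligned, {n_mismatch} mismatches)")
    return res_index


def extract_case_coded_sequence(
        model: StructureModel,
        constructs: list[tuple[str, str]] | dict[str, str]) -> list[SequenceRecord]:
    """Case-code each protein chain against its construct sequence.

    Uppercase marks construct positions whose mapped residue has a complete
    main chain (N, CA, C, O above the zero-occupancy cutoff); everything else
    is lowercase.  Each chain must map onto exactly one construct.
    """
    if isinstance(constructs, dict):
        constructs = list(constructs.items())
    out = []
    for chain in model.chains:
        if not chain.polymer():
            continue
        record = None
        last_err = None
        for _, seq in constructs:
            try:
                idx = map_chain_to_construct(chain, seq)
            except UnmappedChainError as exc:
                last_err = exc
                continue
            poly = chain.polymer()
            letters = []
            for pos, ri in enumerate(idx):
                code = seq[pos].upper()
                if ri is not None and poly[ri].main_chain_complete:
                    letters.append(code)
                else:
                    letters.append(code.lower())
            record = SequenceRecord(chain.id, "".join(letters), idx)
            break
        if record is None:
            raise last_err or UnmappedChainError(
                f"chain {chain.id}: no construct sequence given")
        out.append(record)
    return out


def _consecutive_modeled(letters: str, idx: int, direction: int) -> int:
    n = 0
    i = idx
    while 0 <= i < len(letters) and letters[i].isupper():
        n += 1
        i += direction
    return n


def find_missing_loops(model: StructureModel, seqs: list[SequenceRecord],
                       max_len: int = 30, min_anchor: int = 5) -> list[LoopGap]:
    """Detect internal unmodeled (or zero-occupancy) runs eligible for transfer.

    Terminal runs are never gaps.  Runs longer than ``max_len`` are dropped.
    Gaps whose anchors carry non-CA backbone alternates are returned flagged
    ``skipped`` (the alignment target is ambiguous); CA-only alternates are
    tolerated.
    """
    gaps: list[LoopGap] = []
    for rec in seqs:
        chain = model.chain(rec.chain_id)
        poly = chain.polymer()
        letters = rec.letters
        n = len(letters)
        i = 0
        while i < n:
            if letters[i].isupper():
                i += 1
                continue
            j = i
            while j < n and letters[j].islower():
                j += 1
            run = (i, j - 1)
            i = j
            start, end = run
            # terminal runs are not loops
            if start == 0 or end == n - 1:
                continue
            if end - start + 1 > max_len:
                continue
            before = _consecutive_modeled(letters, start - 1, -1)
            after = _consecutive_modeled(letters, end + 1, +1)
            gap = LoopGap(rec.chain_id, start, end,
                          letters[start:end + 1].upper(),
                          n_anchor_before=before, n_anchor_after=after)
            if before < min_anchor or after < min_anchor:
                gap.skipped = True
                gap.skip_reason = "insufficient-anchor"
            # zero-occupancy stretch: residues present, all atoms at <= 0.01
            in_run = [poly[rec.res_index[p]] for p in range(start, end + 1)
                      if rec.res_index[p] is not None]
            if len(in_run) == end - start + 1 and all(
                    r.main_chain_present and
                    all(a.occ <= ZERO_OCC for a in r.atoms) for r in in_run):
                gap.zero_occupancy_modeled = True
            # partial edge residues: gap-edge positions with some atoms modeled
            first = rec.res_index[start]
            last = rec.res_index[end]
            if first is not None and poly[first].atoms \
                    and not gap.zero_occupancy_modeled:
                gap.partial_edge_residue_before = True
            if last is not None and poly[last].atoms \
                    and not gap.zero_occupancy_modeled:
                gap.partial_edge_residue_after = True
            # alternate conformations among the anchor residues
            ca_only = False
            for p in list(range(start - min_anchor, start)) + \
                    list(range(end + 1, end + 1 + min_anchor)):
                if not (0 <= p < n) or rec.res_index[p] is None:
                    continue
                alts = poly[rec.res_index[p]].backbone_alternate_atoms()
                if alts - {"CA"}:
                    gap.skipped = True
                    gap.skip_reason = "ambiguous-alternates"
                elif alts == {"CA"}:
                    ca_only = True
            gap.ca_only_alternates_in_anchor = ca_only
            gaps.append(gap)
    return [g for g in gaps]


def backbone_complete_over(rec: SequenceRecord, chain: Chain,
                           start: int, end: int) -> bool:
    """True when every construct position in [start, end] has a complete
    backbone in this chain — the eligibility query for homolog donors."""
    poly = chain.polymer()
    for p in range(start, end + 1):
        if p < 0 or p >= len(rec.res_index):
            return False
        ri = rec.res_index[p]
        if ri is None or not poly[ri].main_chain_complete:
            return False
    return True


def deepcopy_model(model: StructureModel) -> StructureModel:
    return copy.deepcopy(model)
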