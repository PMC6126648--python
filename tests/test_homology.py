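"""Sequence pairing, anchor preparation (DEFY flips) and quaternion
superposition, cross-checked against an independent Kabsch/SVD oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from loopgraft.fixtures import FixtureSpec, build_ground_truth, make_fixture
from loopgraft.homology import (DegenerateGeometryError, AnchorSet,
                                align_homolog_sequence, collect_sources,
                                prepare_anchor_atoms, superpose_quaternion)
from loopgraft.model_io import extract_case_coded_sequence, find_missing_loops


def kabsch_rmsd(fixed, moving):
    """Independent SVD-based optimal-superposition RMSD (the oracle)."""
    fc = fixed - fixed.mean(0)
    mc = moving - moving.mean(0)
    H = mc.T @ fc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    moved = mc @ R.T
    return float(np.sqrt(np.mean(np.sum((moved - fc) ** 2, axis=1))))


class TestSuperposition:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(12, 3))
        tr = superpose_quaternion(pts, pts)
        assert tr.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(tr.matrix, np.eye(3), atol=1e-9)

    def test_pure_translation(self):
        pts = np.random.default_rng(1).normal(size=(10, 3))
        moved = pts + np.array([5.0, 0.0, 0.0])
        tr = superpose_quaternion(pts, moved)
        assert tr.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(tr.translation, [-5.0, 0.0, 0.0], atol=1e-9)

    def test_rotation_with_noise_matches_kabsch(self):
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(20, 3)) * 3
        th = np.radians(30.0)
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        moving = pts @ R.T + rng.normal(0, 0.1, size=pts.shape)
        tr = superpose_quaternion(pts, moving)
        assert tr.rmsd == pytest.approx(kabsch_rmsd(pts, moving), abs=1e-9)

    def test_rotation_always_proper(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a = rng.normal(size=(6, 3))
            b = rng.normal(size=(6, 3))
            tr = superpose_quaternion(a, b)
            assert np.linalg.det(tr.matrix) == pytest.approx(1.0, abs=1e-9)
            assert np.linalg.norm(tr.rotation_quaternion) == \
                pytest.approx(1.0, abs=1e-9)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(9, 3))
        b = rng.normal(size=(9, 3))
        assert superpose_quaternion(a, b).rmsd == \
            pytest.approx(superpose_quaternion(b, a).rmsd, abs=1e-9)

    def test_invariant_to_global_rigid_motion(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(8, 3))
        b = rng.normal(size=(8, 3))
        base = superpose_quaternion(a, b).rmsd
        th = 1.1
        R = np.array([[np.cos(th), 0, np.sin(th)], [0, 1, 0],
                      [-np.sin(th), 0, np.cos(th)]])
        t = np.array([3.0, -7.0, 2.0])
        moved = superpose_quaternion(a @ R.T + t, b @ R.T + t).rmsd
        assert moved == pytest.approx(base, abs=1e-9)

    def test_degenerate_points_raise(self):
        line = np.stack([np.array([i, 0.0, 0.0]) for i in range(5)])
        with pytest.raises(DegenerateGeometryError):
            superpose_quaternion(line, line + 1.0)
        with pytest.raises(DegenerateGeometryError):
            superpose_quaternion(np.zeros((2, 3)), np.zeros((2, 3)))

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_kabsch_oracle_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        fixed = rng.normal(size=(n, 3)) * rng.uniform(0.5, 5)
        moving = rng.normal(size=(n, 3)) * rng.uniform(0.5, 5)
        tr = superpose_quaternion(fixed, moving)
        assert tr.rmsd == pytest.approx(kabsch_rmsd(fixed, moving), abs=1e-9)


class TestSequencePairing:
    def test_identical_sequences(self):
        p = align_homolog_sequence("ACDEFGHIK", "ACDEFGHIK")
        assert p.identity_overall == 100.0
        assert p.target_to_homolog == {i: i for i in range(9)}

    def test_single_substitution_in_window(self):
        t = "ACDEFGHIKLMNPQRSTVWY"
        h = "ACDEFGHIKAMNPQRSTVWY"  # L->A at position 9
        p = align_homolog_sequence(t, h)
        assert p.identity_over(t, h, range(5, 15)) == pytest.approx(90.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_homolog_sequence("", "ACD")


class TestAnchors:
    def test_anchor_set_geometry(self):
        from loopgraft.model_io import LoopGap
        gap = LoopGap("A", 10, 13, "ABCD")
        a = AnchorSet.around(gap)
        assert a.pre_anchor == [5, 6, 7, 8]
        assert a.post_anchor == [15, 16, 17, 18]
        assert a.remodel_pair == (9, 14)

    def test_identical_anchors_pair_side_chains(self, truth):
        poly = truth.chains[0].polymer()
        res = poly[2:10]
        fixed, moving, bb = prepare_anchor_atoms(res, [r.copy() for r in res])
        n_bb = 4 * len(res)
        assert bb.sum() == n_bb
        assert len(fixed) > n_bb  # side chains joined the pairing
        assert np.allclose(fixed, moving)

    def test_mutation_crops_to_cb(self, truth):
        from loopgraft.fixtures import mutate_residue
        poly = truth.chains[0].polymer()
        res = [r.copy() for r in poly[2:10]]
        hom = [r.copy() for r in poly[2:10]]
        # mutate a Ser-like position to Ala in the homolog
        target_idx = next(i for i, r in enumerate(res)
                          if len(r.atoms) > 5)
        mutate_residue(hom[target_idx], "ALA")
        fixed, _, _ = prepare_anchor_atoms(res, hom)
        _, full, _ = prepare_anchor_atoms(res, [r.copy() for r in res])
        assert len(fixed) < len(full)

    def test_defy_flip_reduces_distance(self, truth):
        poly = truth.chains[0].polymer()
        res = [r.copy() for r in poly[0:8]]
        asp_idx = next(i for i, r in enumerate(res) if r.type == "ASP")
        hom = [r.copy() for r in res]
        asp = hom[asp_idx]
        od1 = asp.atom("OD1")
        od2 = asp.atom("OD2")
        od1.name, od2.name = "OD2", "OD1"  # administrative swap
        fixed, moving, _ = prepare_anchor_atoms(res, hom)
        # after the flip the pairing must be numerically identical again
        assert np.allclose(fixed, moving, atol=1e-9)


class TestCollectSources:
    def _setup(self, **kw):
        spec = FixtureSpec(seed=11, **kw)
        truth, target, homologs, grid, constructs = make_fixture(spec)
        seqs = extract_case_coded_sequence(target, constructs)
        gap = find_missing_loops(target, seqs)[0]
        return spec, target, homologs, seqs[0], gap

    def test_complete_homolog_yields_source(self):
        _, _, homologs, rec, gap = self._setup()
        sources = collect_sources(gap, rec, homologs)
        assert len(sources) == len(homologs)

    def test_homolog_with_missing_loop_residue_excluded(self):
        _, _, homologs, rec, gap = self._setup()
        ch = homologs[0].chains[0]
        ch.residues = [r for r in ch.residues if r.number - 1 != gap.start]
        sources = collect_sources(gap, rec, homologs)
        assert len(sources) == len(homologs) - 1

    def test_backbone_alternates_become_separate_sources(self):
        _, _, homologs, rec, gap = self._setup()
        res = homologs[0].chains[0].polymer()[gap.start]
        for name in ("N", "CA", "C", "O"):
            a = res.atom(name)
            for alt in ("A", "B"):
                dup = a.copy()
                dup.alt = alt
                dup.occ = 0.5
                if alt == "B":
                    dup.pos = dup.pos + 0.3
                res.atoms.append(dup)
        sources = collect_sources(gap, rec, homologs)
        labels = [s.label for s in sources]
        assert len(sources) == len(homologs) + 1
        assert any(s.alt == "A" for s in sources) and \
            any(s.alt == "B" for s in sources), labels

    def test_low_loop_identity_skips_homolog_except_single_residue(self):
        from loopgraft.fixtures import mutate_residue
        spec, target, homologs, rec, gap = self._setup()
        # mutate every loop residue in one homolog -> 0% loop identity
        hom = homologs[0]
        for pos in range(gap.start, gap.end + 1):
            res = hom.chains[0].polymer()[pos]
            mutate_residue(res, "TRP" if res.type != "TRP" else "PHE")
        sources = collect_sources(gap, rec, homologs)
        assert len(sources) == len(homologs) - 1

    def test_single_residue_gap_tolerates_mutation(self):
        from loopgraft.fixtures import mutate_residue
        spec = FixtureSpec(seed=12, gap_start=15, gap_end=15)
        truth, target, homologs, grid, constructs = make_fixture(spec)
        seqs = extract_case_coded_sequence(target, constructs)
        gap = find_missing_loops(target, seqs)[0]
        res = homologs[0].chains[0].polymer()[gap.start]
        mutate_residue(res, "TRP" if res.type != "TRP" else "PHE")
        sources = collect_sources(gap, seqs[0], homologs)
        assert len(sources) == len(homologs)
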