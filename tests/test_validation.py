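"""Geometry RMSZ scoring, omega/cis rules and the Ramachandran Z score."""

import numpy as np
import pytest

from loopgraft import geom
from loopgraft.fixtures import FixtureSpec, build_ground_truth
from loopgraft.geom import place_atom
from loopgraft.model_io import AtomRecord, Residue
from loopgraft.validation import (GeometryScores, RAMA_TABLES, geometry_filter,
                                  geometry_scores, rama_outlier_filter,
                                  rama_z, rama_z_from_dihedrals,
                                  sample_reference_dihedrals)


def build_backbone(n_res, phi=-63.0, psi=-42.0, bond_bump=0.0,
                   omega=180.0):
    """Backbone-only fragment from internal coordinates; ``bond_bump`` adds
    the stated multiple of each bond's sigma to its length (independent
    construction route for the RMSZ oracle)."""
    bN = geom.BOND_N_CA[0] + bond_bump * geom.BOND_N_CA[1]
    bC = geom.BOND_CA_C[0] + bond_bump * geom.BOND_CA_C[1]
    bO = geom.BOND_C_O[0] + bond_bump * geom.BOND_C_O[1]
    bP = geom.BOND_C_N[0] + bond_bump * geom.BOND_C_N[1]
    coords = []
    n0 = np.zeros(3)
    ca0 = np.array([bN, 0.0, 0.0])
    th = np.radians(geom.ANGLE_N_CA_C[0])
    c0 = ca0 + bC * np.array([-np.cos(th), np.sin(th), 0.0])
    coords.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = coords[-1]
        n = place_atom(prev["N"], prev["CA"], prev["C"], bP,
                       geom.ANGLE_CA_C_N[0], psi)
        ca = place_atom(prev["CA"], prev["C"], n, bN,
                        geom.ANGLE_C_N_CA[0], omega)
        c = place_atom(prev["C"], n, ca, bC, geom.ANGLE_N_CA_C[0], phi)
        coords.append({"N": n, "CA": ca, "C": c})
    for i, d in enumerate(coords):
        if i + 1 < len(coords):
            d["O"] = place_atom(coords[i + 1]["N"], d["CA"], d["C"], bO,
                                geom.ANGLE_CA_C_O[0], 180.0)
        else:
            d["O"] = place_atom(d["N"], d["CA"], d["C"], bO,
                                geom.ANGLE_CA_C_O[0], psi + 180.0)
    residues = []
    for i, d in enumerate(coords):
        residues.append(Residue(i + 1, "ALA", [
            AtomRecord(nm, "N" if nm == "N" else ("O" if nm == "O" else "C"),
                       d[nm]) for nm in ("N", "CA", "C", "O")]))
    return residues


class TestGeometryScores:
    def test_ideal_fragment_scores_zero(self):
        sc = geometry_scores(build_backbone(10))
        for v in sc.as_dict().values():
            assert v < 0.1

    def test_plus_one_sigma_bonds_give_rmsz_one(self):
        sc = geometry_scores(build_backbone(10, bond_bump=1.0))
        assert sc.rmsz_bond == pytest.approx(1.0, abs=0.05)
        assert sc.rmsz_angle < 0.1  # angles untouched by construction

    def test_rigid_motion_invariance(self):
        residues = build_backbone(8, bond_bump=0.5)
        base = geometry_scores(residues).as_dict()
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        t = np.array([11.0, -3.0, 5.0])
        for r in residues:
            for a in r.atoms:
                a.pos = R @ a.pos + t
        moved = geometry_scores(residues).as_dict()
        for k in base:
            assert moved[k] == pytest.approx(base[k], abs=1e-9)

    def test_missing_atom_reported(self):
        residues = build_backbone(4)
        residues[2].atoms = [a for a in residues[2].atoms if a.name != "O"]
        with pytest.raises(ValueError, match="O"):
            geometry_scores(residues)

    def test_cis_flagged(self):
        residues = build_backbone(4, omega=0.0)
        sc = geometry_scores(residues)
        assert all(sc.cis_flags)
        assert all(d < 1.0 for d in sc.omega_devs)


class TestGeometryFilter:
    def _scores(self, **kw):
        base = dict(rmsz_bond=0.5, rmsz_angle=0.5, rmsz_chir=0.5,
                    rmsz_plane=0.5, rmsz_torsion=0.5, omega_devs=[2.0, 3.0],
                    cis_flags=[False, False], cn_distances=[1.33, 1.33])
        base.update(kw)
        return GeometryScores(**base)

    @pytest.mark.parametrize("field,limit", [
        ("rmsz_bond", 1.2), ("rmsz_angle", 1.2), ("rmsz_chir", 1.5),
        ("rmsz_plane", 2.0), ("rmsz_torsion", 2.0)])
    def test_rmsz_thresholds_flip_at_boundary(self, field, limit):
        ok, _ = geometry_filter(self._scores(**{field: limit - 0.01}))
        assert ok
        bad, reason = geometry_filter(self._scores(**{field: limit + 0.01}))
        assert not bad and reason

    def test_not_converged_rejected(self):
        ok, reason = geometry_filter(self._scores(), converged=False)
        assert not ok and reason == "not-converged"

    def test_broken_peptide_bond_rejected(self):
        bad, reason = geometry_filter(
            self._scores(cn_distances=[1.33, 1.6]))
        assert not bad and reason == "broken-peptide-bond"
        ok, _ = geometry_filter(self._scores(cn_distances=[1.33, 1.49]))
        assert ok

    def test_single_omega_distortion_allowed(self):
        ok, _ = geometry_filter(
            self._scores(omega_devs=[5.0, 30.5, 2.0],
                         cis_flags=[False] * 3,
                         cn_distances=[1.33] * 3))
        assert ok

    def test_sequential_omega_distortions_rejected(self):
        bad, reason = geometry_filter(
            self._scores(omega_devs=[40.0, 41.0],
                         cn_distances=[1.33, 1.33]))
        assert not bad and reason == "sequential-omega-distortions"

    def test_boundary_thirty_degrees_not_distorted(self):
        ok, _ = geometry_filter(
            self._scores(omega_devs=[30.0, 30.0],
                         cn_distances=[1.33, 1.33]))
        assert ok

    def test_cis_only_if_source_cis(self):
        bad, reason = geometry_filter(
            self._scores(cis_flags=[True, False]),
            source_cis_flags=[False, False])
        assert not bad and reason == "cis-peptide-not-in-source"
        ok, _ = geometry_filter(
            self._scores(cis_flags=[True, False]),
            source_cis_flags=[True, False])
        assert ok


class TestRamaZ:
    def test_ideal_helix_passes(self):
        pairs = [(-63.0, -42.0)] * 20
        assert rama_z_from_dihedrals(pairs) > -5.0

    def test_uniform_random_dihedrals_poor(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            pairs = [(rng.uniform(-180, 180), rng.uniform(-180, 180))
                     for _ in range(20)]
            assert rama_z_from_dihedrals(pairs) < -5.0

    def test_reference_samples_center_on_zero(self):
        rng = np.random.default_rng(1)
        zs = [rama_z_from_dihedrals(
            sample_reference_dihedrals("general", 20, rng))
            for _ in range(200)]
        assert abs(float(np.mean(zs))) < 0.2

    def test_fragment_scoring_uses_classes(self, truth):
        score = rama_z(truth.chains[0].polymer())
        classes = {cls for _, cls, _, _, _ in score.per_residue}
        assert "general" in classes
        assert np.isfinite(score.z)

    def test_renumbering_invariance(self, truth):
        poly = [r.copy() for r in truth.chains[0].polymer()]
        base = rama_z(poly).z
        for i, r in enumerate(poly):
            r.number = 1000 + i
        assert rama_z(poly).z == pytest.approx(base, abs=1e-12)

    def test_no_scoreable_residue_raises(self):
        residues = build_backbone(1)
        with pytest.raises(ValueError):
            rama_z(residues)

    def test_modal_residue_never_decreases_mean_logodds(self):
        from loopgraft.validation import RAMA_BIN_DEG, rama_logodds
        t = RAMA_TABLES["general"]
        idx = np.unravel_index(t["logodds"].argmax(), t["logodds"].shape)
        phi = -180 + RAMA_BIN_DEG * (idx[0] + 0.5)
        psi = -180 + RAMA_BIN_DEG * (idx[1] + 0.5)
        pairs = [(-100.0, 100.0)] * 5
        mean_before = np.mean([rama_logodds(p, q, "general")
                               for p, q in pairs])
        mean_after = np.mean([rama_logodds(p, q, "general")
                              for p, q in pairs + [(phi, psi)]])
        assert mean_after >= mean_before


class TestRamaOutlierFilter:
    def test_not_invoked_above_minus_five(self):
        ok, _ = rama_outlier_filter(-4.0, [-1.0, -1.0, -1.0], [])
        assert ok

    def test_similar_peers_accept(self):
        ok, _ = rama_outlier_filter(-6.0, [-5.5, -6.2, -5.8], [])
        assert ok

    def test_outlier_vs_peers_rejected(self):
        bad, reason = rama_outlier_filter(
            -9.0, [-2.1, -2.4, -1.9, -2.2], [])
        assert not bad and "peers" in reason

    def test_outlier_vs_sources_rejected(self):
        bad, reason = rama_outlier_filter(
            -9.0, [], [-2.0, -2.5, -2.2])
        assert not bad and "sources" in reason

    def test_two_sigma_boundary(self):
        peers = [-1.0, -2.0, -3.0]  # mean -2, sd ~0.8165
        sd = float(np.std(peers))
        just_in = -2.0 - 1.99 * sd - 5.0  # ensure < -5 trigger
        # construct: z such that (mean - z)/sd crosses 2 exactly
        z_inside = -2.0 - 1.99 * sd
        z_outside = -2.0 - 2.01 * sd
        # shift population so both z values are < -5
        shift = -6.0
        peers_s = [p + shift for p in peers]
        ok, _ = rama_outlier_filter(z_inside + shift, peers_s, [])
        assert ok
        bad, _ = rama_outlier_filter(z_outside + shift, peers_s, [])
        assert not bad

    def test_small_population_skipped(self):
        ok, _ = rama_outlier_filter(-9.0, [-2.0, -2.1], [])
        assert ok
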