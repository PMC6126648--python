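"""Tricubic interpolation, synthetic maps, density ratio and RSCC/RSR."""

import numpy as np
import pytest

from loopgraft.density import (DensityFitReport, MapGrid, density_ratio,
                               interpolate_cubic, read_ccp4, rscc,
                               synthesize_map, write_ccp4, zero_out_sphere)
from loopgraft.fixtures import FixtureSpec, build_ground_truth


def grid_from_function(fn, cell=(16.0, 16.0, 16.0, 90, 90, 90), n=16):
    xs = np.arange(n) * cell[0] / n
    ys = np.arange(n) * cell[1] / n
    zs = np.arange(n) * cell[2] / n
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    return MapGrid(cell, fn(X, Y, Z))


class TestInterpolation:
    def test_exact_at_grid_nodes(self):
        rng = np.random.default_rng(0)
        grid = MapGrid((8, 8, 8, 90, 90, 90), rng.normal(size=(8, 8, 8)))
        for i, j, k in [(0, 0, 0), (3, 5, 2), (7, 7, 7)]:
            pos = np.array([i, j, k], dtype=float)
            assert interpolate_cubic(grid, pos) == \
                pytest.approx(grid.values[i, j, k], abs=1e-9)

    def test_linear_field_reproduced(self):
        grid = grid_from_function(lambda x, y, z: x + 2 * y + 3 * z)
        rng = np.random.default_rng(1)
        pts = rng.uniform(4.0, 12.0, size=(100, 3))
        vals = interpolate_cubic(grid, pts)
        expect = pts[:, 0] + 2 * pts[:, 1] + 3 * pts[:, 2]
        assert np.max(np.abs(vals - expect)) < 1e-9

    def test_cubic_field_reproduced(self):
        grid = grid_from_function(
            lambda x, y, z: 0.01 * x ** 3 - 0.2 * y ** 2 + z ** 3 / 50 + x * y)
        rng = np.random.default_rng(2)
        pts = rng.uniform(4.0, 12.0, size=(100, 3))
        vals = interpolate_cubic(grid, pts)
        expect = (0.01 * pts[:, 0] ** 3 - 0.2 * pts[:, 1] ** 2
                  + pts[:, 2] ** 3 / 50 + pts[:, 0] * pts[:, 1])
        assert np.max(np.abs(vals - expect)) < 1e-9

    def test_constant_map_constant_everywhere(self):
        grid = MapGrid((10, 10, 10, 90, 90, 90), np.full((10, 10, 10), 4.2))
        pts = np.random.default_rng(3).uniform(0, 10, size=(20, 3))
        assert np.allclose(interpolate_cubic(grid, pts), 4.2, atol=1e-9)

    def test_gradient_matches_finite_difference(self):
        grid = grid_from_function(
            lambda x, y, z: np.sin(x / 3) + np.cos(y / 4) * z / 8)
        pt = np.array([7.3, 6.1, 8.8])
        _, g = interpolate_cubic(grid, pt, gradient=True)
        h = 1e-6
        for ax in range(3):
            dp = pt.copy()
            dp[ax] += h
            dm = pt.copy()
            dm[ax] -= h
            num = (interpolate_cubic(grid, dp)
                   - interpolate_cubic(grid, dm)) / (2 * h)
            assert g[ax] == pytest.approx(num, abs=1e-5)

    def test_nonfinite_position_rejected(self):
        grid = MapGrid((8, 8, 8, 90, 90, 90), np.zeros((8, 8, 8)))
        with pytest.raises(ValueError):
            interpolate_cubic(grid, np.array([np.nan, 0, 0]))

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            MapGrid((8, 8, 8, 90, 90, 90), np.zeros((3, 8, 8)))


class TestSynthesizeMap:
    def test_peak_at_atom_and_monotone_decay(self, truth):
        from loopgraft.model_io import AtomRecord, Chain, Residue, \
            StructureModel
        model = StructureModel([Chain("A", [Residue(1, "GLY", [
            AtomRecord("CA", "C", np.array([8.0, 8.0, 8.0]))])])],
            cell=(16, 16, 16, 90, 90, 90))
        grid = synthesize_map(model, b_blur=20.0, spacing=0.5)
        center = interpolate_cubic(grid, np.array([8.0, 8.0, 8.0]))
        last = center
        for r in (0.5, 1.0, 1.5, 2.0):
            v = interpolate_cubic(grid, np.array([8.0 + r, 8.0, 8.0]))
            assert v < last
            last = v

    def test_peak_heights_proportional_to_electrons(self):
        from loopgraft.model_io import AtomRecord, Chain, Residue, \
            StructureModel
        model = StructureModel([Chain("A", [Residue(1, "CYS", [
            AtomRecord("C", "C", np.array([5.0, 8.0, 8.0]), b=10.0),
            AtomRecord("SG", "S", np.array([15.0, 8.0, 8.0]), b=10.0),
        ])])], cell=(20, 16, 16, 90, 90, 90))
        grid = synthesize_map(model, b_blur=20.0, spacing=0.4)
        vc = interpolate_cubic(grid, np.array([5.0, 8.0, 8.0]))
        vs = interpolate_cubic(grid, np.array([15.0, 8.0, 8.0]))
        assert vs / vc == pytest.approx(16.0 / 6.0, rel=1e-3)

    def test_occupancy_linearity(self):
        from loopgraft.model_io import AtomRecord, Chain, Residue, \
            StructureModel

        def one(occ):
            m = StructureModel([Chain("A", [Residue(1, "GLY", [
                AtomRecord("CA", "C", np.array([8.0, 8.0, 8.0]), occ=occ)])])],
                cell=(16, 16, 16, 90, 90, 90))
            g = synthesize_map(m, b_blur=20.0, spacing=0.5)
            return interpolate_cubic(g, np.array([8.0, 8.0, 8.0]))

        assert one(1.0) == pytest.approx(2 * one(0.5), rel=1e-9)

    def test_bad_spacing_rejected(self, truth):
        with pytest.raises(ValueError):
            synthesize_map(truth, spacing=0.0)


class TestDensityRatio:
    def _loop(self, positions):
        from loopgraft.model_io import AtomRecord, Residue
        residues = []
        for i, p in enumerate(positions):
            residues.append(Residue(i + 1, "GLY", [
                AtomRecord(nm, "C" if nm != "O" else "O", np.asarray(p))
                for nm in ("N", "CA", "C", "O")]))
        return residues

    def test_equal_heights_give_ratio_one(self):
        grid = MapGrid((16, 16, 16, 90, 90, 90), np.full((16, 16, 16), 2.0))
        loop = self._loop([[8, 8, 8]])
        rep = density_ratio(loop, np.array([[4.0, 4.0, 4.0]]), grid)
        assert rep.ratio == pytest.approx(1.0, abs=1e-9)
        assert rep.acceptable

    def test_zero_density_loop_rejected(self):
        vals = np.full((16, 16, 16), 1.0)
        vals[6:11, 6:11, 6:11] = 0.0
        grid = MapGrid((16, 16, 16, 90, 90, 90), vals)
        loop = self._loop([[8, 8, 8]])
        rep = density_ratio(loop, np.array([[2.0, 2.0, 2.0]]), grid)
        assert rep.ratio == pytest.approx(0.0, abs=1e-9)
        assert not rep.acceptable

    def test_half_height_gives_half_ratio(self):
        vals = np.ones((32, 16, 16))
        vals[:16] = 0.5
        grid = MapGrid((32, 16, 16, 90, 90, 90), vals)
        loop = self._loop([[8, 8, 8]])
        rep = density_ratio(loop, np.array([[24.0, 8.0, 8.0]]), grid)
        assert rep.ratio == pytest.approx(0.5, abs=0.05)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0.5, 2.0, size=(16, 16, 16))
        g1 = MapGrid((16, 16, 16, 90, 90, 90), vals)
        g2 = MapGrid((16, 16, 16, 90, 90, 90), vals * 7.5)
        loop = self._loop([[8, 8, 8]])
        ctrl = np.array([[4.0, 4.0, 4.0], [12.0, 12.0, 12.0]])
        assert density_ratio(loop, ctrl, g1).ratio == \
            pytest.approx(density_ratio(loop, ctrl, g2).ratio, rel=1e-12)

    def test_empty_control_rejected(self):
        grid = MapGrid((16, 16, 16, 90, 90, 90), np.ones((16, 16, 16)))
        with pytest.raises(ValueError):
            density_ratio(self._loop([[8, 8, 8]]), np.zeros((0, 3)), grid)


class TestRscc:
    def _maps(self, seed=0, snr=None):
        spec = FixtureSpec(seed=seed)
        truth = build_ground_truth(spec)
        calc = synthesize_map(truth, b_blur=15.0, spacing=0.9)
        obs = MapGrid(calc.cell, calc.values.copy())
        if snr:
            rng = np.random.default_rng(seed)
            obs.values = obs.values + rng.normal(
                0, obs.values.std() / snr, obs.values.shape)
        pts = np.array([a.pos for _, _, a in truth.all_atoms()])
        return pts, obs, calc

    def test_identical_maps(self):
        pts, obs, calc = self._maps()
        cc, rsr = rscc(pts[:40], obs, calc)
        assert cc == pytest.approx(1.0, abs=1e-12)
        assert rsr == pytest.approx(0.0, abs=1e-12)

    def test_negated_map_gives_minus_one(self):
        pts, obs, calc = self._maps()
        obs.values = -obs.values
        cc, _ = rscc(pts[:40], obs, calc)
        assert cc == pytest.approx(-1.0, abs=1e-12)

    def test_matches_brute_force_pearson(self):
        pts, obs, calc = self._maps(seed=2, snr=5)
        from loopgraft.density import _mask_indices
        idx = _mask_indices(obs, pts[:30], 2.0)
        o = obs.values[idx]
        c = calc.values[idx]
        expect = float(np.corrcoef(o, c)[0, 1])
        cc, rsr = rscc(pts[:30], obs, calc)
        assert cc == pytest.approx(expect, abs=1e-12)
        assert rsr == pytest.approx(
            float(np.sum(np.abs(o - c)) / np.sum(np.abs(o + c))), abs=1e-12)

    def test_affine_rescale_invariance(self):
        pts, obs, calc = self._maps(seed=3, snr=4)
        cc1, _ = rscc(pts[:30], obs, calc)
        obs.values = 3.0 * obs.values + 10.0
        cc2, _ = rscc(pts[:30], obs, calc)
        assert cc1 == pytest.approx(cc2, abs=1e-12)

    def test_zero_variance_region_rejected(self):
        grid = MapGrid((16, 16, 16, 90, 90, 90), np.ones((16, 16, 16)))
        with pytest.raises(ValueError):
            rscc(np.array([[8.0, 8.0, 8.0]]), grid, grid)


def test_zero_out_sphere():
    grid = MapGrid((16, 16, 16, 90, 90, 90), np.ones((16, 16, 16)))
    zero_out_sphere(grid, np.array([8.0, 8.0, 8.0]), 3.0)
    assert interpolate_cubic(grid, np.array([8.0, 8.0, 8.0])) == \
        pytest.approx(0.0, abs=1e-9)
    assert interpolate_cubic(grid, np.array([1.0, 1.0, 1.0])) == \
        pytest.approx(1.0, abs=1e-9)


def test_ccp4_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    grid = MapGrid((12, 10, 8, 90, 90, 90),
                   rng.normal(size=(12, 10, 8)).astype(np.float32))
    path = tmp_path / "map.ccp4"
    write_ccp4(grid, path)
    back = read_ccp4(path)
    assert back.shape == grid.shape
    assert np.allclose(back.values, grid.values, atol=1e-6)
    assert np.allclose(back.cell, grid.cell, atol=1e-4)
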