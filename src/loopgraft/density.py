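"""Density-map handling: tricubic interpolation, synthetic Gaussian maps,
density-ratio acceptance and real-space fit statistics (RSCC/RSR).

Maps are whole-cell periodic scalar grids; grid node (i, j, k) sits at
fractional coordinate (i/nx, j/ny, k/nz).  Interpolation is tensor-product
4-point Lagrange cubic, which is exact for per-axis polynomials of degree
up to three and exact at grid nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np

from .geom import ELEMENT_ELECTRONS, MAIN_CHAIN_ATOMS

#: minimum mean-density ratio between loop main chain and the control set
DENSITY_RATIO_MIN = 0.25
#: the always-ordered control set must have at least this many atoms
CONTROL_MIN_ATOMS = 30
RSCC_MASK_RADIUS = 2.0
DEFAULT_GRID_SPACING = 0.7


@dataclass
class MapGrid:
    cell: tuple                 # a, b, c, alpha, beta, gamma
    values: np.ndarray          # (nx, ny, nz)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 4:
            raise ValueError("map grid must be 3-D with >= 4 nodes per axis")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite map values")
        self._ucell = gemmi.UnitCell(*self.cell)
        self.orth_mat = np.array(self._ucell.orth.mat.tolist())
        self.frac_mat = np.array(self._ucell.frac.mat.tolist())

    @property
    def shape(self):
        return self.values.shape

    def fractionalize(self, pos: np.ndarray) -> np.ndarray:
        return np.asarray(pos, dtype=float) @ self.frac_mat.T

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.orth_mat.T

    def node_value(self, i: int, j: int, k: int) -> float:
        n = self.shape
        return float(self.values[i % n[0], j % n[1], k % n[2]])


def _lagrange_weights(t: np.ndarray, deriv: bool = False) -> np.ndarray:
    """Cubic Lagrange basis on nodes {-1, 0, 1, 2} evaluated at t in [0, 1)."""
    if not deriv:
        return np.stack([
            -t * (t - 1) * (t - 2) / 6.0,
            (t + 1) * (t - 1) * (t - 2) / 2.0,
            -(t + 1) * t * (t - 2) / 2.0,
            (t + 1) * t * (t - 1) / 6.0,
        ], axis=-1)
    return np.stack([
        -(3 * t * t - 6 * t + 2) / 6.0,
        (3 * t * t - 4 * t - 1) / 2.0,
        -(3 * t * t - 2 * t - 2) / 2.0,
        (3 * t * t - 1) / 6.0,
    ], axis=-1)


def interpolate_cubic(grid: MapGrid, pos: np.ndarray,
                      gradient: bool = False):
    """Tricubic (tensor Lagrange) interpolation at Cartesian position(s).

    With ``gradient=True`` returns (values, gradients) where gradients are
    with respect to Cartesian coordinates (density units per Angstrom).
    """
    pos = np.asarray(pos, dtype=float)
    single = pos.ndim == 1
    pts = pos[None, :] if single else pos
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite position")
    n = np.array(grid.shape)
    u = grid.fractionalize(pts) * n            # grid coordinates
    i0 = np.floor(u).astype(int)
    t = u - i0
    w = [_lagrange_weights(t[:, ax]) for ax in range(3)]
    idx = [(i0[:, ax, None] + np.arange(-1, 3)[None, :]) % n[ax]
           for ax in range(3)]
    # gather 4x4x4 neighborhoods: (npts, 4, 4, 4)
    block = grid.values[idx[0][:, :, None, None],
                        idx[1][:, None, :, None],
                        idx[2][:, None, None, :]]
    vals = np.einsum("pijk,pi,pj,pk->p", block, w[0], w[1], w[2])
    if not gradient:
        return float(vals[0]) if single else vals
    dw = [_lagrange_weights(t[:, ax], deriv=True) for ax in range(3)]
    du = np.stack([
        np.einsum("pijk,pi,pj,pk->p", block, dw[0], w[1], w[2]),
        np.einsum("pijk,pi,pj,pk->p", block, w[0], dw[1], w[2]),
        np.einsum("pijk,pi,pj,pk->p", block, w[0], w[1], dw[2]),
    ], axis=-1)
    # chain rule: u = n * F @ pos
    grads = (du * n[None, :]) @ grid.frac_mat
    if single:
        return float(vals[0]), grads[0]
    return vals, grads


# ---------------------------------------------------------------------------
# Synthetic maps


def synthesize_map(model, b_blur: float = 20.0,
                   spacing: float = DEFAULT_GRID_SPACING,
                   cell: tuple | None = None,
                   shape: tuple | None = None) -> MapGrid:
    """Sum-of-Gaussians density for a model: one isotropic Gaussian per atom,
    width from (B + b_blur), amplitude proportional to electron count times
    occupancy, sampled on the cell grid with periodic wrap.  ``shape`` forces
    the grid dimensions (for commensurate calc/obs map pairs)."""
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    cell = tuple(cell) if cell is not None else tuple(model.cell)
    ucell = gemmi.UnitCell(*cell)
    if shape is not None:
        dims = tuple(int(s) for s in shape)
    else:
        dims = tuple(max(4, int(np.ceil(ucell.parameters[i] / spacing)))
                     for i in range(3))
    values = np.zeros(dims)
    grid = MapGrid(cell, values)
    grid.values = values  # stamp in place
    n = np.array(dims)
    atoms = [(a.pos, ELEMENT_ELECTRONS.get(a.element, 6) * a.occ, a.b)
             for c, r, a in model.all_atoms() if a.occ > 0 and a.element != "H"]
    for pos, ne, b in atoms:
        if ne <= 0:
            continue
        sigma2 = (b + b_blur) / (8.0 * np.pi ** 2)
        sigma = np.sqrt(sigma2)
        amp = ne / (2 * np.pi * sigma2) ** 1.5
        cutoff = 4.0 * sigma
        frac = grid.fractionalize(pos)
        center = frac * n
        # per-axis half-widths in grid units (orthogonal estimate w/ margins)
        lengths = np.array([ucell.parameters[i] for i in range(3)])
        half = np.ceil(cutoff / lengths * n).astype(int) + 1
        ranges = [np.arange(int(np.floor(center[ax])) - half[ax],
                            int(np.floor(center[ax])) + half[ax] + 1)
                  for ax in range(3)]
        fr = np.stack(np.meshgrid(*[r / n[ax] for ax, r in enumerate(ranges)],
                                  indexing="ij"), axis=-1)
        cart = fr @ grid.orth_mat.T
        d2 = np.sum((cart - pos) ** 2, axis=-1)
        contrib = amp * np.exp(-d2 / (2.0 * sigma2))
        contrib[d2 > cutoff ** 2] = 0.0
        ii = ranges[0] % n[0]
        jj = ranges[1] % n[1]
        kk = ranges[2] % n[2]
        np.add.at(values, np.ix_(ii, jj, kk), contrib)
    return grid


def zero_out_sphere(grid: MapGrid, center: np.ndarray, radius: float) -> None:
    """Zero map values at all grid nodes within radius of a Cartesian point."""
    n = np.array(grid.shape)
    frac = grid.fractionalize(np.asarray(center, dtype=float))
    c = frac * n
    lengths = np.array([grid._ucell.parameters[i] for i in range(3)])
    half = np.ceil(radius / lengths * n).astype(int) + 1
    ranges = [np.arange(int(np.floor(c[ax])) - half[ax],
                        int(np.floor(c[ax])) + half[ax] + 1)
              for ax in range(3)]
    fr = np.stack(np.meshgrid(*[r / n[ax] for ax, r in enumerate(ranges)],
                              indexing="ij"), axis=-1)
    cart = fr @ grid.orth_mat.T
    mask = np.sum((cart - center) ** 2, axis=-1) <= radius ** 2
    ii = ranges[0] % n[0]
    jj = ranges[1] % n[1]
    kk = ranges[2] % n[2]
    sub = grid.values[np.ix_(ii, jj, kk)]
    sub[mask] = 0.0
    grid.values[np.ix_(ii, jj, kk)] = sub


# ---------------------------------------------------------------------------
# Density-fit statistics


@dataclass
class DensityFitReport:
    loop_mean: float
    control_mean: float
    ratio: float
    rscc: float = float("nan")
    rsr: float = float("nan")
    control_set_size: int = 0

    @property
    def acceptable(self) -> bool:
        return self.ratio > DENSITY_RATIO_MIN


def main_chain_positions(residues) -> np.ndarray:
    pts = []
    for r in residues:
        for name in MAIN_CHAIN_ATOMS:
            a = r.atom(name)
            if a is not None:
                pts.append(a.pos)
    return np.array(pts)


def density_ratio(loop_residues, control_positions: np.ndarray,
                  grid: MapGrid,
                  ratio_min: float = DENSITY_RATIO_MIN) -> DensityFitReport:
    """Mean interpolated density over loop main-chain atoms, relative to the
    mean over the control set of reliably ordered main-chain atoms."""
    control_positions = np.asarray(control_positions, dtype=float)
    if control_positions.size == 0:
        raise ValueError("empty density control set")
    loop_pos = main_chain_positions(loop_residues)
    loop_mean = float(np.mean(interpolate_cubic(grid, loop_pos)))
    control_mean = float(np.mean(interpolate_cubic(grid, control_positions)))
    if control_mean <= 0:
        raise ValueError("control mean density is not positive")
    return DensityFitReport(loop_mean, control_mean, loop_mean / control_mean,
                            control_set_size=len(control_positions))


def _mask_indices(grid: MapGrid, positions: np.ndarray, radius: float):
    n = np.array(grid.shape)
    lengths = np.array([grid._ucell.parameters[i] for i in range(3)])
    sel = set()
    for pos in np.atleast_2d(positions):
        c = grid.fractionalize(pos) * n
        half = np.ceil(radius / lengths * n).astype(int) + 1
        ranges = [np.arange(int(np.floor(c[ax])) - half[ax],
                            int(np.floor(c[ax])) + half[ax] + 1)
                  for ax in range(3)]
        fr = np.stack(np.meshgrid(*[r / n[ax] for ax, r in enumerate(ranges)],
                                  indexing="ij"), axis=-1)
        cart = fr @ grid.orth_mat.T
        mask = np.sum((cart - pos) ** 2, axis=-1) <= radius ** 2
        ii, jj, kk = np.nonzero(mask)
        for a, b, cc in zip(ii, jj, kk):
            sel.add((int(ranges[0][a] % n[0]), int(ranges[1][b] % n[1]),
                     int(ranges[2][cc] % n[2])))
    if not sel:
        return None
    arr = np.array(sorted(sel))
    return arr[:, 0], arr[:, 1], arr[:, 2]


def rscc(positions: np.ndarray, obs: MapGrid, calc: MapGrid,
         radius: float = RSCC_MASK_RADIUS) -> tuple[float, float]:
    """Real-space correlation coefficient and real-space R over the grid
    points within ``radius`` of the atom positions.  Returns (RSCC, RSR)."""
    if obs.shape != calc.shape:
        raise ValueError("maps are not on commensurate grids")
    idx = _mask_indices(obs, positions, radius)
    if idx is None:
        raise ValueError("empty mask region")
    o = obs.values[idx]
    c = calc.values[idx]
    if np.std(o) < 1e-15 or np.std(c) < 1e-15:
        raise ValueError("zero-variance region: correlation undefined")
    cc = float(np.corrcoef(o, c)[0, 1])
    denom = float(np.sum(np.abs(o + c)))
    rsr = float(np.sum(np.abs(o - c)) / denom) if denom > 0 else float("nan")
    return cc, rsr


# ---------------------------------------------------------------------------
# CCP4/MRC I/O (gemmi-backed)


def read_ccp4(path) -> MapGrid:
    m = gemmi.read_ccp4_map(str(path))
    m.setup(float("nan"))
    cell = m.grid.unit_cell
    values = np.array(m.grid, copy=True).astype(float)
    return MapGrid((cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma),
                   values)


def write_ccp4(grid: MapGrid, path) -> None:
    g = gemmi.FloatGrid(np.ascontiguousarray(grid.values, dtype=np.float32))
    g.unit_cell = gemmi.UnitCell(*grid.cell)
    g.spacegroup = gemmi.find_spacegroup_by_name("P 1")
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))
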