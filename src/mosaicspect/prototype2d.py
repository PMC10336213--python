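"""Simulation of the 2-D experimental prototype.

A single 67.5 x 67.5 x 20 mm detector block holds 128 GAGG(Ce) bars
(2.1 x 2.1 mm cross-section) on a 16 x 16 checkerboard at 4.2-mm pitch.
Rotating a planar source about the FOV axis in 13 steps is equivalent to a
virtual half-ring of 13 such detectors, giving 13 x 128 = 1664 detector
bins over a 100 x 100 mm planar FOV.

The measured single-detector response (here: Monte Carlo simulated on the
35 x 35 source grid at 3-mm pitch) is expanded to the 103 x 103 grid at
1-mm pitch by bicubic spline interpolation, and the ring matrix is
assembled by rotational symmetry.  Transport is in-plane: bars are treated
as infinite along z for the planar FOV, and the physical sub-millimetre
point source is modelled as ideal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.interpolate import RectBivariateSpline
from scipy.ndimage import map_coordinates

from .physics import (ELECTRON_REST_KEV, EnergyModel, MaterialTable,
                      _mu_mm, _sample_kn_cos)
from .recon import ProjectionVector
from .transport import ENERGY_CUTOFF_KEV, FWHM_TO_SIGMA, _circle_interval

__all__ = [
    "PrototypeGeometry", "PrototypeSysmat", "coarse_source_grid",
    "fine_source_grid", "simulate_single_detector_matrix", "expand_grid",
    "assemble_ring", "multi_point_projection",
]

N_BARS = 128
GRID_N = 16
PITCH_MM = 4.2
BAR_HALF_MM = 1.05           # 2.1-mm bar centred in its 4.2-mm cell
N_RING_POSITIONS = 13
RING_STEP_DEG = 15.0
COARSE_GRID = np.arange(-51.0, 52.0, 3.0)    # 35 positions
FINE_GRID = np.arange(-51.0, 52.0, 1.0)      # 103 positions


@dataclass
class PrototypeGeometry:
    """Single checkerboard detector block facing the rotation axis."""

    face_distance_mm: float = 125.0       # front face to rotation axis
    pitch: float = PITCH_MM
    grid_n: int = GRID_N
    bar_half: float = BAR_HALF_MM
    parity: int = 0                       # (row+col) % 2 of occupied cells
    world_radius_mm: float = 350.0

    @property
    def half_size(self) -> float:
        return self.grid_n * self.pitch / 2.0

    @property
    def center_distance(self) -> float:
        return self.face_distance_mm + self.half_size

    @property
    def n_bars(self) -> int:
        return self.grid_n * self.grid_n // 2

    def occupied_cells(self) -> np.ndarray:
        rows, cols = np.indices((self.grid_n, self.grid_n))
        return (rows + cols) % 2 == self.parity

    def bar_centers(self) -> np.ndarray:
        """(n_bars, 2) world (x, y) of bar centres for the 0-degree pose."""
        rows, cols = np.nonzero(self.occupied_cells())
        u = (rows + 0.5) * self.pitch - self.half_size + self.center_distance
        v = (cols + 0.5) * self.pitch - self.half_size
        return np.column_stack([u, v])


def coarse_source_grid() -> np.ndarray:
    return COARSE_GRID.copy()


def fine_source_grid() -> np.ndarray:
    return FINE_GRID.copy()


@njit(cache=True)
def _proto_point_run(sx, sy, n, seed, det_cx, pitch, half, grid_n, bar_half,
                     parity, world_r, mu_pe140, mu_inc140, resolution,
                     win_lo, win_hi, pe_force):
    """In-plane transport of ``n`` photons from a point source; 128 bin counts."""
    np.random.seed(seed)
    n_bars = grid_n * grid_n // 2
    counts = np.zeros(n_bars, dtype=np.int64)
    world_r2 = world_r * world_r
    dep_bin = np.empty(64, dtype=np.int64)
    dep_e = np.empty(64, dtype=np.float64)

    for _ in range(n):
        x, y = sx, sy
        ph = 2.0 * math.pi * np.random.random()
        dx, dy = math.cos(ph), math.sin(ph)
        e = 140.0
        ndep = 0
        mu_maj = _mu_mm(1, e, mu_pe140, mu_inc140)
        bound_r = half * math.sqrt(2.0) + 1e-3

        while True:
            # fly through air up to the detector's bounding circle
            t0, t1 = _circle_interval(x, y, dx, dy, det_cx, 0.0, bound_r)
            if t1 <= t0 or t1 <= 0.0:
                break
            if t0 > 0.0:
                x += dx * (t0 + 1e-6)
                y += dy * (t0 + 1e-6)
            step = -math.log(np.random.random()) / mu_maj
            x += dx * step
            y += dy * step
            if x * x + y * y > world_r2:
                break
            u = x - det_cx
            v = y
            mat = 0
            flat = -1
            if -half <= u < half and -half <= v < half:
                iu = int((u + half) / pitch)
                iv = int((v + half) / pitch)
                if iu >= grid_n:
                    iu = grid_n - 1
                if iv >= grid_n:
                    iv = grid_n - 1
                if (iu + iv) % 2 == parity:
                    du = u - ((iu + 0.5) * pitch - half)
                    dv = v - ((iv + 0.5) * pitch - half)
                    if abs(du) <= bar_half and abs(dv) <= bar_half:
                        mat = 1
                        flat = (iu * grid_n + iv) // 2
            if mat == 0:
                continue
            mu = _mu_mm(mat, e, mu_pe140, mu_inc140)
            if np.random.random() * mu_maj > mu:
                continue
            if pe_force >= 0.0:
                p_pe = pe_force
            else:
                p_pe = (mu_pe140[mat] * (140.0 / e) ** 3) / mu
            if np.random.random() < p_pe:
                dep_bin[ndep] = flat
                dep_e[ndep] = e
                ndep += 1
                break
            cos_sc = _sample_kn_cos(e)
            e_new = e / (1.0 + (e / ELECTRON_REST_KEV) * (1.0 - cos_sc))
            if ndep < 64:
                dep_bin[ndep] = flat
                dep_e[ndep] = e - e_new
                ndep += 1
            else:
                dep_e[ndep - 1] += e - e_new
            sgn = 1.0 if np.random.random() < 0.5 else -1.0
            sin_sc = sgn * math.sqrt(max(0.0, 1.0 - cos_sc * cos_sc))
            dx, dy = cos_sc * dx - sin_sc * dy, sin_sc * dx + cos_sc * dy
            if e_new < ENERGY_CUTOFF_KEV:
                if ndep < 64:
                    dep_bin[ndep] = flat
                    dep_e[ndep] = e_new
                    ndep += 1
                else:
                    dep_e[ndep - 1] += e_new
                break
            e = e_new
            mu_maj = _mu_mm(1, e, mu_pe140, mu_inc140)

        if ndep == 0:
            continue
        gagg_sum = 0.0
        for d in range(ndep):
            gagg_sum += dep_e[d]
        best = 0
        for d in range(1, ndep):
            if dep_e[d] > dep_e[best] or \
               (dep_e[d] == dep_e[best] and dep_bin[d] < dep_bin[best]):
                best = d
        sigma = resolution * math.sqrt(140.0 * gagg_sum) * FWHM_TO_SIGMA
        e_meas = gagg_sum + sigma * np.random.standard_normal()
        if win_lo <= e_meas <= win_hi:
            counts[dep_bin[best]] += 1

    return counts


def simulate_single_detector_matrix(geom: PrototypeGeometry | None = None,
                                    n_per_position: int = 50_000,
                                    seed: int = 0,
                                    source_grid: np.ndarray | None = None,
                                    energy_model: EnergyModel | None = None,
                                    material_table: MaterialTable | None = None,
                                    pe_force: float | None = None) -> np.ndarray:
    """Simulated per-position detector response on the coarse source grid.

    Returns an array of shape ``(nx, ny, 128)``: the detection probability
    per emitted (in-plane) photon for each of the 35 x 35 source positions.
    """
    geom = geom or PrototypeGeometry()
    grid = coarse_source_grid() if source_grid is None else np.asarray(source_grid)
    model = energy_model or EnergyModel()
    table = material_table or MaterialTable()
    mu_pe, mu_inc = table.packed()
    out = np.empty((grid.size, grid.size, geom.n_bars))
    for ix, sx in enumerate(grid):
        for iy, sy in enumerate(grid):
            sub_seed = (seed + 1_000_003 * (ix * grid.size + iy)) % (2**31 - 1)
            counts = _proto_point_run(
                float(sx), float(sy), int(n_per_position), sub_seed,
                geom.center_distance, geom.pitch, geom.half_size, geom.grid_n,
                geom.bar_half, geom.parity, geom.world_radius_mm,
                mu_pe, mu_inc, model.resolution,
                model.window_kev[0], model.window_kev[1],
                -1.0 if pe_force is None else float(pe_force))
            out[ix, iy] = counts / n_per_position
    return out


def expand_grid(coarse: np.ndarray, coarse_xy: np.ndarray | None = None,
                fine_xy: np.ndarray | None = None) -> np.ndarray:
    """Bicubic-spline expansion of per-bin responses to the fine source grid.

    Negative interpolants are clipped to zero; requesting points outside the
    coarse hull raises.
    """
    cx = coarse_source_grid() if coarse_xy is None else np.asarray(coarse_xy)
    fx = fine_source_grid() if fine_xy is None else np.asarray(fine_xy)
    if fx.min() < cx.min() - 1e-9 or fx.max() > cx.max() + 1e-9:
        raise ValueError("target grid extends outside the measured hull")
    n_bins = coarse.shape[2]
    fine = np.empty((fx.size, fx.size, n_bins))
    for b in range(n_bins):
        spl = RectBivariateSpline(cx, cx, coarse[:, :, b], kx=3, ky=3, s=0)
        fine[:, :, b] = spl(fx, fx)
    return np.clip(fine, 0.0, None)


@dataclass
class PrototypeSysmat:
    """Dense 13-position ring matrix: (13 x 128) bins x (103 x 103) voxels."""

    matrix: np.ndarray
    grid_xy: np.ndarray
    n_positions: int = N_RING_POSITIONS
    step_deg: float = RING_STEP_DEG
    n_masked: int = 0
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.matrix.shape

    @property
    def n_voxels(self) -> int:
        return self.grid_xy.size ** 2

    def voxel_index(self, x_mm: float, y_mm: float) -> int:
        ix = int(np.argmin(np.abs(self.grid_xy - x_mm)))
        iy = int(np.argmin(np.abs(self.grid_xy - y_mm)))
        return ix * self.grid_xy.size + iy


def assemble_ring(fine: np.ndarray, n_positions: int = N_RING_POSITIONS,
                  step_deg: float = RING_STEP_DEG,
                  fine_xy: np.ndarray | None = None) -> PrototypeSysmat:
    """Assemble the virtual-ring matrix from the single-detector response.

    Position ``p`` (detector rotated by ``p * step_deg - 90 deg``) responds
    to a source at (x, y) as the 0-degree detector responds to the source
    rotated the opposite way; rotated points falling outside the fine-grid
    hull get zero response and are counted in ``n_masked``.  Rows are
    concatenated module-major: row = position * 128 + bar.
    """
    fx = fine_source_grid() if fine_xy is None else np.asarray(fine_xy)
    n_bins = fine.shape[2]
    ng = fx.size
    xx, yy = np.meshgrid(fx, fx, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    A = np.zeros((n_positions * n_bins, ng * ng))
    n_masked = 0
    origin, pitch = fx[0], fx[1] - fx[0]
    start = -(n_positions - 1) / 2.0 * step_deg
    for p in range(n_positions):
        ang = math.radians(start + p * step_deg)
        ca, sa = math.cos(ang), math.sin(ang)
        # rotate sources by -ang into the detector-0 frame
        rx = ca * pts[:, 0] + sa * pts[:, 1]
        ry = -sa * pts[:, 0] + ca * pts[:, 1]
        inside = (rx >= fx[0]) & (rx <= fx[-1]) & (ry >= fx[0]) & (ry <= fx[-1])
        n_masked += int((~inside).sum())
        ci = (np.clip(rx, fx[0], fx[-1]) - origin) / pitch
        cj = (np.clip(ry, fx[0], fx[-1]) - origin) / pitch
        for b in range(n_bins):
            vals = map_coordinates(fine[:, :, b], np.vstack([ci, cj]),
                                   order=1, mode="nearest")
            vals[~inside] = 0.0
            A[p * n_bins + b] = vals
    return PrototypeSysmat(A, fx, n_positions, step_deg, n_masked)


def multi_point_projection(sources, A: PrototypeSysmat, counts_budget: float,
                           rng: np.random.Generator) -> ProjectionVector:
    """Poisson projection of weighted point sources.

    ``sources`` is a list of ``(x_mm, y_mm, weight)``; ``counts_budget`` is
    the total number of emitted photons shared between the sources in
    proportion to their weights (the expected detected counts follow from
    the per-photon sensitivities in ``A``).
    """
    if not sources:
        raise ValueError("empty source list")
    weights = np.array([w for _, _, w in sources], dtype=float)
    expected = np.zeros(A.matrix.shape[0])
    for (x, y, _), w in zip(sources, weights / weights.sum()):
        expected += counts_budget * w * A.matrix[:, A.voxel_index(x, y)]
    return ProjectionVector(rng.poisson(expected).astype(np.float64))
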