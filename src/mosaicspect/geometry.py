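"""Parametric geometry of the collimator-less mosaic-scintillator system.

The full system is a half-ring of 7 identical detector modules whose centres
lie on a 600-mm-diameter circle around the patient axis (z).  Each module is
a stack of 10 cylindrical detector blocks (149.52 mm diameter x 20 mm), and
each block holds 768 scintillator bars of 1.68 x 1.68 x 20 mm placed on a
regular 89 x 89 cell grid in a sparse "mosaic" pattern.  Along z every bar
interlaces five 2-mm GAGG(Ce) segments with five 2-mm optical-glass
segments, so a module resolves 768 x 50 = 38,400 GAGG segments and the
system has 7 x 38,400 = 268,800 detector bins.

Coordinates are right-handed with z along the patient axis, the origin at
the centre of the 180 mm (dia.) x 100 mm field of view, lengths in mm and
configuration angles in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .physics import MaterialID

__all__ = [
    "PITCH_MM", "BLOCK_DIAMETER_MM", "GRID_N", "BARS_PER_BLOCK",
    "SEGMENT_MM", "BLOCK_LENGTH_MM", "BLOCKS_PER_MODULE", "N_MODULES",
    "RING_DIAMETER_MM", "GAGG_SEGMENTS_PER_BAR", "BINS_PER_MODULE",
    "PhaseRule", "MosaicPattern", "AxialLayout", "DetectorModule",
    "SystemGeometry", "SystemConfig", "VoxelGrid", "BinIndex",
    "generate_mosaic_pattern", "build_system", "material_at", "trace_path",
    "flat_bin_index", "unflat_bin_index", "pack_geometry",
]

PITCH_MM = 1.68
BLOCK_DIAMETER_MM = 149.52
GRID_N = 89                       # 89 * 1.68 mm = 149.52 mm
BARS_PER_BLOCK = 768
SEGMENT_MM = 2.0
BLOCK_LENGTH_MM = 20.0
BLOCKS_PER_MODULE = 10
N_MODULES = 7
RING_DIAMETER_MM = 600.0
GAGG_SEGMENTS_PER_BAR = BLOCKS_PER_MODULE * 5   # 50 over the 200-mm module
BINS_PER_MODULE = BARS_PER_BLOCK * GAGG_SEGMENTS_PER_BAR   # 38,400
FOV_RADIUS_MM = 90.0
FOV_HALF_LENGTH_MM = 50.0
ATTENUATOR_RADIUS_MM = 100.0
ATTENUATOR_HALF_LENGTH_MM = 50.0
WORLD_RADIUS_MM = 450.0


class PhaseRule(str, Enum):
    """How the axial GAGG/glass interlace is phased between neighbouring bars.

    ``PARITY_ALTERNATING`` starts bars on even (row+col) parity with GAGG and
    odd-parity bars with glass, producing a 3-D mosaic; ``UNIFORM`` starts
    every bar with GAGG.
    """

    UNIFORM = "UNIFORM"
    PARITY_ALTERNATING = "PARITY_ALTERNATING"


# ---------------------------------------------------------------------------
# Mosaic pattern
# ---------------------------------------------------------------------------


@dataclass
class MosaicPattern:
    """Trans-axial occupancy of scintillator bars on the block cell grid."""

    pitch: float
    grid_dims: tuple
    occupancy: np.ndarray            # bool (rows, cols)
    block_diameter: float
    seed: int

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.shape != tuple(self.grid_dims):
            raise ValueError("occupancy shape does not match grid_dims")

    @property
    def n_occupied(self) -> int:
        return int(self.occupancy.sum())

    def cell_ids(self) -> np.ndarray:
        """int32 map (rows, cols): bar index 0..n-1 for occupied cells, -1 else.

        Bars are numbered row-major over the grid, which fixes the trans-axial
        part of the detector-bin ordering.
        """
        ids = np.full(self.occupancy.shape, -1, dtype=np.int32)
        rows, cols = np.nonzero(self.occupancy)
        ids[rows, cols] = np.arange(rows.size, dtype=np.int32)
        return ids

    def cell_centers(self) -> np.ndarray:
        """(n_occupied, 2) local (u, v) centres of occupied cells, mm."""
        rows, cols = np.nonzero(self.occupancy)
        half = self.grid_dims[0] * self.pitch / 2.0
        u = (rows + 0.5) * self.pitch - half
        v = (cols + 0.5) * self.pitch - half
        return np.column_stack([u, v])

    def occupied_area_fraction(self) -> float:
        return self.n_occupied * self.pitch**2 / (math.pi * (self.block_diameter / 2.0) ** 2)

    def to_pairs(self) -> list:
        rows, cols = np.nonzero(self.occupancy)
        return list(zip(rows.tolist(), cols.tolist()))

    @classmethod
    def from_pairs(cls, pairs, pitch=PITCH_MM, grid_n=GRID_N,
                   block_diameter=BLOCK_DIAMETER_MM, seed=-1) -> "MosaicPattern":
        occ = np.zeros((grid_n, grid_n), dtype=bool)
        for r, c in pairs:
            occ[r, c] = True
        return cls(pitch, (grid_n, grid_n), occ, block_diameter, seed)


def generate_mosaic_pattern(seed: int, n_bars: int = BARS_PER_BLOCK,
                            pitch: float = PITCH_MM,
                            diameter: float = BLOCK_DIAMETER_MM) -> MosaicPattern:
    """Generate a seeded, spatially stratified sparse bar layout.

    Cells are visited in a seeded random order and accepted greedily subject
    to (a) never completing a fully occupied 2 x 2 square and (b) a local
    density cap of at most two occupied neighbours in the surrounding 3 x 3
    block.  Constraint (b) is relaxed if the target count cannot otherwise be
    reached.  Only cells lying entirely inside the block circle are eligible.
    The same seed always reproduces the same mask.
    """
    grid_n = int(round(diameter / pitch))
    radius = diameter / 2.0
    half = grid_n * pitch / 2.0
    idx = np.arange(grid_n)
    cu = (idx + 0.5) * pitch - half
    uu, vv = np.meshgrid(cu, cu, indexing="ij")
    # whole cell inside the circle: centre within radius minus half-diagonal
    eligible = np.hypot(uu, vv) <= radius - pitch * math.sqrt(0.5)
    n_eligible = int(eligible.sum())
    if n_bars > n_eligible:
        raise ValueError(f"infeasible pattern: {n_bars} bars requested but only "
                         f"{n_eligible} grid cells fit inside the block circle")

    occ = np.zeros((grid_n, grid_n), dtype=bool)
    if n_bars == 0:
        return MosaicPattern(pitch, (grid_n, grid_n), occ, diameter, seed)

    rng = np.random.default_rng(seed)
    cells = np.argwhere(eligible)
    order = rng.permutation(cells.shape[0])

    def completes_square(r, c):
        for dr in (-1, 0):
            for dc in (-1, 0):
                r0, c0 = r + dr, c + dc
                if 0 <= r0 and r0 + 1 < grid_n and 0 <= c0 and c0 + 1 < grid_n:
                    block = occ[r0:r0 + 2, c0:c0 + 2]
                    if block.sum() == 3 and not occ[r, c]:
                        return True
        return False

    def neighbour_count(r, c):
        r0, r1 = max(r - 1, 0), min(r + 2, grid_n)
        c0, c1 = max(c - 1, 0), min(c + 2, grid_n)
        return int(occ[r0:r1, c0:c1].sum())

    placed = 0
    for cap in (2, 3, 8):
        for k in order:
            if placed == n_bars:
                break
            r, c = cells[k]
            if occ[r, c] or completes_square(r, c) or neighbour_count(r, c) > cap:
                continue
            occ[r, c] = True
            placed += 1
        if placed == n_bars:
            break
    if placed < n_bars:
        raise ValueError("infeasible pattern: constraints left too few cells")
    return MosaicPattern(pitch, (grid_n, grid_n), occ, diameter, seed)


# ---------------------------------------------------------------------------
# Axial layout, modules and the system
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AxialLayout:
    """One block's 20-mm axial interlace of 2-mm GAGG and glass segments."""

    segment_length: float = SEGMENT_MM
    phase_rule: PhaseRule = PhaseRule.PARITY_ALTERNATING

    def sequence(self, phase: int = 0) -> list:
        """Materials of the 10 segments of one block for a bar of ``phase``."""
        seq = []
        for t in range(int(round(BLOCK_LENGTH_MM / self.segment_length))):
            seq.append(MaterialID.GAGG if t % 2 == phase % 2 else MaterialID.GLASS)
        return seq

    def bar_phase(self, row: int, col: int) -> int:
        if self.phase_rule is PhaseRule.PARITY_ALTERNATING:
            return (row + col) % 2
        return 0


@dataclass
class DetectorModule:
    """A 10-block stack of mosaic scintillator bars placed on the ring."""

    pattern: MosaicPattern
    axial: AxialLayout
    angle_deg: float                 # position angle of the module centre
    ring_radius: float = RING_DIAMETER_MM / 2.0
    n_blocks: int = BLOCKS_PER_MODULE
    block_length: float = BLOCK_LENGTH_MM

    @property
    def center(self) -> np.ndarray:
        a = math.radians(self.angle_deg)
        return np.array([self.ring_radius * math.cos(a),
                         self.ring_radius * math.sin(a), 0.0])

    @property
    def axial_extent(self) -> float:
        return self.n_blocks * self.block_length

    @property
    def z_range(self) -> tuple:
        h = self.axial_extent / 2.0
        return (-h, h)

    @property
    def n_gagg_segments(self) -> int:
        return self.pattern.n_occupied * self.n_blocks * 5


@dataclass(frozen=True)
class CylinderSpec:
    radius: float
    half_length: float
    material: MaterialID = MaterialID.WATER


@dataclass
class SystemConfig:
    """All free parameters of the half-ring system build."""

    ring_diameter: float = RING_DIAMETER_MM
    n_modules: int = N_MODULES
    angle_start_deg: float = -60.0
    angle_step_deg: float = 30.0
    pattern_seed: int = 20230628
    n_bars: int = BARS_PER_BLOCK
    phase_rule: PhaseRule = PhaseRule.PARITY_ALTERNATING
    attenuator: bool = False
    pattern_pairs: list | None = None   # optional hand-specified occupancy


@dataclass
class SystemGeometry:
    """The assembled half-ring system plus FOV and optional water attenuator."""

    modules: list
    ring_diameter: float = RING_DIAMETER_MM
    fov: CylinderSpec = field(default_factory=lambda: CylinderSpec(
        FOV_RADIUS_MM, FOV_HALF_LENGTH_MM, MaterialID.AIR))
    attenuator: CylinderSpec | None = None
    world_radius: float = WORLD_RADIUS_MM

    @property
    def n_bins(self) -> int:
        return sum(m.n_gagg_segments for m in self.modules)

    @property
    def angular_span(self) -> tuple:
        return (self.modules[0].angle_deg, self.modules[-1].angle_deg)


def build_system(config: SystemConfig | None = None) -> SystemGeometry:
    """Construct the half-ring system from a :class:`SystemConfig`."""
    config = config or SystemConfig()
    if config.pattern_pairs is not None:
        pattern = MosaicPattern.from_pairs(config.pattern_pairs,
                                           seed=config.pattern_seed)
    else:
        pattern = generate_mosaic_pattern(config.pattern_seed, config.n_bars)
    axial = AxialLayout(phase_rule=config.phase_rule)
    ring_radius = config.ring_diameter / 2.0
    modules = [
        DetectorModule(pattern, axial,
                       config.angle_start_deg + k * config.angle_step_deg,
                       ring_radius)
        for k in range(config.n_modules)
    ]
    # overlap check: adjacent block cylinders must not intersect
    for a, b in zip(modules, modules[1:]):
        gap = np.linalg.norm(a.center - b.center)
        if gap < pattern.block_diameter - 1e-9:
            raise ValueError(f"geometry conflict: modules at {a.angle_deg} and "
                             f"{b.angle_deg} deg overlap (centre gap {gap:.2f} mm)")
    attenuator = (CylinderSpec(ATTENUATOR_RADIUS_MM, ATTENUATOR_HALF_LENGTH_MM)
                  if config.attenuator else None)
    return SystemGeometry(modules, config.ring_diameter, attenuator=attenuator)


# ---------------------------------------------------------------------------
# Detector-bin indexing (module-major concatenation of the projection vector)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinIndex:
    """(module k, trans-axial cell c, axial GAGG segment s) <-> flat index."""

    module: int
    cell: int
    segment: int

    @property
    def flat(self) -> int:
        return flat_bin_index(self.module, self.cell, self.segment)


def flat_bin_index(k, c, s, n_cells=BARS_PER_BLOCK, n_seg=GAGG_SEGMENTS_PER_BAR):
    return (k * n_cells + c) * n_seg + s


def unflat_bin_index(i, n_cells=BARS_PER_BLOCK, n_seg=GAGG_SEGMENTS_PER_BAR):
    s = i % n_seg
    rest = i // n_seg
    return rest // n_cells, rest % n_cells, s


# ---------------------------------------------------------------------------
# Voxel grids
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VoxelGrid:
    """A half-open, 0-based, x-fastest voxel lattice in world coordinates."""

    origin: tuple                    # corner of voxel (0,0,0), mm
    voxel_size: tuple                # mm
    dims: tuple                      # nx, ny, nz

    @classmethod
    def centered(cls, voxel_size, dims) -> "VoxelGrid":
        vs = np.asarray(voxel_size, dtype=float)
        d = np.asarray(dims, dtype=int)
        origin = -vs * d / 2.0
        return cls(tuple(origin), tuple(vs), tuple(int(x) for x in d))

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def flat_index(self, ix, iy, iz):
        nx, ny, _ = self.dims
        return (iz * ny + iy) * nx + ix   # x fastest

    def voxel_centers(self) -> np.ndarray:
        nx, ny, nz = self.dims
        ox, oy, oz = self.origin
        sx, sy, sz = self.voxel_size
        x = ox + (np.arange(nx) + 0.5) * sx
        y = oy + (np.arange(ny) + 0.5) * sy
        z = oz + (np.arange(nz) + 0.5) * sz
        zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    def world_to_index(self, points) -> np.ndarray:
        p = np.atleast_2d(points)
        idx = np.floor((p - np.asarray(self.origin)) /
                       np.asarray(self.voxel_size)).astype(np.int64)
        return idx


def default_grid_2mm() -> VoxelGrid:
    """The 90 x 90 x 50 grid at 2-mm voxels used for the resolution phantoms."""
    return VoxelGrid.centered((2.0, 2.0, 2.0), (90, 90, 50))


def default_grid_3mm() -> VoxelGrid:
    """The 60 x 60 x 34 grid at 3-mm voxels used for the cardiac phantom."""
    return VoxelGrid.centered((3.0, 3.0, 3.0), (60, 60, 34))


# ---------------------------------------------------------------------------
# Point-in-material and ray-traversal queries
# ---------------------------------------------------------------------------


def material_at(points, geom: SystemGeometry):
    """Material at one point (3-vector) or many points ((N, 3) array).

    Returns a :class:`MaterialID` for a single point, otherwise a uint8 array
    of material codes.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.zeros(pts.shape[0], dtype=np.uint8)

    if geom.attenuator is not None:
        att = geom.attenuator
        inside = (np.hypot(pts[:, 0], pts[:, 1]) <= att.radius) & \
                 (np.abs(pts[:, 2]) <= att.half_length)
        out[inside] = np.uint8(int(att.material))

    for module in geom.modules:
        pat = module.pattern
        grid_n = pat.grid_dims[0]
        half = grid_n * pat.pitch / 2.0
        a = math.radians(module.angle_deg)
        ca, sa = math.cos(a), math.sin(a)
        cx, cy, _ = module.center
        dx = pts[:, 0] - cx
        dy = pts[:, 1] - cy
        u = ca * dx + sa * dy
        v = -sa * dx + ca * dy
        zmin, zmax = module.z_range
        inside = (np.abs(u) < half) & (np.abs(v) < half) & \
                 (pts[:, 2] >= zmin) & (pts[:, 2] < zmax)
        if not inside.any():
            continue
        iu = np.floor((u[inside] + half) / pat.pitch).astype(np.int64)
        iv = np.floor((v[inside] + half) / pat.pitch).astype(np.int64)
        iu = np.clip(iu, 0, grid_n - 1)
        iv = np.clip(iv, 0, grid_n - 1)
        occupied = pat.occupancy[iu, iv]
        t = np.floor((pts[inside, 2][occupied] - zmin) /
                     module.axial.segment_length).astype(np.int64)
        if module.axial.phase_rule is PhaseRule.PARITY_ALTERNATING:
            phase = (iu[occupied] + iv[occupied]) % 2
        else:
            phase = np.zeros(occupied.sum(), dtype=np.int64)
        mat = np.where(t % 2 == phase, np.uint8(int(MaterialID.GAGG)),
                       np.uint8(int(MaterialID.GLASS)))
        sub = out[inside]
        sub[occupied] = mat
        out[inside] = sub

    if np.asarray(points).ndim == 1:
        return MaterialID(int(out[0]))
    return out


def _cylinder_ts(origin, direction, cx, cy, radius, zmin, zmax):
    """Candidate parameter values where a ray crosses a finite z-cylinder."""
    ts = []
    ox, oy, oz = origin
    dx, dy, dz = direction
    rx, ry = ox - cx, oy - cy
    a = dx * dx + dy * dy
    if a > 1e-14:
        b = 2.0 * (rx * dx + ry * dy)
        c = rx * rx + ry * ry - radius * radius
        disc = b * b - 4 * a * c
        if disc > 0:
            sq = math.sqrt(disc)
            ts.extend([(-b - sq) / (2 * a), (-b + sq) / (2 * a)])
    if abs(dz) > 1e-14:
        ts.extend([(zmin - oz) / dz, (zmax - oz) / dz])
    return ts


def _lattice_crossings(p0, dp, t_lo, t_hi, pitch, offset):
    """t values in (t_lo, t_hi) where p0 + dp*t crosses lattice planes."""
    if abs(dp) < 1e-14:
        return []
    lo = p0 + dp * t_lo + offset
    hi = p0 + dp * t_hi + offset
    k0, k1 = sorted((lo / pitch, hi / pitch))
    ks = np.arange(math.floor(k0) + 1, math.ceil(k1))
    return list((ks * pitch - offset - p0) / dp)


def trace_path(origin, direction, geom: SystemGeometry):
    """Trace a ray and return an ordered list of (MaterialID, length_mm).

    Segments are contiguous, consecutive segments differ in material, and
    the lengths sum to the distance from the origin to the world boundary.
    """
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm < 1e-12:
        raise ValueError("zero direction vector")
    direction = direction / norm

    # world boundary: sphere of geom.world_radius
    b = 2.0 * float(origin @ direction)
    c = float(origin @ origin) - geom.world_radius**2
    disc = b * b - 4 * c
    if disc <= 0:
        return [(MaterialID.AIR, 0.0)]
    t_end = (-b + math.sqrt(disc)) / 2.0
    if t_end <= 0:
        return [(MaterialID.AIR, 0.0)]

    ts = {0.0, t_end}
    if geom.attenuator is not None:
        att = geom.attenuator
        for t in _cylinder_ts(origin, direction, 0.0, 0.0, att.radius,
                              -att.half_length, att.half_length):
            if 0.0 < t < t_end:
                ts.add(t)

    for module in geom.modules:
        pat = module.pattern
        half = pat.grid_dims[0] * pat.pitch / 2.0
        zmin, zmax = module.z_range
        cx, cy, _ = module.center
        bounds = [t for t in _cylinder_ts(origin, direction, cx, cy,
                                          half * math.sqrt(2.0) + 1.0, zmin, zmax)]
        bounds = sorted(max(0.0, min(t, t_end)) for t in bounds)
        if not bounds:
            continue
        t_lo, t_hi = min(bounds), max(bounds)
        if t_hi - t_lo < 1e-12:
            continue
        a = math.radians(module.angle_deg)
        ca, sa = math.cos(a), math.sin(a)
        u0 = ca * (origin[0] - cx) + sa * (origin[1] - cy)
        v0 = -sa * (origin[0] - cx) + ca * (origin[1] - cy)
        du = ca * direction[0] + sa * direction[1]
        dv = -sa * direction[0] + ca * direction[1]
        for t in _lattice_crossings(u0, du, t_lo, t_hi, pat.pitch, half):
            ts.add(t)
        for t in _lattice_crossings(v0, dv, t_lo, t_hi, pat.pitch, half):
            ts.add(t)
        for t in _lattice_crossings(origin[2], direction[2], t_lo, t_hi,
                                    module.axial.segment_length, -zmin):
            ts.add(t)
        for t in bounds:
            if 0.0 < t < t_end:
                ts.add(t)

    t_sorted = np.array(sorted(t for t in ts if 0.0 <= t <= t_end))
    mids = origin[None, :] + direction[None, :] * \
        ((t_sorted[:-1] + t_sorted[1:]) / 2.0)[:, None]
    mats = material_at(mids, geom)
    lengths = np.diff(t_sorted)

    segments = []
    for m, L in zip(mats, lengths):
        if L <= 0:
            continue
        if segments and segments[-1][0] == MaterialID(int(m)):
            segments[-1] = (segments[-1][0], segments[-1][1] + float(L))
        else:
            segments.append((MaterialID(int(m)), float(L)))
    if not segments:
        segments = [(MaterialID.AIR, float(t_end))]
    return segments


# ---------------------------------------------------------------------------
# Packed representation for the numba transport kernels
# ---------------------------------------------------------------------------


def pack_geometry(geom: SystemGeometry):
    """Flatten a :class:`SystemGeometry` into plain arrays for jit kernels."""
    n_mod = len(geom.modules)
    cx = np.empty(n_mod)
    cy = np.empty(n_mod)
    cos_a = np.empty(n_mod)
    sin_a = np.empty(n_mod)
    for k, m in enumerate(geom.modules):
        cx[k], cy[k] = m.center[0], m.center[1]
        a = math.radians(m.angle_deg)
        cos_a[k], sin_a[k] = math.cos(a), math.sin(a)
    module0 = geom.modules[0]
    pat = module0.pattern
    cell_id = pat.cell_ids()
    if module0.axial.phase_rule is PhaseRule.PARITY_ALTERNATING:
        rows, cols = np.indices(pat.occupancy.shape)
        phase = ((rows + cols) % 2).astype(np.uint8)
    else:
        phase = np.zeros(pat.occupancy.shape, dtype=np.uint8)
    zmin, zmax = module0.z_range
    att = geom.attenuator
    return dict(
        cx=cx, cy=cy, cos_a=cos_a, sin_a=sin_a,
        pitch=pat.pitch,
        half=pat.grid_dims[0] * pat.pitch / 2.0,
        grid_n=pat.grid_dims[0],
        cell_id=np.ascontiguousarray(cell_id),
        phase=np.ascontiguousarray(phase),
        zmin=zmin, zmax=zmax,
        seg_len=module0.axial.segment_length,
        n_cells=pat.n_occupied,
        n_seg=int(round(module0.axial_extent / module0.axial.segment_length)) // 2,
        att_on=att is not None,
        att_radius=att.radius if att is not None else 0.0,
        att_half=att.half_length if att is not None else 0.0,
        world_radius=geom.world_radius,
    )
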