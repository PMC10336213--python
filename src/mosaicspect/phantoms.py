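"""Voxelized activity and attenuation phantoms.

All activity images are stored as emission rates (photons per second per
voxel, one 140 keV photon per decay) and normalised so that the sum over
voxels matches the stated total activity; 1 mCi = 3.7e7 photons/s.

Four phantoms are provided:

* a Derenzo-style hot-rod phantom (six 60-degree sectors of hexagonally
  packed rods, diameters 4–9 mm, centre spacing twice the diameter);
* axially stacked disk phantoms (five 120-mm disks, gaps twice the
  thickness);
* an analytic left-ventricle phantom (truncated half-ellipsoid shell with
  75 : 2 : 2 myocardium : blood pool : vessel uptake) standing in for an
  anthropomorphic cardiac phantom, plus its water-cylinder attenuation map;
* the uniform FOV-filling cylinder used to estimate system matrices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import (VoxelGrid, FOV_RADIUS_MM, FOV_HALF_LENGTH_MM,
                       ATTENUATOR_RADIUS_MM, ATTENUATOR_HALF_LENGTH_MM)
from .physics import MaterialID, MaterialTable

__all__ = [
    "MCI_TO_PHOTONS_PER_S", "VoxelImage", "hot_rod_layout", "make_hot_rod",
    "make_disks", "make_cardiac", "make_uniform_cylinder",
    "make_hot_rod_2d", "make_uniform_disk_2d", "disk_centers_mm",
]

MCI_TO_PHOTONS_PER_S = 3.7e7
DEFAULT_ACTIVITY_MCI = 0.45
ROD_DIAMETERS_MM = (4.0, 5.0, 6.0, 7.0, 8.0, 9.0)
DISK_DIAMETER_MM = 120.0
DISK_THICKNESSES_MM = (4.0, 5.0, 6.0, 7.0, 8.0)
EDGE_MARGIN_MM = 5.0


@dataclass
class VoxelImage:
    """A scalar volume on a :class:`VoxelGrid`.

    ``values`` is indexed ``[ix, iy, iz]``; flattening uses Fortran order so
    the flat index runs x-fastest, matching the voxel indexing convention of
    the system matrix.
    """

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != tuple(self.grid.dims):
            raise ValueError("values shape does not match grid dims")
        if (self.values < 0).any():
            raise ValueError("voxel values must be non-negative")

    def flatten(self) -> np.ndarray:
        return self.values.ravel(order="F")

    def total(self) -> float:
        return float(self.values.sum())

    def normalized(self, total_mci: float) -> "VoxelImage":
        target = total_mci * MCI_TO_PHOTONS_PER_S
        s = self.total()
        if s <= 0:
            raise ValueError("cannot normalise an all-zero image")
        return VoxelImage(self.grid, self.values * (target / s))


def _center_mesh(grid: VoxelGrid):
    nx, ny, nz = grid.dims
    ox, oy, oz = grid.origin
    sx, sy, sz = grid.voxel_size
    x = ox + (np.arange(nx) + 0.5) * sx
    y = oy + (np.arange(ny) + 0.5) * sy
    z = oz + (np.arange(nz) + 0.5) * sz
    return np.meshgrid(x, y, z, indexing="ij")


# ---------------------------------------------------------------------------
# Hot-rod phantom
# ---------------------------------------------------------------------------


def hot_rod_layout(phantom_radius: float = FOV_RADIUS_MM,
                   diameters=ROD_DIAMETERS_MM,
                   margin: float = EDGE_MARGIN_MM) -> list:
    """Rod centres for the six-sector Derenzo layout.

    Returns a list of ``(x, y, diameter)``.  Each 60-degree sector holds a
    hexagonal lattice of rods with centre-to-centre spacing twice the
    diameter, keeping a ``margin`` between every rod edge and both the
    sector boundaries and the phantom rim.
    """
    rods = []
    for i, d in enumerate(diameters):
        theta0 = math.radians(60.0 * i)
        theta1 = math.radians(60.0 * (i + 1))
        bisector = (theta0 + theta1) / 2.0
        spacing = 2.0 * d
        a1 = np.array([math.cos(bisector), math.sin(bisector)]) * spacing
        a2 = np.array([math.cos(bisector + math.pi / 3.0),
                       math.sin(bisector + math.pi / 3.0)]) * spacing
        # inward normals of the two boundary half-planes
        n0 = np.array([-math.sin(theta0), math.cos(theta0)])
        n1 = np.array([math.sin(theta1), -math.cos(theta1)])
        clearance = margin + d / 2.0
        r_max = phantom_radius - clearance
        span = int(math.ceil(r_max / spacing)) + 2
        for m in range(-span, span + 1):
            for n in range(-span, span + 1):
                p = m * a1 + n * a2
                if p @ n0 < clearance or p @ n1 < clearance:
                    continue
                if np.hypot(*p) > r_max:
                    continue
                rods.append((float(p[0]), float(p[1]), float(d)))
    return rods


def _paint_rods(xx, yy, rods):
    img = np.zeros(xx.shape, dtype=np.float64)
    for x0, y0, d in rods:
        img[(xx - x0) ** 2 + (yy - y0) ** 2 <= (d / 2.0) ** 2] = 1.0
    return img


def make_hot_rod(grid: VoxelGrid,
                 total_mci: float = DEFAULT_ACTIVITY_MCI) -> VoxelImage:
    """Voxelize the hot-rod phantom (zero background, rods span the FOV length)."""
    min_d = min(ROD_DIAMETERS_MM)
    if max(grid.voxel_size[:2]) > min_d / 2.0:
        warnings.warn(f"voxel size {grid.voxel_size} coarser than half the "
                      f"smallest rod diameter {min_d} mm", stacklevel=2)
    xx, yy, zz = _center_mesh(grid)
    plane = _paint_rods(xx[:, :, 0], yy[:, :, 0], hot_rod_layout())
    vol = plane[:, :, None] * (np.abs(zz) <= FOV_HALF_LENGTH_MM)
    return VoxelImage(grid, vol).normalized(total_mci)


def make_hot_rod_2d(n: int = 90, pixel: float = 2.0) -> np.ndarray:
    """2-D hot-rod layout on an ``n x n`` grid (for the single-slice preset).

    Unnormalised (unit rod intensity); callers scale as needed.
    """
    c = (np.arange(n) + 0.5) * pixel - n * pixel / 2.0
    xx, yy = np.meshgrid(c, c, indexing="ij")
    return _paint_rods(xx, yy, hot_rod_layout())


# ---------------------------------------------------------------------------
# Disk phantoms
# ---------------------------------------------------------------------------


def disk_centers_mm(thickness: float) -> np.ndarray:
    """Axial centres of the five disks (adjacent centre spacing 3 x thickness)."""
    return (np.arange(5) - 2.0) * 3.0 * thickness


def make_disks(thickness: float, grid: VoxelGrid,
               total_mci: float = DEFAULT_ACTIVITY_MCI) -> VoxelImage:
    """Five axially stacked 120-mm disks with gaps twice the thickness.

    The stack is centred axially; for 8-mm disks the 104-mm stack extends
    2 mm beyond each end of the 100-mm FOV (that activity is simulated but
    lies outside the reconstructable volume).
    """
    if thickness not in DISK_THICKNESSES_MM:
        raise ValueError(f"disk thickness must be one of {DISK_THICKNESSES_MM}")
    xx, yy, zz = _center_mesh(grid)
    in_plane = xx**2 + yy**2 <= (DISK_DIAMETER_MM / 2.0) ** 2
    axial = np.zeros(zz.shape, dtype=bool)
    for zc in disk_centers_mm(thickness):
        axial |= np.abs(zz - zc) <= thickness / 2.0
    return VoxelImage(grid, (in_plane & axial).astype(float)).normalized(total_mci)


# ---------------------------------------------------------------------------
# Analytic cardiac phantom
# ---------------------------------------------------------------------------

LV_OUTER_SEMI_MM = (17.5, 17.5, 25.0)   # outer half-axes of the LV ellipsoid
LV_WALL_MM = 10.0
LV_TRUNCATION_MM = 10.0                 # basal cut plane above the equator
VESSEL_RADIUS_MM = 3.0
UPTAKE_MYOCARDIUM = 75.0
UPTAKE_BLOOD = 2.0
UPTAKE_VESSEL = 2.0


def make_cardiac(grid: VoxelGrid, total_mci: float = DEFAULT_ACTIVITY_MCI,
                 material_table: MaterialTable | None = None,
                 wall_value: float = UPTAKE_MYOCARDIUM):
    """Analytic left-ventricle phantom and its water-cylinder attenuation map.

    The myocardium is a truncated half-ellipsoid shell (outer axes
    35 x 35 x 50 mm, 10-mm wall) with relative uptake 75; the enclosed blood
    pool has uptake 2; two 3-mm-radius surface tubes stand in for the
    coronary vessels at uptake 2.  The attenuation image is the water
    cylinder (200 mm dia. x 100 mm) in cm^-1.
    """
    table = material_table or MaterialTable()
    xx, yy, zz = _center_mesh(grid)
    ax, ay, az = LV_OUTER_SEMI_MM
    bx, by, bz = ax - LV_WALL_MM, ay - LV_WALL_MM, az - LV_WALL_MM
    outer = (xx / ax) ** 2 + (yy / ay) ** 2 + (zz / az) ** 2 <= 1.0
    inner = (xx / bx) ** 2 + (yy / by) ** 2 + (zz / bz) ** 2 <= 1.0
    cup = zz <= LV_TRUNCATION_MM
    act = np.zeros(xx.shape, dtype=np.float64)
    act[outer & ~inner & cup] = wall_value
    act[inner & cup] = UPTAKE_BLOOD
    # two vertical surface tubes tangent to the equator of the outer shell
    for phi_deg in (30.0, 150.0):
        phi = math.radians(phi_deg)
        cxv = (ax + VESSEL_RADIUS_MM) * math.cos(phi)
        cyv = (ay + VESSEL_RADIUS_MM) * math.sin(phi)
        tube = ((xx - cxv) ** 2 + (yy - cyv) ** 2 <= VESSEL_RADIUS_MM**2) & \
               (zz >= -az * 0.8) & (zz <= LV_TRUNCATION_MM)
        act[tube] = UPTAKE_VESSEL
    activity = VoxelImage(grid, act).normalized(total_mci)

    mu_water = table.mu(MaterialID.WATER, 140.0)
    att = np.where((np.hypot(xx, yy) <= ATTENUATOR_RADIUS_MM) &
                   (np.abs(zz) <= ATTENUATOR_HALF_LENGTH_MM), mu_water, 0.0)
    return activity, VoxelImage(grid, att)


# ---------------------------------------------------------------------------
# Uniform sources
# ---------------------------------------------------------------------------


def make_uniform_cylinder(grid: VoxelGrid,
                          total_mci: float = DEFAULT_ACTIVITY_MCI) -> VoxelImage:
    """Uniform cylinder (180 mm dia. x 100 mm) filling the FOV."""
    xx, yy, zz = _center_mesh(grid)
    inside = (np.hypot(xx, yy) <= FOV_RADIUS_MM) & \
             (np.abs(zz) <= FOV_HALF_LENGTH_MM)
    return VoxelImage(grid, inside.astype(float)).normalized(total_mci)


def make_uniform_disk_2d(n: int = 90, pixel: float = 2.0,
                         radius: float = FOV_RADIUS_MM) -> np.ndarray:
    """Uniform disk on an ``n x n`` 2-D grid (single-slice preset source)."""
    c = (np.arange(n) + 0.5) * pixel - n * pixel / 2.0
    xx, yy = np.meshgrid(c, c, indexing="ij")
    return (np.hypot(xx, yy) <= radius).astype(np.float64)
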