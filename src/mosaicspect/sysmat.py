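"""Monte Carlo system-matrix estimation and sensitivity analysis.

The system matrix ``A`` has one row per detector bin and one column per
image voxel; ``A[i, j]`` estimates the probability that a photon emitted
from voxel ``j`` produces an accepted event in bin ``i``.  It is estimated
from a uniform-source list-mode run as recorded counts divided by emitted
photons per voxel, with no smoothing.  Per-voxel sensitivity is the column
sum of ``A``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import geometry as geo
from .transport import (ListModeSet, SliceSystem, build_slice_system,
                        simulate, simulate_slice2d)
from .phantoms import make_uniform_cylinder, make_uniform_disk_2d

__all__ = [
    "SystemMatrix", "SensitivityMap", "estimate_sysmat",
    "system_matrix_from_counts", "sensitivity_stats", "axial_slices",
    "slice2d_system_matrix", "axial_system_matrix", "event_projection",
]


@dataclass
class SystemMatrix:
    """Sparse detection-probability matrix with its Monte Carlo provenance."""

    matrix: sp.csr_matrix
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.matrix.shape

    def sensitivity(self) -> np.ndarray:
        """Per-voxel sensitivity s_j = sum_i A_ij."""
        return np.asarray(self.matrix.sum(axis=0)).ravel()

    def to_hdf5(self, path) -> None:
        import h5py

        coo = self.matrix.tocoo()
        with h5py.File(path, "w") as fh:
            fh.create_dataset("row", data=coo.row.astype(np.int32))
            fh.create_dataset("col", data=coo.col.astype(np.int32))
            fh.create_dataset("value", data=coo.data)
            fh.attrs["shape"] = self.matrix.shape
            for k, v in self.provenance.items():
                fh.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path) -> "SystemMatrix":
        import h5py

        with h5py.File(path, "r") as fh:
            shape = tuple(fh.attrs["shape"])
            m = sp.coo_matrix((fh["value"][...],
                               (fh["row"][...], fh["col"][...])),
                              shape=shape).tocsr()
            prov = {k: v for k, v in fh.attrs.items() if k != "shape"}
        return cls(m, prov)

    def to_mtx(self, path) -> None:
        from scipy.io import mmwrite

        mmwrite(str(path), self.matrix.tocoo())

    @classmethod
    def from_mtx(cls, path) -> "SystemMatrix":
        from scipy.io import mmread

        return cls(sp.csr_matrix(mmread(str(path))))


@dataclass
class SensitivityMap:
    """Per-voxel detection fractions and their FOV summary (in percent)."""

    values: np.ndarray               # flat, one entry per voxel
    mean_pct: float
    std_pct: float
    fov_mask: np.ndarray | None = None


def system_matrix_from_counts(ev_bin, ev_vox, emitted, n_bins,
                              provenance=None) -> SystemMatrix:
    """Build ``A`` from event (bin, voxel) pairs and per-voxel emissions."""
    ev_bin = np.asarray(ev_bin)
    ev_vox = np.asarray(ev_vox)
    emitted = np.asarray(emitted, dtype=np.float64)
    if ev_vox.size and (emitted[ev_vox] == 0).any():
        raise ValueError("events recorded from voxels with zero emissions")
    n_vox = emitted.size
    counts = sp.coo_matrix(
        (np.ones(ev_bin.size, dtype=np.float64), (ev_bin, ev_vox)),
        shape=(int(n_bins), n_vox)).tocsr()
    counts.sum_duplicates()
    inv = np.zeros(n_vox)
    nz = emitted > 0
    inv[nz] = 1.0 / emitted[nz]
    A = counts @ sp.diags(inv)
    return SystemMatrix(A.tocsr(), dict(provenance or {}))


def estimate_sysmat(events: ListModeSet, grid: geo.VoxelGrid,
                    n_bins: int = geo.N_MODULES * geo.BINS_PER_MODULE,
                    fov_mask=None) -> SystemMatrix:
    """Estimate the system matrix from a uniform-source list-mode run.

    ``fov_mask`` (flat boolean, optional) marks voxels that the uniform
    source must have covered; any masked voxel without emissions raises.
    """
    if events.emitted_per_voxel.size != grid.n_voxels:
        raise ValueError("grid does not match the event voxel indexing")
    if fov_mask is not None:
        mask = np.asarray(fov_mask, dtype=bool).ravel()
        if (events.emitted_per_voxel[mask] == 0).any():
            raise ValueError("FOV voxels with zero emissions; "
                             "increase n_histories or fix the source")
    acc = events.accepted
    prov = dict(n_histories=events.n_histories, seed=events.seed)
    return system_matrix_from_counts(events.bin[acc], events.emission_voxel[acc],
                                     events.emitted_per_voxel, n_bins, prov)


def sensitivity_stats(A: SystemMatrix, fov_mask) -> SensitivityMap:
    """Mean and population std of per-voxel sensitivity over the FOV, in %."""
    mask = np.asarray(fov_mask, dtype=bool).ravel()
    if not mask.any():
        raise ValueError("empty FOV mask")
    s = A.sensitivity()
    sel = s[mask]
    return SensitivityMap(s, float(sel.mean() * 100.0),
                          float(sel.std() * 100.0), mask)


def axial_slices(s: SensitivityMap, grid: geo.VoxelGrid, z_indices) -> list:
    """Extract trans-axial sensitivity maps at the requested z indices."""
    nx, ny, nz = grid.dims
    vol = s.values.reshape((nx, ny, nz), order="F")
    maps = []
    for iz in z_indices:
        if not 0 <= iz < nz:
            raise IndexError(f"z index {iz} out of range [0, {nz})")
        maps.append(vol[:, :, iz].copy())
    return maps


# ---------------------------------------------------------------------------
# Desk-scale presets
# ---------------------------------------------------------------------------


def slice2d_system_matrix(n_histories: int, seed: int,
                          config: geo.SystemConfig | None = None,
                          n_pix: int = 90, pixel_mm: float = 2.0,
                          system: SliceSystem | None = None):
    """Uniform-disk Monte Carlo system matrix on the single-slice preset.

    Returns ``(SliceSystem, SystemMatrix)`` with one row per (module, bar)
    bin and one column per 2-D source pixel.
    """
    system = system or build_slice_system(config, n_pix, pixel_mm)
    disk = make_uniform_disk_2d(system.n_pix, system.pixel_mm)
    ev_bin, ev_vox, emitted = simulate_slice2d(disk, system, n_histories, seed)
    A = system_matrix_from_counts(
        ev_bin, ev_vox, emitted, system.n_bins,
        dict(n_histories=n_histories, seed=seed, preset="slice2d"))
    return system, A


def axial_system_matrix(events: ListModeSet, grid: geo.VoxelGrid,
                        n_bins: int = geo.N_MODULES * geo.BINS_PER_MODULE
                        ) -> SystemMatrix:
    """Axially resolved system matrix (the "axial1d" preset).

    The unknown is reduced to a single trans-axial column — the 1-D axial
    activity profile over the image z-slices — while the detector keeps its
    full binning (every GAGG segment z-resolved): rows are all detector
    bins, columns the z-slices.  The axial self-collimation signal lives in
    the joint (bar, segment) response; any trans-axial aggregation of the
    bins averages the GAGG/glass interlace of neighbouring bars away
    (opposite parity phases cancel), so the full binning is retained.
    """
    nx, ny, nz = grid.dims
    acc = events.accepted
    zbins = events.emission_voxel[acc] // (nx * ny)
    emitted_z = events.emitted_per_voxel.reshape((nz, nx * ny)).sum(axis=1)
    return system_matrix_from_counts(
        events.bin[acc], zbins, emitted_z, n_bins,
        dict(n_histories=events.n_histories, seed=events.seed, preset="axial1d"))


def event_projection(events: ListModeSet,
                     n_bins: int = geo.N_MODULES * geo.BINS_PER_MODULE
                     ) -> np.ndarray:
    """Accepted-event counts per flat detector bin."""
    return np.bincount(events.bin[events.accepted],
                       minlength=n_bins).astype(np.float64)


def uniform_cylinder_run(geom, grid, n_histories, seed, **kw) -> ListModeSet:
    """Convenience: simulate the FOV-filling uniform cylinder."""
    return simulate(make_uniform_cylinder(grid), geom, n_histories, seed, **kw)
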