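"""End-to-end recomputation of the system's headline performance figures.

These routines run the full pipeline at desk scale — smaller Monte Carlo
sample sizes than the original multi-day simulations, but the identical
geometry, physics and reconstruction settings — and measure:

* the per-photon detection efficiency (sensitivity) of the full 3-D system
  for a uniform FOV-filling source;
* the fraction of accepted events that Compton-scattered in the detector,
  and the fraction of those spanning several scintillator elements;
* the smallest separable hot-rod diameter on the single-slice ring;
* the smallest disk thickness resolved axially;
* the recovered two-point separation of the 2-D prototype.
"""

from __future__ import annotations

import numpy as np

from . import geometry as geo
from . import prototype2d as proto
from .evaluation import (SEPARABILITY_THRESHOLD, find_peaks_2d,
                         profile_separability, rod_separability)
from .phantoms import (DISK_THICKNESSES_MM, MCI_TO_PHOTONS_PER_S,
                       disk_centers_mm, hot_rod_layout, make_disks,
                       make_hot_rod_2d, make_uniform_cylinder)
from .recon import ReconConfig, forward_project, gaussian_postfilter, osem
from .sysmat import axial_system_matrix, slice2d_system_matrix
from .transport import scatter_fractions, simulate

__all__ = [
    "sensitivity_and_scatter", "inplane_resolution", "axial_resolution",
    "build_prototype_matrix", "prototype_two_point_study", "run_all_targets",
]


def _subseed(seed: int, offset: int) -> int:
    return (seed * 9973 + offset) % (2**31 - 1)


def sensitivity_and_scatter(seed: int, n_histories: int = 400_000) -> dict:
    """Uniform-cylinder run on the full 3-D system (no attenuator, window on).

    Sensitivity is accepted events / emitted photons in percent; the scatter
    figures follow the accepted-event provenance flags.
    """
    geom = geo.build_system()
    grid = geo.default_grid_2mm()
    activity = make_uniform_cylinder(grid)
    events = simulate(activity, geom, n_histories, _subseed(seed, 1))
    sensitivity = 100.0 * len(events) / n_histories
    compton_pct, inter_pct = scatter_fractions(events)
    return dict(sensitivity_pct=sensitivity, compton_fraction_pct=compton_pct,
                inter_crystal_fraction_pct=inter_pct, n_histories=n_histories)


def inplane_resolution(seed: int, n_histories: int = 50_000_000,
                       threshold: float = SEPARABILITY_THRESHOLD) -> dict:
    """Smallest separable hot-rod diameter on the single-slice preset.

    Estimates the slice system matrix from a uniform-disk run, forward
    projects the hot-rod layout without noise, reconstructs with 50 OSEM
    iterations (35 subsets) and a 2-mm FWHM post-filter, and applies the
    valley-to-peak criterion per rod sector.  The reported size is the
    smallest diameter that passes together with all larger ones.
    """
    system, A = slice2d_system_matrix(n_histories, _subseed(seed, 2))
    phantom = make_hot_rod_2d(system.n_pix, system.pixel_mm)
    y = forward_project(A, phantom)
    f = osem(A, y, ReconConfig(n_subsets=35, n_iterations=50))
    img = f.reshape((system.n_pix, system.n_pix), order="F")
    img = gaussian_postfilter(img, 7, 2.0, (system.pixel_mm, system.pixel_mm))
    reports = rod_separability(img, hot_rod_layout(), system.pixel_mm, threshold)
    sizes = sorted(reports)
    smallest = None
    for d in reversed(sizes):
        if reports[d].separable:
            smallest = d
        else:
            break
    return dict(smallest_separable_mm=smallest, n_histories=n_histories,
                per_size={f"{d:g}": reports[d].separable for d in sizes})


def axial_resolution(seed: int, n_uniform: int = 10_000_000,
                     threshold: float = SEPARABILITY_THRESHOLD) -> dict:
    """Smallest disk thickness resolved as five axial maxima.

    Uses the axially resolved preset: the unknown is the 1-D axial activity
    profile over the 2-mm image slices while the detector keeps all
    268,800 z-resolved bins.  The system matrix is estimated from a
    uniform-cylinder run; each disk phantom's axial profile is forward
    projected without noise (the same construction as the hot-rod study)
    and reconstructed with 10 MLEM iterations and a 2-mm FWHM post-filter;
    the valley-to-peak criterion is applied between adjacent disk peaks of
    the z-profile.
    """
    geom = geo.build_system()
    grid = geo.default_grid_2mm()
    uniform = simulate(make_uniform_cylinder(grid), geom, n_uniform,
                       _subseed(seed, 3))
    A = axial_system_matrix(uniform, grid)
    nz = grid.dims[2]
    vz = grid.voxel_size[2]
    per_thickness = {}
    for t in DISK_THICKNESSES_MM:
        truth_z = make_disks(t, grid).values.sum(axis=(0, 1))
        y = forward_project(A, truth_z.reshape((1, 1, nz)))
        f = osem(A, y, ReconConfig(n_subsets=1, n_iterations=10))
        prof = gaussian_postfilter(f, 7, 2.0, (vz,))
        centers_idx = [int(round((zc - grid.origin[2]) / vz - 0.5))
                       for zc in disk_centers_mm(t)]
        centers_idx = [min(max(c, 0), nz - 1) for c in centers_idx]
        halfwidth = max(1, int(t / 2.0 / vz))
        _, separable = profile_separability(prof, centers_idx, threshold,
                                            halfwidth)
        per_thickness[t] = separable
    smallest = None
    for t in sorted(per_thickness, reverse=True):
        if per_thickness[t]:
            smallest = t
        else:
            break
    return dict(smallest_resolved_mm=smallest, n_uniform=n_uniform,
                per_thickness={f"{t:g}": v for t, v in per_thickness.items()})


# three two-point placements: pair centres and orientations inside the FOV
TWO_POINT_PLACEMENTS = (
    ((0.0, -4.0), (0.0, 4.0)),          # centred, vertical
    ((20.0, 6.0), (20.0, 14.0)),        # off-centre, vertical
    ((-28.0, -16.0), (-20.0, -16.0)),   # off-centre, horizontal
)
TWO_POINT_ACQ_S = 240.0
TWO_POINT_ACTIVITY_MCI = 0.45


def build_prototype_matrix(seed: int,
                           n_per_position: int = 50_000) -> "proto.PrototypeSysmat":
    """Simulate, expand and assemble the 13-position virtual-ring matrix."""
    geom = proto.PrototypeGeometry()
    coarse = proto.simulate_single_detector_matrix(
        geom, n_per_position, _subseed(seed, 4))
    fine = proto.expand_grid(coarse)
    A = proto.assemble_ring(fine)
    A.provenance["n_per_position"] = n_per_position
    return A


def prototype_two_point_study(seed: int, n_per_position: int = 50_000,
                              n_iterations: int = 150,
                              placements=TWO_POINT_PLACEMENTS,
                              ring_matrix=None) -> dict:
    """Recovered centre-to-centre distance of two point sources 8 mm apart.

    Simulates the single-detector response on the 35 x 35 grid, expands it
    to 103 x 103 by bicubic interpolation, assembles the 13-position ring,
    projects each source pair at the 240-s-equivalent photon budget and
    reconstructs with MLEM; the distance is measured between the two
    subvoxel-refined image peaks.
    """
    A = ring_matrix or build_prototype_matrix(seed, n_per_position)
    budget = TWO_POINT_ACTIVITY_MCI * MCI_TO_PHOTONS_PER_S * TWO_POINT_ACQ_S
    rng = np.random.default_rng(_subseed(seed, 5))
    ng = A.grid_xy.size
    pitch = A.grid_xy[1] - A.grid_xy[0]
    distances = []
    for (p0, p1) in placements:
        y = proto.multi_point_projection([(p0[0], p0[1], 1.0),
                                          (p1[0], p1[1], 1.0)], A, budget, rng)
        f = osem(A.matrix, y, ReconConfig(n_subsets=1,
                                          n_iterations=n_iterations))
        img = f.reshape((ng, ng))
        coords, complete = find_peaks_2d(img, 2, min_separation=5.0)
        if not complete:
            distances.append(float("nan"))
            continue
        distances.append(float(np.linalg.norm(coords[0] - coords[1]) * pitch))
    valid = [d for d in distances if np.isfinite(d)]
    return dict(distances_mm=distances,
                mean_distance_mm=float(np.mean(valid)) if valid else float("nan"),
                n_per_position=A.provenance.get("n_per_position",
                                                n_per_position))


def run_all_targets(seed: int, fast: bool = False) -> dict:
    """Recompute every headline figure; returns {name: {value, n}}."""
    scale = 50 if fast else 1
    sens = sensitivity_and_scatter(seed, 400_000 // scale)
    inplane = inplane_resolution(seed, 50_000_000 // scale)
    axial = axial_resolution(seed, 10_000_000 // scale)
    proto_res = prototype_two_point_study(seed, 50_000 // scale)
    return {
        "t2": {"value": sens["sensitivity_pct"], "n": sens["n_histories"]},
        "t3": {"value": sens["compton_fraction_pct"], "n": sens["n_histories"]},
        "t4": {"value": sens["inter_crystal_fraction_pct"],
               "n": sens["n_histories"]},
        "t6": {"value": inplane["smallest_separable_mm"],
               "n": inplane["n_histories"]},
        "t7": {"value": axial["smallest_resolved_mm"], "n": axial["n_uniform"]},
        "t8": {"value": proto_res["mean_distance_mm"],
               "n": proto_res["n_per_position"]},
    }
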