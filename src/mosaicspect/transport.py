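"""Analog Monte Carlo photon transport and event formation.

Photon histories start as 140 keV emissions distributed proportionally to a
voxelized activity image (uniform within each voxel, isotropic direction).
Free paths are sampled by Woodcock delta-tracking with the GAGG attenuation
at the current photon energy as majorant, which handles the fine mosaic
geometry without surface bookkeeping.  Real collisions branch into
photoelectric absorption (history ends, remaining energy deposited locally)
or Compton scattering with Klein–Nishina kinematics (energy deposited at
the interaction point, scattered photon continues).  Histories end on
escape from the world sphere or when the photon drops below 1 keV (the
residual energy is deposited locally to conserve energy exactly).

Energy deposited in GAGG segments is recorded per detector element; glass
and water deposits attenuate but produce no signal.  One event is formed
per history: the system-wide sum of GAGG deposits is blurred with the
20%-at-140-keV Gaussian response and tested against the 112–168 keV
acquisition window; the event is positioned at the element with the largest
single deposit (ties to the lowest flat bin index).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import geometry as geo
from .physics import (EnergyModel, MaterialID, MaterialTable, _kn_total_cm2,
                      _mu_mm, _sample_kn_cos, ELECTRON_REST_KEV)
from .phantoms import VoxelImage

__all__ = [
    "EventRecord", "ListModeSet", "simulate", "form_event",
    "scatter_fractions", "energy_spectrum", "SliceSystem",
    "build_slice_system", "simulate_slice2d", "slab_transmission",
    "pencil_interaction_fraction",
]

ENERGY_CUTOFF_KEV = 1.0
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

FLAG_ACCEPTED = np.uint8(1)
FLAG_SCATTERED_IN_ATTENUATOR = np.uint8(2)


# ---------------------------------------------------------------------------
# Jitted helpers
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _circle_interval(px, py, dx, dy, cx, cy, r):
    """Ray-parameter interval inside a circle (t_in, t_out); t_in > t_out if none."""
    rx = px - cx
    ry = py - cy
    a = dx * dx + dy * dy
    if a < 1e-14:
        if rx * rx + ry * ry <= r * r:
            return -1.0e30, 1.0e30
        return 1.0, 0.0
    b = rx * dx + ry * dy
    c = rx * rx + ry * ry - r * r
    disc = b * b - a * c
    if disc <= 0.0:
        return 1.0, 0.0
    sq = math.sqrt(disc)
    return (-b - sq) / a, (-b + sq) / a


@njit(cache=True, inline="always")
def _slab_interval(p, d, lo, hi):
    if abs(d) < 1e-14:
        if lo <= p <= hi:
            return -1.0e30, 1.0e30
        return 1.0, 0.0
    t0 = (lo - p) / d
    t1 = (hi - p) / d
    if t0 > t1:
        t0, t1 = t1, t0
    return t0, t1


@njit(cache=True, inline="always")
def _fly_3d(x, y, z, dx, dy, dz, cx, cy, bound_r, zmin, zmax,
            att_on, att_radius, att_half):
    """Distance to the nearest attenuating region along the ray.

    Returns 0.0 when already inside a region's bounding volume, a positive
    flight distance to the next entry, or -1.0 when no region lies ahead
    (the photon escapes through air).  Skipping the air gap analytically is
    exact because air does not attenuate.
    """
    best = 1.0e30
    for k in range(cx.shape[0]):
        t0, t1 = _circle_interval(x, y, dx, dy, cx[k], cy[k], bound_r)
        z0, z1 = _slab_interval(z, dz, zmin, zmax)
        t_in = max(t0, z0)
        t_out = min(t1, z1)
        if t_out <= t_in:
            continue
        if t_in <= 0.0 < t_out:
            return 0.0
        if 0.0 < t_in < best:
            best = t_in
    if att_on:
        t0, t1 = _circle_interval(x, y, dx, dy, 0.0, 0.0, att_radius)
        z0, z1 = _slab_interval(z, dz, -att_half, att_half)
        t_in = max(t0, z0)
        t_out = min(t1, z1)
        if t_out > t_in:
            if t_in <= 0.0 < t_out:
                return 0.0
            if 0.0 < t_in < best:
                best = t_in
    if best >= 1.0e29:
        return -1.0
    return best + 1.0e-6


@njit(cache=True, inline="always")
def _fly_2d(x, y, dx, dy, cx, cy, bound_r):
    best = 1.0e30
    for k in range(cx.shape[0]):
        t0, t1 = _circle_interval(x, y, dx, dy, cx[k], cy[k], bound_r)
        if t1 <= t0:
            continue
        if t0 <= 0.0 < t1:
            return 0.0
        if 0.0 < t0 < best:
            best = t0
    if best >= 1.0e29:
        return -1.0
    return best + 1.0e-6


@njit(cache=True, inline="always")
def _material_3d(x, y, z, cx, cy, cos_a, sin_a, pitch, half, grid_n, cell_id,
                 phase, zmin, zmax, seg_len, n_cells, n_seg,
                 att_on, att_radius, att_half):
    """Material code and flat detector-bin index (-1 if not GAGG) at a point."""
    bound2 = 2.0 * half * half          # circumscribed radius^2 of the grid
    if zmin <= z < zmax:
        for k in range(cx.shape[0]):
            dx = x - cx[k]
            dy = y - cy[k]
            if dx * dx + dy * dy > bound2:
                continue
            u = cos_a[k] * dx + sin_a[k] * dy
            v = -sin_a[k] * dx + cos_a[k] * dy
            if -half <= u < half and -half <= v < half:
                iu = int((u + half) / pitch)
                iv = int((v + half) / pitch)
                if iu >= grid_n:
                    iu = grid_n - 1
                if iv >= grid_n:
                    iv = grid_n - 1
                cid = cell_id[iu, iv]
                if cid >= 0:
                    t = int((z - zmin) / seg_len)
                    if t % 2 == phase[iu, iv]:
                        s = t // 2
                        return 1, (k * n_cells + cid) * n_seg + s   # GAGG
                    return 2, -1                                    # GLASS
                return 0, -1
    if att_on and abs(z) <= att_half:
        if x * x + y * y <= att_radius * att_radius:
            return 3, -1                                            # WATER
    return 0, -1                                                    # AIR


@njit(cache=True, inline="always")
def _rotate_direction(dx, dy, dz, cos_t, phi):
    """Rotate a unit vector by polar angle theta about itself, azimuth phi."""
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    # build an orthonormal basis around (dx, dy, dz)
    if abs(dz) < 0.99:
        ux, uy, uz = -dy, dx, 0.0
    else:
        ux, uy, uz = 0.0, -dz, dy
    un = math.sqrt(ux * ux + uy * uy + uz * uz)
    ux, uy, uz = ux / un, uy / un, uz / un
    vx = dy * uz - dz * uy
    vy = dz * ux - dx * uz
    vz = dx * uy - dy * ux
    cp, sp = math.cos(phi), math.sin(phi)
    nx = sin_t * (cp * ux + sp * vx) + cos_t * dx
    ny = sin_t * (cp * uy + sp * vy) + cos_t * dy
    nz = sin_t * (cp * uz + sp * vz) + cos_t * dz
    return nx, ny, nz


@njit(cache=True)
def _run3d(n_histories, seed, cdf, nx, ny, nz, ox, oy, oz, sx, sy, sz,
           cx, cy, cos_a, sin_a, pitch, half, grid_n, cell_id, phase,
           zmin, zmax, seg_len, n_cells, n_seg,
           att_on, att_radius, att_half, world_r,
           mu_pe140, mu_inc140, resolution, win_lo, win_hi, window_on,
           pe_force, adder_policy):
    np.random.seed(seed)
    n_vox = nx * ny * nz
    emitted = np.zeros(n_vox, dtype=np.int64)
    cap = n_histories + 1
    ev_bin = np.empty(cap, dtype=np.int32)
    ev_e = np.empty(cap, dtype=np.float32)
    ev_vox = np.empty(cap, dtype=np.int32)
    ev_nc = np.empty(cap, dtype=np.uint8)
    ev_ncg = np.empty(cap, dtype=np.uint8)
    ev_nel = np.empty(cap, dtype=np.uint8)
    ev_flags = np.empty(cap, dtype=np.uint8)
    n_ev = 0
    max_residual = 0.0
    world_r2 = world_r * world_r

    dep_bin = np.empty(64, dtype=np.int64)
    dep_e = np.empty(64, dtype=np.float64)

    for _ in range(n_histories):
        # emission voxel and position
        r = np.random.random()
        j = np.searchsorted(cdf, r)
        iz = j // (nx * ny)
        iy = (j - iz * nx * ny) // nx
        ix = j - iz * nx * ny - iy * nx
        emitted[j] += 1
        x = ox + (ix + np.random.random()) * sx
        y = oy + (iy + np.random.random()) * sy
        z = oz + (iz + np.random.random()) * sz
        # isotropic direction
        ct = 2.0 * np.random.random() - 1.0
        st = math.sqrt(1.0 - ct * ct)
        ph = 2.0 * math.pi * np.random.random()
        dx, dy, dz = st * math.cos(ph), st * math.sin(ph), ct

        e = 140.0
        ndep = 0
        n_compton = 0
        n_compton_gagg = 0
        scat_att = False
        other_dep = 0.0
        escaped = 0.0
        mu_maj = _mu_mm(1, e, mu_pe140, mu_inc140)

        bound_r = half * math.sqrt(2.0) + 1e-3
        while True:
            # analytic flight through the air gaps between regions
            fly = _fly_3d(x, y, z, dx, dy, dz, cx, cy, bound_r, zmin, zmax,
                          att_on, att_radius, att_half)
            if fly < 0.0:
                escaped = e
                break
            if fly > 0.0:
                x += dx * fly
                y += dy * fly
                z += dz * fly
            step = -math.log(np.random.random()) / mu_maj
            x += dx * step
            y += dy * step
            z += dz * step
            if x * x + y * y + z * z > world_r2:
                escaped = e
                break
            mat, flat = _material_3d(x, y, z, cx, cy, cos_a, sin_a, pitch,
                                     half, grid_n, cell_id, phase, zmin, zmax,
                                     seg_len, n_cells, n_seg,
                                     att_on, att_radius, att_half)
            if mat == 0:
                continue
            mu = _mu_mm(mat, e, mu_pe140, mu_inc140)
            if np.random.random() * mu_maj > mu:
                continue                 # null collision
            if pe_force >= 0.0:
                p_pe = pe_force
            else:
                mu_pe = mu_pe140[mat] * (140.0 / e) ** 3
                p_pe = mu_pe / mu
            if np.random.random() < p_pe:
                # photoelectric absorption
                if mat == 1:
                    dep_bin[ndep] = flat
                    dep_e[ndep] = e
                    ndep += 1
                else:
                    other_dep += e
                e = 0.0
                break
            # Compton scatter
            cos_sc = _sample_kn_cos(e)
            e_new = e / (1.0 + (e / ELECTRON_REST_KEV) * (1.0 - cos_sc))
            de = e - e_new
            if mat == 1:
                if ndep < 64:
                    dep_bin[ndep] = flat
                    dep_e[ndep] = de
                    ndep += 1
                else:
                    dep_e[ndep - 1] += de
                n_compton += 1
                n_compton_gagg += 1
            elif mat == 2:
                other_dep += de
                n_compton += 1
            else:
                other_dep += de
                scat_att = True
            phi_sc = 2.0 * math.pi * np.random.random()
            dx, dy, dz = _rotate_direction(dx, dy, dz, cos_sc, phi_sc)
            if e_new < ENERGY_CUTOFF_KEV:
                # local absorption of the residual photon
                if mat == 1:
                    if ndep < 64:
                        dep_bin[ndep] = flat
                        dep_e[ndep] = e_new
                        ndep += 1
                    else:
                        dep_e[ndep - 1] += e_new
                else:
                    other_dep += e_new
                e = 0.0
                break
            e = e_new
            mu_maj = _mu_mm(1, e, mu_pe140, mu_inc140)

        gagg_sum = 0.0
        for d in range(ndep):
            gagg_sum += dep_e[d]
        residual = abs(140.0 - (gagg_sum + other_dep + escaped))
        if residual > max_residual:
            max_residual = residual
        if ndep == 0:
            continue

        # winning element: largest single deposit, ties to lowest flat index
        best = 0
        for d in range(1, ndep):
            if dep_e[d] > dep_e[best] or \
               (dep_e[d] == dep_e[best] and dep_bin[d] < dep_bin[best]):
                best = d
        # distinct elements hit
        n_el = 0
        for d in range(ndep):
            seen = False
            for d2 in range(d):
                if dep_bin[d2] == dep_bin[d]:
                    seen = True
                    break
            if not seen:
                n_el += 1

        # summation scope of the energy signal (the "adder" policy)
        if adder_policy == 0:            # system-wide
            e_sum = gagg_sum
        else:
            if adder_policy == 1:        # per module
                group = dep_bin[best] // (n_cells * n_seg)
                div = n_cells * n_seg
            elif adder_policy == 2:      # per bar
                group = dep_bin[best] // n_seg
                div = n_seg
            else:                        # per element
                group = dep_bin[best]
                div = 1
            e_sum = 0.0
            for d in range(ndep):
                if dep_bin[d] // div == group:
                    e_sum += dep_e[d]

        sigma = resolution * math.sqrt(140.0 * e_sum) * FWHM_TO_SIGMA
        e_meas = e_sum + sigma * np.random.standard_normal()
        accepted = win_lo <= e_meas <= win_hi
        if window_on and not accepted:
            continue
        flags = np.uint8(0)
        if accepted:
            flags |= np.uint8(1)
        if scat_att:
            flags |= np.uint8(2)
        ev_bin[n_ev] = dep_bin[best]
        ev_e[n_ev] = e_meas
        ev_vox[n_ev] = j
        ev_nc[n_ev] = min(n_compton, 255)
        ev_ncg[n_ev] = min(n_compton_gagg, 255)
        ev_nel[n_ev] = min(n_el, 255)
        ev_flags[n_ev] = flags
        n_ev += 1

    return (ev_bin[:n_ev], ev_e[:n_ev], ev_vox[:n_ev], ev_nc[:n_ev],
            ev_ncg[:n_ev], ev_nel[:n_ev], ev_flags[:n_ev], emitted,
            max_residual)


@njit(cache=True)
def _run2d(n_histories, seed, cdf, n_pix, ox, px_size,
           cx, cy, cos_a, sin_a, pitch, half, grid_n, cell_id, n_cells,
           world_r, mu_pe140, mu_inc140, resolution, win_lo, win_hi,
           window_on, pe_force):
    """In-plane transport through the single-slice ring (bins = module*cell)."""
    np.random.seed(seed)
    n_vox = n_pix * n_pix
    emitted = np.zeros(n_vox, dtype=np.int64)
    cap = n_histories + 1
    ev_bin = np.empty(cap, dtype=np.int32)
    ev_vox = np.empty(cap, dtype=np.int32)
    n_ev = 0
    world_r2 = world_r * world_r
    bound2 = 2.0 * half * half

    dep_bin = np.empty(64, dtype=np.int64)
    dep_e = np.empty(64, dtype=np.float64)

    for _ in range(n_histories):
        r = np.random.random()
        j = np.searchsorted(cdf, r)
        iy = j // n_pix
        ix = j - iy * n_pix
        emitted[j] += 1
        x = ox + (ix + np.random.random()) * px_size
        y = ox + (iy + np.random.random()) * px_size
        ph = 2.0 * math.pi * np.random.random()
        dx, dy = math.cos(ph), math.sin(ph)

        e = 140.0
        ndep = 0
        mu_maj = _mu_mm(1, e, mu_pe140, mu_inc140)
        bound_r = half * math.sqrt(2.0) + 1e-3

        while True:
            fly = _fly_2d(x, y, dx, dy, cx, cy, bound_r)
            if fly < 0.0:
                break
            if fly > 0.0:
                x += dx * fly
                y += dy * fly
            step = -math.log(np.random.random()) / mu_maj
            x += dx * step
            y += dy * step
            if x * x + y * y > world_r2:
                break
            mat = 0
            flat = -1
            for k in range(cx.shape[0]):
                ddx = x - cx[k]
                ddy = y - cy[k]
                if ddx * ddx + ddy * ddy > bound2:
                    continue
                u = cos_a[k] * ddx + sin_a[k] * ddy
                v = -sin_a[k] * ddx + cos_a[k] * ddy
                if -half <= u < half and -half <= v < half:
                    iu = int((u + half) / pitch)
                    iv = int((v + half) / pitch)
                    if iu >= grid_n:
                        iu = grid_n - 1
                    if iv >= grid_n:
                        iv = grid_n - 1
                    cid = cell_id[iu, iv]
                    if cid >= 0:
                        mat = 1
                        flat = k * n_cells + cid
                    break
            if mat == 0:
                continue
            mu = _mu_mm(mat, e, mu_pe140, mu_inc140)
            if np.random.random() * mu_maj > mu:
                continue
            if pe_force >= 0.0:
                p_pe = pe_force
            else:
                mu_pe = mu_pe140[mat] * (140.0 / e) ** 3
                p_pe = mu_pe / mu
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
            # in-plane deflection; the azimuth picks the rotation sense
            sgn = 1.0 if np.random.random() < 0.5 else -1.0
            sin_sc = sgn * math.sqrt(max(0.0, 1.0 - cos_sc * cos_sc))
            ndx = cos_sc * dx - sin_sc * dy
            ndy = sin_sc * dx + cos_sc * dy
            dx, dy = ndx, ndy
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
        if window_on and not (win_lo <= e_meas <= win_hi):
            continue
        ev_bin[n_ev] = dep_bin[best]
        ev_vox[n_ev] = j
        n_ev += 1

    return ev_bin[:n_ev], ev_vox[:n_ev], emitted


@njit(cache=True)
def _slab_transmission(mus_mm, lengths_mm, n, seed):
    """Delta-tracking transmission through consecutive 1-D slabs (oracle)."""
    np.random.seed(seed)
    total = 0.0
    for s in range(lengths_mm.shape[0]):
        total += lengths_mm[s]
    mu_maj = mus_mm.max()
    transmitted = 0
    for _ in range(n):
        x = 0.0
        while True:
            x += -math.log(np.random.random()) / mu_maj
            if x >= total:
                transmitted += 1
                break
            acc = 0.0
            mu = 0.0
            for s in range(lengths_mm.shape[0]):
                acc += lengths_mm[s]
                if x < acc:
                    mu = mus_mm[s]
                    break
            if np.random.random() * mu_maj <= mu:
                break
    return transmitted / n


# ---------------------------------------------------------------------------
# Python-level containers and operations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EventRecord:
    """One detected photon history."""

    bin: int
    e_measured: float
    emission_voxel: int
    n_compton_detector: int
    n_gagg_elements_hit: int
    scattered_in_attenuator: bool
    accepted: bool


@dataclass
class ListModeSet:
    """Arrays of detected events plus per-voxel emission bookkeeping."""

    bin: np.ndarray
    e_measured: np.ndarray
    emission_voxel: np.ndarray
    n_compton_detector: np.ndarray       # Compton interactions in GAGG or glass
    n_compton_gagg: np.ndarray           # the GAGG-only subset
    n_gagg_elements_hit: np.ndarray
    flags: np.ndarray
    emitted_per_voxel: np.ndarray
    n_histories: int
    seed: int
    max_energy_residual_kev: float = 0.0
    window_applied: bool = True

    def __len__(self):
        return int(self.bin.shape[0])

    @property
    def accepted(self) -> np.ndarray:
        return (self.flags & FLAG_ACCEPTED) != 0

    @property
    def scattered_in_attenuator(self) -> np.ndarray:
        return (self.flags & FLAG_SCATTERED_IN_ATTENUATOR) != 0

    def records(self):
        for i in range(len(self)):
            yield EventRecord(int(self.bin[i]), float(self.e_measured[i]),
                              int(self.emission_voxel[i]),
                              int(self.n_compton_detector[i]),
                              int(self.n_gagg_elements_hit[i]),
                              bool(self.flags[i] & FLAG_SCATTERED_IN_ATTENUATOR),
                              bool(self.flags[i] & FLAG_ACCEPTED))

    # -- I/O ----------------------------------------------------------------

    def to_hdf5(self, path, extra_meta: dict | None = None) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            for name in ("bin", "e_measured", "emission_voxel",
                         "n_compton_detector", "n_compton_gagg",
                         "n_gagg_elements_hit", "flags", "emitted_per_voxel"):
                fh.create_dataset(name, data=getattr(self, name))
            fh.attrs["n_histories"] = self.n_histories
            fh.attrs["seed"] = self.seed
            fh.attrs["window_applied"] = self.window_applied
        sidecar = dict(n_histories=int(self.n_histories), seed=int(self.seed),
                       n_events=len(self), window_applied=self.window_applied)
        if extra_meta:
            sidecar.update(extra_meta)
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def from_hdf5(cls, path) -> "ListModeSet":
        import h5py

        with h5py.File(path, "r") as fh:
            kw = {name: fh[name][...] for name in
                  ("bin", "e_measured", "emission_voxel", "n_compton_detector",
                   "n_compton_gagg", "n_gagg_elements_hit", "flags",
                   "emitted_per_voxel")}
            return cls(n_histories=int(fh.attrs["n_histories"]),
                       seed=int(fh.attrs["seed"]),
                       window_applied=bool(fh.attrs["window_applied"]), **kw)


def _activity_cdf(values_flat: np.ndarray) -> np.ndarray:
    total = values_flat.sum()
    if total <= 0:
        raise ValueError("empty source: activity image is all zero")
    cdf = np.cumsum(values_flat) / total
    cdf[-1] = 1.0
    return cdf


ADDER_POLICIES = {"system": 0, "module": 1, "bar": 2, "element": 3}
DEFAULT_ADDER_POLICY = "bar"


def simulate(activity: VoxelImage, geom: geo.SystemGeometry, n_histories: int,
             seed: int, window_on: bool = True,
             energy_model: EnergyModel | None = None,
             material_table: MaterialTable | None = None,
             pe_force: float | None = None,
             adder_policy: str = DEFAULT_ADDER_POLICY) -> ListModeSet:
    """Run ``n_histories`` photon histories and return the list-mode set.

    ``window_on=False`` keeps all detected events (with their acceptance
    flag) so energy spectra can be formed; ``pe_force`` overrides the
    photoelectric branching probability in every material (diagnostics).
    ``adder_policy`` sets the summation scope of the energy signal tested
    against the window: each scintillator bar is read out independently by
    its own SiPM pair, so ``"bar"`` (sum the deposits of the winning bar)
    is the default; ``"system"``, ``"module"`` and ``"element"`` are
    available for sensitivity studies of this choice.
    """
    if n_histories < 0:
        raise ValueError("n_histories must be non-negative")
    if adder_policy not in ADDER_POLICIES:
        raise ValueError(f"unknown adder policy {adder_policy!r}")
    model = energy_model or EnergyModel()
    table = material_table or MaterialTable()
    flat = activity.flatten()
    cdf = _activity_cdf(flat)
    grid = activity.grid
    p = geo.pack_geometry(geom)
    mu_pe, mu_inc = table.packed()
    out = _run3d(int(n_histories), int(seed), cdf,
                 grid.dims[0], grid.dims[1], grid.dims[2],
                 grid.origin[0], grid.origin[1], grid.origin[2],
                 grid.voxel_size[0], grid.voxel_size[1], grid.voxel_size[2],
                 p["cx"], p["cy"], p["cos_a"], p["sin_a"], p["pitch"],
                 p["half"], p["grid_n"], p["cell_id"], p["phase"],
                 p["zmin"], p["zmax"], p["seg_len"], p["n_cells"], p["n_seg"],
                 p["att_on"], p["att_radius"], p["att_half"],
                 p["world_radius"], mu_pe, mu_inc, model.resolution,
                 model.window_kev[0], model.window_kev[1], window_on,
                 -1.0 if pe_force is None else float(pe_force),
                 ADDER_POLICIES[adder_policy])
    (ev_bin, ev_e, ev_vox, ev_nc, ev_ncg, ev_nel, ev_flags, emitted,
     residual) = out
    return ListModeSet(ev_bin, ev_e, ev_vox, ev_nc, ev_ncg, ev_nel, ev_flags,
                       emitted, int(n_histories), int(seed), float(residual),
                       window_applied=window_on)


def form_event(deposits, energy_model: EnergyModel,
               rng: np.random.Generator,
               scattered_in_attenuator: bool = False,
               n_compton_detector: int = 0,
               emission_voxel: int = -1,
               adder_policy: str = DEFAULT_ADDER_POLICY) -> EventRecord | None:
    """Form one event from per-element GAGG deposits ``[(flat_bin, keV), ...]``.

    Mirrors the in-kernel positioning logic: the winner is the element with
    the largest single deposit (ties to the lowest flat index) and the
    energy signal sums the deposits within the winner's ``adder_policy``
    scope (bar by default).  Returns ``None`` when there is no GAGG deposit
    or the blurred energy falls outside the window.
    """
    if not deposits:
        return None
    for _, e in deposits:
        if e < 0:
            raise ValueError("negative deposit")
    winner = min(deposits, key=lambda be: (-be[1], be[0]))[0]
    divisor = {"system": None, "module": geo.BINS_PER_MODULE,
               "bar": geo.GAGG_SEGMENTS_PER_BAR, "element": 1}[adder_policy]
    if divisor is None:
        e_true = float(sum(e for _, e in deposits))
    else:
        e_true = float(sum(e for b, e in deposits
                           if b // divisor == winner // divisor))
    n_elements = len({b for b, _ in deposits})
    sigma = energy_model.sigma(e_true)
    e_meas = e_true + sigma * rng.standard_normal() if sigma > 0 else e_true
    if not energy_model.in_window(e_meas):
        return None
    return EventRecord(int(winner), float(e_meas), emission_voxel,
                       n_compton_detector, n_elements,
                       scattered_in_attenuator, True)


def scatter_fractions(events: ListModeSet) -> tuple:
    """(% accepted events with detector Compton, % of those hitting >= 2 elements)."""
    acc = events.accepted
    n_acc = int(acc.sum())
    if n_acc == 0:
        raise ValueError("undefined statistic: no accepted events")
    compton = acc & (events.n_compton_detector >= 1)
    n_compton = int(compton.sum())
    compton_fraction = 100.0 * n_compton / n_acc
    if n_compton == 0:
        return compton_fraction, 0.0
    inter = compton & (events.n_gagg_elements_hit >= 2)
    return compton_fraction, 100.0 * int(inter.sum()) / n_compton


def energy_spectrum(events: ListModeSet, bin_edges) -> np.ndarray:
    """Histogram of measured event energies (window disabled upstream)."""
    edges = np.asarray(bin_edges, dtype=float)
    if len(events) == 0:
        return np.zeros(edges.size - 1, dtype=np.int64)
    hist, _ = np.histogram(events.e_measured, bins=edges)
    return hist


# ---------------------------------------------------------------------------
# Single-slice ("slice2d") system
# ---------------------------------------------------------------------------


@dataclass
class SliceSystem:
    """One axial slice of the 7-module ring with single-GAGG-segment bars.

    Bins are ``module * n_bars + bar``; the source plane is an ``n_pix`` x
    ``n_pix`` pixel grid centred on the axis.
    """

    cx: np.ndarray
    cy: np.ndarray
    cos_a: np.ndarray
    sin_a: np.ndarray
    pitch: float
    half: float
    grid_n: int
    cell_id: np.ndarray
    n_cells: int
    n_pix: int = 90
    pixel_mm: float = 2.0
    world_radius: float = geo.WORLD_RADIUS_MM

    @property
    def n_bins(self) -> int:
        return self.cx.shape[0] * self.n_cells

    @property
    def pixel_origin(self) -> float:
        return -self.n_pix * self.pixel_mm / 2.0

    def pixel_centers(self) -> np.ndarray:
        return self.pixel_origin + (np.arange(self.n_pix) + 0.5) * self.pixel_mm


def build_slice_system(config: geo.SystemConfig | None = None,
                       n_pix: int = 90, pixel_mm: float = 2.0) -> SliceSystem:
    system = geo.build_system(config)
    p = geo.pack_geometry(system)
    return SliceSystem(p["cx"], p["cy"], p["cos_a"], p["sin_a"], p["pitch"],
                       p["half"], p["grid_n"], p["cell_id"], p["n_cells"],
                       n_pix, pixel_mm, p["world_radius"])


def simulate_slice2d(activity_2d: np.ndarray, system: SliceSystem,
                     n_histories: int, seed: int, window_on: bool = True,
                     energy_model: EnergyModel | None = None,
                     material_table: MaterialTable | None = None,
                     pe_force: float | None = None):
    """In-plane Monte Carlo run; returns (bin, pixel) event arrays + emissions."""
    model = energy_model or EnergyModel()
    table = material_table or MaterialTable()
    flat = np.asarray(activity_2d, dtype=np.float64).ravel(order="F")
    cdf = _activity_cdf(flat)
    mu_pe, mu_inc = table.packed()
    ev_bin, ev_vox, emitted = _run2d(
        int(n_histories), int(seed), cdf, system.n_pix, system.pixel_origin,
        system.pixel_mm, system.cx, system.cy, system.cos_a, system.sin_a,
        system.pitch, system.half, system.grid_n, system.cell_id,
        system.n_cells, system.world_radius, mu_pe, mu_inc, model.resolution,
        model.window_kev[0], model.window_kev[1], window_on,
        -1.0 if pe_force is None else float(pe_force))
    return ev_bin, ev_vox, emitted


# ---------------------------------------------------------------------------
# Slab oracles (verification utilities for the delta-tracking sampler)
# ---------------------------------------------------------------------------


def slab_transmission(mus_per_cm, lengths_mm, n: int, seed: int) -> float:
    """Monte Carlo non-interaction probability through stacked slabs.

    Uses the same Woodcock free-path sampling as the transport kernels, so
    agreement with ``exp(-sum(mu_i * L_i))`` validates the sampler.
    """
    mus = np.asarray(mus_per_cm, dtype=np.float64) / 10.0
    lengths = np.asarray(lengths_mm, dtype=np.float64)
    if mus.shape != lengths.shape:
        raise ValueError("mus and lengths must have the same shape")
    return float(_slab_transmission(mus, lengths, int(n), int(seed)))


def pencil_interaction_fraction(mu_per_cm: float, length_mm: float,
                                n: int, seed: int) -> float:
    """Fraction of pencil-beam photons interacting in a homogeneous slab."""
    return 1.0 - slab_transmission([mu_per_cm], [length_mm], n, seed)
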