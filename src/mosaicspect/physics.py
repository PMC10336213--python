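"""Photon-interaction physics for the mosaic-scintillator simulator.

The transport model is deliberately minimal: photons in the 50–160 keV range
interact by photoelectric absorption or incoherent (Compton) scattering only.
Each material is described by two numbers at the 140 keV reference energy —
its total linear attenuation coefficient and its electron density — from
which the energy dependence is built analytically:

* the incoherent part follows the total Klein–Nishina cross-section per
  electron times the material electron density;
* the remainder of the total attenuation at 140 keV is treated as
  photoelectric-like absorption and scaled with the standard ``E**-3`` law.

Coherent (Rayleigh) scattering, fluorescence escape and Doppler broadening
are not modelled; the residual non-Compton attenuation is folded into the
absorption channel.  The 140 keV GAGG(Ce) and K-9 glass coefficients are
pinned to their measured values (4.746 and 0.399 cm^-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from numba import njit

__all__ = [
    "MaterialID",
    "MaterialTable",
    "EnergyModel",
    "attenuation",
    "sample_interaction",
    "sample_compton",
    "blur_and_window",
    "klein_nishina_total",
    "klein_nishina_pdf",
    "klein_nishina_cdf",
    "compton_scattered_energy",
]

ELECTRON_REST_KEV = 511.0
R_E_CM = 2.8179403262e-13  # classical electron radius, cm
AVOGADRO = 6.02214076e23

E_MIN_KEV = 10.0
E_MAX_KEV = 200.0
REFERENCE_KEV = 140.0


class MaterialID(IntEnum):
    """The four materials the simulator distinguishes."""

    AIR = 0
    GAGG = 1
    GLASS = 2
    WATER = 3


@njit(cache=True)
def _kn_total_cm2(e_kev):
    """Total Klein–Nishina cross-section per electron (cm^2)."""
    k = e_kev / ELECTRON_REST_KEV
    if k <= 0.0:
        return 0.0
    one_two_k = 1.0 + 2.0 * k
    log_term = math.log(one_two_k)
    t1 = (1.0 + k) / (k * k) * (2.0 * (1.0 + k) / one_two_k - log_term / k)
    t2 = log_term / (2.0 * k)
    t3 = (1.0 + 3.0 * k) / (one_two_k * one_two_k)
    return 2.0 * math.pi * R_E_CM * R_E_CM * (t1 + t2 - t3)


def klein_nishina_total(e_kev: float) -> float:
    """Total Klein–Nishina cross-section per electron at ``e_kev`` (cm^2)."""
    return float(_kn_total_cm2(float(e_kev)))


def compton_scattered_energy(e_kev: float, cos_theta: float) -> float:
    """Energy of a photon of ``e_kev`` Compton-scattered through ``theta``."""
    return e_kev / (1.0 + (e_kev / ELECTRON_REST_KEV) * (1.0 - cos_theta))


def klein_nishina_pdf(cos_theta, e_kev: float):
    """Unnormalised Klein–Nishina differential cross-section in cos(theta)."""
    cos_theta = np.asarray(cos_theta, dtype=float)
    k = e_kev / ELECTRON_REST_KEV
    r = 1.0 / (1.0 + k * (1.0 - cos_theta))  # E'/E
    sin2 = 1.0 - cos_theta**2
    return r * r * (r + 1.0 / r - sin2)


def klein_nishina_cdf(cos_theta, e_kev: float, n_quad: int = 20001):
    """Numerically integrated CDF of cos(theta) for Klein–Nishina sampling.

    Used as an independent oracle against the rejection sampler.
    """
    grid = np.linspace(-1.0, 1.0, n_quad)
    pdf = klein_nishina_pdf(grid, e_kev)
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) * 0.5 * np.diff(grid))])
    cdf /= cdf[-1]
    return np.interp(np.asarray(cos_theta, dtype=float), grid, cdf)


# ---------------------------------------------------------------------------
# Material table
# ---------------------------------------------------------------------------

# (total mu at 140 keV [cm^-1], density [g/cm^3], Z/A)
# GAGG = Gd3Al2Ga3O12 (rho 6.63): Z/A = 407/926.87
# K-9 borosilicate crown glass: rho 2.53, Z/A ~= 0.497
# Water: mu(140) from standard photon-attenuation compilations.
_DEFAULTS = {
    MaterialID.AIR: (0.0, 0.0, 0.0),
    MaterialID.GAGG: (4.746, 6.63, 0.43911),
    MaterialID.GLASS: (0.399, 2.53, 0.4965),
    MaterialID.WATER: (0.154, 1.0, 0.55509),
}


@dataclass
class MaterialTable:
    """Attenuation and interaction-branching data for the four materials.

    ``mu(material, E)`` is the total linear attenuation coefficient (cm^-1)
    and ``pe_fraction(material, E)`` the probability that an interaction is
    photoelectric (the complement is Compton).  Values at 140 keV are pinned
    to the constructor constants; the energy dependence follows the
    two-component model in the module docstring.
    """

    mu_140: dict = field(default_factory=lambda: {m: _DEFAULTS[m][0] for m in MaterialID})
    density: dict = field(default_factory=lambda: {m: _DEFAULTS[m][1] for m in MaterialID})
    z_over_a: dict = field(default_factory=lambda: {m: _DEFAULTS[m][2] for m in MaterialID})

    def electron_density(self, material: MaterialID) -> float:
        """Electrons per cm^3."""
        return AVOGADRO * self.density[material] * self.z_over_a[material]

    def mu_incoherent(self, material: MaterialID, e_kev: float) -> float:
        return self.electron_density(material) * klein_nishina_total(e_kev)

    def mu_photoelectric(self, material: MaterialID, e_kev: float) -> float:
        base = max(self.mu_140[material] - self.mu_incoherent(material, REFERENCE_KEV), 0.0)
        return base * (REFERENCE_KEV / e_kev) ** 3

    def mu(self, material: MaterialID, e_kev: float) -> float:
        if not (E_MIN_KEV <= e_kev <= E_MAX_KEV):
            raise ValueError(f"energy {e_kev} keV outside tabulated range "
                             f"[{E_MIN_KEV}, {E_MAX_KEV}]")
        if material == MaterialID.AIR:
            return 0.0
        return self.mu_photoelectric(material, e_kev) + self.mu_incoherent(material, e_kev)

    def pe_fraction(self, material: MaterialID, e_kev: float) -> float:
        mu = self.mu(material, e_kev)
        if mu == 0.0:
            return 0.0
        return self.mu_photoelectric(material, e_kev) / mu

    # -- serialisation ------------------------------------------------------

    def to_csv(self, path, energies=None) -> None:
        """Write a (material, energy_keV, mu_per_cm, pe_fraction) table."""
        if energies is None:
            energies = np.arange(10.0, 201.0, 5.0)
        with open(path, "w") as fh:
            fh.write("material,energy_keV,mu_per_cm,pe_fraction\n")
            for m in MaterialID:
                for e in energies:
                    fh.write(f"{m.name},{e:.1f},{self.mu(m, e):.6e},"
                             f"{self.pe_fraction(m, e):.6f}\n")

    @classmethod
    def from_constants(cls, mu_140=None, density=None, z_over_a=None) -> "MaterialTable":
        table = cls()
        for target, override in ((table.mu_140, mu_140), (table.density, density),
                                 (table.z_over_a, z_over_a)):
            if override:
                target.update({MaterialID[k] if isinstance(k, str) else k: v
                               for k, v in override.items()})
        return table

    def packed(self):
        """Per-material (mu_pe_140, mu_inc_140) in mm^-1 for the jit kernels."""
        mu_pe = np.zeros(4)
        mu_inc = np.zeros(4)
        for m in MaterialID:
            mu_inc[int(m)] = self.mu_incoherent(m, REFERENCE_KEV) / 10.0
            mu_pe[int(m)] = max(self.mu_140[m] / 10.0 - mu_inc[int(m)], 0.0)
        return mu_pe, mu_inc


@njit(cache=True, inline="always")
def _mu_mm(material, e_kev, mu_pe140, mu_inc140):
    """Total attenuation in mm^-1 inside the transport kernels."""
    scale_pe = (REFERENCE_KEV / e_kev) ** 3
    scale_inc = _kn_total_cm2(e_kev) / _kn_total_cm2(REFERENCE_KEV)
    return mu_pe140[material] * scale_pe + mu_inc140[material] * scale_inc


@njit(cache=True, inline="always")
def _pe_prob(material, e_kev, mu_pe140, mu_inc140):
    mu_pe = mu_pe140[material] * (REFERENCE_KEV / e_kev) ** 3
    mu_inc = mu_inc140[material] * _kn_total_cm2(e_kev) / _kn_total_cm2(REFERENCE_KEV)
    total = mu_pe + mu_inc
    if total <= 0.0:
        return 0.0
    return mu_pe / total


# ---------------------------------------------------------------------------
# Energy response
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnergyModel:
    """Gaussian energy response and the photopeak acquisition window.

    The fractional FWHM scales as ``resolution * sqrt(reference/E)`` so that
    the absolute FWHM grows like sqrt(E), the usual statistical behaviour of
    scintillation light yield.
    """

    resolution: float = 0.20           # FWHM / E at the reference energy
    reference_kev: float = REFERENCE_KEV
    window_kev: tuple = (112.0, 168.0)

    def fwhm(self, e_kev: float) -> float:
        if e_kev <= 0.0:
            return 0.0
        return self.resolution * math.sqrt(self.reference_kev * e_kev)

    def sigma(self, e_kev: float) -> float:
        return self.fwhm(e_kev) / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    def in_window(self, e_kev: float) -> bool:
        lo, hi = self.window_kev
        return lo <= e_kev <= hi


# ---------------------------------------------------------------------------
# Spec-level operations (thin wrappers used by the API and the test suite;
# the transport kernels use the jitted internals directly)
# ---------------------------------------------------------------------------


def attenuation(material: MaterialID, e_kev: float,
                table: MaterialTable | None = None) -> float:
    """Total linear attenuation coefficient (cm^-1) of ``material`` at ``e_kev``."""
    table = table or MaterialTable()
    return table.mu(material, e_kev)


def sample_interaction(material: MaterialID, e_kev: float, rng: np.random.Generator,
                       table: MaterialTable | None = None,
                       pe_fraction: float | None = None) -> str:
    """Draw the interaction type: ``"PHOTOELECTRIC"`` or ``"COMPTON"``.

    ``pe_fraction`` overrides the table-derived branching (used by tests and
    physics-variation studies).
    """
    table = table or MaterialTable()
    if table.mu(material, e_kev) <= 0.0 and pe_fraction is None:
        raise ValueError(f"material {material.name} does not absorb at {e_kev} keV")
    p = table.pe_fraction(material, e_kev) if pe_fraction is None else pe_fraction
    return "PHOTOELECTRIC" if rng.random() < p else "COMPTON"


@njit(cache=True)
def _sample_kn_cos(e_kev):
    """Rejection-sample cos(theta) from the Klein–Nishina distribution.

    The unnormalised density r^2 (r + 1/r - sin^2) with r = E'/E is bounded
    by its forward-scatter value 2.
    """
    k = e_kev / ELECTRON_REST_KEV
    while True:
        c = 2.0 * np.random.random() - 1.0
        r = 1.0 / (1.0 + k * (1.0 - c))
        f = r * r * (r + 1.0 / r - (1.0 - c * c))
        if np.random.random() * 2.0 <= f:
            return c


@njit(cache=True)
def _sample_kn_many(e_kev, n, seed):
    np.random.seed(seed)
    out = np.empty(n)
    for i in range(n):
        out[i] = _sample_kn_cos(e_kev)
    return out


def sample_compton(e_kev: float, rng_or_seed) -> tuple:
    """Sample a Compton scatter: ``(E_scattered, polar_angle, azimuth)``.

    The polar angle is drawn from the Klein–Nishina differential
    cross-section; the azimuth is uniform on [0, 2*pi).
    """
    if e_kev <= 0.0:
        raise ValueError("photon energy must be positive")
    if isinstance(rng_or_seed, (int, np.integer)):
        seed = int(rng_or_seed)
        phi_rng = np.random.default_rng(seed)
    else:
        seed = int(rng_or_seed.integers(0, 2**31 - 1))
        phi_rng = rng_or_seed
    cos_theta = float(_sample_kn_many(e_kev, 1, seed)[0])
    theta = math.acos(min(1.0, max(-1.0, cos_theta)))
    phi = 2.0 * math.pi * phi_rng.random()
    return compton_scattered_energy(e_kev, cos_theta), theta, phi


def sample_compton_cosines(e_kev: float, n: int, seed: int) -> np.ndarray:
    """Vectorised draw of ``n`` Klein–Nishina cos(theta) samples (for tests)."""
    return _sample_kn_many(float(e_kev), int(n), int(seed))


def blur_and_window(e_true: float, model: EnergyModel,
                    rng: np.random.Generator) -> tuple:
    """Apply Gaussian energy blurring and the acquisition window.

    Returns ``(E_measured, accepted)``.
    """
    if e_true < 0.0:
        raise ValueError("true energy must be non-negative")
    sigma = model.sigma(e_true)
    e_meas = e_true + sigma * rng.standard_normal() if sigma > 0.0 else e_true
    return e_meas, model.in_window(e_meas)
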