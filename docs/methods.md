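# Methods

`mosaicspect` is a desk-scale simulator and reconstruction toolkit for a
collimator-less cardiac SPECT design built from sparse, interspaced
("mosaic") scintillator bars.  This note records the model, its
assumptions, the parameters that matter, and the choices made where the
design was genuinely open.

## Imaging model

Conventional SPECT forms projections with a heavy-metal collimator that
absorbs all photons outside a narrow acceptance cone.  The system modelled
here removes the collimator: GAGG(Ce) scintillator bars are placed sparsely
on a regular grid, so each bar is partially shadowed by the bars in front of
it.  The attenuation pattern depends on the photon's direction, which makes
the count distribution over the detector elements ("the projection") a
function of the source position.  Image formation is then the generic
emission-tomography model

    y ~ Poisson(A f),      A[i, j] = P(photon emitted in voxel j is
                                       recorded in detector bin i)

with `A` estimated by Monte Carlo from a uniform source filling the field
of view, and `f` recovered by OSEM/MLEM.

### Geometry

* 7 detector modules on a 600-mm-diameter circle, centred (by choice, the
  phase of the half-ring is not critical) at −60°…+120° in 30° steps; the
  overlap check rejects configurations whose block cylinders intersect.
* Each module: 10 axially stacked blocks, each a 149.52 mm (dia.) × 20 mm
  cylinder holding 768 bars of 1.68 × 1.68 × 20 mm on an 89 × 89 cell grid.
* Each bar interlaces five 2-mm GAGG(Ce) segments with five 2-mm optical
  glass segments; over the 200-mm module a bar contributes 50 resolvable
  GAGG segments (dual-end light readout is abstracted as perfect axial
  segment identification).  Total: 268,800 detector bins.
* Field of view: 180 mm (dia.) × 100 mm cylinder at the isocentre; an
  optional water cylinder (200 mm dia. × 100 mm) models body attenuation.

Two aspects of the block are only published as drawings and are therefore
parametrised rather than copied:

* **Trans-axial occupancy.**  The 768 occupied cells are drawn by seeded
  stratified sampling under two constraints — no fully-occupied 2 × 2 cell
  square, and at most two occupied neighbours per 3 × 3 neighbourhood —
  which reproduces the published fill fraction (12.3%) and spreads
  incident photons over many elements.  The mask is deterministic in the
  seed and can be replaced by any hand-specified `(row, col)` list in the
  configuration.
* **Axial phase.**  Neighbouring bars alternate the GAGG/glass phase by
  `(row + col)` parity (`PARITY_ALTERNATING`), realising a true 3-D mosaic;
  a `UNIFORM` phase is available.  Note one consequence, found while
  validating the axial preset: at any height the parity-alternating block
  is statistically 50% GAGG / 50% glass, so *aggregated* axial responses
  carry almost no interlace signal — axial discrimination lives in the
  joint (bar, segment) response (see "Axial preset" below).

Sub-0.1-mm wrapping/reflector layers and inter-bar air gaps are ignored:
bars fill their 1.68-mm cells, unoccupied cells are air.

### Photon physics

Photons start at 140 keV (one photon per decay; 1 mCi = 3.7 × 10⁷ s⁻¹) and
undergo photoelectric absorption or Compton scattering only.  Each material
carries two constants — total attenuation at 140 keV and electron density:

| material | μ(140 keV) cm⁻¹ | ρ g/cm³ | Z/A | p_pe(140) |
|----------|----------------|---------|-------|-----------|
| GAGG(Ce) | 4.746          | 6.63    | 0.439 | 0.834     |
| K-9 glass| 0.399          | 2.53    | 0.497 | 0.148     |
| water    | 0.154          | 1.00    | 0.555 | 0.026     |
| air      | 0              | —       | —     | —         |

The incoherent part of μ(E) is the Klein–Nishina total cross-section times
the electron density; the remainder at 140 keV is treated as absorption and
scaled as E⁻³.  Rayleigh scattering, fluorescence escape and Doppler
broadening are omitted; because the totals are pinned, the Rayleigh share
is implicitly folded into the absorption channel, which slightly raises the
photoelectric branching (0.834 for GAGG versus ≈0.79 from cross-section
compilations that list Rayleigh separately).  The branching is overridable
per run (`pe_force`) for sensitivity studies.  Valid energy range:
10–200 keV; K-edges are not modelled (the lowest relevant photon energy,
140 keV backscatter, is 90.4 keV, above the Gd K-edge).

Transport uses Woodcock delta-tracking with the GAGG attenuation at the
current energy as majorant, combined with analytic flight across the air
gaps between region bounding volumes (exact, since air does not
attenuate).  Compton angles are rejection-sampled from the Klein–Nishina
density.  Electron transport is ignored (deposits are local), photons below
1 keV deposit their residual energy locally — together this makes per-history
energy accounting exact to machine precision, which the test suite asserts.

### Event formation

Per history, energy deposited in GAGG segments is recorded per element.
The event is positioned at the element with the largest single deposit
(ties break to the lowest flat bin index).  The energy tested against the
112–168 keV window is Gaussian-blurred (20% FWHM at 140 keV, FWHM ∝ √E)
from the summed deposit within the **adder scope**.  The scope defaults to
the winning *bar*, because each bar is read out independently by its own
SiPM pair; `system`, `module` and `element` scopes are available.  The
measured Compton/inter-crystal fractions are moderately sensitive to this
choice (Compton fraction 15.3% per-bar vs 17.6% system-wide at 2 × 10⁵
histories), and substantially more sensitive to the (unpublished) physics
list behind any reference figures; the package reports what its own model
computes.

## Phantoms (synthetic-data generator)

All activity images are photons/s per voxel, normalised to 0.45 mCi (the
myocardial uptake equivalent of a 30 mCi injection at 1.5% uptake).

* **Hot rod** — six 60° sectors of hexagonally packed rods (diameters
  4–9 mm, centre spacing twice the diameter, 5-mm margins to sector
  boundaries and rim), zero background, extruded over the 100-mm FOV.
* **Disks** — five 120-mm-diameter disks of thickness t ∈ {4…8} mm, axial
  gaps 2t, stack centred.  For t = 8 the 104-mm stack extends 2 mm past
  each FOV end; that activity is simulated but unreconstructable.
* **Cardiac** — an analytic left ventricle standing in for an
  anthropomorphic phantom: a truncated half-ellipsoid shell (outer axes
  35 × 35 × 50 mm, 10-mm wall) at relative uptake 75, blood pool 2, two
  3-mm-radius surface tubes (vessels) at 2; attenuation is the uniform
  water cylinder.  The shape is artifact-defined — it preserves the uptake
  ratios and gross topology, not patient anatomy.
* **Uniform cylinder** — the FOV-filling source used for system matrices.

What passing tests on these phantoms do **not** show: performance under
non-uniform body attenuation, anatomical background uptake, motion, or
out-of-FOV activity — none of which the generator emulates.

## System matrix and presets

`A[i, j]` = recorded events from voxel j in bin i ÷ photons emitted in
voxel j; no smoothing (entries below any count floor are kept as-is).
Sensitivity is the column sum, summarised as mean ± population std over
FOV voxels in percent.

Desk-scale presets replace the original multi-day runs (2 × 10¹²
histories; ~4 × 10⁶ recorded events per voxel):

* **slice2d** — one axial slice of the 7-module ring with single-segment
  GAGG bars and in-plane transport; 5376 bins × 90 × 90 pixels at 2 mm.
  The in-plane resolution study estimates `A` from 5 × 10⁷ uniform-disk
  histories, forward-projects the hot-rod layout noise-free through the
  same matrix, reconstructs with 50 OSEM iterations (35 subsets) and a
  2-mm FWHM post-filter, and applies the valley-to-peak criterion.
* **axial1d** — the unknown is the 1-D axial profile (50 slices at 2 mm)
  while the detector keeps all 268,800 z-resolved bins.  The disk profiles
  are forward-projected noise-free through the estimated matrix (the same
  construction as the hot-rod study) and reconstructed with 10 MLEM
  iterations.  Two design findings are baked in here: aggregating bins
  trans-axially destroys the axial interlace signal (parity cancellation,
  above), and at desk-scale statistics (~1 count per nonzero matrix entry)
  an *independently simulated* projection is dominated by matrix noise —
  the matched noise-free projection isolates the resolution question the
  preset is meant to answer.  Both studies therefore share their matrix
  between projection and reconstruction, which makes them sharper than a
  full-scale study with independent noisy data; their results are reported
  as upper bounds on what the geometry supports, not as noise-limited
  resolution measurements.

## Reconstruction

Standard multiplicative OSEM: per subset,
`f ← f / Σ_{i∈S_q} A_ij · Σ_{i∈S_q} A_ij y_i / (A f)_i`.  Subsets are
round-robin over the flat bin index (i mod 35 by default), which
interleaves modules and positions; one subset is MLEM.  Iterations default
to 50 (hot-rod, cardiac) and 10 (disks).  Numerical guards: voxels with
zero total sensitivity are frozen at zero; bins with zero prediction
contribute ratio 1 when their measurement is zero and ratio 0 (with a
data-inconsistency warning) otherwise.  The Gaussian post-filter is a
separable truncated kernel (7 voxels per axis, FWHM in mm) with
renormalised edges, so constant images are exactly preserved.

## 2-D prototype

A single 67.5 × 67.5 × 20 mm block with 128 GAGG bars (2.1 × 2.1 mm) on a
16 × 16 checkerboard at 4.2-mm pitch, facing the rotation axis at 125 mm
(front face; ring radius and 15° step over 180° are configurable — the
original publication gives them only graphically).  The per-position
response is simulated on the 35 × 35 source grid (3-mm pitch, 100 × 100 mm
FOV), expanded to 103 × 103 at 1 mm by bicubic splines (negative
interpolants clipped), and the 13-position virtual-ring matrix is
assembled by rotational symmetry; rotated source points outside the
measured hull get zero response and are counted.  Point sources are ideal
(the physical source was 0.69 mm).  Two-point studies use the
240-s-equivalent photon budget at 0.45 mCi, MLEM (150 iterations), and
peak distances from 3-point parabolic sub-voxel refinement.  MLEM point
spread pulls an 8-mm pair together by a few tenths of a millimetre —
recovered distances at the default settings are ≈7.3–7.9 mm.

## Problem sizes and determinism

Default sample sizes, chosen so each study gives stable answers at desk
scale: 4 × 10⁵ histories for sensitivity/scatter statistics (binomial
s.e. ≈ 0.06 pp), 5 × 10⁷ for the slice2d matrix, 10⁷ for the axial1d
matrix, 5 × 10⁴ photons per source position for the prototype matrix.  All
randomness flows from explicit integer seeds (kernels run single-threaded;
identical seeds reproduce list-mode output bit-for-bit).  The transport
kernels are Numba-compiled; first use pays a one-off JIT cost.

## Known limitations

* Attenuation-only material model (no Rayleigh, fluorescence, Doppler);
  branching ratios near published figures depend on the unpublished
  physics list and event-classification rules of any reference simulation
  — the package's Compton-involved event fraction (~15%) and
  multi-element fraction among those (~30%) are truth-level counts under
  its own model.
* One event per history: a photon depositing in several modules forms a
  single event at the winning element; independent per-module triggering
  is not modelled beyond the adder scope.
* The resolution presets share the estimated matrix between projection and
  reconstruction (see above) — deliberate at desk scale, but not a
  substitute for full-scale noisy-data studies.
* Slab-shaped phantoms quantize in whole voxel layers, so their voxelized
  volume converges slowly unless thickness is a multiple of the voxel.
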