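"""Quantitative image-quality metrics.

"Clearly separable" is made operational with a valley-to-peak criterion:
two neighbouring structures are separable when the minimum of the image
profile between their centres is below 0.75 of the mean of the two centre
values.  The threshold is configurable and applied uniformly to rods,
disks and point sources.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates, maximum_filter

__all__ = [
    "SEPARABILITY_THRESHOLD", "SeparabilityReport", "rod_separability",
    "axial_profile", "profile_separability", "find_peaks_2d",
]

SEPARABILITY_THRESHOLD = 0.75


@dataclass
class SeparabilityReport:
    """Valley-to-peak ratios for all adjacent structure pairs of one size."""

    size_mm: float
    ratios: np.ndarray
    threshold: float
    separable: bool

    @classmethod
    def from_ratios(cls, size_mm, ratios, threshold) -> "SeparabilityReport":
        r = np.asarray(ratios, dtype=float)
        return cls(float(size_mm), r, float(threshold),
                   bool(r.size and (r < threshold).all()))


def _line_profile(img: np.ndarray, p0, p1, pixel_mm, origin_mm, n_samples=64):
    """Image values along the segment p0 -> p1 (world mm, 2-D image)."""
    p0 = (np.asarray(p0, dtype=float) - origin_mm) / pixel_mm - 0.5
    p1 = (np.asarray(p1, dtype=float) - origin_mm) / pixel_mm - 0.5
    t = np.linspace(0.0, 1.0, n_samples)
    coords = np.outer(1 - t, p0) + np.outer(t, p1)
    return map_coordinates(img, coords.T, order=1, mode="nearest")


def rod_separability(img: np.ndarray, rods, pixel_mm: float,
                     threshold: float = SEPARABILITY_THRESHOLD,
                     origin_mm=None) -> dict:
    """Valley-to-peak separability of the hot-rod image, per rod diameter.

    ``img`` is the 2-D trans-axial image indexed ``[ix, iy]``; ``rods`` is
    the ``(x, y, diameter)`` list of the phantom layout.  For every pair of
    adjacent rods (centre distance about twice the diameter) the ratio is
    the minimum profile value between the centres divided by the mean of
    the two centre values.  Returns ``{diameter: SeparabilityReport}``.
    """
    img = np.asarray(img, dtype=float)
    if origin_mm is None:
        origin_mm = -np.asarray(img.shape, dtype=float) * pixel_mm / 2.0
    else:
        origin_mm = np.asarray(origin_mm, dtype=float)
    half_extent = np.asarray(img.shape) * pixel_mm
    reports = {}
    diameters = sorted({d for _, _, d in rods})
    for d in diameters:
        centers = np.array([(x, y) for x, y, dd in rods if dd == d])
        if centers.size and (np.any(centers < origin_mm) or
                             np.any(centers > origin_mm + half_extent)):
            raise ValueError("rod centres fall outside the image")
        ratios = []
        for a in range(len(centers)):
            for b in range(a + 1, len(centers)):
                dist = np.linalg.norm(centers[a] - centers[b])
                if dist > 2.0 * d * 1.05:       # not an adjacent lattice pair
                    continue
                prof = _line_profile(img, centers[a], centers[b],
                                     pixel_mm, origin_mm)
                peak = 0.5 * (prof[0] + prof[-1])
                ratios.append(prof.min() / peak if peak > 0 else 1.0)
        reports[d] = SeparabilityReport.from_ratios(d, ratios, threshold)
    return reports


def axial_profile(img, x_mm: float, y_mm: float) -> np.ndarray:
    """Values along z at the trans-axial location closest to (x, y)."""
    grid = img.grid
    vol = img.values
    ix = int((x_mm - grid.origin[0]) / grid.voxel_size[0])
    iy = int((y_mm - grid.origin[1]) / grid.voxel_size[1])
    if not (0 <= ix < grid.dims[0] and 0 <= iy < grid.dims[1]):
        raise IndexError(f"({x_mm}, {y_mm}) mm outside the image")
    return vol[ix, iy, :].copy()


def profile_separability(profile, peak_indices,
                         threshold: float = SEPARABILITY_THRESHOLD,
                         search_halfwidth: int = 1):
    """Valley-to-peak ratios between consecutive peaks of a 1-D profile.

    ``peak_indices`` are the expected structure centres (e.g. disk centres);
    the peak value is the profile maximum within ``search_halfwidth``
    samples of each centre, the valley the minimum strictly between the two
    peak positions.  Returns ``(ratios, all_separable)``.
    """
    profile = np.asarray(profile, dtype=float)
    idx = [int(i) for i in peak_indices]
    peaks = []
    for i in idx:
        lo = max(i - search_halfwidth, 0)
        hi = min(i + search_halfwidth + 1, profile.size)
        peaks.append(profile[lo:hi].max())
    ratios = []
    for (i0, p0), (i1, p1) in zip(zip(idx, peaks), zip(idx[1:], peaks[1:])):
        valley = profile[i0:i1 + 1].min()
        mean_peak = 0.5 * (p0 + p1)
        ratios.append(valley / mean_peak if mean_peak > 0 else 1.0)
    ratios = np.asarray(ratios)
    return ratios, bool(ratios.size and (ratios < threshold).all())


def _parabolic_refine(values, i):
    """3-point parabolic sub-sample refinement along one axis."""
    if i <= 0 or i >= values.size - 1:
        return 0.0
    y0, y1, y2 = values[i - 1], values[i], values[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:
        return 0.0
    return float(0.5 * (y0 - y2) / denom)


def find_peaks_2d(img: np.ndarray, n_expected: int, min_separation: float):
    """Locate local maxima with non-maximum suppression and subpixel refinement.

    ``min_separation`` is in pixels.  Returns ``(coords, complete)`` where
    ``coords`` is an (n, 2) float array of (row, col) peak positions sorted
    by decreasing height and ``complete`` flags whether ``n_expected`` peaks
    were found.
    """
    if n_expected < 1:
        raise ValueError("n_expected must be >= 1")
    img = np.asarray(img, dtype=float)
    size = max(3, int(round(min_separation)) | 1)
    local_max = (img == maximum_filter(img, size=size)) & (img > 0)
    cand = np.argwhere(local_max)
    order = np.argsort(img[cand[:, 0], cand[:, 1]])[::-1]
    cand = cand[order]
    kept = []
    for rc in cand:
        if all(np.linalg.norm(rc - k) >= min_separation for k in kept):
            kept.append(rc)
        if len(kept) == n_expected:
            break
    coords = []
    for r, c in kept:
        dr = _parabolic_refine(img[:, c], r)
        dc = _parabolic_refine(img[r, :], c)
        coords.append((r + dr, c + dc))
    return np.asarray(coords, dtype=float), len(kept) == n_expected
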