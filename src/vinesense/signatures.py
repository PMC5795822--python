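"""Per-plant and per-class mean spectral signatures, difference spectra,
band-of-interest discovery and data-driven index proposal.

The infested-vs-healthy difference spectrum highlights wavelengths where the
two canopies diverge most (|difference| maxima) or agree exactly (zero
crossings); normalised-difference indices built on pairs of such bands are
the mechanism behind the PI index family.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point
from shapely.prepared import prep

from .containers import SpectralCube, SpectralSignature
from .errors import ValidationError
from .indices import IndexDefinition

__all__ = [
    "BandOfInterest",
    "disc_mask",
    "pixel_mask",
    "plant_pixel_mask",
    "mean_signature",
    "class_signatures",
    "difference_spectrum",
    "bands_of_interest",
    "propose_indices",
]

log = logging.getLogger(__name__)

DEFAULT_PLANT_RADIUS = 0.3  # m; disc around the trunk for signature extraction


@dataclass(frozen=True)
class BandOfInterest:
    wavelength: float  # nm
    kind: str  # {max_difference, zero_crossing}
    difference: float  # smoothed difference value at the band


def disc_mask(transform, shape, x: float, y: float, radius: float) -> np.ndarray:
    """Cells whose centres lie within ``radius`` of (x, y).

    The comparison carries a 1e-9 relative tolerance so centres exactly on
    the rim (aligned grids) are included regardless of rounding.
    """
    cx, cy = transform.center_grids(shape)
    return (cx - x) ** 2 + (cy - y) ** 2 <= radius**2 * (1.0 + 1e-9)


def pixel_mask(transform, shape, geometry) -> np.ndarray:
    """Cells of a (shape, transform) raster whose centres the geometry covers."""
    cx, cy = transform.center_grids(shape)
    if geometry.is_empty or geometry.area == 0:
        return np.zeros(shape, dtype=bool)
    minx, miny, maxx, maxy = geometry.bounds
    coarse = (cx >= minx) & (cx <= maxx) & (cy >= miny) & (cy <= maxy)
    mask = np.zeros(shape, dtype=bool)
    if np.any(coarse):
        prepared = prep(geometry)
        idx = np.argwhere(coarse)
        hits = [prepared.covers(Point(cx[r, c], cy[r, c])) for r, c in idx]
        mask[idx[hits, 0], idx[hits, 1]] = True
    return mask


def plant_pixel_mask(cube: SpectralCube, plant=None, geometry=None,
                     radius: float = DEFAULT_PLANT_RADIUS) -> np.ndarray:
    """Boolean mask of cube cells whose centres fall inside the plant geometry.

    ``geometry`` may be any shapely polygon; by default a disc of ``radius``
    around the trunk of ``plant`` is used (hand-drawn GIS polygons are the
    field practice; the disc is the automated stand-in).
    """
    if geometry is None:
        if plant is None:
            raise ValidationError("need a plant or an explicit geometry")
        mask = disc_mask(cube.transform, cube.shape[:2], plant.x, plant.y, radius)
    else:
        mask = pixel_mask(cube.transform, cube.shape[:2], geometry)
    if not mask.any():
        log.warning("empty pixel mask for plant %s",
                    getattr(plant, "tree_number", "<geometry>"))
    return mask


def mean_signature(cube: SpectralCube, mask: np.ndarray,
                   label: str = "") -> SpectralSignature:
    """Per-band mean/sd reflectance over masked pixels, nodata excluded."""
    mask = np.asarray(mask, dtype=bool) & cube.valid_mask()
    pixels = cube.values[mask]
    if pixels.size == 0:
        log.warning("mean_signature: empty mask (label=%r)", label)
        n = cube.n_bands
        return SpectralSignature(cube.wavelengths, np.full(n, np.nan),
                                 np.full(n, np.nan), 0, label)
    return SpectralSignature(
        wavelengths=cube.wavelengths,
        mean=pixels.mean(axis=0),
        sd=pixels.std(axis=0, ddof=0),
        n_pixels=pixels.shape[0],
        label=label,
    )


def class_signatures(cube: SpectralCube, plants, classes,
                     radius: float = DEFAULT_PLANT_RADIUS) -> list[SpectralSignature]:
    """One pooled signature per class over all member plants' pixels.

    ``classes`` maps each plant (by position) to its label; pixels of all
    plants sharing a label are pooled before the mean, so the result equals
    the pixel-count-weighted mean of the member plants' signatures.
    """
    classes = list(classes)
    if len(classes) != len(plants):
        raise ValidationError("classes must align with plants")
    out = []
    for label in sorted(set(classes), key=str):
        mask = np.zeros(cube.shape[:2], dtype=bool)
        for plant, cls in zip(plants, classes):
            if cls == label:
                mask |= plant_pixel_mask(cube, plant, radius=radius)
        out.append(mean_signature(cube, mask, label=str(label)))
    return out


def difference_spectrum(sig_a: SpectralSignature,
                        sig_b: SpectralSignature) -> SpectralSignature:
    """Band-wise ``a − b``; spreads combine in quadrature."""
    if not np.array_equal(sig_a.wavelengths, sig_b.wavelengths):
        raise ValidationError("signatures must share one wavelength grid")
    return SpectralSignature(
        wavelengths=sig_a.wavelengths,
        mean=sig_a.mean - sig_b.mean,
        sd=np.sqrt(sig_a.sd**2 + sig_b.sd**2),
        n_pixels=min(sig_a.n_pixels, sig_b.n_pixels),
        label=f"{sig_a.label}-{sig_b.label}",
    )


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(values, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="valid")
    return out[: len(values)]


def bands_of_interest(diff: SpectralSignature, smoothing_window: int = 5,
                      k: int = 7) -> list[BandOfInterest]:
    """Wavelengths where the difference spectrum peaks or crosses zero.

    The difference is moving-average smoothed, then local maxima of its
    absolute value and sign-change positions are collected and ranked by
    |difference| (zero crossings rank by the unsmoothed gradient magnitude
    at the crossing, after the maxima).  The top ``k`` (default 7) return.
    Adding one constant to both parent signatures leaves the result
    unchanged, since only the difference enters.
    """
    w = diff.wavelengths
    if smoothing_window < 1 or smoothing_window > len(w):
        raise ValidationError(
            f"smoothing window {smoothing_window} incompatible with {len(w)} bands"
        )
    d = _smooth(diff.mean, smoothing_window)
    absd = np.abs(d)

    found: list[BandOfInterest] = []
    for i in range(1, len(w) - 1):
        if absd[i] >= absd[i - 1] and absd[i] > absd[i + 1]:
            found.append(BandOfInterest(float(w[i]), "max_difference", float(d[i])))
    sign = np.sign(d)
    nz = sign != 0
    for i in range(1, len(w)):
        if nz[i] and nz[i - 1] and sign[i] != sign[i - 1]:
            # linear zero location between the two bands
            frac = abs(d[i - 1]) / (abs(d[i - 1]) + abs(d[i]))
            wl = w[i - 1] + frac * (w[i] - w[i - 1])
            found.append(BandOfInterest(float(wl), "zero_crossing", 0.0))

    maxima = sorted((b for b in found if b.kind == "max_difference"),
                    key=lambda b: -abs(b.difference))
    crossings = [b for b in found if b.kind == "zero_crossing"]
    ranked = maxima + crossings
    return ranked[:k]


def propose_indices(bands) -> list[IndexDefinition]:
    """Normalised-difference definitions for every pair of selected bands.

    Each pair (λ_lo, λ_hi) yields (R_hi − R_lo)/(R_hi + R_lo), named
    ``PI_<lo>_<hi>``; duplicates (same wavelength pair) are dropped.
    """
    wavelengths = sorted({round(float(getattr(b, "wavelength", b)), 6) for b in bands})
    out = []
    for lo, hi in itertools.combinations(wavelengths, 2):
        def formula(R, hi=hi, lo=lo):
            return (R[hi] - R[lo]) / (R[hi] + R[lo])

        out.append(
            IndexDefinition(
                name=f"PI_{lo:g}_{hi:g}",
                required_wavelengths=(hi, lo),
                formula=formula,
                source_sensor="hyperspectral",
            )
        )
    return out
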