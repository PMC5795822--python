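"""White-reference handling and radiance-to-reflectance conversion.

A near-perfectly reflective board imaged before/after flight supplies, per
band, the radiance of a 100%-reflectance surface.  Scene reflectance is then
the band-wise ratio of scene radiance to the board's cropped-patch mean.
Boards are screened for sensor saturation first: a band whose fraction of
pixels at the sensor maximum exceeds a small threshold invalidates the whole
reference, because division by a clipped mean biases every pixel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import SpectralCube
from .errors import CalibrationError, ValidationError

__all__ = [
    "WhiteReference",
    "SaturationReport",
    "check_saturation",
    "crop_white_reference",
    "radiance_to_reflectance",
]

log = logging.getLogger(__name__)


@dataclass
class SaturationReport:
    saturation_fraction: np.ndarray  # per band, in [0, 1]
    threshold: float
    flagged_bands: np.ndarray  # positions whose fraction exceeds threshold

    @property
    def accepted(self) -> bool:
        return self.flagged_bands.size == 0


@dataclass
class WhiteReference:
    """Cropped white-board patch with its per-band mean radiance."""

    patch: np.ndarray  # (rows, cols, bands) radiance
    mean_spectrum: np.ndarray
    saturation_fraction: np.ndarray
    dn_max: float

    def __post_init__(self) -> None:
        if np.any(self.saturation_fraction < 0) or np.any(self.saturation_fraction > 1):
            raise ValidationError("saturation fractions must lie in [0, 1]")


def check_saturation(patch: np.ndarray, dn_max: float,
                     threshold: float = 0.01) -> SaturationReport:
    """Per-band fraction of pixels at the sensor ceiling, plus accept/reject.

    The reference is rejected when any band's saturated fraction exceeds
    ``threshold`` (default 1%).
    """
    if dn_max <= 0:
        raise ValidationError(f"dn_max must be positive, got {dn_max}")
    patch = np.asarray(patch, dtype=float)
    fractions = np.mean(patch >= dn_max, axis=(0, 1))
    flagged = np.flatnonzero(fractions > threshold)
    if flagged.size:
        log.warning("white reference rejected: %d band(s) saturated above %.2f%%",
                    flagged.size, 100 * threshold)
    return SaturationReport(fractions, threshold, flagged)


def _best_window(image: np.ndarray, size: tuple[int, int]) -> tuple[int, int]:
    """Top-left corner of the size-fixed window maximising mean radiance.

    Evaluated exhaustively with a summed-area table over the band-mean image;
    ties break toward the smallest (row, col) in raster order.
    """
    h, w = size
    band_mean = image.mean(axis=2)
    sat = np.zeros((band_mean.shape[0] + 1, band_mean.shape[1] + 1))
    np.cumsum(np.cumsum(band_mean, axis=0), axis=1, out=sat[1:, 1:])
    sums = sat[h:, w:] - sat[:-h, w:] - sat[h:, :-w] + sat[:-h, :-w]
    flat = int(np.argmax(sums))  # first maximum in raster order
    return flat // sums.shape[1], flat % sums.shape[1]


def crop_white_reference(image: np.ndarray, window=None, dn_max: float = 4095.0,
                         window_size: tuple[int, int] = (8, 8)) -> WhiteReference:
    """Restrict a white-board image to its brightest (or a given) window.

    ``window`` is ``(row0, col0, height, width)``; when omitted the
    maximal-mean-radiance window of ``window_size`` is located automatically
    (Fig. 3-style cropping to the clean part of the board).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3:
        raise ValidationError("white-reference image must be (rows, cols, bands)")
    if window is None:
        h = min(window_size[0], image.shape[0])
        w = min(window_size[1], image.shape[1])
        r0, c0 = _best_window(image, (h, w))
        window = (r0, c0, h, w)
    r0, c0, h, w = window
    if r0 < 0 or c0 < 0 or h < 1 or w < 1 or r0 + h > image.shape[0] or c0 + w > image.shape[1]:
        raise ValidationError(f"window {window} outside image bounds {image.shape[:2]}")
    patch = image[r0 : r0 + h, c0 : c0 + w, :]
    report = check_saturation(patch, dn_max)
    return WhiteReference(
        patch=patch,
        mean_spectrum=patch.mean(axis=(0, 1)),
        saturation_fraction=report.saturation_fraction,
        dn_max=dn_max,
    )


def radiance_to_reflectance(cube: SpectralCube, white: WhiteReference,
                            saturation_threshold: float = 0.01,
                            qc_threshold: float = 1.2) -> SpectralCube:
    """Divide a radiance cube band-wise by the white reference mean spectrum.

    Reflectance is deliberately not clipped at 1.0 — specular or brighter-
    than-board pixels are real; instead pixels above ``qc_threshold`` are
    counted and logged.  Nodata cells pass through untouched.
    """
    if cube.kind != "radiance":
        raise CalibrationError(f"expected a radiance cube, got kind={cube.kind!r}")
    mean = np.asarray(white.mean_spectrum, dtype=float)
    if mean.size != cube.n_bands:
        raise CalibrationError(
            f"band-count mismatch: cube has {cube.n_bands}, reference {mean.size}"
        )
    if np.any(mean <= 0):
        bad = np.flatnonzero(mean <= 0)
        raise CalibrationError(f"non-positive white-reference mean in bands {bad[:10]}")
    if np.any(white.saturation_fraction > saturation_threshold):
        raise CalibrationError("white reference is saturated; recrop or rescan")

    valid = cube.valid_mask()
    out = cube.values / mean  # broadcasts over the band axis
    out[~valid] = cube.nodata

    n_bright = int(np.count_nonzero(out[valid] > qc_threshold))
    if n_bright:
        log.warning("%d reflectance value(s) above %.2f after calibration",
                    n_bright, qc_threshold)
    return SpectralCube(
        values=out,
        wavelengths=cube.wavelengths,
        transform=cube.transform,
        kind="reflectance",
        nodata=cube.nodata,
    )
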