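"""Vegetation-index registry and evaluation over cubes and 5-band rasters.

Twenty indices are registered: the classical chlorophyll/vigour set in both
hyperspectral (``_H``, single VNIR bands resolved by nearest wavelength) and
multispectral (``_M``, the five fixed camera bands) variants, plus the six
phylloxera indices PI1-PI6 derived from infested-vs-healthy difference
spectra.  ``R`` in a formula is the mapping wavelength (nm) -> reflectance.

Conventions worth stating once:

* normalised-difference forms (x - y)/(x + y) are scale-invariant and bounded
  in [-1, 1] for positive reflectances;
* OSAVI/MCARI/TCARI carry additive constants or products and are neither;
* TCARI applies its (R700/R670) factor inside the bracket, i.e.
  3[(R700 - R670) - 0.2 (R700 - R551)(R700/R670)];
* MCARI2 uses the Haboudane (2004) form
  1.5[2.5(NIR - Red) - 1.3(NIR - Green)] /
  (sqrt((2 NIR + 1)^2 - (6 NIR - 5 sqrt(Red))) - 0.5).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .containers import (
    DEFAULT_NODATA,
    GeoTransform,
    MultispectralRaster,
    SpectralCube,
)
from .errors import BandResolutionError, CapabilityError

__all__ = [
    "IndexDefinition",
    "IndexRaster",
    "REGISTRY",
    "nearest_band",
    "evaluate_index",
    "compute_index_raster",
    "available_indices",
]

log = logging.getLogger(__name__)


def nearest_band(wavelengths, target_nm: float, tolerance_nm: float = 3.0) -> int:
    """Position of the band closest to ``target_nm``; ties go to the lower λ.

    Raises :class:`BandResolutionError` when the best match is farther than
    ``tolerance_nm`` (e.g. a narrow-band request against the 5-band camera).
    """
    w = np.asarray(wavelengths, dtype=float)
    dist = np.abs(w - target_nm)
    pos = int(np.argmin(dist))  # argmin takes the first (lower-λ) minimum
    if dist[pos] > tolerance_nm:
        raise BandResolutionError(
            f"no band within {tolerance_nm} nm of {target_nm} nm "
            f"(closest: {w[pos]:.1f} nm)"
        )
    return pos


@dataclass(frozen=True)
class IndexDefinition:
    """A named scalar function of reflectances at fixed wavelengths."""

    name: str
    required_wavelengths: tuple
    formula: Callable[[Mapping[float, np.ndarray]], np.ndarray]
    source_sensor: str = "either"  # {hyperspectral, multispectral, either}

    def __post_init__(self) -> None:
        for wl in self.required_wavelengths:
            if not 400.0 <= wl <= 1000.0:
                raise ValueError(f"{self.name}: wavelength {wl} outside 400-1000 nm")


@dataclass
class IndexRaster:
    values: np.ndarray
    name: str
    transform: GeoTransform
    nodata: float = DEFAULT_NODATA


def _nd(hi: float, lo: float):
    return lambda R: (R[hi] - R[lo]) / (R[hi] + R[lo])


def _registry() -> dict[str, IndexDefinition]:
    defs = [
        IndexDefinition("NDVI_H", (800, 670), _nd(800, 670), "hyperspectral"),
        IndexDefinition("NDVI_M", (840, 668), _nd(840, 668), "multispectral"),
        IndexDefinition("NDVI_Green_H", (800, 551), _nd(800, 551), "hyperspectral"),
        IndexDefinition("NDVI_Green_M", (840, 560), _nd(840, 560), "multispectral"),
        IndexDefinition("NDRE_M", (840, 717), _nd(840, 717), "multispectral"),
        IndexDefinition(
            "MCARI_H",
            (700, 670, 551),
            lambda R: ((R[700] - R[670]) - 0.2 * (R[700] - R[551])) * (R[700] / R[670]),
            "hyperspectral",
        ),
        IndexDefinition(
            "MCARI_M",
            (717, 668, 560),
            lambda R: ((R[717] - R[668]) - 0.2 * (R[717] - R[560])) * (R[717] / R[668]),
            "multispectral",
        ),
        IndexDefinition(
            "MCARI1_M",
            (840, 668, 560),
            lambda R: 1.2 * (2.5 * (R[840] - R[668]) - 1.3 * (R[840] - R[560])),
            "multispectral",
        ),
        IndexDefinition(
            "MCARI2_M",
            (840, 668, 560),
            lambda R: 1.5
            * (2.5 * (R[840] - R[668]) - 1.3 * (R[840] - R[560]))
            / (
                np.sqrt((2.0 * R[840] + 1.0) ** 2 - (6.0 * R[840] - 5.0 * np.sqrt(R[668])))
                - 0.5
            ),
            "multispectral",
        ),
        IndexDefinition(
            "TCARI_H",
            (700, 670, 551),
            lambda R: 3.0
            * ((R[700] - R[670]) - 0.2 * (R[700] - R[551]) * (R[700] / R[670])),
            "hyperspectral",
        ),
        IndexDefinition(
            "TCARI_M",
            (717, 668, 560),
            lambda R: 3.0
            * ((R[717] - R[668]) - 0.2 * (R[717] - R[560]) * (R[717] / R[668])),
            "multispectral",
        ),
        IndexDefinition(
            "OSAVI_H",
            (800, 670),
            lambda R: 1.16 * (R[800] - R[670]) / (R[800] + R[670] + 0.16),
            "hyperspectral",
        ),
        IndexDefinition(
            "OSAVI_M",
            (840, 668),
            lambda R: 1.16 * (R[840] - R[668]) / (R[840] + R[668] + 0.16),
            "multispectral",
        ),
        IndexDefinition(
            "BGI2_M", (475, 560), lambda R: R[475] / R[560], "multispectral"
        ),
        IndexDefinition(
            "BRI2_M", (475, 668), lambda R: R[475] / R[668], "multispectral"
        ),
        IndexDefinition("PI1", (522, 504), _nd(522, 504), "hyperspectral"),
        IndexDefinition("PI2", (551, 562), _nd(551, 562), "hyperspectral"),
        IndexDefinition("PI3", (700, 680), _nd(700, 680), "hyperspectral"),
        IndexDefinition("PI4", (782, 700), _nd(782, 700), "hyperspectral"),
        IndexDefinition("PI5", (782, 671), _nd(782, 671), "hyperspectral"),
        IndexDefinition("PI6", (680, 563), _nd(680, 563), "hyperspectral"),
    ]
    return {d.name: d for d in defs}


REGISTRY: dict[str, IndexDefinition] = _registry()

#: Pure-ratio indices: invariant under uniform scaling of reflectance.
SCALE_INVARIANT = frozenset(
    name
    for name in REGISTRY
    if name.startswith(("NDVI", "NDRE", "PI", "BGI", "BRI"))
)


def evaluate_index(definition: IndexDefinition, reflectance_by_wavelength) -> np.ndarray:
    """Evaluate ``definition`` on resolved reflectances (scalars or arrays).

    A zero denominator yields NaN with a logged warning rather than an error,
    matching the raster path where a few degenerate pixels must not abort a
    whole-scene computation.
    """
    R = {float(k): np.asarray(v, dtype=float) for k, v in reflectance_by_wavelength.items()}
    missing = [wl for wl in definition.required_wavelengths if float(wl) not in R]
    if missing:
        raise BandResolutionError(f"{definition.name}: unresolved wavelengths {missing}")
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = definition.formula({float(k): R[float(k)] for k in R})
    out = np.asarray(out, dtype=float)
    n_bad = np.size(out) - np.count_nonzero(np.isfinite(out))
    if n_bad:
        log.warning("%s: %d cell(s) with zero/invalid denominator -> nodata",
                    definition.name, n_bad)
    return out if out.ndim else float(out)


def _resolve_planes(source, definition, tolerance_nm=3.0):
    """Map each required wavelength to a reflectance plane of ``source``."""
    if isinstance(source, SpectralCube):
        planes = {}
        for wl in definition.required_wavelengths:
            pos = nearest_band(source.wavelengths, wl, tolerance_nm)
            planes[float(wl)] = source.band(pos)
            log.debug("%s: R_%s -> band %d (%.1f nm)", definition.name, wl, pos,
                      source.wavelengths[pos])
        return planes, source.transform, source.nodata, source.valid_mask()
    if isinstance(source, MultispectralRaster):
        if definition.source_sensor == "hyperspectral":
            raise CapabilityError(
                f"{definition.name} needs narrow VNIR bands "
                f"{definition.required_wavelengths}; the 5-band camera cannot supply them"
            )
        centres = np.array(sorted(set(v for v in source.wavelengths)))
        planes = {}
        for wl in definition.required_wavelengths:
            try:
                pos = nearest_band(centres, wl, tolerance_nm)
            except BandResolutionError as exc:
                raise CapabilityError(str(exc)) from exc
            planes[float(wl)] = source.plane_by_wavelength(centres[pos])
        valid = ~np.any(
            np.stack([p == source.nodata for p in source.bands.values()]), axis=0
        )
        return planes, source.transform, source.nodata, valid
    raise TypeError(f"unsupported source type {type(source).__name__}")


def compute_index_raster(source, name: str, canopy_mask=None,
                         tolerance_nm: float = 3.0) -> IndexRaster:
    """Per-cell index raster from a cube or multispectral raster.

    ``canopy_mask`` (optional boolean plane) restricts output to canopy cells;
    everything else becomes nodata.  The geotransform passes through unchanged.
    """
    definition = REGISTRY[name]
    planes, transform, nodata, valid = _resolve_planes(source, definition, tolerance_nm)
    values = np.asarray(evaluate_index(definition, planes), dtype=float)
    if canopy_mask is not None:
        valid = valid & np.asarray(canopy_mask, dtype=bool)
    values = np.where(valid & np.isfinite(values), values, nodata)
    return IndexRaster(values, name, transform, nodata)


def available_indices(source) -> list[str]:
    """Names of registered indices computable from ``source``."""
    out = []
    for name, definition in REGISTRY.items():
        try:
            _resolve_planes(source, definition)
        except (CapabilityError, BandResolutionError):
            continue
        out.append(name)
    return out
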