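"""Single- and multi-band GeoTIFF IO via tifffile.

Georeferencing is carried in the standard GeoTIFF tags ModelPixelScaleTag
(33550) and ModelTiepointTag (33922): tie point (0, 0) pixel corner ->
(origin_x, origin_y), north-up.  Nodata travels in GDAL_NODATA (42113).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from ..containers import (
    DEFAULT_NODATA,
    ElevationGrid,
    GeoTransform,
    MultispectralRaster,
    MULTISPECTRAL_BANDS,
)
from ..errors import FormatError

__all__ = [
    "write_raster",
    "read_raster",
    "write_elevation_grid",
    "read_elevation_grid",
    "write_multispectral",
    "read_multispectral",
]

_TAG_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_NODATA = 42113

# Fixed plane order for 5-band multispectral TIFFs, blue..nir by wavelength.
_MS_ORDER = sorted(MULTISPECTRAL_BANDS, key=MULTISPECTRAL_BANDS.get)


def _geo_tags(transform: GeoTransform, nodata: float):
    scale = (transform.cell, transform.cell, 0.0)
    tie = (0.0, 0.0, 0.0, transform.origin_x, transform.origin_y, 0.0)
    return [
        (_TAG_SCALE, "d", 3, scale, True),
        (_TAG_TIEPOINT, "d", 6, tie, True),
        (_TAG_NODATA, "s", 0, str(nodata), True),
    ]


def write_raster(values: np.ndarray, transform: GeoTransform, path,
                 nodata: float = DEFAULT_NODATA) -> Path:
    """Write a (rows, cols) or (rows, cols, planes) float64 GeoTIFF."""
    path = Path(path)
    data = np.asarray(values, dtype=np.float64)
    tifffile.imwrite(path, data, extratags=_geo_tags(transform, nodata),
                     photometric="minisblack", planarconfig="contig"
                     if data.ndim == 3 else None)
    return path


def read_raster(path):
    """Return (values, GeoTransform, nodata) from a GeoTIFF."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = tif.asarray()
        tags = page.tags
        if _TAG_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise FormatError(f"{path} lacks GeoTIFF georeferencing tags")
        scale = tags[_TAG_SCALE].value
        tie = tags[_TAG_TIEPOINT].value
        nodata = DEFAULT_NODATA
        if _TAG_NODATA in tags:
            nodata = float(str(tags[_TAG_NODATA].value).strip("\x00 "))
    if abs(scale[0] - scale[1]) > 1e-9:
        raise FormatError(f"{path}: anisotropic cells unsupported")
    transform = GeoTransform(tie[3] - tie[0] * scale[0],
                             tie[4] + tie[1] * scale[1], scale[0])
    return np.asarray(values, dtype=float), transform, nodata


def write_elevation_grid(grid: ElevationGrid, path,
                         nodata: float = DEFAULT_NODATA) -> Path:
    values = np.where(np.isfinite(grid.values), grid.values, nodata)
    return write_raster(values, grid.transform, path, nodata)


def read_elevation_grid(path, role: str = "DSM") -> ElevationGrid:
    values, transform, nodata = read_raster(path)
    values = np.where(values == nodata, np.nan, values)
    return ElevationGrid(values, transform, role)


def write_multispectral(raster: MultispectralRaster, path) -> Path:
    planes = np.stack([raster.bands[name] for name in _MS_ORDER], axis=-1)
    return write_raster(planes, raster.transform, path, raster.nodata)


def read_multispectral(path) -> MultispectralRaster:
    values, transform, nodata = read_raster(path)
    if values.ndim != 3 or values.shape[2] != len(_MS_ORDER):
        raise FormatError(
            f"{path}: expected {len(_MS_ORDER)} planes, got shape {values.shape}"
        )
    bands = {name: values[:, :, i] for i, name in enumerate(_MS_ORDER)}
    return MultispectralRaster(bands, transform, nodata)
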