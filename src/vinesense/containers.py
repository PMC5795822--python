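"""Core in-memory containers shared by every pipeline stage.

All rasters use a planar metric CRS (easting/northing in metres), origin at
the upper-left cell *corner*, row-major storage, north-up: row index grows
southwards, column index grows eastwards.  Cell membership is half-open:
a point on the shared edge of two cells belongs to the cell with the larger
index along that axis's storage direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "GeoTransform",
    "SpectralCube",
    "MultispectralRaster",
    "MULTISPECTRAL_BANDS",
    "PointCloud",
    "GROUND",
    "CANOPY",
    "UNCLASSIFIED",
    "ElevationGrid",
    "PlantRecord",
    "SpectralSignature",
]

DEFAULT_NODATA = -9999.0

#: MicaSense RedEdge band centres, nm.
MULTISPECTRAL_BANDS = {
    "blue": 475.0,
    "green": 560.0,
    "red": 668.0,
    "red_edge": 717.0,
    "nir": 840.0,
}

# LAS-style point classification codes.
UNCLASSIFIED = 1
GROUND = 2
CANOPY = 5


@dataclass(frozen=True)
class GeoTransform:
    """North-up affine transform: origin is the upper-left cell corner."""

    origin_x: float
    origin_y: float
    cell: float

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError(f"cell size must be positive, got {self.cell}")

    def cell_center(self, row, col):
        """Easting/northing of cell centres for (row, col) index arrays."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.cell
        y = self.origin_y - (np.asarray(row) + 0.5) * self.cell
        return x, y

    def index_of(self, x, y):
        """Row/col containing points (x, y); half-open cell intervals."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell).astype(int)
        row = np.floor((self.origin_y - np.asarray(y)) / self.cell).astype(int)
        return row, col

    def center_grids(self, shape):
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
        return self.cell_center(rows, cols)


def _check_wavelengths(wavelengths: np.ndarray, nbands: int) -> np.ndarray:
    w = np.asarray(wavelengths, dtype=float)
    if w.ndim != 1 or w.size != nbands:
        raise ValueError(
            f"wavelength list length {w.size} does not match band count {nbands}"
        )
    if w.size > 1 and not np.all(np.diff(w) > 0):
        raise ValueError("wavelengths must be strictly increasing")
    return w


@dataclass
class SpectralCube:
    """Wavelength-indexed raster: values[row, col, band].

    ``kind`` distinguishes sensor radiance (arbitrary units) from unitless
    reflectance (typically in [0, ~1.2]; bright specular pixels may exceed 1).
    """

    values: np.ndarray
    wavelengths: np.ndarray
    transform: GeoTransform
    kind: str = "reflectance"
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("cube values must be 3-D (rows, cols, bands)")
        self.wavelengths = _check_wavelengths(self.wavelengths, self.values.shape[2])
        if self.kind not in ("radiance", "reflectance"):
            raise ValueError(f"unknown cube kind {self.kind!r}")

    @property
    def shape(self):
        return self.values.shape

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    def band(self, index: int) -> np.ndarray:
        return self.values[:, :, index]

    def valid_mask(self) -> np.ndarray:
        """True where no band carries the nodata sentinel."""
        return ~np.any(self.values == self.nodata, axis=2)

    def copy_with(self, **changes) -> "SpectralCube":
        out = replace(self, **changes)
        return out


@dataclass
class MultispectralRaster:
    """Five named planes at the fixed MicaSense RedEdge centres."""

    bands: Mapping[str, np.ndarray]
    transform: GeoTransform
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        missing = set(MULTISPECTRAL_BANDS) - set(self.bands)
        extra = set(self.bands) - set(MULTISPECTRAL_BANDS)
        if missing or extra:
            raise ValueError(
                f"multispectral raster needs exactly bands {sorted(MULTISPECTRAL_BANDS)}; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        shapes = {np.asarray(v).shape for v in self.bands.values()}
        if len(shapes) != 1:
            raise ValueError("all band planes must share one shape")
        self.bands = {k: np.asarray(v, dtype=float) for k, v in self.bands.items()}

    @property
    def wavelengths(self) -> np.ndarray:
        return np.array(sorted(MULTISPECTRAL_BANDS.values()))

    @property
    def shape(self):
        return next(iter(self.bands.values())).shape

    def plane_by_wavelength(self, nm: float) -> np.ndarray:
        for name, centre in MULTISPECTRAL_BANDS.items():
            if centre == nm:
                return self.bands[name]
        raise KeyError(f"no multispectral band centred at {nm} nm")


@dataclass
class PointCloud:
    """3-D points in metres with per-point ground/canopy labels."""

    xyz: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("point coordinates must be finite")
        if self.labels is None:
            self.labels = np.full(len(self.xyz), UNCLASSIFIED, dtype=np.uint8)
        else:
            self.labels = np.asarray(self.labels, dtype=np.uint8).reshape(-1)
            if len(self.labels) != len(self.xyz):
                raise ValueError("labels length must match point count")
            bad = ~np.isin(self.labels, [UNCLASSIFIED, GROUND, CANOPY])
            if np.any(bad):
                raise ValueError(
                    f"labels restricted to {{unclassified={UNCLASSIFIED}, "
                    f"ground={GROUND}, canopy={CANOPY}}}; found {set(self.labels[bad])}"
                )

    def __len__(self) -> int:
        return len(self.xyz)

    @property
    def x(self):
        return self.xyz[:, 0]

    @property
    def y(self):
        return self.xyz[:, 1]

    @property
    def z(self):
        return self.xyz[:, 2]

    def subset(self, mask) -> "PointCloud":
        return PointCloud(self.xyz[mask], self.labels[mask])


@dataclass
class ElevationGrid:
    """Single-band elevation/height raster playing the DSM, DTM or DVM role.

    ``nodata`` cells are stored as NaN; the IO layer maps them to/from the
    configured sentinel.
    """

    values: np.ndarray
    transform: GeoTransform
    role: str = "DSM"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("elevation grid must be 2-D")
        if self.role not in ("DSM", "DTM", "DVM"):
            raise ValueError(f"unknown grid role {self.role!r}")

    @property
    def shape(self):
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class PlantRecord:
    """One grapevine: identity, location, scores and derived measurements."""

    tree_number: int
    x: float
    y: float
    block: int = 1
    row: int = 1
    panel: int = 1
    variety: str = ""
    expert_vigour: int | None = None
    dvm_max: float | None = None
    dvm_mean: float | None = None
    index_values: dict = field(default_factory=dict)
    em38: float | None = None

    def __post_init__(self) -> None:
        if self.expert_vigour is not None and self.expert_vigour not in range(1, 6):
            raise ValueError(
                f"vigour class must be 1..5, got {self.expert_vigour} "
                f"(tree {self.tree_number})"
            )


@dataclass
class SpectralSignature:
    """Per-wavelength mean/sd reflectance of a labelled pixel population."""

    wavelengths: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_pixels: int
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (len(self.wavelengths) == len(self.mean) == len(self.sd)):
            raise ValueError("signature arrays must share one length")
        if self.n_pixels < 0:
            raise ValueError("n_pixels must be non-negative")
        if np.any(self.sd < -1e-12):
            raise ValueError("sd must be non-negative")
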