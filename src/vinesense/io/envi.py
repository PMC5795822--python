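"""ENVI cube reader/writer (.bil/.bip/.bsq + text .hdr with a wavelength list).

The format is a headerless binary array whose layout is declared in a
side-car ``.hdr`` text file.  BIL (band-interleaved-by-line) is written by
default — the native order of push-broom scanners — and all three
interleaves are accepted on read.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from ..containers import DEFAULT_NODATA, GeoTransform, SpectralCube
from ..errors import FormatError

__all__ = ["read_envi_cube", "write_envi_cube"]

# ENVI "data type" codes we support.
_DTYPES = {4: np.float32, 5: np.float64, 12: np.uint16, 2: np.int16}
_DTYPE_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}

_INTERLEAVE_AXES = {
    # storage order -> transpose to (rows, cols, bands)
    "bsq": ((0, 1, 2), (1, 2, 0)),  # stored (bands, rows, cols)
    "bil": ((0, 1, 2), (0, 2, 1)),  # stored (rows, bands, cols)
    "bip": ((0, 1, 2), (0, 1, 2)),  # stored (rows, cols, bands)
}


def _parse_header(text: str) -> dict:
    """Parse the key = value / key = { multi, line, list } ENVI dialect."""
    fields: dict[str, str] = {}
    # Collapse brace-delimited lists onto one line first.
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def _parse_list(raw: str) -> list[float]:
    inner = raw.strip().lstrip("{").rstrip("}")
    return [float(tok) for tok in inner.split(",") if tok.strip()]


def read_envi_cube(path) -> SpectralCube:
    """Read an ENVI cube; wavelengths come from the header's wavelength list.

    Raises
    ------
    FormatError
        If the header is missing, lacks a wavelength list, or the declared
        band count disagrees with the wavelength list or file size.
    """
    path = Path(path)
    hdr_path = path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise FormatError(f"missing ENVI header {hdr_path}")
    fields = _parse_header(hdr_path.read_text())

    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise FormatError(f"ENVI header missing required field {exc}") from exc

    if "wavelength" not in fields:
        raise FormatError(f"{hdr_path} declares no wavelength list")
    wavelengths = _parse_list(fields["wavelength"])
    if len(wavelengths) != bands:
        raise FormatError(
            f"{hdr_path}: {len(wavelengths)} wavelengths but {bands} bands"
        )
    if dtype_code not in _DTYPES:
        raise FormatError(f"unsupported ENVI data type {dtype_code}")
    if interleave not in _INTERLEAVE_AXES:
        raise FormatError(f"unknown interleave {interleave!r}")

    dtype = np.dtype(_DTYPES[dtype_code])
    expected = samples * lines * bands
    raw = np.fromfile(path, dtype=dtype)
    if raw.size != expected:
        raise FormatError(
            f"{path}: file holds {raw.size} values, header implies {expected}"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        data = raw.reshape(lines, samples, bands)

    if "map info" in fields:
        toks = [t.strip() for t in fields["map info"].strip("{} ").split(",")]
        # map info = {proj, ref col, ref row, easting, northing, xcell, ycell, ...}
        origin_x = float(toks[3]) - (float(toks[1]) - 1.0) * float(toks[5])
        origin_y = float(toks[4]) + (float(toks[2]) - 1.0) * float(toks[6])
        transform = GeoTransform(origin_x, origin_y, float(toks[5]))
    else:
        transform = GeoTransform(0.0, float(lines), 1.0)

    nodata = float(fields.get("data ignore value", DEFAULT_NODATA))
    kind = fields.get("vinesense kind", "reflectance")
    return SpectralCube(
        values=np.ascontiguousarray(data, dtype=float),
        wavelengths=np.asarray(wavelengths),
        transform=transform,
        kind=kind,
        nodata=nodata,
    )


def write_envi_cube(cube: SpectralCube, path, interleave: str = "bil") -> Path:
    """Write ``cube`` as float64 ENVI with the given interleave (default BIL)."""
    if interleave not in _INTERLEAVE_AXES:
        raise FormatError(f"unknown interleave {interleave!r}")
    path = Path(path)
    rows, cols, bands = cube.shape
    data = cube.values.astype(np.float64)
    if interleave == "bsq":
        out = data.transpose(2, 0, 1)
    elif interleave == "bil":
        out = data.transpose(0, 2, 1)
    else:
        out = data
    np.ascontiguousarray(out).tofile(path)

    t = cube.transform
    wl = ", ".join(f"{w:.17g}" for w in cube.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[np.dtype(np.float64)]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"data ignore value = {cube.nodata}\n"
        f"vinesense kind = {cube.kind}\n"
        f"map info = {{Arbitrary, 1, 1, {t.origin_x}, {t.origin_y}, "
        f"{t.cell}, {t.cell}, units=Meters}}\n"
        f"wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    path.with_suffix(".hdr").write_text(header)
    return path
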