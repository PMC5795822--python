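"""Point-cloud IO: LAS 1.2 (point format 0) and whitespace/comma XYZ text.

The LAS writer emits the minimal spec-conformant subset this pipeline needs:
scaled int32 coordinates plus the classification byte (ground = 2,
high vegetation = 5, unclassified = 1).
"""

from __future__ import annotations

import logging
import struct
from pathlib import Path

import numpy as np

from ..containers import GROUND, CANOPY, UNCLASSIFIED, PointCloud
from ..errors import FormatError

__all__ = ["read_point_cloud", "write_las", "write_xyz", "read_las", "read_xyz"]

log = logging.getLogger(__name__)

_HEADER_SIZE = 227  # LAS 1.2 public header block
_POINT0 = np.dtype(
    [
        ("x", "<i4"),
        ("y", "<i4"),
        ("z", "<i4"),
        ("intensity", "<u2"),
        ("flags", "u1"),
        ("classification", "u1"),
        ("scan_angle", "i1"),
        ("user_data", "u1"),
        ("point_source", "<u2"),
    ]
)

_VALID_LABELS = {UNCLASSIFIED, GROUND, CANOPY}


def read_point_cloud(path) -> PointCloud:
    """Read a point cloud, sniffing LAS vs XYZ text by signature."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic == b"LASF":
        return read_las(path)
    return read_xyz(path)


def read_las(path) -> PointCloud:
    path = Path(path)
    buf = path.read_bytes()
    if buf[:4] != b"LASF":
        raise FormatError(f"{path} is not a LAS file")
    (point_offset,) = struct.unpack_from("<I", buf, 96)
    fmt_id = buf[104]
    (record_len,) = struct.unpack_from("<H", buf, 105)
    (n_points,) = struct.unpack_from("<I", buf, 107)
    scales = struct.unpack_from("<3d", buf, 131)
    offsets = struct.unpack_from("<3d", buf, 155)
    if fmt_id != 0 or record_len != _POINT0.itemsize:
        raise FormatError(
            f"{path}: unsupported LAS point format {fmt_id} (record {record_len} B)"
        )
    records = np.frombuffer(
        buf, dtype=_POINT0, count=n_points, offset=point_offset
    )
    xyz = np.column_stack(
        [
            records["x"] * scales[0] + offsets[0],
            records["y"] * scales[1] + offsets[1],
            records["z"] * scales[2] + offsets[2],
        ]
    )
    labels = records["classification"].astype(np.uint8).copy()
    labels[~np.isin(labels, list(_VALID_LABELS))] = UNCLASSIFIED
    return PointCloud(xyz, labels)


def write_las(cloud: PointCloud, path, scale: float = 0.001) -> Path:
    """Write LAS 1.2 point format 0 with the given coordinate resolution."""
    path = Path(path)
    n = len(cloud)
    if n:
        offsets = cloud.xyz.min(axis=0)
        mins = cloud.xyz.min(axis=0)
        maxs = cloud.xyz.max(axis=0)
    else:
        offsets = mins = maxs = np.zeros(3)

    records = np.zeros(n, dtype=_POINT0)
    ints = np.round((cloud.xyz - offsets) / scale)
    if n and np.any(np.abs(ints) > 2**31 - 1):
        raise FormatError("coordinates overflow int32 at this storage scale")
    records["x"], records["y"], records["z"] = ints.astype(np.int64).T
    records["flags"] = 1  # single return, first of one
    records["classification"] = cloud.labels

    header = bytearray(_HEADER_SIZE)
    header[0:4] = b"LASF"
    struct.pack_into("<BB", header, 24, 1, 2)  # version 1.2
    struct.pack_into("<32s", header, 26, b"vinesense")
    struct.pack_into("<H", header, 94, _HEADER_SIZE)
    struct.pack_into("<I", header, 96, _HEADER_SIZE)  # offset to points
    struct.pack_into("<I", header, 100, 0)  # no VLRs
    header[104] = 0
    struct.pack_into("<H", header, 105, _POINT0.itemsize)
    struct.pack_into("<I", header, 107, n)
    struct.pack_into("<3d", header, 131, scale, scale, scale)
    struct.pack_into("<3d", header, 155, *offsets)
    struct.pack_into("<6d", header, 179, maxs[0], mins[0], maxs[1], mins[1], maxs[2], mins[2])

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(records.tobytes())
    return path


def read_xyz(path) -> PointCloud:
    """Read ``x y z [label]`` text, comma- or whitespace-delimited."""
    path = Path(path)
    xyz, labels = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.replace(",", " ").split()
            try:
                vals = [float(t) for t in toks[:3]]
                if len(vals) != 3:
                    raise ValueError("fewer than 3 coordinates")
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric coordinate in {line!r}"
                ) from exc
            xyz.append(vals)
            labels.append(int(float(toks[3])) if len(toks) > 3 else UNCLASSIFIED)
    if not xyz:
        log.warning("%s: empty point cloud", path)
        return PointCloud(np.empty((0, 3)))
    labels = np.asarray(labels, dtype=np.uint8)
    labels[~np.isin(labels, list(_VALID_LABELS))] = UNCLASSIFIED
    return PointCloud(np.asarray(xyz), labels)


def write_xyz(cloud: PointCloud, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for (x, y, z), lab in zip(cloud.xyz, cloud.labels):
            fh.write(f"{x:.6f} {y:.6f} {z:.6f} {int(lab)}\n")
    return path
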