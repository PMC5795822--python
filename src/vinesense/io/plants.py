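"""Plant/trunk location tables: GeoJSON points or delimited text.

The column registry follows the per-plant attribute table: tree number,
location, block/row/panel, variety, expert vigour class (1-5), canopy-height
statistics, one column per vegetation index, and EM38 soil conductivity.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from ..containers import PlantRecord
from ..errors import ValidationError

__all__ = ["read_plant_locations", "write_plant_locations", "records_to_frame"]

_CORE_COLUMNS = ["tree_number", "x", "y", "block", "row", "panel", "variety"]

# Local equirectangular approximation for lat/lon inputs (single site,
# metre-scale extents); the reference latitude is the dataset mean.
_EARTH_R = 6_371_000.0


def _lonlat_to_xy(lon, lat, lat0):
    x = np.radians(np.asarray(lon)) * _EARTH_R * math.cos(math.radians(lat0))
    y = np.radians(np.asarray(lat)) * _EARTH_R
    return x, y


def _records_from_frame(df: pd.DataFrame, source: str) -> list[PlantRecord]:
    cols = {c.lower().strip(): c for c in df.columns}

    def col(*names):
        for n in names:
            if n in cols:
                return cols[n]
        return None

    tn = col("tree_number", "tree number", "tree")
    if tn is None:
        raise ValidationError(f"{source}: no tree_number column")
    if df[tn].duplicated().any():
        dupes = sorted(df.loc[df[tn].duplicated(), tn].unique())
        raise ValidationError(f"{source}: duplicate tree_number {dupes}")

    xcol, ycol = col("x", "easting"), col("y", "northing")
    if xcol is None or ycol is None:
        loncol, latcol = col("longitude", "lon"), col("latitude", "lat")
        if loncol is None or latcol is None:
            raise ValidationError(f"{source}: no x/y or longitude/latitude columns")
        lat0 = float(df[latcol].mean())
        xs, ys = _lonlat_to_xy(df[loncol], df[latcol], lat0)
    else:
        xs, ys = df[xcol].to_numpy(float), df[ycol].to_numpy(float)

    def opt(row, name, cast):
        c = col(name)
        if c is None:
            return None
        v = row[c]
        if pd.isna(v):
            return None
        return cast(v)

    records = []
    for i, (_, r) in enumerate(df.iterrows()):
        records.append(
            PlantRecord(
                tree_number=int(r[tn]),
                x=float(xs[i]),
                y=float(ys[i]),
                block=int(r[col("block")]) if col("block") else 1,
                row=int(r[col("row")]) if col("row") else 1,
                panel=int(r[col("panel")]) if col("panel") else 1,
                variety=str(r[col("variety")]) if col("variety") else "",
                expert_vigour=opt(r, "expert_vigour", int),
                em38=opt(r, "em38", float),
            )
        )
    records.sort(key=lambda p: p.tree_number)
    return records


def read_plant_locations(path) -> list[PlantRecord]:
    """Read plants from GeoJSON or a delimited table, ordered by tree_number."""
    path = Path(path)
    head = path.read_text(encoding="utf-8")[:512].lstrip()
    if head.startswith("{"):
        gj = json.loads(path.read_text(encoding="utf-8"))
        rows = []
        for feat in gj.get("features", []):
            props = dict(feat.get("properties", {}))
            lon, lat = feat["geometry"]["coordinates"][:2]
            props.setdefault("longitude", lon)
            props.setdefault("latitude", lat)
            rows.append(props)
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path)
    if df.empty:
        return []
    return _records_from_frame(df, str(path))


def records_to_frame(records: list[PlantRecord]) -> pd.DataFrame:
    """Flatten records into the attribute-table column layout."""
    index_names = sorted({k for r in records for k in r.index_values})
    rows = []
    for r in records:
        row = {
            "tree_number": r.tree_number,
            "x": r.x,
            "y": r.y,
            "block": r.block,
            "row": r.row,
            "panel": r.panel,
            "variety": r.variety,
            "expert_vigour": r.expert_vigour,
            "dvm_max": r.dvm_max,
            "dvm_mean": r.dvm_mean,
        }
        for name in index_names:
            row[name] = r.index_values.get(name)
        row["em38"] = r.em38
        rows.append(row)
    return pd.DataFrame(rows)


def write_plant_locations(records: list[PlantRecord], path) -> Path:
    """Write records as CSV (columns beyond the core set when populated)."""
    path = Path(path)
    records_to_frame(records).to_csv(path, index=False)
    return path
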