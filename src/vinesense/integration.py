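"""Per-plant data integration and Pearson correlation analysis.

Every source — expert panel scores, DVM zonal heights, index rasters
averaged over each plant's canopy pixels, EM38 conductivity — is joined into
one attribute table keyed by tree number, and the pairwise Pearson matrix is
computed on complete cases per column pair (expert scores are panel-sparse,
so listwise deletion would discard most plants).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import IntegrityError, ValidationError
from .indices import IndexRaster
from .signatures import disc_mask

__all__ = [
    "AttributeTable",
    "CorrelationMatrix",
    "align_expert_to_plants",
    "index_over_canopy",
    "build_attribute_table",
    "pearson_matrix",
    "correlation_report",
    "plot_correlation_heatmap",
]

log = logging.getLogger(__name__)

STRONG_CORRELATION = 0.4  # reporting flag, not a significance test

_IDENTITY_COLUMNS = ["tree_number", "x", "y", "block", "row", "panel", "variety"]


@dataclass
class AttributeTable:
    """The per-plant information system: one row per vine."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if self.frame["tree_number"].duplicated().any():
            raise IntegrityError("duplicate tree_number in attribute table")

    @property
    def numeric_columns(self) -> list[str]:
        skip = set(_IDENTITY_COLUMNS) - {"tree_number"}
        return [
            c
            for c in self.frame.columns
            if c not in skip and c != "tree_number"
            and pd.api.types.is_numeric_dtype(self.frame[c])
        ]


@dataclass
class CorrelationMatrix:
    labels: list
    r: np.ndarray  # pairwise Pearson, symmetric, unit diagonal
    n: np.ndarray  # pairwise complete-case counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.labels, columns=self.labels)


def align_expert_to_plants(panel_table: pd.DataFrame, plants) -> pd.Series:
    """Broadcast panel-level expert classes to the plants of each panel.

    The expert table has one class per (row, panel) cell; every plant in the
    cell inherits it.  Plants in unscored panels get missing values; scored
    panels with no plants only warn.  Row order of the table is irrelevant.
    """
    required = {"row", "panel", "vigour"}
    if not required <= set(panel_table.columns):
        raise ValidationError(f"panel table needs columns {sorted(required)}")
    key = {}
    for _, rec in panel_table.iterrows():
        key[(int(rec["row"]), int(rec["panel"]))] = int(rec["vigour"])
    plant_cells = {(p.row, p.panel) for p in plants}
    for cell in set(key) - plant_cells:
        log.warning("expert panel %s contains no plants", cell)
    values = [key.get((p.row, p.panel), np.nan) for p in plants]
    return pd.Series(values, index=[p.tree_number for p in plants],
                     name="expert_vigour", dtype=float)


def index_over_canopy(raster: IndexRaster, plants,
                      radius: float = 0.3) -> pd.Series:
    """Mean index value over each plant's canopy pixels.

    Averaging over the plant's pixel disc mirrors sampling every vine from
    the canopy coverage; plants whose mask is empty get a missing value.
    """
    out = {}
    for plant in plants:
        mask = disc_mask(raster.transform, raster.values.shape,
                         plant.x, plant.y, radius)
        vals = raster.values[mask]
        vals = vals[(vals != raster.nodata) & np.isfinite(vals)]
        out[plant.tree_number] = float(vals.mean()) if vals.size else np.nan
    return pd.Series(out, name=raster.name)


def build_attribute_table(plants, zonal_stats: pd.DataFrame | None = None,
                          index_values: dict | None = None,
                          expert: pd.Series | None = None,
                          em38=None) -> AttributeTable:
    """Join all per-plant sources into the attribute table.

    ``index_values`` maps index name -> Series keyed by tree number (as
    produced by :func:`index_over_canopy`); ``zonal_stats`` is the DVM zonal
    frame.  Trap counts, if ever supplied as an extra index column, pass
    through untouched — they are verification data, not statistics inputs.
    """
    ids = [p.tree_number for p in plants]
    if len(set(ids)) != len(ids):
        raise IntegrityError("duplicate tree_number among plants")
    frame = pd.DataFrame(
        {
            "tree_number": ids,
            "x": [p.x for p in plants],
            "y": [p.y for p in plants],
            "block": [p.block for p in plants],
            "row": [p.row for p in plants],
            "panel": [p.panel for p in plants],
            "variety": [p.variety for p in plants],
        }
    ).set_index("tree_number", drop=False)

    frame["expert_vigour"] = (
        expert.reindex(frame.index)
        if expert is not None
        else pd.Series([p.expert_vigour for p in plants], index=frame.index, dtype=float)
    )
    if zonal_stats is not None:
        frame["dvm_max"] = zonal_stats["max"].reindex(frame.index)
        frame["dvm_mean"] = zonal_stats["mean"].reindex(frame.index)
    else:
        frame["dvm_max"] = [p.dvm_max for p in plants]
        frame["dvm_mean"] = [p.dvm_mean for p in plants]
    for name in sorted(index_values or {}):
        frame[name] = index_values[name].reindex(frame.index)
    if em38 is not None:
        em38 = np.asarray(em38, dtype=float)
        if em38.size != len(ids):
            raise IntegrityError("em38 length does not match plant count")
        frame["em38"] = em38
    else:
        frame["em38"] = [p.em38 for p in plants]
    return AttributeTable(frame.reset_index(drop=True))


def pearson_matrix(table: AttributeTable | pd.DataFrame,
                   columns=None, min_pairs: int = 3) -> CorrelationMatrix:
    """Pairwise complete-case Pearson matrix over numeric columns.

    Zero-variance columns (on the complete cases of a pair) yield missing
    entries with a warning; pairs with fewer than ``min_pairs`` complete
    cases are missing too.  The matrix is symmetric with a unit diagonal.
    """
    frame = table.frame if isinstance(table, AttributeTable) else table
    if columns is None:
        columns = (table.numeric_columns if isinstance(table, AttributeTable)
                   else [c for c in frame.columns
                         if pd.api.types.is_numeric_dtype(frame[c])])
    m = len(columns)
    r = np.full((m, m), np.nan)
    n = np.zeros((m, m), dtype=int)
    data = {c: frame[c].to_numpy(dtype=float) for c in columns}
    for i in range(m):
        for j in range(i + 1, m):
            a, b = data[columns[i]], data[columns[j]]
            ok = np.isfinite(a) & np.isfinite(b)
            n[i, j] = n[j, i] = int(ok.sum())
            if n[i, j] < min_pairs:
                continue
            aa, bb = a[ok], b[ok]
            if np.std(aa) == 0 or np.std(bb) == 0:
                log.warning("zero-variance pair (%s, %s): r undefined",
                            columns[i], columns[j])
                continue
            r[i, j] = r[j, i] = float(np.corrcoef(aa, bb)[0, 1])
    for i in range(m):
        a = data[columns[i]]
        ok = np.isfinite(a)
        n[i, i] = int(ok.sum())
        r[i, i] = 1.0 if n[i, i] >= min_pairs and np.std(a[ok]) > 0 else np.nan
    return CorrelationMatrix(list(columns), r, n)


def correlation_report(matrix: CorrelationMatrix,
                       reference_columns=("expert_vigour", "dvm_max"),
                       strong: float = STRONG_CORRELATION) -> pd.DataFrame:
    """Indices ranked by correlation against each reference column.

    Rows: (reference, variable, r, n, strong) sorted by descending r within
    each reference; ``strong`` flags |r| above the reporting threshold 0.4.
    """
    rows = []
    for ref in reference_columns:
        if ref not in matrix.labels:
            continue
        i = matrix.labels.index(ref)
        for j, name in enumerate(matrix.labels):
            if name == ref or name in reference_columns:
                continue
            rows.append(
                {
                    "reference": ref,
                    "variable": name,
                    "r": matrix.r[i, j],
                    "n": matrix.n[i, j],
                    "strong": bool(np.isfinite(matrix.r[i, j])
                                   and abs(matrix.r[i, j]) > strong),
                }
            )
    report = pd.DataFrame(rows, columns=["reference", "variable", "r", "n", "strong"])
    if not report.empty:
        report = report.sort_values(["reference", "r"],
                                    ascending=[True, False]).reset_index(drop=True)
    return report


def plot_correlation_heatmap(matrix: CorrelationMatrix, path) -> None:
    """Render the Pearson matrix as a diverging heat map (blue positive,
    orange negative, intensity by strength)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = len(matrix.labels)
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * m), max(5, 0.45 * m)))
    im = ax.imshow(matrix.r, vmin=-1, vmax=1, cmap="RdBu")
    ax.set_xticks(range(m), matrix.labels, rotation=90, fontsize=8)
    ax.set_yticks(range(m), matrix.labels, fontsize=8)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
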