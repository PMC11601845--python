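"""Plain-format readers/writers: cell tables as CSV, label images as TIFF.

The on-disk cell-table layout is one CSV with columns
``cell_id, roi_id, cohort, x_um, y_um`` followed by one column per marker.
Label images are single-channel integer TIFFs; paths not ending in
.tif/.tiff fall back to a whitespace-delimited integer matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CELL_COLUMNS = ["cell_id", "roi_id", "cohort", "x_um", "y_um"]


def write_cell_table(cells: pd.DataFrame, markers: pd.DataFrame, path) -> None:
    """Merge the cell and marker tables on cell_id and write one CSV."""
    merged = cells.merge(markers.drop(columns=["roi_id"], errors="ignore"), on="cell_id")
    merged.to_csv(path, index=False)


def read_cell_table(path):
    """Read a combined CSV back into (cells, markers) DataFrames."""
    df = pd.read_csv(path)
    missing = [c for c in ("cell_id", "roi_id", "x_um", "y_um") if c not in df.columns]
    if missing:
        raise ValueError(f"cell table {path} lacks column(s): {missing}")
    meta = [c for c in CELL_COLUMNS if c in df.columns]
    marker_cols = [c for c in df.columns if c not in meta]
    cells = df[meta].copy()
    markers = df[["cell_id", "roi_id"] + marker_cols].copy()
    return cells, markers


def _is_tiff(path) -> bool:
    return str(path).lower().endswith((".tif", ".tiff"))


def write_label_image(image: np.ndarray, path) -> None:
    arr = np.asarray(image)
    if _is_tiff(path):
        import tifffile

        tifffile.imwrite(path, arr.astype(np.uint32))
    else:
        np.savetxt(path, arr, fmt="%d")


def read_label_image(path) -> np.ndarray:
    if _is_tiff(path):
        import tifffile

        arr = tifffile.imread(path)
    else:
        arr = np.loadtxt(path)
    return np.asarray(arr).astype(np.int64)


def write_expression(expr: pd.DataFrame, groups: pd.Series, path) -> None:
    out = expr.copy()
    out.insert(0, "group", groups.reindex(expr.index))
    out.to_csv(path)


def read_expression(path):
    df = pd.read_csv(path, index_col=0)
    if "group" not in df.columns:
        raise ValueError(f"expression file {path} lacks a 'group' column")
    groups = df.pop("group")
    return df.astype(float), groups


def read_cohort_map(path) -> pd.Series:
    """CSV with columns roi_id, cohort -> Series roi_id -> cohort."""
    df = pd.read_csv(path)
    if "roi_id" not in df.columns or "cohort" not in df.columns:
        raise ValueError(f"cohort map {path} needs columns roi_id and cohort")
    return df.set_index("roi_id")["cohort"]
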