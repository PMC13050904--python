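"""Readers and writers for response-matrix tables.

Long-format CSV is canonical (one row per receptor–hydrocarbon grid cell,
columns ``receptor, hydrocarbon, mean_delta, sem, n``); wide format
(receptors as rows, hydrocarbons as columns) is a convenience view that
carries means only.  Missing cells are written as empty fields and read back
as missing — "NA" is also accepted — and are never coerced to zero.  All
headers are plain ASCII.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import (  # noqa: F401  (re-exported surface)
    ExpressionTable,
    SubfamilyMap,
    load_expression,
    load_subfamilies,
)
from .matrix import ResponseMatrix
from .panel import StimulusPanel, load_panel, default_panel  # noqa: F401
from .rename import RenameMap, apply_rename_map, load_rename_map, default_rename_map  # noqa: F401

_MISSING_TOKENS = {"", "NA", "NaN", "nan"}


def _parse_float(token: str, row_num: int, col: str) -> float | None:
    if token.strip() in _MISSING_TOKENS:
        return None
    try:
        return float(token)
    except ValueError:
        raise ValueError(
            f"non-numeric {col} value {token!r} at data row {row_num}"
        ) from None


def _read_long(path: str | Path) -> ResponseMatrix:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file")
        cols = set(reader.fieldnames)
        if not {"receptor", "hydrocarbon", "mean_delta"} <= cols:
            raise ValueError(
                f"{path}: long dialect needs columns receptor, hydrocarbon, mean_delta"
            )
        has_sem, has_n = "sem" in cols, "n" in cols
        receptors: list[str] = []
        hcs: list[str] = []
        cells: dict[tuple[str, str], tuple[float | None, float | None, float | None]] = {}
        for i, row in enumerate(reader, start=1):
            rec, hc = row["receptor"], row["hydrocarbon"]
            key = (rec, hc)
            if key in cells:
                raise ValueError(f"duplicate (receptor, hydrocarbon) pair {key}")
            if rec not in receptors:
                receptors.append(rec)
            if hc not in hcs:
                hcs.append(hc)
            mean = _parse_float(row["mean_delta"], i, "mean_delta")
            sem = _parse_float(row["sem"], i, "sem") if has_sem else None
            n = _parse_float(row["n"], i, "n") if has_n else None
            cells[key] = (mean, sem, n)

    def _grid(slot: int) -> pd.DataFrame:
        g = pd.DataFrame(np.nan, index=receptors, columns=hcs, dtype=float)
        for (rec, hc), vals in cells.items():
            if vals[slot] is not None:
                g.loc[rec, hc] = vals[slot]
        return g

    return ResponseMatrix(
        mean=_grid(0),
        sem=_grid(1) if has_sem else None,
        n=_grid(2) if has_n else None,
    )


def _read_wide(path: str | Path) -> ResponseMatrix:
    df = pd.read_csv(path, index_col=0, na_values=["NA"], keep_default_na=True)
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate receptor rows: {dupes}")
    try:
        mean = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric mean value in wide table: {exc}") from None
    mean.index = mean.index.astype(str)
    mean.columns = mean.columns.astype(str)
    return ResponseMatrix(mean=mean)


def read_response_matrix(path: str | Path, dialect: str = "long") -> ResponseMatrix:
    """Read a response matrix from CSV.

    ``dialect="long"`` expects one row per grid cell with columns
    ``receptor, hydrocarbon, mean_delta`` and optional ``sem``/``n``;
    ``dialect="wide"`` expects receptors as rows and hydrocarbons as columns.
    Empty fields / "NA" are read as missing cells.  Duplicate pairs and
    non-numeric means are hard errors.
    """
    if dialect == "long":
        return _read_long(path)
    if dialect == "wide":
        return _read_wide(path)
    raise ValueError(f"unknown dialect {dialect!r}; use 'long' or 'wide'")


def _fmt(v: float) -> str:
    return "" if pd.isna(v) else repr(float(v))


def write_response_matrix(
    matrix: ResponseMatrix, path: str | Path, dialect: str = "long"
) -> None:
    """Write a response matrix to CSV; read(write(m)) == m including missing
    cells.  Long output covers every grid cell (missing → empty mean field);
    the SEM/n columns appear only when the matrix carries those grids."""
    if dialect == "wide":
        out = matrix.mean.copy()
        out.index.name = "receptor"
        out.to_csv(path, na_rep="")
        return
    if dialect != "long":
        raise ValueError(f"unknown dialect {dialect!r}; use 'long' or 'wide'")
    header = ["receptor", "hydrocarbon", "mean_delta"]
    if matrix.sem is not None:
        header.append("sem")
    if matrix.n is not None:
        header.append("n")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rec in matrix.receptor_ids:
            for hc in matrix.hc_names:
                row = [rec, hc, _fmt(matrix.mean.loc[rec, hc])]
                if matrix.sem is not None:
                    row.append(_fmt(matrix.sem.loc[rec, hc]))
                if matrix.n is not None:
                    row.append(_fmt(matrix.n.loc[rec, hc]))
                writer.writerow(row)


def export_three_tab(
    matrix: ResponseMatrix, subfamilies: SubfamilyMap, out_dir: str | Path
) -> dict[str, Path]:
    """Export the response database as three tables: by receptor, by
    hydrocarbon, and by subfamily (the input tables of the response-browser
    web app)."""
    from .coding import mean_response_per_hc, subfamily_sum

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "receptor": out_dir / "by_receptor.csv",
        "hydrocarbon": out_dir / "by_hydrocarbon.csv",
        "subfamily": out_dir / "by_subfamily.csv",
    }
    write_response_matrix(matrix, paths["receptor"], dialect="long")
    mean_response_per_hc(matrix).to_csv(paths["hydrocarbon"], index=False)
    grid = subfamily_sum(matrix, subfamilies)
    long = grid.stack(future_stack=True).reset_index()
    long.columns = ["subfamily", "hydrocarbon", "summed_delta"]
    long.to_csv(paths["subfamily"], index=False)
    return paths
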