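"""The receptor × hydrocarbon response matrix — the pipeline's exchange object.

Cells hold the solvent-corrected mean evoked firing-rate change (Δspikes/s,
column header spelled ``mean_delta`` in files) with optional SEM and
replicate-count grids.  Missing cells — receptor–hydrocarbon pairs never
tested — are first-class: they are NaN in memory, empty fields on disk, and
every downstream denominator excludes them rather than treating them as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass
class ResponseMatrix:
    """Mean Δspikes/s per (receptor, hydrocarbon) with optional SEM and n.

    ``mean``, ``sem`` and ``n`` are aligned DataFrames (receptors as index,
    hydrocarbons as columns); NaN marks an untested pair.  ``sem`` and ``n``
    are optional but must share the grid when present.
    """

    mean: pd.DataFrame
    sem: pd.DataFrame | None = None
    n: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.mean.index.has_duplicates or self.mean.columns.has_duplicates:
            raise ValueError("duplicate receptor or hydrocarbon labels")
        for name, grid in (("sem", self.sem), ("n", self.n)):
            if grid is None:
                continue
            if not grid.index.equals(self.mean.index) or not grid.columns.equals(
                self.mean.columns
            ):
                raise ValueError(f"{name} grid does not match mean grid labels")
        if self.sem is not None and (self.sem.to_numpy() < 0).any():
            raise ValueError("sem values must be non-negative")

    @property
    def receptor_ids(self) -> list[str]:
        return list(self.mean.index)

    @property
    def hc_names(self) -> list[str]:
        return list(self.mean.columns)

    def row(self, receptor_id: str) -> pd.Series:
        """One receptor's response profile (NaN = untested)."""
        return self.mean.loc[receptor_id]

    def n_tested(self) -> int:
        """Number of non-missing (tested) receptor–hydrocarbon pairs."""
        return int(self.mean.notna().sum().sum())

    def equals(self, other: "ResponseMatrix", atol: float = 0.0) -> bool:
        """Grid equality including the missing-cell pattern."""
        if self.receptor_ids != other.receptor_ids:
            return False
        if self.hc_names != other.hc_names:
            return False

        def _grids_equal(a: pd.DataFrame | None, b: pd.DataFrame | None) -> bool:
            if (a is None) != (b is None):
                return False
            if a is None:
                return True
            av, bv = a.to_numpy(dtype=float), b.to_numpy(dtype=float)
            same_na = np.isnan(av) == np.isnan(bv)
            close = np.isclose(av, bv, atol=atol, rtol=0.0, equal_nan=True)
            return bool(same_na.all() and close.all())

        return (
            _grids_equal(self.mean, other.mean)
            and _grids_equal(self.sem, other.sem)
            and _grids_equal(self.n, other.n)
        )

    @classmethod
    def from_records(
        cls,
        records: Mapping[tuple[str, str], tuple[float, float, int]],
        receptor_ids: list[str],
        hc_names: list[str],
    ) -> "ResponseMatrix":
        """Build a matrix from {(receptor, hc): (mean, sem, n)} records."""
        mean = pd.DataFrame(np.nan, index=receptor_ids, columns=hc_names, dtype=float)
        sem = mean.copy()
        n = mean.copy()
        for (rec, hc), (m, s, k) in records.items():
            mean.loc[rec, hc] = m
            sem.loc[rec, hc] = s
            n.loc[rec, hc] = k
        return cls(mean=mean, sem=sem, n=n)
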