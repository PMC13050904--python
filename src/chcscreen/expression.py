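"""Receptor expression values and subfamily assignments.

Expression is in FPKM (fragments per kilobase of transcript per million
mapped reads) from antennal transcriptomes, kept separately for workers and
males.  Worker-antenna FPKM weights responses into "receptivity" scores;
receptors with no expression value are excluded from that weighting, never
zeroed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd


@dataclass(frozen=True)
class ExpressionTable:
    """receptor → (worker_fpkm, male_fpkm); ``None`` marks a missing value."""

    worker_fpkm: dict[str, float | None]
    male_fpkm: dict[str, float | None]

    def __post_init__(self) -> None:
        for name, table in (("worker", self.worker_fpkm), ("male", self.male_fpkm)):
            for rec, v in table.items():
                if v is not None and (math.isnan(v) or v < 0):
                    raise ValueError(f"{name} FPKM for {rec} must be >= 0, got {v}")

    @property
    def receptor_ids(self) -> list[str]:
        return list(self.worker_fpkm)

    def has_worker(self, receptor_id: str) -> bool:
        return self.worker_fpkm.get(receptor_id) is not None

    @classmethod
    def from_mapping(cls, worker: Mapping[str, float | None]) -> "ExpressionTable":
        worker = dict(worker)
        return cls(worker_fpkm=worker, male_fpkm={r: None for r in worker})


def load_expression(path: str | Path) -> ExpressionTable:
    """Read a TSV/CSV with columns receptor, worker_fpkm[, male_fpkm].

    Empty fields and "NA" mark missing values (the receptor stays listed but
    is excluded from receptivity weighting downstream).
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    if "receptor" not in df.columns or "worker_fpkm" not in df.columns:
        raise ValueError(f"expression table {path} needs columns receptor, worker_fpkm")
    if df["receptor"].duplicated().any():
        dupes = sorted(df.loc[df["receptor"].duplicated(), "receptor"].unique())
        raise ValueError(f"duplicate receptors in expression table: {dupes}")

    def _col(col: str) -> dict[str, float | None]:
        if col not in df.columns:
            return {str(r): None for r in df["receptor"]}
        vals = pd.to_numeric(df[col], errors="raise")
        return {
            str(r): (None if pd.isna(v) else float(v))
            for r, v in zip(df["receptor"], vals)
        }

    return ExpressionTable(worker_fpkm=_col("worker_fpkm"), male_fpkm=_col("male_fpkm"))


@dataclass(frozen=True)
class SubfamilyMap:
    """receptor → subfamily label (single letters, or "9-exon")."""

    labels: dict[str, str]

    def __getitem__(self, receptor_id: str) -> str:
        return self.labels[receptor_id]

    def __contains__(self, receptor_id: str) -> bool:
        return receptor_id in self.labels

    @property
    def subfamilies(self) -> list[str]:
        return sorted(set(self.labels.values()))


def load_subfamilies(path: str | Path) -> SubfamilyMap:
    """Read a TSV/CSV with columns receptor, subfamily."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    if "receptor" not in df.columns or "subfamily" not in df.columns:
        raise ValueError(f"subfamily table {path} needs columns receptor, subfamily")
    return SubfamilyMap(dict(zip(df["receptor"], df["subfamily"])))
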