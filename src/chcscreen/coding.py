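"""Combinatorial-coding summaries over the combined response matrix.

Aggregates the receptor × hydrocarbon matrix three ways: summed responses
per receptor subfamily, mean response per hydrocarbon, and expression-
weighted "receptivity" (mean Δspikes/s × worker-antenna FPKM, arbitrary
units).  Missing pairs are eliminated from every sum and denominator —
a hydrocarbon's mean divides by the number of receptors actually tested on
it, and receptors without a worker FPKM value are dropped from receptivity
altogether rather than zeroed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionTable, SubfamilyMap
from .matrix import ResponseMatrix


@dataclass
class ReceptivityMatrix:
    """Expression-weighted responses; ``excluded`` lists receptors dropped
    for lack of a worker FPKM value."""

    values: pd.DataFrame  # receptor × hydrocarbon, arbitrary units, NaN missing
    excluded: tuple[str, ...]

    @property
    def receptor_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def hc_names(self) -> list[str]:
        return list(self.values.columns)


def subfamily_sum(matrix: ResponseMatrix, subfamilies: SubfamilyMap) -> pd.DataFrame:
    """Cellwise sum of member responses per subfamily × hydrocarbon.

    Missing member cells contribute nothing; a cell with no tested member at
    all stays missing.  Every receptor must carry a subfamily label.
    """
    unmapped = [r for r in matrix.receptor_ids if r not in subfamilies]
    if unmapped:
        raise ValueError(f"receptors without subfamily label: {unmapped}")
    labels = pd.Series(
        {r: subfamilies[r] for r in matrix.receptor_ids}, name="subfamily"
    )
    grouped = matrix.mean.groupby(labels).sum(min_count=1)
    grouped.index.name = "subfamily"
    return grouped.sort_index()


def mean_response_per_hc(matrix: ResponseMatrix) -> pd.DataFrame:
    """Per hydrocarbon: summed Δspikes/s ÷ number of tested receptors.

    A hydrocarbon never tested stays missing (NaN), not zero.  Columns:
    hydrocarbon, n_tested, mean_response.
    """
    n_tested = matrix.mean.notna().sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        means = matrix.mean.mean(axis=0, skipna=True)
    return pd.DataFrame(
        {
            "hydrocarbon": matrix.hc_names,
            "n_tested": n_tested.to_numpy(dtype=int),
            "mean_response": means.to_numpy(dtype=float),
        }
    )


def receptivity(matrix: ResponseMatrix, expression: ExpressionTable) -> ReceptivityMatrix:
    """Weight each response by the receptor's worker-antenna FPKM.

    Receptors lacking a worker FPKM value are excluded from the output (and
    hence from downstream denominators) — exclusion is provenance, not an
    error.  Sign is preserved: inhibitory responses yield negative
    receptivity.
    """
    kept = [r for r in matrix.receptor_ids if expression.has_worker(r)]
    excluded = tuple(r for r in matrix.receptor_ids if r not in set(kept))
    fpkm = pd.Series({r: float(expression.worker_fpkm[r]) for r in kept})
    values = matrix.mean.loc[kept].mul(fpkm, axis=0)
    return ReceptivityMatrix(values=values, excluded=excluded)


def mean_receptivity_per_hc(recept: ReceptivityMatrix) -> pd.DataFrame:
    """Per hydrocarbon: summed receptivity ÷ number of tested receptors,
    counted after the FPKM exclusion."""
    n_tested = recept.values.notna().sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = recept.values.mean(axis=0, skipna=True)
    return pd.DataFrame(
        {
            "hydrocarbon": recept.hc_names,
            "n_tested": n_tested.to_numpy(dtype=int),
            "mean_receptivity": means.to_numpy(dtype=float),
        }
    )


def hc_summaries(
    matrix: ResponseMatrix, expression: ExpressionTable | None = None
) -> pd.DataFrame:
    """Combined per-hydrocarbon summary with ranks.

    Columns: hydrocarbon, n_tested, mean_response, rank_by_response and —
    when an expression table is given — n_tested_receptivity,
    mean_receptivity, rank_by_receptivity.  Ranks are dense descending with
    alphabetical tie-break; missing summaries are unranked.
    """
    out = mean_response_per_hc(matrix)
    out["rank_by_response"] = _rank(out, "mean_response")
    if expression is not None:
        rec = receptivity(matrix, expression)
        r = mean_receptivity_per_hc(rec).rename(
            columns={"n_tested": "n_tested_receptivity"}
        )
        out = out.merge(r, on="hydrocarbon", how="left")
        out["rank_by_receptivity"] = _rank(out, "mean_receptivity")
    return out


def _rank(df: pd.DataFrame, col: str) -> pd.Series:
    order = df.sort_values(
        [col, "hydrocarbon"], ascending=[False, True]
    ).index
    ranks = pd.Series(np.nan, index=df.index)
    pos = 1
    for i in order:
        if pd.notna(df.loc[i, col]):
            ranks[i] = pos
            pos += 1
    return ranks.astype("Int64")


def rank_hcs(
    summaries: pd.DataFrame, by: str = "response", k: int = 6
) -> pd.DataFrame:
    """Top-``k`` hydrocarbons by mean response or mean receptivity.

    Descending by the chosen statistic, ties broken alphabetically.  If
    fewer than ``k`` hydrocarbons have a value, all are returned with a
    warning.
    """
    col = {"response": "mean_response", "receptivity": "mean_receptivity"}.get(by)
    if col is None or col not in summaries.columns:
        raise ValueError(f"cannot rank by {by!r}")
    avail = summaries.dropna(subset=[col])
    if k > len(avail):
        warnings.warn(
            f"requested top {k} but only {len(avail)} hydrocarbons have a "
            f"{by} summary",
            stacklevel=2,
        )
        k = len(avail)
    ordered = avail.sort_values([col, "hydrocarbon"], ascending=[False, True])
    return ordered.head(k)[["hydrocarbon", col]].reset_index(drop=True)
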