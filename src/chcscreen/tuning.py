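"""Tuning classification and dose–response fitting.

A receptor "responds" to a hydrocarbon when its solvent-corrected mean
response is strictly above 30 Δspikes/s — six times the host neuron's
spontaneous rate.  Tuning classes follow the counting rules used for the
screened repertoire: broad (≥7 hydrocarbons above threshold), narrow
(exactly 1), intermediate (2–6), and for receptors with no excitatory hit,
inhibited (≥5 pairs at or below −10 Δspikes/s) versus nonresponder.  Dose
dependence of the most efficacious ligand is fit with a three-parameter
Hill curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .matrix import ResponseMatrix

DEFAULT_THRESHOLD = 30.0
DEFAULT_INHIBITION_THRESHOLD = -10.0
DEFAULT_BROAD_MIN = 7
#: Minimum count of inhibitory pairs for the "inhibited" class.  The
#: narrative anchor is only "several pairs"; 5 is this package's documented,
#: configurable stand-in.
DEFAULT_INHIBIT_MIN = 5


@dataclass(frozen=True)
class TuningProfile:
    """Per-receptor tuning summary at a fixed responder threshold."""

    receptor_id: str
    hcs_above_threshold: tuple[str, ...]
    max_response: tuple[str, float]
    tuning_class: str  # narrow | broad | intermediate | nonresponder | inhibited
    n_inhibitory_pairs: int

    @property
    def n_above(self) -> int:
        return len(self.hcs_above_threshold)


@dataclass(frozen=True)
class DoseResponseFit:
    """Hill-curve fit Δ(d) = max_delta · d^h / (ec50^h + d^h)."""

    receptor_id: str
    hc_name: str
    doses: tuple[float, ...]
    mean_deltas: tuple[float, ...]
    max_delta: float
    ec50_nmol: float
    hill_slope: float
    converged: bool
    rmse: float


def classify_response(mean_delta: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """"above" iff the mean response is strictly above the threshold."""
    return "above" if mean_delta > threshold else "below"


def profile_receptor(
    row: pd.Series,
    receptor_id: str | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    inhibition_threshold: float = DEFAULT_INHIBITION_THRESHOLD,
    broad_min: int = DEFAULT_BROAD_MIN,
    inhibit_min: int = DEFAULT_INHIBIT_MIN,
) -> TuningProfile:
    """Classify one receptor's response profile.

    ``row`` is a hydrocarbon-indexed Series of mean Δspikes/s with NaN for
    untested pairs; all counts run over tested pairs only.
    """
    rid = receptor_id if receptor_id is not None else str(row.name)
    tested = row.dropna()
    if tested.empty:
        raise ValueError(f"receptor {rid}: all cells missing")
    above = tested[tested > threshold]
    n_inhib = int((tested <= inhibition_threshold).sum())
    # argmax with alphabetical tie-break
    best = tested[tested == tested.max()]
    max_hc = sorted(best.index)[0]
    n_above = len(above)
    if n_above >= broad_min:
        cls = "broad"
    elif n_above == 1:
        cls = "narrow"
    elif n_above >= 2:
        cls = "intermediate"
    elif n_inhib >= inhibit_min:
        cls = "inhibited"
    else:
        cls = "nonresponder"
    return TuningProfile(
        receptor_id=rid,
        hcs_above_threshold=tuple(above.index),
        max_response=(max_hc, float(tested[max_hc])),
        tuning_class=cls,
        n_inhibitory_pairs=n_inhib,
    )


def profile_all(
    matrix: ResponseMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    inhibition_threshold: float = DEFAULT_INHIBITION_THRESHOLD,
    broad_min: int = DEFAULT_BROAD_MIN,
    inhibit_min: int = DEFAULT_INHIBIT_MIN,
) -> dict[str, TuningProfile]:
    """Tuning profile for every receptor in the matrix."""
    return {
        rec: profile_receptor(
            matrix.row(rec), rec, threshold, inhibition_threshold, broad_min, inhibit_min
        )
        for rec in matrix.receptor_ids
    }


def profiles_to_frame(profiles: dict[str, TuningProfile]) -> pd.DataFrame:
    rows = [
        {
            "receptor": p.receptor_id,
            "n_above": p.n_above,
            "class": p.tuning_class,
            "max_hc": p.max_response[0],
            "max_delta": p.max_response[1],
            "n_inhibitory_pairs": p.n_inhibitory_pairs,
        }
        for p in profiles.values()
    ]
    return pd.DataFrame(rows)


def count_responding_receptors(
    matrix: ResponseMatrix, threshold: float = DEFAULT_THRESHOLD
) -> int:
    """Receptors with at least one hydrocarbon strictly above threshold."""
    return sum(
        profile_receptor(matrix.row(r), r, threshold).n_above >= 1
        for r in matrix.receptor_ids
    )


def most_efficacious_ligand(row: pd.Series) -> tuple[str, float]:
    """The hydrocarbon with the largest mean response (alphabetical
    tie-break over tested cells)."""
    tested = row.dropna()
    if tested.empty:
        raise ValueError("all cells missing")
    best = tested[tested == tested.max()]
    hc = sorted(best.index)[0]
    return hc, float(tested[hc])


def _hill(d: np.ndarray, m: float, ec50: float, h: float) -> np.ndarray:
    return m * d**h / (ec50**h + d**h)


def fit_dose_response(
    doses: Sequence[float],
    mean_deltas: Sequence[float],
    receptor_id: str = "",
    hc_name: str = "",
    *,
    hill_bounds: tuple[float, float] = (0.3, 6.0),
) -> DoseResponseFit:
    """Least-squares Hill fit of a dose series.

    Bounds: hill slope within ``hill_bounds``, ec50 within
    [min_dose/10, max_dose·10].  Degenerate data (all responses ≈ 0) or an
    optimizer failure is reported via ``converged=False`` rather than
    raised; fewer than 3 distinct positive doses is an error.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(mean_deltas, dtype=float)
    if d.shape != y.shape:
        raise ValueError("doses and responses must have equal length")
    if np.unique(d).size < 3:
        raise ValueError("need at least 3 distinct doses to fit a Hill curve")
    if np.any(d <= 0):
        raise ValueError("doses must be positive")

    def _failed() -> DoseResponseFit:
        return DoseResponseFit(
            receptor_id, hc_name, tuple(d), tuple(y),
            np.nan, np.nan, np.nan, False, np.nan,
        )

    if np.max(np.abs(y)) < 1e-9:
        return _failed()

    ec50_lo, ec50_hi = d.min() / 10.0, d.max() * 10.0
    ymax = float(y.max())
    p0 = [max(ymax, 1.0), float(np.sqrt(d.min() * d.max())), 1.5]
    bounds = (
        [0.0, ec50_lo, hill_bounds[0]],
        [max(10.0 * abs(y).max(), 1.0), ec50_hi, hill_bounds[1]],
    )
    p0 = [min(max(p, lo), hi) for p, lo, hi in zip(p0, bounds[0], bounds[1])]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_hill, d, y, p0=p0, bounds=bounds, maxfev=20000)
    except (RuntimeError, ValueError):
        return _failed()
    resid = y - _hill(d, *popt)
    return DoseResponseFit(
        receptor_id, hc_name, tuple(d), tuple(y),
        float(popt[0]), float(popt[1]), float(popt[2]),
        True, float(np.sqrt(np.mean(resid**2))),
    )


def check_low_dose_silence(
    dose_table: pd.DataFrame,
    dose_cutoff: float = 2.0,
    response_cutoff: float = 10.0,
) -> tuple[bool, pd.DataFrame]:
    """Is every response at doses ≤ ``dose_cutoff`` nmol at or below
    ``response_cutoff`` Δspikes/s?

    ``dose_table`` is a long table with columns receptor, hydrocarbon,
    dose_nmol, mean_delta.  Returns (verdict, offending rows).  With no
    doses at or below the cutoff the check is vacuously true, with a
    warning.
    """
    low = dose_table[dose_table["dose_nmol"] <= dose_cutoff]
    if low.empty:
        warnings.warn(
            f"no doses at or below {dose_cutoff} nmol: check is vacuous",
            stacklevel=2,
        )
        return True, low
    offenders = low[low["mean_delta"] > response_cutoff]
    return offenders.empty, offenders.reset_index(drop=True)
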