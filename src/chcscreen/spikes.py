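"""Spike-train quantification: windowed counts → Δspikes/s → response matrix.

The response statistic follows standard single-sensillum practice: spikes
are counted in a 1 s pre-stimulus window and in a 200 ms response window
0.2–0.4 s after the stimulus command (matching the delivery delay), both
counts are converted to frequencies, their difference is the raw Δspikes/s,
and the mean solvent-control response of the same receptor is subtracted.
Replicates aggregate to mean ± SEM (sample SD / √n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .matrix import ResponseMatrix
from .panel import StimulusPanel
from .simulate import Trial
from .voltage import VoltageTrace


@dataclass(frozen=True)
class Windows:
    """Half-open count windows [a, b) in seconds relative to stimulus onset."""

    pre: tuple[float, float] = (-1.0, 0.0)
    response: tuple[float, float] = (0.2, 0.4)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("pre", self.pre), ("response", self.response)):
            if hi <= lo:
                raise ValueError(f"{name} window must have positive width")
        if self.pre[1] > self.response[0] and self.response[1] > self.pre[0]:
            raise ValueError("pre and response windows must not overlap")


DEFAULT_WINDOWS = Windows()


def count_spikes(spike_times: Sequence[float], window: tuple[float, float]) -> int:
    """Count spikes with window_start <= t < window_end (half-open)."""
    t = np.asarray(spike_times, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("spike_times must be sorted")
    lo, hi = window
    return int(np.searchsorted(t, hi, side="left") - np.searchsorted(t, lo, side="left"))


def compute_delta(trial: Trial, windows: Windows = DEFAULT_WINDOWS) -> float:
    """Raw (un-normalized) Δspikes/s of one trial.

    Both counts are converted to frequencies before subtraction:
    response_count / response_width − pre_count / pre_width.
    """
    lo_needed = min(windows.pre[0], windows.response[0])
    hi_needed = max(windows.pre[1], windows.response[1])
    if trial.window[0] > lo_needed or trial.window[1] < hi_needed:
        raise ValueError(
            f"recording window {trial.window} does not cover "
            f"[{lo_needed}, {hi_needed}]"
        )
    pre = count_spikes(trial.spike_times, windows.pre)
    resp = count_spikes(trial.spike_times, windows.response)
    pre_w = windows.pre[1] - windows.pre[0]
    resp_w = windows.response[1] - windows.response[0]
    return resp / resp_w - pre / pre_w


def normalize_to_solvent(delta: float, solvent_delta: float) -> float:
    """Subtract the receptor's mean solvent-control Δspikes/s."""
    return delta - solvent_delta


def aggregate_replicates(deltas: Sequence[float]) -> tuple[float, float, int]:
    """Mean, SEM (sample SD / √n) and n of per-replicate Δspikes/s values."""
    arr = np.asarray(deltas, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot aggregate an empty replicate list")
    if arr.size == 1:
        warnings.warn("single replicate: SEM reported as 0", stacklevel=2)
        return float(arr[0]), 0.0, 1
    return (
        float(arr.mean()),
        float(arr.std(ddof=1) / np.sqrt(arr.size)),
        int(arr.size),
    )


def solvent_means(
    trials: Iterable[Trial], solvent_name: str, windows: Windows = DEFAULT_WINDOWS
) -> dict[str, float]:
    """Per-receptor mean solvent-control Δspikes/s."""
    by_rec: dict[str, list[float]] = {}
    for t in trials:
        if t.stimulus_name == solvent_name:
            by_rec.setdefault(t.receptor_id, []).append(compute_delta(t, windows))
    return {rec: float(np.mean(v)) for rec, v in by_rec.items()}


def _grouped_deltas(
    trials: list[Trial],
    panel: StimulusPanel,
    windows: Windows,
) -> tuple[dict[str, float], dict[tuple[str, str, float], list[float]]]:
    solvent = solvent_means(trials, panel.solvent_name, windows)
    panel_names = set(panel.names)
    groups: dict[tuple[str, str, float], list[float]] = {}
    for t in trials:
        if t.stimulus_name == panel.solvent_name:
            continue
        if t.stimulus_name not in panel_names:
            raise ValueError(f"stimulus {t.stimulus_name!r} is not in the panel")
        if t.receptor_id not in solvent:
            raise ValueError(f"no solvent trials for receptor {t.receptor_id}")
        raw = compute_delta(t, windows)
        key = (t.receptor_id, t.stimulus_name, float(t.dose_nmol))
        groups.setdefault(key, []).append(
            normalize_to_solvent(raw, solvent[t.receptor_id])
        )
    return solvent, groups


def build_response_matrix(
    trials: list[Trial],
    panel: StimulusPanel,
    windows: Windows = DEFAULT_WINDOWS,
    dose_nmol: float | None = None,
) -> ResponseMatrix:
    """Aggregate screen-dose trials into a receptor × hydrocarbon matrix.

    One cell per tested pair at ``dose_nmol`` (default: the panel's screen
    dose); untested pairs stay missing.  Every receptor must have solvent
    trials — their mean is subtracted from each replicate before
    aggregation.
    """
    if dose_nmol is None:
        dose_nmol = panel.default_dose_nmol
    _, groups = _grouped_deltas(trials, panel, windows)
    receptors: list[str] = []
    for t in trials:
        if t.receptor_id not in receptors:
            receptors.append(t.receptor_id)
    records = {}
    for (rec, hc, dose), deltas in groups.items():
        if np.isclose(dose, dose_nmol):
            records[(rec, hc)] = aggregate_replicates(deltas)
    return ResponseMatrix.from_records(records, receptors, panel.names)


def dose_response_table(
    trials: list[Trial],
    panel: StimulusPanel,
    windows: Windows = DEFAULT_WINDOWS,
) -> pd.DataFrame:
    """Long table of solvent-normalized responses at every tested dose.

    Columns: receptor, hydrocarbon, dose_nmol, mean_delta, sem, n.
    """
    _, groups = _grouped_deltas(trials, panel, windows)
    rows = []
    for (rec, hc, dose), deltas in sorted(groups.items()):
        mean, sem, n = aggregate_replicates(deltas)
        rows.append(
            {
                "receptor": rec,
                "hydrocarbon": hc,
                "dose_nmol": dose,
                "mean_delta": mean,
                "sem": sem,
                "n": n,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# optional pathway: spike detection from voltage traces


@dataclass
class DetectionResult:
    """Threshold-crossing detections with amplitudes and the noise estimate."""

    spike_times: np.ndarray
    amplitudes: np.ndarray
    noise_sd: float


def detect_spikes(
    trace: VoltageTrace,
    *,
    threshold_sd: float = 5.0,
    refractory_s: float = 0.002,
) -> DetectionResult:
    """Peak detection above ``threshold_sd`` × noise SD with a dead time.

    Noise SD is estimated robustly from the median absolute deviation of the
    samples.  Detected times are corrected for the spike-waveform peak lag,
    so on a noiseless trace they line up with the true spike times.  A flat
    trace yields an empty result, not an error.
    """
    if trace.sampling_rate_hz < 5000:
        raise ValueError("sampling_rate_hz must be >= 5000")
    x = np.asarray(trace.samples, dtype=float)
    noise_sd = float(np.median(np.abs(x - np.median(x))) / 0.6744897501960817)
    height = threshold_sd * noise_sd if noise_sd > 0 else 0.5 * x.max() if x.max() > 0 else np.inf
    if not np.isfinite(height) or x.size == 0:
        return DetectionResult(np.empty(0), np.empty(0), noise_sd)
    distance = max(1, int(round(refractory_s * trace.sampling_rate_hz)))
    peaks, props = find_peaks(x, height=height, distance=distance)
    # peak of the biphasic waveform lags the spike time by ~0.8 ms
    from .voltage import _biphasic_template

    lag = int(np.argmax(_biphasic_template(trace.sampling_rate_hz)))
    times = trace.t_start + (peaks - lag) / trace.sampling_rate_hz
    return DetectionResult(times, props["peak_heights"], noise_sd)


def _best_1d_split(amps: np.ndarray) -> tuple[float, float, float]:
    """Exact 1-D two-means: returns (split_value, low_mean, high_mean)."""
    s = np.sort(amps)
    n = s.size
    csum = np.cumsum(s)
    total = csum[-1]
    best = (np.inf, 1)
    for k in range(1, n):
        m1, m2 = csum[k - 1] / k, (total - csum[k - 1]) / (n - k)
        cost = ((s[:k] - m1) ** 2).sum() + ((s[k:] - m2) ** 2).sum()
        if cost < best[0]:
            best = (cost, k)
    k = best[1]
    return float((s[k - 1] + s[k]) / 2), float(s[:k].mean()), float(s[k:].mean())


def sort_two_units(
    detections: DetectionResult,
    *,
    n_units: str | int = "auto",
    min_separation_sd: float = 4.0,
) -> np.ndarray:
    """Assign detections to the larger-amplitude A unit.

    Amplitudes are split by exact 1-D two-means; the higher-amplitude
    cluster is unit A.  The split is accepted only when the cluster means
    are at least ``min_separation_sd`` noise SDs apart: with ``n_units=2``
    an unseparable split is an error (degenerate clusters), with
    ``n_units="auto"`` it means a single unit and all detections go to A.
    """
    amps = detections.amplitudes
    if amps.size == 0:
        return np.empty(0)
    if n_units == 1:
        return detections.spike_times
    if amps.size < 2:
        if n_units == 2:
            raise ValueError("cannot split fewer than 2 detections into two units")
        return detections.spike_times
    split, lo_mean, hi_mean = _best_1d_split(amps)
    scale = detections.noise_sd if detections.noise_sd > 0 else np.std(amps)
    separable = scale > 0 and (hi_mean - lo_mean) >= min_separation_sd * scale
    if n_units == 2 and not separable:
        raise ValueError(
            "amplitude clusters are not separable: cannot sort two units"
        )
    if n_units == "auto":
        # a handful of amplitude outliers (overlapping spikes) is not a unit
        min_count = max(2, int(np.ceil(0.03 * amps.size)))
        if min((amps <= split).sum(), (amps > split).sum()) < min_count:
            separable = False
    if not separable:
        return detections.spike_times
    return detections.spike_times[amps > split]
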