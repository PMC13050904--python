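"""Optional extracellular-voltage pathway: render traces from spike times.

A sensillum recording picks up two units: the large-amplitude A neuron (the
one expressing the foreign receptor) and a smaller background B neuron.
``render_voltage`` places a biphasic spike waveform at each ground-truth
spike time, adds an independent Poisson B unit and Gaussian noise, and keeps
the true times so detection and sorting can be benchmarked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import Trial, _rng


@dataclass
class VoltageTrace:
    """Synthetic extracellular trace with per-unit ground-truth spike times."""

    sampling_rate_hz: float
    samples: np.ndarray
    t_start: float
    true_times_a: np.ndarray
    true_times_b: np.ndarray
    amp_a: float
    amp_b: float

    def __post_init__(self) -> None:
        if self.amp_a <= self.amp_b:
            raise ValueError("unit A amplitude must exceed unit B amplitude")

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.samples.size) / self.sampling_rate_hz


def _biphasic_template(sampling_rate: float) -> np.ndarray:
    """Unit-amplitude biphasic extracellular spike, ~3 ms long."""
    t = np.arange(-0.0005, 0.0025, 1.0 / sampling_rate)
    wave = np.exp(-((t - 0.0003) ** 2) / (2 * 0.00025**2)) - 0.6 * np.exp(
        -((t - 0.0011) ** 2) / (2 * 0.00035**2)
    )
    return wave / wave.max()


def render_voltage(
    trial: Trial,
    *,
    unit_a_amp: float = 1.0,
    unit_b_amp: float = 0.45,
    unit_b_rate: float = 3.0,
    noise_sd: float = 0.05,
    sampling_rate_hz: float = 10_000.0,
    seed: int = 0,
) -> VoltageTrace:
    """Render one trial's spike train into an extracellular voltage trace."""
    if sampling_rate_hz < 5000:
        raise ValueError("sampling_rate_hz must be >= 5000")
    if unit_a_amp <= 0 or unit_b_amp <= 0:
        raise ValueError("unit amplitudes must be positive")
    if unit_b_amp >= unit_a_amp:
        raise ValueError("unit B amplitude must be below unit A amplitude")
    rng = _rng(seed, "voltage", trial.receptor_id, trial.stimulus_name, trial.replicate)
    t0, t1 = trial.window
    n = int(round((t1 - t0) * sampling_rate_hz)) + 1
    trace = np.zeros(n)
    if unit_b_rate < 0:
        raise ValueError("unit_b_rate must be non-negative")
    b_count = rng.poisson(unit_b_rate * (t1 - t0))
    times_b = np.sort(rng.uniform(t0, t1, size=b_count))

    template = _biphasic_template(sampling_rate_hz)
    for times, amp in ((trial.spike_times, unit_a_amp), (times_b, unit_b_amp)):
        for t in times:
            i = int(round((t - t0) * sampling_rate_hz))
            j = min(i + template.size, n)
            if i < n:
                trace[i:j] += amp * template[: j - i]
    if noise_sd > 0:
        trace += rng.normal(0.0, noise_sd, size=n)
    return VoltageTrace(
        sampling_rate_hz=sampling_rate_hz,
        samples=trace,
        t_start=t0,
        true_times_a=np.asarray(trial.spike_times, dtype=float),
        true_times_b=times_b,
        amp_a=unit_a_amp,
        amp_b=unit_b_amp,
    )
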