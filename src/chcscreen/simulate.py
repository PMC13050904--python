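"""Synthetic single-sensillum recording (SSR) experiments with known truth.

Emulates the statistical structure of a heterologous receptor screen: each
trial is one extracellular recording of the host neuron while a hydrocarbon
cartridge is puffed over the antenna.  Spikes follow a piecewise-homogeneous
Poisson process — spontaneous rate before/after the stimulus epoch, evoked
rate inside it — with a 200 ms delivery delay (the travel time down the air
tube) and a non-paralyzable refractory period.

Receptors are drawn from four tuning archetypes:

* ``narrow``   — one strong ligand (Δ 60–110 spikes/s), everything else flat;
* ``broad``    — Gaussian tuning over backbone chain length, at least seven
  hydrocarbons above the 30 Δspikes/s responder threshold by construction;
* ``inhibited``— weak suppression (Δ −15 … −5 spikes/s) across the panel,
  from an elevated spontaneous rate so the suppression is observable;
* ``nonresponder`` — evoked rate equals the spontaneous rate everywhere.

Dose dependence of every responsive pair follows a three-parameter Hill
curve anchored so that the stored screen-dose response is exact.  All
randomness descends from one integer seed through a hierarchical splitting
scheme (experiment → receptor → stimulus → replicate), so adding a receptor
or stimulus never perturbs the spike times of another.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import StimulusPanel

ARCHETYPES = ("narrow", "broad", "inhibited", "nonresponder")

#: Default archetype mix, mirroring the screened repertoire's outcome
#: (1 narrow, 6 broad, 4 inhibited, 12 unresponsive of 23 receptors).
DEFAULT_MIX: dict[str, float] = {
    "narrow": 1 / 23,
    "broad": 6 / 23,
    "inhibited": 4 / 23,
    "nonresponder": 12 / 23,
}

#: Host-neuron spontaneous rate, spikes/s (the 30 Δspikes/s responder
#: threshold is six times this rate).
DEFAULT_BASELINE_RATE = 5.0

#: Spontaneous rate for inhibited receptors, spikes/s.  Suppression down to
#: −15 Δspikes/s is only observable when the spontaneous rate exceeds it;
#: receptor expression can elevate spontaneous activity in the host neuron.
INHIBITED_BASELINE_RATE = 20.0

DEFAULT_DELAY_S = 0.2
DEFAULT_STIM_DURATION_S = 1.0
DEFAULT_WINDOW = (-1.0, 1.5)
DEFAULT_REFRACTORY_S = 0.002
DEFAULT_N_REPS = 6
#: Dose series for dose–response assays, nmol (screen dose is 20 nmol).
DEFAULT_DOSES = (0.2, 2.0, 20.0, 200.0)

_SUBFAMILY_LETTERS = tuple("ABCDEFGHIJKLMNOP")


def _stable_u32(label: str) -> int:
    """Stable 32-bit hash of a label (independent of PYTHONHASHSEED)."""
    return int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "big")


def _rng(seed: int, *labels: object) -> np.random.Generator:
    """Generator for one node of the hierarchical seed tree."""
    entropy = [int(seed)] + [
        _stable_u32(x) if isinstance(x, str) else int(x) for x in labels
    ]
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(entropy)))


# ---------------------------------------------------------------------------
# trial container


@dataclass
class Trial:
    """One recording: sorted spike times (s, stimulus-onset command at 0)."""

    receptor_id: str
    stimulus_name: str
    dose_nmol: float
    replicate: int
    spike_times: np.ndarray
    window: tuple[float, float] = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times, dtype=float)
        if np.any(np.diff(t) < 0):
            raise ValueError("spike_times must be sorted")
        lo, hi = self.window
        if t.size and (t[0] < lo or t[-1] > hi):
            raise ValueError("spike_times outside recording window")
        self.spike_times = t


# ---------------------------------------------------------------------------
# spike-train generation


def generate_spike_train(
    baseline_rate: float,
    evoked_rate: float,
    *,
    delay_s: float = DEFAULT_DELAY_S,
    stim_duration_s: float = DEFAULT_STIM_DURATION_S,
    window: tuple[float, float] = DEFAULT_WINDOW,
    refractory_s: float = DEFAULT_REFRACTORY_S,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate one spike train as a piecewise-homogeneous Poisson process.

    The rate is ``baseline_rate`` outside ``[delay_s, delay_s +
    stim_duration_s]`` and ``evoked_rate`` inside.  A non-paralyzable dead
    time of ``refractory_s`` is enforced by thinning; the generating rate is
    dead-time-compensated (λ' = λ / (1 − λ·τ)) so the realized rate matches
    the nominal rate rather than undershooting it.
    """
    if baseline_rate < 0 or evoked_rate < 0:
        raise ValueError("rates must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else _rng(int(seed), "train")
    t0, t1 = window
    stim_lo = max(t0, delay_s)
    stim_hi = min(t1, delay_s + stim_duration_s)
    segments = []
    if stim_lo > t0:
        segments.append((t0, stim_lo, baseline_rate))
    if stim_hi > stim_lo:
        segments.append((stim_lo, stim_hi, evoked_rate))
    if t1 > stim_hi:
        segments.append((max(stim_hi, t0), t1, baseline_rate))

    times = []
    for lo, hi, rate in segments:
        if rate <= 0:
            continue
        if rate * refractory_s >= 1.0:
            raise ValueError(
                f"rate {rate} spikes/s unreachable with {refractory_s}s refractory"
            )
        lam = rate / (1.0 - rate * refractory_s)
        count = rng.poisson(lam * (hi - lo))
        times.append(rng.uniform(lo, hi, size=count))
    if not times:
        return np.empty(0)
    t = np.sort(np.concatenate(times))

    if refractory_s > 0 and t.size > 1:
        keep = np.empty(t.size, dtype=bool)
        keep[0] = True
        last = t[0]
        for i in range(1, t.size):
            if t[i] - last >= refractory_s:
                keep[i] = True
                last = t[i]
            else:
                keep[i] = False
        t = t[keep]
    return t


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class ReceptorTruth:
    """Latent tuning of one synthetic receptor."""

    receptor_id: str
    archetype: str
    baseline_rate: float
    worker_fpkm: float
    subfamily: str
    #: true screen-dose response per hydrocarbon, Δspikes/s
    true_delta: dict[str, float]
    #: per responsive hydrocarbon: (max_delta, ec50_nmol, hill_slope)
    dose_params: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def delta_at_dose(self, hc_name: str, dose_nmol: float) -> float:
        """True Δspikes/s at an arbitrary dose (Hill-scaled)."""
        if hc_name not in self.dose_params:
            return 0.0
        m, ec50, h = self.dose_params[hc_name]
        return m * dose_nmol**h / (ec50**h + dose_nmol**h)

    def evoked_rate(self, stimulus: str, dose_nmol: float, solvent: str) -> float:
        if stimulus == solvent:
            return self.baseline_rate
        return max(0.0, self.baseline_rate + self.delta_at_dose(stimulus, dose_nmol))


@dataclass
class GroundTruth:
    """Latent quantities of a synthetic experiment, keyed by receptor."""

    receptors: dict[str, ReceptorTruth]
    screen_dose_nmol: float

    @property
    def receptor_ids(self) -> list[str]:
        return list(self.receptors)

    def archetype_of(self) -> dict[str, str]:
        return {r: t.archetype for r, t in self.receptors.items()}

    def expression_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "receptor": self.receptor_ids,
                "worker_fpkm": [t.worker_fpkm for t in self.receptors.values()],
            }
        )

    def subfamily_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "receptor": self.receptor_ids,
                "subfamily": [t.subfamily for t in self.receptors.values()],
            }
        )

    def to_frame(self) -> pd.DataFrame:
        """Long ground-truth table (one row per receptor × hydrocarbon)."""
        rows = []
        for t in self.receptors.values():
            for hc, d in t.true_delta.items():
                m, e, h = t.dose_params.get(hc, (0.0, np.nan, np.nan))
                rows.append(
                    {
                        "receptor": t.receptor_id,
                        "archetype": t.archetype,
                        "subfamily": t.subfamily,
                        "baseline_rate": t.baseline_rate,
                        "worker_fpkm": t.worker_fpkm,
                        "hydrocarbon": hc,
                        "true_delta": d,
                        "max_delta": m,
                        "ec50_nmol": e,
                        "hill_slope": h,
                    }
                )
        return pd.DataFrame(rows)


def _hill_anchor(
    screen_delta: float, screen_dose: float, rng: np.random.Generator
) -> tuple[float, float, float]:
    """Hill parameters whose curve passes exactly through the screen dose.

    The saturation factor s = max_delta / screen_delta is drawn from
    U[2, 3] and the slope h from U[2, 3]; ec50 = screen_dose·(s−1)^(1/h)
    then guarantees Δ(screen_dose) == screen_delta exactly.  The resulting
    ec50 lies in [20, 28.3] nmol (≥ the screen dose), so the response at
    2 nmol is ≲2% of the screen response — nothing exceeds 10 Δspikes/s at
    or below 2 nmol — while saturated rates stay physiological.
    """
    s = rng.uniform(2.0, 3.0)
    h = rng.uniform(2.0, 3.0)
    ec50 = screen_dose * (s - 1.0) ** (1.0 / h)
    return s * screen_delta, ec50, h


def assign_archetypes(
    receptor_count: int,
    panel: StimulusPanel,
    mix: Mapping[str, float] | None = None,
    seed: int = 0,
    *,
    baseline_rate: float = DEFAULT_BASELINE_RATE,
    inhibited_baseline_rate: float = INHIBITED_BASELINE_RATE,
    broad_min: int = 7,
    threshold: float = 30.0,
) -> GroundTruth:
    """Draw ground truth for ``receptor_count`` synthetic receptors.

    Each receptor's archetype and tuning parameters are drawn from a stream
    keyed by (seed, receptor id), so truths are stable under addition or
    removal of other receptors.  Broad receptors are redrawn until at least
    ``broad_min`` hydrocarbons sit strictly above ``threshold``, which the
    Gaussian chain-length tuning guarantees is reachable.
    """
    if len(panel) == 0:
        raise ValueError("panel must contain at least one hydrocarbon")
    mix = dict(DEFAULT_MIX if mix is None else mix)
    unknown = set(mix) - set(ARCHETYPES)
    if unknown:
        raise ValueError(f"unknown archetypes in mix: {sorted(unknown)}")
    probs = np.array([mix.get(a, 0.0) for a in ARCHETYPES], dtype=float)
    if probs.sum() <= 0 or not np.isclose(probs.sum(), 1.0, atol=1e-6):
        raise ValueError("mix proportions must sum to 1")
    probs = probs / probs.sum()

    chains = panel.chain_lengths
    hc_names = panel.names
    screen_dose = panel.default_dose_nmol
    receptors: dict[str, ReceptorTruth] = {}
    width = len(str(receptor_count))
    for i in range(receptor_count):
        rid = f"R{i + 1:0{width}d}"
        rng = _rng(seed, "truth", rid)
        archetype = str(rng.choice(ARCHETYPES, p=probs))
        base = inhibited_baseline_rate if archetype == "inhibited" else baseline_rate

        if archetype == "narrow":
            peak_hc = str(rng.choice(hc_names))
            delta = {hc: float(rng.normal(0.0, 1.0)) for hc in hc_names}
            delta[peak_hc] = float(rng.uniform(60.0, 110.0))
        elif archetype == "broad":
            for _ in range(200):
                center = rng.uniform(28.0, 35.0)
                sigma = rng.uniform(2.0, 4.0)
                peak = rng.uniform(30.0, 60.0)
                delta = {
                    hc: float(
                        peak * np.exp(-((chains[hc] - center) ** 2) / (2 * sigma**2))
                    )
                    for hc in hc_names
                }
                if sum(d > threshold for d in delta.values()) >= broad_min:
                    break
            else:  # pragma: no cover - panel always has enough long chains
                raise RuntimeError("could not construct a broad tuning profile")
        elif archetype == "inhibited":
            delta = {hc: float(rng.uniform(-15.0, -5.0)) for hc in hc_names}
        else:  # nonresponder: evoked rate equals baseline everywhere
            delta = {hc: 0.0 for hc in hc_names}

        dose_params = {
            hc: _hill_anchor(d, screen_dose, rng)
            for hc, d in delta.items()
            if d != 0.0
        }
        receptors[rid] = ReceptorTruth(
            receptor_id=rid,
            archetype=archetype,
            baseline_rate=base,
            worker_fpkm=float(rng.lognormal(mean=3.0, sigma=1.0)),
            subfamily=str(rng.choice(_SUBFAMILY_LETTERS)),
            true_delta=delta,
            dose_params=dose_params,
        )
    return GroundTruth(receptors=receptors, screen_dose_nmol=screen_dose)


# ---------------------------------------------------------------------------
# experiment generation


def generate_experiment(
    ground_truth: GroundTruth,
    panel: StimulusPanel,
    n_reps: int = DEFAULT_N_REPS,
    doses: Sequence[float] | None = None,
    seed: int = 0,
    *,
    delay_s: float = DEFAULT_DELAY_S,
    stim_duration_s: float = DEFAULT_STIM_DURATION_S,
    window: tuple[float, float] = DEFAULT_WINDOW,
    refractory_s: float = DEFAULT_REFRACTORY_S,
    stimuli: Sequence[str] | None = None,
) -> list[Trial]:
    """Simulate the full trial grid: receptor × hydrocarbon × dose ×
    replicate, plus ``n_reps`` solvent-control trials per receptor.

    ``stimuli`` restricts the hydrocarbons tested (default: whole panel),
    e.g. for a dose–response assay of each receptor's best ligand.  Every
    trial's random stream is keyed by (seed, receptor, stimulus, dose,
    replicate); the same seed reproduces identical spike times.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if doses is None:
        doses = (ground_truth.screen_dose_nmol,)
    hc_list = panel.names if stimuli is None else list(stimuli)
    unknown = set(hc_list) - set(panel.names)
    if unknown:
        raise ValueError(f"stimuli not in panel: {sorted(unknown)}")
    trials: list[Trial] = []

    def _one(truth: ReceptorTruth, stimulus: str, dose: float, rep: int) -> Trial:
        rng = _rng(seed, truth.receptor_id, stimulus, int(round(dose * 1000)), rep)
        times = generate_spike_train(
            truth.baseline_rate,
            truth.evoked_rate(stimulus, dose, panel.solvent_name),
            delay_s=delay_s,
            stim_duration_s=stim_duration_s,
            window=window,
            refractory_s=refractory_s,
            seed=rng,
        )
        return Trial(truth.receptor_id, stimulus, dose, rep, times, window)

    for truth in ground_truth.receptors.values():
        for rep in range(1, n_reps + 1):
            trials.append(
                _one(truth, panel.solvent_name, ground_truth.screen_dose_nmol, rep)
            )
        for dose in doses:
            for hc in hc_list:
                for rep in range(1, n_reps + 1):
                    trials.append(_one(truth, hc, float(dose), rep))
    return trials


# ---------------------------------------------------------------------------
# trial table I/O (long CSV; spike times semicolon-joined seconds)


def write_trials(trials: Iterable[Trial], path: str | Path) -> None:
    rows = [
        {
            "receptor": t.receptor_id,
            "stimulus": t.stimulus_name,
            "dose_nmol": t.dose_nmol,
            "replicate": t.replicate,
            "t_start": t.window[0],
            "t_end": t.window[1],
            "spike_times": ";".join(format(x, ".6f") for x in t.spike_times),
        }
        for t in trials
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trials(path: str | Path) -> list[Trial]:
    df = pd.read_csv(path, keep_default_na=False)
    trials = []
    for _, row in df.iterrows():
        raw = str(row["spike_times"])
        times = np.array([float(x) for x in raw.split(";") if x], dtype=float)
        trials.append(
            Trial(
                receptor_id=str(row["receptor"]),
                stimulus_name=str(row["stimulus"]),
                dose_nmol=float(row["dose_nmol"]),
                replicate=int(row["replicate"]),
                spike_times=times,
                window=(float(row["t_start"]), float(row["t_end"])),
            )
        )
    return trials
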