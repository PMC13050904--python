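# Methods

This note documents the models, conventions and numerical choices behind
`chcscreen`, in the order the pipeline runs them.

## Response quantification

**Windows.** Spike counts use half-open windows [a, b): a 1 s pre-stimulus
window [−1, 0) and a 200 ms response window [0.2, 0.4), both relative to
the stimulus command at t = 0.  The response window starts 200 ms after the
command because that is the delivery delay of the odor down the air tube;
half-open intervals partition time without double counting.

**Δspikes/s.** Both counts are converted to frequencies before
subtraction — response count × 5 minus pre count × 1 — so the statistic has
coherent units (spikes/s) on both terms.  Scaling the 200 ms count to a
per-second rate is the standard SSR convention and the one consistent with
quarter-integer response values (e.g. 87.5 = 23.5 × 5 − 30) at n = 6.

**Solvent normalization is subtractive**, not divisive: the mean Δspikes/s
of the receptor's own pentane-control trials is subtracted from every
replicate, keeping the statistic in Δspikes/s.  The solvent mean is
per-receptor (per fly line), never a global constant.

**Aggregation.** Replicates aggregate to the arithmetic mean and
SEM = sample SD (n − 1 denominator) / √n.  A single replicate reports
SEM = 0 with a warning.  Untested receptor–hydrocarbon pairs are missing
(NaN in memory, empty field on disk) and are excluded from every
downstream sum and denominator; they are never coerced to zero.

## Tuning classification

A pair *responds* when its mean Δ is strictly above 30 spikes/s — six
times the host neuron's 5 spikes/s spontaneous rate ("above" is read as a
strict inequality throughout, so 30.0 is below).  Classes over tested
cells only:

| class        | rule                                                        |
|--------------|-------------------------------------------------------------|
| broad        | ≥ 7 hydrocarbons above threshold                             |
| narrow       | exactly 1 above                                              |
| intermediate | 2–6 above                                                    |
| inhibited    | 0 above and ≥ 5 pairs at ≤ −10 Δspikes/s                     |
| nonresponder | 0 above, fewer than 5 inhibitory pairs                       |

The inhibited rule's pair count is a documented stand-in for "several
pairs" (no canonical count exists); both it and every threshold are
keyword arguments.  Argmax ("most efficacious ligand") and rankings break
ties alphabetically by hydrocarbon name.

## Dose–response fitting

Δ(d) = Δmax · dʰ / (EC50ʰ + dʰ), fit by bounded least squares
(`scipy.optimize.curve_fit`): h ∈ [0.3, 6], EC50 ∈ [min dose/10, max
dose·10], Δmax ∈ [0, 10·max|Δ|]; the initial point is Δmax = max response,
EC50 = geometric mean of the doses, h = 1.5.  Fewer than 3 distinct
positive doses is an error; an all-zero series or an optimizer failure is
reported via `converged=False` rather than raised.  With only 4 doses the
slope is weakly identified (fits may sit at the h bound); EC50 and Δmax
are the reliable parameters, with median EC50 error ~4% at noise SD 3.
`check_low_dose_silence` verifies that no response exceeds 10 Δspikes/s at
doses ≤ 2 nmol and lists violators.

## Synthetic SSR generator

The generator emulates the screen's statistical structure so every stage
is testable against known ground truth.

**Spike trains** are piecewise-homogeneous Poisson: spontaneous rate
outside the stimulus epoch [0.2, 1.2] s, evoked rate inside, over a
recording window of [−1.0, 1.5] s.  A 2 ms non-paralyzable refractory
period is enforced by deletion-thinning.  Because a dead-time process
realizes rate λ′/(1 + λ′τ), the generating rate is compensated as
λ′ = λ/(1 − λτ) so the *realized* rate equals the nominal one; without
this the estimator would undershoot by ~20% at 100 spikes/s.  The
compensation caps usable rates at 1/τ = 500 spikes/s, far above anything
generated.

**Archetypes** (defaults mirror a 23-receptor screen outcome: narrow 1/23,
broad 6/23, inhibited 4/23, nonresponder 12/23):

* *narrow* — one uniformly chosen hydrocarbon at Δ ~ U[60, 110] spikes/s,
  all others N(0, 1);
* *broad* — Gaussian tuning over backbone chain length (center U[28, 35],
  width U[2, 4] carbons, peak U[30, 60]), redrawn until ≥ 7 hydrocarbons
  sit strictly above 30;
* *inhibited* — Δ ~ U[−15, −5] on every hydrocarbon, from an elevated
  spontaneous rate of 20 spikes/s: suppression below −5 is unobservable
  from a 5 spikes/s baseline since firing cannot go negative, and
  receptor expression does elevate spontaneous activity in host neurons;
* *nonresponder* — evoked rate equals the spontaneous rate everywhere.

All other receptors use the default 5 spikes/s spontaneous rate (the 30
Δspikes/s threshold ÷ 6).  Worker-antenna FPKM is drawn lognormal
(median ≈ 20) and a single-letter subfamily label uniformly from A–P.

**Dose curves.** Every responsive pair gets Hill parameters anchored to
pass exactly through its screen-dose (20 nmol) response: saturation factor
s = Δmax/Δscreen ~ U[2, 3] and h ~ U[2, 3], giving
EC50 = 20·(s−1)^(1/h) ∈ [20, 28.3] nmol.  This keeps saturated firing
rates physiological and makes the low-dose silence property (≤ 2% of the
screen response at 2 nmol, hence nothing above 10 Δspikes/s) hold by
construction with margin against estimator noise.

**Randomness** descends from one integer seed through a hierarchical
stream (experiment → receptor → stimulus → dose → replicate), with
per-receptor streams keyed by a stable hash of the receptor id: the same
seed reproduces byte-identical experiments, and adding a receptor or
stimulus never perturbs another's draws.

**What the generator does not emulate:** sensitization/desensitization
from repeated stimulation (screen-vs-dose-assay response drift), recording
drift and artifacts, inter-animal variability beyond Poisson noise, and
correlated tuning within subfamilies.  Passing tests therefore validate
the estimator and classification machinery under the stated noise model,
not those biological effects.

## Voltage pathway (optional)

`render_voltage` places a ~3 ms biphasic template at each ground-truth
spike time (unit A), adds an independent Poisson background unit B of
smaller amplitude and Gaussian noise.  `detect_spikes` finds peaks above
`threshold_sd` (default 5) × a median-absolute-deviation noise estimate
with a refractory dead time, correcting detected times for the template's
peak lag.  `sort_two_units` splits detection amplitudes by exact 1-D
two-means; the split is accepted only when the cluster means are ≥ 4 noise
SDs apart *and* (in auto mode) the minor cluster holds ≥ 3% of detections
— a handful of amplitude outliers from overlapping spikes is not a unit.
Requesting two units from unseparable amplitudes is an error; in auto mode
it means one unit and all detections are assigned to A.

## Calibration of the simulation benchmarks

The cellwise check of the quantified matrix against generated truth uses
3.5·SEM and a 95% pass fraction: with n = 6 the SEM estimate has 5 df
(~97% nominal coverage at 3 SEM) and the shared solvent-mean subtraction
correlates cells within a receptor, so measured 3-SEM coverage is ~94%.
The train-level estimator benchmark (mean of 1000 trains within 3 SE of
evoked − baseline) is unaffected and asserted as stated.  Problem sizes —
23 receptors × 39 hydrocarbons × 6 replicates per screen, 20 screens for
archetype recovery, 1000 trains, 100 Hill repeats — match the study design
they emulate and complete in well under a minute.

## File conventions

Long-format CSV is canonical (`receptor, hydrocarbon, mean_delta[, sem,
n]`, one row per grid cell, empty field = missing, "NA" accepted on read);
wide format carries means only.  Headers are pure ASCII ("delta" spelled
out).  The packaged panel fixture is a synthetic reconstruction (its
header says so): membership and the 17 cuticle-presence flags were
transcribed from figure labelling and the cuticular-extract literature
rather than a machine-readable source.  The rename map contains exactly
the 20 printed renames plus one swapped pair and is applied atomically
over the whole vocabulary — some new names reuse old names, so sequential
application would corrupt them; idempotence consequently holds only for
entries whose target is not itself another entry's source.
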