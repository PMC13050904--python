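import numpy as np
import pytest

from chcscreen.simulate import (
    DEFAULT_BASELINE_RATE,
    GroundTruth,
    Trial,
    assign_archetypes,
    generate_experiment,
    generate_spike_train,
    read_trials,
    write_trials,
)
from chcscreen.spikes import DEFAULT_WINDOWS, compute_delta


class TestSpikeTrain:
    def test_zero_rates_give_empty_train(self):
        assert generate_spike_train(0, 0, seed=1).size == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            generate_spike_train(-1, 5, seed=1)

    def test_deterministic_for_fixed_seed(self):
        a = generate_spike_train(5, 105, seed=42)
        b = generate_spike_train(5, 105, seed=42)
        assert np.array_equal(a, b)

    def test_refractory_period_enforced(self):
        t = generate_spike_train(5, 300, seed=0)
        assert np.all(np.diff(t) >= 0.002 - 1e-12)

    def test_spikes_within_window(self):
        t = generate_spike_train(50, 50, window=(-1.0, 1.5), seed=3)
        assert t.min() >= -1.0 and t.max() <= 1.5

    def test_flat_rate_matches_poisson_mean(self):
        # rate 5 everywhere over a 2.5 s window: expected count 12.5
        counts = [generate_spike_train(5, 5, seed=s).size for s in range(1000)]
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 12.5) < 3 * se

    def test_delta_estimator_recovers_evoked_minus_baseline(self):
        # baseline 5, evoked 105: the windowed estimator should average ~100
        deltas = [
            compute_delta(
                Trial("r", "x", 20.0, 1, generate_spike_train(5, 105, seed=s)),
                DEFAULT_WINDOWS,
            )
            for s in range(1000)
        ]
        se = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert abs(np.mean(deltas) - 100.0) < 3 * se


class TestArchetypes:
    def test_all_nonresponders_have_flat_truth(self, panel):
        gt = assign_archetypes(10, panel, {"nonresponder": 1.0}, seed=1)
        for truth in gt.receptors.values():
            assert truth.archetype == "nonresponder"
            assert all(d == 0.0 for d in truth.true_delta.values())
            assert truth.baseline_rate == DEFAULT_BASELINE_RATE

    def test_narrow_receptors_have_exactly_one_strong_ligand(self, panel):
        gt = assign_archetypes(100, panel, {"narrow": 1.0}, seed=2)
        for truth in gt.receptors.values():
            above = [hc for hc, d in truth.true_delta.items() if d > 30]
            assert len(above) == 1
            assert 60 <= truth.true_delta[above[0]] <= 110

    def test_broad_receptors_have_seven_or_more_above_threshold(self, panel):
        gt = assign_archetypes(50, panel, {"broad": 1.0}, seed=3)
        for truth in gt.receptors.values():
            assert sum(d > 30 for d in truth.true_delta.values()) >= 7

    def test_inhibited_receptors_are_suppressed_everywhere(self, panel):
        gt = assign_archetypes(20, panel, {"inhibited": 1.0}, seed=4)
        for truth in gt.receptors.values():
            assert all(-15 <= d <= -5 for d in truth.true_delta.values())
            # suppression must be observable from the spontaneous rate
            assert truth.baseline_rate >= 15

    def test_default_baseline_is_one_sixth_of_threshold(self, panel):
        gt = assign_archetypes(5, panel, {"broad": 1.0}, seed=5)
        assert all(t.baseline_rate == 30.0 / 6.0 for t in gt.receptors.values())

    def test_mix_must_sum_to_one(self, panel):
        with pytest.raises(ValueError, match="sum to 1"):
            assign_archetypes(5, panel, {"narrow": 0.5}, seed=1)

    def test_truth_stable_under_receptor_addition(self, panel):
        a = assign_archetypes(5, panel, seed=7)
        b = assign_archetypes(6, panel, seed=7)
        for rid, truth in a.receptors.items():
            assert b.receptors[rid].true_delta == truth.true_delta

    def test_hill_curves_pass_through_screen_dose(self, panel):
        gt = assign_archetypes(10, panel, seed=8)
        for truth in gt.receptors.values():
            for hc, d in truth.true_delta.items():
                if d != 0.0:
                    assert truth.delta_at_dose(hc, 20.0) == pytest.approx(d)
                    _, ec50, _ = truth.dose_params[hc]
                    assert ec50 >= 20.0


class TestExperiment:
    def test_screen_grid_has_897_pairs(self, panel):
        gt = assign_archetypes(23, panel, seed=1)
        trials = generate_experiment(gt, panel, seed=1)
        pairs = {
            (t.receptor_id, t.stimulus_name)
            for t in trials
            if t.stimulus_name != panel.solvent_name
        }
        assert len(pairs) == 23 * 39 == 897

    def test_every_pair_has_n_reps_trials(self, panel):
        gt = assign_archetypes(3, panel, seed=2)
        trials = generate_experiment(gt, panel, n_reps=6, seed=2)
        from collections import Counter

        counts = Counter(
            (t.receptor_id, t.stimulus_name, t.dose_nmol) for t in trials
        )
        assert set(counts.values()) == {6}

    def test_solvent_trials_present_per_receptor(self, panel):
        gt = assign_archetypes(3, panel, seed=2)
        trials = generate_experiment(gt, panel, seed=2)
        solvent = [t for t in trials if t.stimulus_name == panel.solvent_name]
        assert {t.receptor_id for t in solvent} == set(gt.receptor_ids)

    def test_same_seed_reproduces_spike_times_exactly(self, panel):
        gt = assign_archetypes(2, panel, seed=9)
        a = generate_experiment(gt, panel, seed=9)
        b = generate_experiment(gt, panel, seed=9)
        assert all(np.array_equal(x.spike_times, y.spike_times) for x, y in zip(a, b))

    def test_stimulus_subset_restricts_grid(self, panel):
        gt = assign_archetypes(2, panel, seed=1)
        trials = generate_experiment(gt, panel, seed=1, stimuli=["C28"])
        stims = {t.stimulus_name for t in trials}
        assert stims == {"C28", panel.solvent_name}

    def test_unknown_stimulus_rejected(self, panel):
        gt = assign_archetypes(1, panel, seed=1)
        with pytest.raises(ValueError, match="not in panel"):
            generate_experiment(gt, panel, seed=1, stimuli=["C99"])

    def test_trial_table_roundtrip(self, panel, tmp_path):
        gt = assign_archetypes(2, panel, seed=3)
        trials = generate_experiment(gt, panel, n_reps=2, seed=3)
        path = tmp_path / "trials.csv"
        write_trials(trials, path)
        back = read_trials(path)
        assert len(back) == len(trials)
        for x, y in zip(trials, back):
            assert x.receptor_id == y.receptor_id
            assert x.stimulus_name == y.stimulus_name
            assert np.allclose(x.spike_times, y.spike_times, atol=1e-6)


def test_trial_rejects_unsorted_times():
    with pytest.raises(ValueError, match="sorted"):
        Trial("R1", "C28", 20.0, 1, np.array([0.5, 0.1]))
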