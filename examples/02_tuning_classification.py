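"""Classify receptor tuning from a quantified screen.

Runs the full 23-receptor screen and applies the responder threshold
(strictly above 30 Δspikes/s, six times the host neuron's spontaneous
rate): broad = 7+ hydrocarbons above threshold, narrow = exactly 1,
inhibited = no excitatory hit but 5+ pairs at or below −10 Δspikes/s.
"""

from collections import Counter

import chcscreen as c

panel = c.default_panel()
truth = c.assign_archetypes(23, panel, seed=1)
trials = c.generate_experiment(truth, panel, seed=1)
matrix = c.build_response_matrix(trials, panel)

profiles = c.profile_all(matrix)
n_resp = c.count_responding_receptors(matrix)
print(f"{n_resp} of {len(profiles)} receptors respond above 30 Delta-spikes/s")
print("classes:", dict(Counter(p.tuning_class for p in profiles.values())))
print()
truth_arch = truth.archetype_of()
hits = sum(profiles[r].tuning_class == truth_arch[r] for r in profiles)
print(f"classification recovers the generated archetype for {hits}/{len(profiles)}")
for rid, p in profiles.items():
    if p.tuning_class != truth_arch[rid]:
        print(f"  miss: {rid} generated {truth_arch[rid]}, classified {p.tuning_class}"
              f" (n_above={p.n_above}, n_inhibitory={p.n_inhibitory_pairs})")
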