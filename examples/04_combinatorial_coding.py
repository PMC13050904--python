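"""Combinatorial-coding summaries: subfamily sums, per-HC means, receptivity.

Aggregates a quantified screen across receptors: summed responses per
subfamily, the mean response each hydrocarbon evokes across the receptors
tested on it, and the expression-weighted "receptivity" (Δspikes/s x
worker-antenna FPKM) with its own per-HC ranking.
"""

import chcscreen as c
from chcscreen.coding import receptivity, subfamily_sum
from chcscreen.expression import ExpressionTable, SubfamilyMap

panel = c.default_panel()
truth = c.assign_archetypes(23, panel, seed=1)
trials = c.generate_experiment(truth, panel, seed=1)
matrix = c.build_response_matrix(trials, panel)

subs = SubfamilyMap(dict(zip(truth.receptor_ids,
                             (t.subfamily for t in truth.receptors.values()))))
expr = ExpressionTable.from_mapping(
    {r: t.worker_fpkm for r, t in truth.receptors.items()}
)

grid = subfamily_sum(matrix, subs)
print(f"subfamily grid: {grid.shape[0]} subfamilies x {grid.shape[1]} hydrocarbons")

summaries = c.hc_summaries(matrix, expr)
print("\ntop 6 hydrocarbons by mean response (Delta-spikes/s per tested receptor):")
print(c.rank_hcs(summaries, by="response", k=6).to_string(index=False))
print("\ntop 6 by mean receptivity (response x worker FPKM, arbitrary units):")
print(c.rank_hcs(summaries, by="receptivity", k=6).to_string(index=False))
print("\nexcluded from receptivity (no worker FPKM):",
      list(receptivity(matrix, expr).excluded) or "none")
print("\nExpression weighting re-orders the ranking toward ligands of highly")
print("expressed receptors - the antenna-level view of the same screen.")
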