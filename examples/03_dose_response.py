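"""Dose-response assay of each responder's most efficacious ligand.

For every receptor with a response above 30 Δspikes/s in the screen, runs a
4-dose series (0.2, 2, 20, 200 nmol) of its best ligand, fits a Hill curve,
and checks the low-dose silence property (no response above 10 Δspikes/s at
or below 2 nmol).
"""

import chcscreen as c
from chcscreen.simulate import GroundTruth

panel = c.default_panel()
truth = c.assign_archetypes(23, panel, seed=1)
trials = c.generate_experiment(truth, panel, seed=1)
matrix = c.build_response_matrix(trials, panel)
profiles = c.profile_all(matrix)

dose_trials = []
for rid, p in profiles.items():
    if p.n_above == 0:
        continue
    sub = GroundTruth({rid: truth.receptors[rid]}, truth.screen_dose_nmol)
    dose_trials += c.generate_experiment(
        sub, panel, doses=(0.2, 2.0, 20.0, 200.0), seed=1,
        stimuli=[p.max_response[0]],
    )
table = c.dose_response_table(dose_trials, panel)

print("receptor  ligand        EC50 (nmol)  true EC50   max Delta  hill")
for (rid, hc), grp in table.groupby(["receptor", "hydrocarbon"]):
    fit = c.fit_dose_response(grp["dose_nmol"], grp["mean_delta"], rid, hc)
    _, true_ec50, _ = truth.receptors[rid].dose_params[hc]
    print(
        f"{rid:<9} {hc:<12} {fit.ec50_nmol:>10.1f} {true_ec50:>10.1f}"
        f" {fit.max_delta:>10.1f} {fit.hill_slope:>5.2f}"
    )

silent, offenders = c.check_low_dose_silence(table)
low_max = table[table.dose_nmol <= 2.0]["mean_delta"].max()
print()
print(f"low-dose silence (nothing above 10 Delta-spikes/s at <=2 nmol): {silent}")
print(f"largest response at <=2 nmol: {low_max:.1f} Delta-spikes/s")
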