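"""Closed-loop self-consistency experiment over a panel of virtual drugs.

Runs the full fit -> release -> predict pipeline for 10 seeded virtual drugs
with 15% CV observation noise and summarizes the predicted-vs-true fold
errors against the 2-fold and 1.25-fold acceptance boundaries.
"""

from biphasepk import recovery_experiment

rep = recovery_experiment(n_drugs=10, seed=42, cv=0.15)
cols = ["shape", "n_comp_true", "n_comp_fit", "fe_auc", "fe_cmax"]
print(rep.records[cols].round(3).to_string(index=False))
print(f"\nfraction within 2-fold   : {rep.fraction_within_2fold:.2f}")
print(f"fraction within 1.25-fold: {rep.fraction_within_1p25fold:.2f}")
print(f"worst ratio              : {rep.max_ratio_pct:.1f} % (boundary 200%)")
print("\nEvery AUC/Cmax prediction within 50-200% of truth means the pipeline")
print("recovers product PK from noisy i.v. data plus the in vitro profile alone.")
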