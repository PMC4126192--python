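"""Benchmark imputation/selection combinations with averaged ROC curves.

Runs a small replicated study (Ising-chain genotypes, MAR missingness,
six true QTLs) comparing model-based imputation + weighted lasso
(model1) against nearest-marker imputation + weighted lasso (model3)
and the plain lasso, and prints the mean AUC of each.
"""

from wlassoqtl import SimulationScenario, run_study

scenario = SimulationScenario(
    n_rils=165,
    sigma2=1.0,
    mechanism="MAR",
    n_reps=10,  # the full studies use 50
    seed=42,
)
results = run_study(scenario, ["model1", "model3", "lasso"])
for name, r in results.items():
    print(f"{name:8s} mean AUC = {r.auc:.3f}  "
          f"({r.confusion.shape[0]} replicates x {len(r.sweep)} sweep points)")
# AUC near 1 means the selector ranks the six causal markers ahead of
# the 63 null markers across the whole regularization sweep
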