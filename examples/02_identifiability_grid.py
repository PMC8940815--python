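"""Run the structural-identifiability screen.

Every absorption model simulates a rich noiseless 48 h dataset; every model
then re-estimates its pulmonary parameters from the plasma profile alone.
The scenario matrix shows which wrong-model choices are detectable from
plasma data (scenarios 3 and 4) and which silently corrupt the inferred
lung exposure (scenario 2).

Runtime: a couple of minutes on one core.
"""

from pulmodeconv.workflow import GridConfig, run_identifiability_grid

cfg = GridConfig(n_retries=5, fit_subsample=10, seed=0,
                 include_semimechanistic=True)
result = run_identifiability_grid(cfg)

print("scenario matrix (rows: simulation model, columns: estimation model)")
print("  1 = plasma and lung recovered, 2 = plasma fine but lung wrong,")
print("  3 = plasma misfit (detectable), 4 = not identifiable\n")
print(result.matrix().to_string())

nal_i = next(c for c in result.cells
             if c.simulation == "NaL" and c.estimation == "I")
print(f"\nNaL data re-fitted with the single-process model:")
print(f"  plasma GMFE          : {nal_i.gmfe_plasma:.4f}  (< 1.05: indistinguishable)")
print(f"  lung AUC fold error  : {1 / nal_i.auc_lung_ratio:.1f}x underestimated")
print("  -> the classic silent failure: perfect plasma description, lung")
print("     exposure wrong by the loss/absorption ratio (k_fast+k_nal)/k_fast.")

semi = next(c for c in result.cells
            if c.simulation == "SemiMechanistic" and c.estimation == "II")
print(f"\nBack-flow data re-fitted with the two-process model:")
print(f"  lung AUC deviation   : {abs(semi.auc_lung_ratio - 1) * 100:.2f}%")
print(f"  t_C24h deviation     : {abs(semi.t_c24h_ratio - 1) * 100:.2f}%")
print("  -> ignoring lung re-distribution is harmless for a high-clearance drug.")
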