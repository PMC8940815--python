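"""A miniature population simulation-estimation study.

Simulates the cross-over trial (13 subjects, i.v. + inhalation) from the
two-process model with inter-individual and residual variability, then fits
both the true model and the too-simple single-process model by FOCE using
the sequential PPP strategy (disposition fixed from the i.v. stage).

Two replicates keep the runtime to a few minutes; scripts/acceptance.py and
the pulmodeconv CLI run the larger version.
"""

from dataclasses import replace

from pulmodeconv import AbsorptionVariant
from pulmodeconv.defaults import two_process_study
from pulmodeconv.nlme import Strategy
from pulmodeconv.workflow import EstimationArm, StudyConfig, run_population_study

study = two_process_study()
model_i_start = replace(study["params"], f_fast=None, f_slow=None,
                        k_slow=None, k_fast=0.3)

cfg = StudyConfig(
    simulation_variant=study["variant"],
    simulation_params=study["params"],
    design=study["design"],
    variability=study["variability"],
    arms=[
        EstimationArm("II (true)", study["variant"], study["params"]),
        EstimationArm("I (misfit)", AbsorptionVariant.from_name("I"), model_i_start),
    ],
    strategies=[Strategy.PPP],
    iiv=("f_pul", "cl", "v1", "q2"),
    n_replicates=2,
    master_seed=7,
)
result = run_population_study(cfg, progress=lambda d, t: print(f"  replicate {d}/{t}"))

print("\nper-replicate population exposure estimates (ratio to truth):")
cols = ["replicate", "arm", "success", "auc_plasma_ratio", "auc_lung_ratio",
        "t_c24h_h", "aic"]
print(result.records[cols].round(3).to_string(index=False))
print("""
Reading the table: the true two-process model recovers plasma and lung AUC
near 100% and a retention time near 24 h. The single-process misfit locks
onto the fast absorption phase: it loses part of the absorbed dose (low
plasma AUC ratio) and drains its fitted lung within hours (t_C24h far
below 12 h). Its higher AIC is the statistical clue that would reject it.""")
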