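"""Simulate plasma/lung profiles for one inhaled drug model and compute
its exposure metrics.

Builds the two-parallel-process absorption model (fast + slow pulmonary
absorption into a two-compartment systemic disposition), solves the linear
system for a 100 µg inhaled dose, and prints the closed-form exposure
numbers a deconvolution would try to recover.
"""

import numpy as np

from pulmodeconv import (
    AbsorptionVariant,
    ParameterSet,
    analytic_auc,
    solve_profiles,
)

variant = AbsorptionVariant.from_name("II")
params = ParameterSet(
    cl=30.0, v1=20.0, q2=20.0, v2=100.0,          # systemic disposition
    f_pul=0.4,                                     # 40% of dose reaches the lung
    f_fast=0.7, k_fast=1.5,                        # 70% absorbed fast (t1/2 28 min)
    f_slow=0.3, k_slow=0.1,                        # 30% absorbed slowly (t1/2 6.9 h)
)
dose = 100.0  # µg

times = np.linspace(0.0, 48.0, 481)
profile = solve_profiles(variant, params, dose, "inhaled", times)

auc_plasma = analytic_auc(variant, params, dose, "inhaled", "plasma")
auc_lung = analytic_auc(variant, params, dose, "inhaled", "lung")
c24 = profile.c_lung[np.searchsorted(times, 24.0)]

print(f"plasma Cmax           : {profile.c_plasma.max():8.4f} µg/L "
      f"at t = {times[np.argmax(profile.c_plasma)]:.2f} h")
print(f"AUC(0-inf) plasma     : {auc_plasma:8.3f} µg·h/L   (= dose·F_pul/CL)")
print(f"AUC(0-inf) lung       : {auc_lung:8.1f} µg·h/L   (= dose·F_pul·Σ f_i/k_i / V_lung)")
print(f"lung concentration 24h: {c24:8.4f} µg/L")
print()
print("The lung AUC exceeds the plasma AUC ~{:.0f}-fold: high local exposure".format(
    auc_lung / auc_plasma))
print("before absorption is exactly what makes inhaled dosing attractive, and")
print("what a plasma-only analysis must infer indirectly.")
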