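"""Classify single-molecule trajectories and estimate turnaround hazards.

Generates trajectories at the study conditions, classifies each (directed /
turnaround / base-diffusive / stationary), and estimates the per-micrometre
switching densities P_AR and P_RA with their survival-model consequences:
run lengths 1/P and the probabilities of crossing a 9 um cilium without
switching.
"""

from collections import Counter

from iftflow.smtrack import ClassRules, classify_trajectory, \
    turnaround_statistics
from iftflow.synthdata import KineticsConfig, simulate_mixture

cfg = KineticsConfig()          # truth: P_AR = 0.14, P_RA = 0.07 um^-1
rules = ClassRules(dt_frame=cfg.dt_frame)
generated = simulate_mixture(cfg, 2000, seed=61)
classified = [classify_trajectory(g.trajectory, rules) for g in generated]

print("classified shares:", dict(Counter(c.primary_class for c in classified)))

stats = turnaround_statistics(classified, L_um=cfg.L / 1000.0, rules=rules)
print(f"\nP_AR = {stats.p_ar:.3f} +- {stats.p_ar_err:.3f} um^-1 (truth 0.14)")
print(f"P_RA = {stats.p_ra:.3f} +- {stats.p_ra_err:.3f} um^-1 (truth 0.07)")
print(f"run lengths: anterograde {stats.run_length_antero_um:.1f} um, "
      f"retrograde {stats.run_length_retro_um:.1f} um")
print(f"reach-tip probability  exp(-P_AR L) = {stats.reach_tip_prob:.2f}")
print(f"reach-base probability exp(-P_RA L) = {stats.reach_base_prob:.2f}")
print("\nAt the published hazards these survival probabilities evaluate to "
      "28% (base to tip) and 53% (tip to base).")
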