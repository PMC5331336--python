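"""Stochastic single-motor simulation of the ensemble distribution.

Runs base-to-base round trips of a single motor switching direction at the
measured per-micrometre hazards, accumulates the time-averaged occupancy,
applies the phasmid-overlap correction and PSF smoothing, and prints the
transit survival and occupancy shape.  Also shows how sensitive the
distribution is to swapping the two hazards.
"""

import numpy as np

from iftflow.core import survival_probability
from iftflow.motorsim import (SimConfig, compare_distributions,
                              corrected_profile, run_simulation)

cfg = SimConfig(n_events=10_000, seed=4)  # P_AR = 0.14, P_RA = 0.07 um^-1
res = run_simulation(cfg)

frac = res.n_transits_clean / res.n_transits_attempted
print(f"base-to-tip transits without a switch: {frac:.3f} "
      f"(closed form exp(-0.14*9) = {survival_probability(0.14, 9.0):.3f})")
print(f"hazards recovered from the simulator's own turn logs: "
      f"P_AR = {res.p_ar_recovered:.3f}, P_RA = {res.p_ra_recovered:.3f}")

prof = corrected_profile(res)           # overlap-corrected, PSF-smoothed
sel = (res.x_nm >= 1500) & (res.x_nm <= 8000)
print(f"occupancy max/min over 1.5-8 um: {prof[sel].max() / prof[sel].min():.2f} "
      f"(relatively constant, as measured)")

swapped = run_simulation(SimConfig(p_ar=0.07, p_ra=0.14, n_events=10_000,
                                   seed=5))
d = compare_distributions(corrected_profile(swapped), prof)
print(f"normalized residual after swapping the hazards: {d['rms_residual']:.2f} "
      f"- the steady-state distribution pins down the hazard asymmetry")
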