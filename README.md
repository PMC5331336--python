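# iftflow

Quantitative analysis of intraflagellar-transport (IFT) motor motility in
cilia, at the ensemble and the single-molecule level, together with a
stochastic single-motor simulator that links the two.

IFT-dynein is the sole retrograde motor of the cilium: it drives trains of
IFT particles from the ciliary tip back to the base, and rides anterograde
trains as cargo on the way out. `iftflow` implements the analysis chain used
to characterize such a motor in living *C. elegans* phasmid cilia:

- **Ensemble kymographs** (`iftflow.kymo`) — build kymographs from
  time-lapse stacks along a ciliary spline, separate anterograde, retrograde
  and static components by directional Fourier filtering, extract train
  traces, and compute position-resolved velocity v(x), motor numbers
  (fluorescence calibrated against a single-fluorophore intensity, two
  tagged subunits per motor), train frequencies and motor flux
  (count × velocity).
- **Two-colour colocalization** (`iftflow.coloc`) — channel registration on
  static features, background/bleaching/bleed-through correction,
  thresholded Manders coefficients M1/M2, and per-train intensity ratios
  between a dynein channel and a kinesin channel.
- **Single-molecule tracking and classification** (`iftflow.smtrack`) —
  spot detection and linking, projection onto the ciliary axis, and the
  event rules of the field: a moving event lasts ≥ 600 ms and covers
  ≥ 200 nm; sub-50 nm steps over ≥ 4 frames are stationary; a directional
  switch (turnaround) is a local extremum in x flanked by three consecutive
  same-direction steps on either side.
- **Turnaround hazards** — the central statistic. The probability density of
  switching per micrometre travelled is estimated as

      P_AR = N_AR / D_antero,    P_RA = N_RA / D_retro

  (switch counts over distance travelled in each direction), with
  censoring-aware corrections for short, bleach-limited tracks. Under the
  exponential-distance switching model these hazards imply run lengths
  1/P and the survival probability exp(−P·L) of crossing a cilium of length
  L without switching: with P_AR = 0.14 µm⁻¹ and P_RA = 0.07 µm⁻¹ over
  L = 9 µm, a motor reaches the tip with probability 28% and the base with
  probability 53%, with run lengths 7 µm and 14 µm.
- **Stochastic ensemble simulator** (`iftflow.motorsim`) — a single motor
  shuttles along a 9,000 nm track, switching stochastically at the measured
  hazards, turning deterministically at the tip (no pause) and base
  (exponential pause, mean 500 ms); the time-averaged occupancy, corrected
  for the overlap of the two phasmid cilia by 2 − 1/(e^((x−3500)/200) + 1)
  and convolved with the PSF, is the steady-state motor distribution.
- **Synthetic data** (`iftflow.synthdata`) — a first-class generator of
  single-motor trajectories (directed runs at ~1.7 µm/s with a
  transition-zone slow-down, pauses, base diffusion, 150 ms frames, 40 nm
  localization noise) and rendered kymographs/image stacks with exact
  ground-truth event logs, so every estimator in the package is validated
  against construction truth.

## Worked example

Estimate the switching hazards from 2,000 synthetic single-motor
trajectories generated at the study conditions
(`examples/04_turnaround_hazards.py`):

```
P_AR = 0.121 +- 0.016 um^-1 (truth 0.14)
P_RA = 0.057 +- 0.013 um^-1 (truth 0.07)
run lengths: anterograde 8.3 um, retrograde 17.4 um
reach-tip probability  exp(-P_AR L) = 0.34
reach-base probability exp(-P_RA L) = 0.60
```

The anterograde hazard is about twice the retrograde one: a dynein riding as
cargo on a kinesin-driven train detaches and reverses about twice as often
per micrometre as one actively driving retrograde transport. Feeding the
hazards to the ensemble simulator (`examples/05_ensemble_simulation.py`)
closes the loop between single-molecule switching and the ensemble
distribution:

```
base-to-tip transits without a switch: 0.283 (closed form exp(-0.14*9) = 0.284)
hazards recovered from the simulator's own turn logs: P_AR = 0.139, P_RA = 0.070
occupancy max/min over 1.5-8 um: 1.73 (relatively constant, as measured)
normalized residual after swapping the hazards: 0.34 - the steady-state
distribution pins down the hazard asymmetry
```

The other examples cover kymograph profiling (`02`, recovering the
1.7 µm/s plateau and a 1.6× retro/antero train-frequency ratio),
colocalization (`03`, M1/M2 ≈ 0.89 for co-transported labels versus ≈ 0.2
for an independent control) and the end-to-end recovery pipeline (`06`).

## Command line

A thin CLI wraps the library for shell use:

```
iftflow simulate-data --n 500 --seed 1 --out data/
iftflow kymo  --stack stack.tif --spline spline.csv --out kymo/
iftflow coloc --ch1 a.tif --ch2 b.tif --roi 0:3500 --direction antero --out m.csv
iftflow track --trajectories data/trajectories.csv --out track/
iftflow sim   --n-events 10000 --seed 1 --out sim/
iftflow recover --n 2000 --seed 1 --out recover/
```

Every command writes a JSON run manifest (parameters, seed, version,
timings) next to its outputs.

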