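# Methods

This note documents the models, estimators and numerical choices behind
`iftflow`, and what the synthetic-data validation does and does not show.

## Coordinate conventions and units

The axial coordinate x runs along the cilium in nanometres, x = 0 at the
base, x = L at the tip (default L = 9,000 nm). Anterograde means dx/dt > 0.
Times are in seconds; hazards (turnaround probability densities) in µm⁻¹.

## The switching model

Directional switches are modelled as a spatial Poisson process: while a
motor moves in one direction, the distance to its next reversal is
exponential with mean 1/P, where P is the direction-specific probability
density per micrometre travelled (P_AR anterograde→retrograde, P_RA the
reverse). Everything downstream follows from this single assumption:

- survival over a distance d without switching: exp(−P·d);
- mean run length: 1/P;
- reach-tip probability from the base: exp(−P_AR·L), and symmetrically
  exp(−P_RA·L) for reaching the base from the tip.

With the reference values P_AR = 0.14 µm⁻¹ and P_RA = 0.07 µm⁻¹ these give
28% and 53% over 9 µm, and run lengths 7 µm and 14 µm. These run lengths
describe how far the motor stays attached to a moving train, not stepping
processivity of the isolated motor.

## Synthetic data generator

`synthdata` draws trajectories from a behaviour mixture and renders optics.
Defaults encode the study conditions; each is a deliberate choice:

| parameter | default | rationale |
|---|---|---|
| speed profile | 1.7 µm/s plateau, linear dip to 0.85 µm/s at 0.5–1.5 µm | plateau is the measured train speed; transport slows in the transition zone; the dip depth is not a measured quantity and is configurable |
| hazards P_AR, P_RA | 0.14, 0.07 µm⁻¹ | the measured switching densities |
| frame interval | 150 ms | single-molecule acquisition rate |
| localization noise | 40 nm Gaussian | single-fluorophore localization accuracy |
| observation window | 0.6 s + Exp(0.6 s), capped at 6 s | bleach-limited tracks; the reference switch counts and hazards imply ≈ 1.1 µm of anterograde distance per track, i.e. ≈ 0.7 s of directed motion |
| pause rate / duration | 0.125 s⁻¹, Exp(0.7 s) | ≈ 14% of directed tracks then contain a pause, with the observed mean duration |
| class mixture | antero 0.44, retro 0.29, base 0.15, stationary 0.12 | chosen so that, after hazard-induced switches, realized shares approximate the observed 37/27/16/12/8% composition |
| base diffusion D | 0.1 µm²/s, reflected in 0–500 nm | not experimentally constrained; set so a diffusing motor explores the base region within one observation window (√(2DT) ≈ base extent) |

Two generation modes exist. In *hazard mode* (default) switches arise
stochastically from the hazards, so a trajectory drawn as "anterograde" may
genuinely become a switching trajectory; its truth label is promoted
accordingly. In *five-class mixture mode* an explicit `turnaround` fraction
plants exactly one switch at an interior frame (≥ 3 steps from either end,
64% of switch pauses shorter than one frame) and directed draws are
conditioned on not switching, giving construction-defined labels for
classification benchmarks.

Rendering sums Gaussian line-spread (kymographs) or 2-D PSF (stacks)
contributions per frame, with single-exponential bleaching, uniform
background, Poisson shot noise, and optional channel-1→2 bleed-through
applied to the expected intensities before noise. No blinking and no
out-of-focus modelling of the bent tip; rendered data are therefore cleaner
than real movies in exactly those respects.

## Classification rules

The event rules are taken literally: a moving event lasts
≥ 600 ms and displaces ≥ 200 nm; interframe steps < 50 nm over ≥ 4 frames
define stationary intervals; a directional switch is a local extremum in x
with ≥ 3 consecutive same-direction steps before and after, where sub-50 nm
steps are sign-neutral (they neither break nor extend a run — necessary
because 40 nm localization noise would otherwise sever genuine runs).

Priority order: **base-confined → turnaround → directed → stationary →
rejected.** A track whose maximum x stays within the extended base region
(default 1 µm) is routed to the stationary/diffusive subtree first: a
confined track cannot be a directed event of meaningful extent, and a
random walk at the base readily produces spurious three-step reversal
patterns that would otherwise contaminate the turnaround class. Directed
tracks additionally need net displacement ≥ 0.5 × path length; the sign of
the net displacement gives the direction. Stationary means one detected
stationary interval covering ≥ 80% of frames, or (robust sd < 75 nm and
span < 200 nm) — the second clause is needed because with 40 nm noise the
step-based rule alone rarely spans a whole track. Base-diffusive means
confined, not stationary, with an MSD log-log exponent inside [0.1, 1.7]
when the track has ≥ 12 frames; shorter tracks cannot support an exponent
estimate and are decided by confinement alone. The duration gate applies to
all classes; the 200 nm displacement gate only to moving classes (a
stationary motor cannot pass it by definition).

## Hazard estimation

The raw estimator is P = N/D: switches counted over distance travelled in
the matching direction, with Poisson errors √N/D and delta-method
propagation to 1/P and exp(−P·L). On short, bleach-limited tracks the raw
ratio is strongly biased, and three refinements — each a bookkeeping
consequence of the detection rules, enabled by default — remove the bias:

1. **Edge censoring.** A switch needs three significant steps on each side
   to be detected, so detected extrema lie in a window that starts and ends
   at the midpoints of the third significant step from each trajectory end
   (and from each detected turn). The denominator integrates distance only
   over this window. Margins are counted in significant steps, not frames:
   pauses consume frames but carry no distance.
2. **Masking.** A switch followed by a re-switch within the three-step
   confirmation distance δ leaves no detectable extremum (the pair
   cancels), so the detected rate is P·exp(−P_other·δ) with
   δ = 3 × median significant step. The hazard pair is recovered by
   fixed-point iteration — a dead-time-style correction.
3. **Base-region exclusion.** Because confined tracks are classified
   diffusive, directed tracks near the base are a sample conditioned on
   *not* having switched there. Switches at, and distance below, the base
   boundary are excluded from both numerator and denominator; the hazard is
   estimated from the region where switching is observable.

Validation against construction truth (12 independent sets of 2,000 tracks
at study conditions): P_RA is recovered without detectable bias; P_AR
carries a residual ≈ −7% (traceable to the transition-zone dip, where
smaller steps interact with the significance threshold); every replicate
falls within ±0.03 µm⁻¹ of the truth, the precision with which the
reference values are quoted. Pause durations are reported as
(number of sub-threshold steps) × frame interval; pauses shorter than four
frames are censored by the stationary rule and durations are quantized at
150 ms, so recovered pause statistics are compared to truth pause-by-pause
at frame resolution, not as a raw population mean.

## Kymograph machinery

The directional Fourier filter assigns the two quadrant pairs of the 2-D
spectrum (a line x = vt lives on f_t = −v·f_x) to anterograde and
retrograde components, with raised-cosine mask edges (default 1.5 DFT bins)
against ringing and a static band |f_t| < 1 bin. The three masks sum to one,
so the components reconstruct the input exactly; negative ripple is clipped
at zero and the per-pixel excess re-apportioned pro rata, conserving photon
counts. For calibrated quantities (motor counts, flux) the temporal-DC mass
of a pixel column cannot be attributed directionally by any linear mask;
`assign_moving_intensity` therefore apportions the *original* intensity by
the local positive moving-component share, which is exact for linear
superpositions at train crossings. Trace extraction ridge-follows per-frame
intensity maxima (parabolic sub-pixel refinement, nearest-position linking,
ties by intensity) above max(median + 3·MAD, 15% of image maximum); velocity
profiles bin finite-difference speeds in 250 nm bins (below the PSF, above
the localization noise). Intensity-calibrated quantities use only the first
100 frames when no bleaching correction is applied. Motor counts assume two
fluorophores per motor dimer.

## Colocalization

Channels are registered by Fourier cross-correlation against static
features (sub-pixel by upsampling; a weak correlation peak raises a
registration error). Corrections follow
I′ = (I − bg)/exp(−k·t) − α·I₁′ (bleed-through subtracted in channel 2
only), with the bleach rate k fitted by least squares on the log of
frame-summed intensity over the first 100 frames. Thresholded Manders
coefficients default to per-channel Otsu inside the ROI; a Costes-style
bisection is available. Note the exact identity M1 = M2 = 1 for identical
images holds at zero threshold; any non-trivial threshold leaves flank
intensity below it, so thresholded coefficients on identical soft-edged
images sit near, but below, one. Train ratios sample both corrected
kymographs along one trace and average the scaled ratio over the
motor-appropriate segment (proximal 0–3.5 µm for kinesin-II, distal
4.0–7.5 µm for OSM-3); uncertainty is the s.d. across trains.

## Ensemble simulator

Each event is one base-to-base round trip starting anterograde at the base.
In the default exponential mode the distance to the next stochastic switch
is drawn directly from the exponential law; the per-step Bernoulli mode
(p = P × step at 1 nm steps, drawn as a geometric variate) is the
discretized equivalent and agrees on transit survival to well under 1%.
Residence time per position follows step/v(x), accumulated into 50 nm
occupancy bins; pauses (tip, base, optional mid-track) deposit their
duration into the bin where they occur. Mid-track switch pauses default to
zero (most observed switches complete within one frame). The tip forces an
immediate A→R turn; the base an R→A turn after an Exp(500 ms) pause. The
occupancy is multiplied by the phasmid-overlap factor
2 − 1/(e^((x−3500)/200) + 1) (two overlapping cilia distally: factor 1→2,
1.5 at 3.5 µm) and convolved with a Gaussian PSF (σ default 150 nm, mass
conserved by reflective boundaries). Profile comparison is
amplitude-invariant: least-squares scale, then RMS residual normalized by
the RMS of the reference.

At the default hazards the corrected occupancy is flat to within a
max/min ratio < 1.8 over 1.5–8 µm, while swapping P_AR and P_RA changes the
profile by an order of magnitude more than the replicate-to-replicate
noise — the distribution is diagnostic of the hazard asymmetry.

## Problem sizes and reproducibility

Defaults used by the test suite and the acceptance script: 2,000–4,000
trajectories for hazard recovery, 2,000 for classification benchmarks,
10,000 simulator events, 600-track grids for estimator consistency across
hazard combinations. All randomness flows through numpy Generators seeded
from a single integer per run; CLI runs write a manifest sufficient to
reproduce deterministic stages bit-for-bit.

## Known limitations

- The generator's realism gaps (no blinking, no tip defocus, Gaussian PSF,
  single-exponential bleaching) mean passing tests demonstrate estimator
  correctness under the stated model, not robustness to every instrumental
  artefact of real movies.
- Run-length and reach-probability errors use the delta method on Poisson
  counting errors; alternative error conventions can give smaller quoted
  errors on 1/P for small N.
- The hazard estimator assumes spatially uniform hazards outside the base
  region when pooling distance; position-resolved estimation is possible
  from the same event logs but not built in.
- Base diffusion is phenomenological (reflected Brownian motion with an
  unconstrained D); the diffusive/stationary boundary at the base is the
  least identifiable part of the classifier.
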