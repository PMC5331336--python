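"""Two-colour colocalization on corrected, directionally filtered kymographs.

Renders the same anterograde trains in two channels (with channel-1 into
channel-2 bleed-through), applies background/bleed-through correction,
computes thresholded Manders coefficients, and contrasts them with an
independent control channel.
"""

import numpy as np

from iftflow.coloc import CorrectionConfig, correct_kymograph, \
    manders_coefficients
from iftflow.kymo import fourier_directional_filter
from iftflow.synthdata import KineticsConfig, OpticsConfig, render_kymograph, \
    render_two_channel_kymographs, simulate_train_set

cfg = KineticsConfig()
duration = 30.0
trains = [g for g in simulate_train_set(cfg, duration, freq_antero=0.8,
                                        freq_retro=0.0, seed=11)]
optics = OpticsConfig(bleedthrough_alpha=0.1)
k1, k2 = render_two_channel_kymographs(trains, trains, optics,
                                       duration=duration, L=cfg.L, seed=12)

corr = CorrectionConfig(background_ch1=float(np.percentile(k1.I, 10)),
                        background_ch2=float(np.percentile(k2.I, 10)),
                        bleedthrough_alpha=0.1)
c1 = correct_kymograph(k1, corr, channel=1)
c2 = correct_kymograph(k2, corr, other_corrected=c1, channel=2)
f1 = fourier_directional_filter(c1)[0]
f2 = fourier_directional_filter(c2)[0]
m = manders_coefficients(f1, f2, roi_nm=(0.0, 3500.0))
print(f"co-transported channels:   M1 = {m['M1']:.2f}, M2 = {m['M2']:.2f}")

control = [g for g in simulate_train_set(cfg, duration, freq_antero=0.8,
                                         freq_retro=0.0, seed=99)]
kc = render_kymograph(control, optics, duration=duration, L=cfg.L, seed=13)
fc = fourier_directional_filter(correct_kymograph(kc, corr, channel=1))[0]
mc = manders_coefficients(f1, fc, roi_nm=(0.0, 3500.0))
print(f"independent control:       M1 = {mc['M1']:.2f}, M2 = {mc['M2']:.2f}")
print("\nCoefficients near one mean the two labels ride the same trains; an "
      "unrelated kymograph of the same directionality gives a much lower "
      "baseline.")
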