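"""Two-colour kymograph colocalization and motor-ratio analysis.

Channel registration against static features, background/bleaching/
bleed-through correction, thresholded Manders coefficients on directionally
filtered kymographs, and per-train intensity ratios between two motor
channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.registration import phase_cross_correlation

from .core import Kymograph
from .kymo import TrainTrace

__all__ = [
    "CorrectionConfig",
    "RegistrationError",
    "register_channels",
    "fit_bleach_rate",
    "correct_kymograph",
    "manders_coefficients",
    "train_intensity_ratio",
]

# segment-averaging windows, nm: proximal for the kinesin-II import motor,
# distal for the OSM-3 long-distance motor
PROXIMAL_SEGMENT = (0.0, 3500.0)
DISTAL_SEGMENT = (4000.0, 7500.0)


class RegistrationError(RuntimeError):
    """Raised when the static cross-correlation peak is too weak to trust."""


@dataclass
class CorrectionConfig:
    """Per-channel correction parameters for quantitative comparison."""

    background_ch1: float = 0.0
    background_ch2: float = 0.0
    bleach_rate_ch1: float = 0.0       # s^-1
    bleach_rate_ch2: float = 0.0
    bleedthrough_alpha: float = 0.0    # channel 1 -> channel 2
    excitation_scale: float = 1.0      # ch1/ch2 excitation-intensity correction

    def validate(self) -> None:
        if not (0.0 <= self.bleedthrough_alpha < 1.0):
            raise ValueError("bleedthrough_alpha must be in [0, 1)")
        if self.excitation_scale <= 0:
            raise ValueError("excitation_scale must be positive")
        if self.bleach_rate_ch1 < 0 or self.bleach_rate_ch2 < 0:
            raise ValueError("bleach rates must be non-negative")


def register_channels(kym1: Kymograph, kym2: Kymograph,
                      upsample_factor: int = 20, min_peak: float = 0.05
                      ) -> tuple[tuple[float, float], Kymograph]:
    """Register channel 2 onto channel 1 using non-moving features.

    The shift maximizing the cross-correlation of the two images (subpixel
    via Fourier upsampling) is estimated and applied to channel 2.  A
    normalized correlation peak below ``min_peak`` raises
    :class:`RegistrationError`.
    """
    a = kym1.I - kym1.I.mean()
    b = kym2.I - kym2.I.mean()
    if a.shape != b.shape:
        raise ValueError("kymographs must have equal shape")
    shift, error, _ = phase_cross_correlation(a, b, upsample_factor=upsample_factor,
                                              normalization=None)
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    peak = 0.0 if denom == 0 else float(1.0 - error)
    if peak < min_peak:
        raise RegistrationError(f"correlation peak {peak:.3f} below {min_peak}")
    shifted = ndimage.shift(kym2.I, shift, order=1, mode="nearest")
    return (float(shift[0]), float(shift[1])), kym2.copy_with(shifted)


def fit_bleach_rate(kym: Kymograph, max_frames: int = 100) -> float:
    """Least-squares bleach rate from the log of frame-summed intensity."""
    total = kym.I[:max_frames].sum(axis=1)
    total = np.clip(total, 1e-12, None)
    t = np.arange(len(total)) * kym.dt_frame
    slope = np.polyfit(t, np.log(total), 1)[0]
    return float(max(0.0, -slope))


def correct_kymograph(kym: Kymograph, cfg: CorrectionConfig,
                      other_corrected: Kymograph | None = None,
                      channel: int = 1) -> Kymograph:
    """Background, bleaching and (channel 2 only) bleed-through correction.

    I' = (I - bg) / exp(-bleach_rate t) - alpha * I_other_corrected, clipped
    at zero.  ``other_corrected`` must be the already-corrected channel-1
    kymograph when correcting channel 2.
    """
    cfg.validate()
    bg = cfg.background_ch1 if channel == 1 else cfg.background_ch2
    rate = cfg.bleach_rate_ch1 if channel == 1 else cfg.bleach_rate_ch2
    t = (np.arange(kym.n_frames) * kym.dt_frame)[:, None]
    I = (kym.I - bg) / np.exp(-rate * t)
    if channel == 2 and cfg.bleedthrough_alpha > 0:
        if other_corrected is None:
            raise ValueError("channel-2 correction needs the corrected channel 1")
        I = I - cfg.bleedthrough_alpha * other_corrected.I
    return kym.copy_with(np.clip(I, 0.0, None))


def _roi_slice(kym: Kymograph, roi_nm: tuple[float, float] | None) -> slice:
    if roi_nm is None:
        return slice(None)
    lo = int(np.floor(roi_nm[0] / kym.dx_pixel))
    hi = int(np.ceil(roi_nm[1] / kym.dx_pixel))
    if lo < 0 or hi > kym.n_pixels or hi <= lo:
        raise ValueError("roi outside the kymograph axial range")
    return slice(lo, hi)


def _costes_thresholds(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Costes-style common threshold: walk down the regression line until the
    below-threshold pixels are uncorrelated (Pearson <= 0)."""
    slope, inter = np.polyfit(a.ravel(), b.ravel(), 1)
    lo, hi = float(a.min()), float(a.max())
    for _ in range(60):
        t1 = 0.5 * (lo + hi)
        t2 = slope * t1 + inter
        sel = (a < t1) & (b < t2)
        if sel.sum() < 10:
            hi = t1
            continue
        av, bv = a[sel], b[sel]
        r = 0.0 if av.std() == 0 or bv.std() == 0 else float(np.corrcoef(av, bv)[0, 1])
        if r > 0:
            hi = t1
        else:
            lo = t1
    t1 = 0.5 * (lo + hi)
    return t1, slope * t1 + inter


def manders_coefficients(kym1: Kymograph, kym2: Kymograph,
                         threshold_method: str = "otsu",
                         roi_nm: tuple[float, float] | None = None,
                         thresholds: tuple[float, float] | None = None) -> dict:
    """Thresholded Manders colocalization coefficients.

    M1 is the fraction of channel-1 intensity in pixels where channel 2
    exceeds its threshold; M2 symmetrically.  Operates on already corrected
    and directionally filtered kymographs, within an axial ROI.
    """
    if kym1.I.shape != kym2.I.shape:
        raise ValueError("kymographs must have equal shape")
    sl = _roi_slice(kym1, roi_nm)
    a = kym1.I[:, sl]
    b = kym2.I[:, sl]
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("undefined Manders coefficient: a channel is all zero")
    if thresholds is not None:
        t1, t2 = thresholds
    elif threshold_method == "otsu":
        t1 = float(threshold_otsu(a)) if a.min() != a.max() else float(a.min())
        t2 = float(threshold_otsu(b)) if b.min() != b.max() else float(b.min())
    elif threshold_method == "costes":
        t1, t2 = _costes_thresholds(a, b)
    else:
        raise ValueError(f"unknown threshold method {threshold_method!r}")
    m1 = float(a[b > t2].sum() / a.sum())
    m2 = float(b[a > t1].sum() / b.sum())
    return {"M1": m1, "M2": m2, "t1": t1, "t2": t2,
            "n_pixels": int(a.size)}


def train_intensity_ratio(kym1: Kymograph, kym2: Kymograph, trace: TrainTrace,
                          cfg: CorrectionConfig,
                          segment_nm: tuple[float, float] | None = None) -> dict:
    """Channel-1 / channel-2 intensity ratio along one train.

    Both kymographs are sampled along the trace (bilinear interpolation);
    the ratio excitation_scale * I1/I2 is reported per sample and averaged
    over ``segment_nm`` (defaults to the proximal 0-3.5 um window).
    Samples with non-positive channel-2 intensity are masked.
    """
    cfg.validate()
    if segment_nm is None:
        segment_nm = PROXIMAL_SEGMENT
    rows = trace.t / kym1.dt_frame
    cols = trace.x / kym1.dx_pixel
    if (cols.min() < 0 or cols.max() > kym1.n_pixels - 1
            or rows.min() < 0 or rows.max() > kym1.n_frames - 1):
        raise ValueError("trace leaves the kymograph")
    i1 = ndimage.map_coordinates(kym1.I, [rows, cols], order=1)
    i2 = ndimage.map_coordinates(kym2.I, [rows, cols], order=1)
    valid = i2 > 0
    if not np.any(valid):
        raise ValueError("channel-2 intensity non-positive along the whole trace")
    ratio = np.full(len(trace.x), np.nan)
    ratio[valid] = cfg.excitation_scale * i1[valid] / i2[valid]
    in_seg = (trace.x >= segment_nm[0]) & (trace.x <= segment_nm[1]) & valid
    seg_mean = float(np.mean(ratio[in_seg])) if np.any(in_seg) else np.nan
    return {"x_nm": trace.x, "ratio": ratio, "segment_mean": seg_mean,
            "segment_nm": segment_nm, "n_valid": int(valid.sum())}
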