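"""Ensemble kymograph analysis.

Builds kymographs from image stacks, separates anterograde, retrograde and
static components by directional Fourier filtering, extracts train traces by
ridge following, and turns them into position-dependent velocity, motor
number, train frequency and flux profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .core import Kymograph

__all__ = [
    "Kymograph",
    "TrainTrace",
    "FluxProfile",
    "build_kymograph",
    "fourier_directional_filter",
    "extract_train_traces",
    "position_velocity_profile",
    "intensity_to_motor_count",
    "detect_train_peaks",
    "train_frequencies",
    "compute_flux",
]


@dataclass
class TrainTrace:
    """Ordered (t, x) samples along one train, with per-position intensity."""

    t: np.ndarray
    x: np.ndarray
    intensity: np.ndarray
    direction: str = "unknown"   # 'anterograde' | 'retrograde'
    trace_id: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trace times must be strictly increasing")

    @property
    def velocity(self) -> float:
        """Overall slope dx/dt (nm/s) from a least-squares line fit."""
        return float(np.polyfit(self.t, self.x, 1)[0])


@dataclass
class FluxProfile:
    """Motor count per unit time, velocity and their product along the cilium."""

    x_nm: np.ndarray
    motors: np.ndarray
    v: np.ndarray
    flux: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.flux, self.motors * self.v, rtol=1e-9, atol=1e-9,
                           equal_nan=True):
            raise ValueError("flux must equal motors * v pointwise")


def build_kymograph(stack: np.ndarray, spline_px: np.ndarray, pixel_size: float,
                    dt_frame: float, width: int = 3, channel: str = "ch1"
                    ) -> Kymograph:
    """Sample an image stack along a spline to produce a kymograph.

    The spline (N x 2 control points, [row, col] in pixels) is resampled at
    equal arc-length steps of one pixel; each kymograph row sums intensity
    over ``width`` pixels perpendicular to the local spline direction.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must be a non-empty (T, H, W) array")
    if width < 1:
        raise ValueError("width must be >= 1 pixel")
    pts = np.asarray(spline_px, dtype=float)
    # dense resample at equal arc length
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n_samp = max(2, int(np.floor(s[-1])) + 1)
    s_eq = np.linspace(0.0, s[-1], n_samp)
    rows = np.interp(s_eq, s, pts[:, 0])
    cols = np.interp(s_eq, s, pts[:, 1])
    H, W = stack.shape[1:]
    if rows.min() < -0.5 or rows.max() > H - 0.5 or cols.min() < -0.5 or cols.max() > W - 0.5:
        raise ValueError("spline exits image bounds")
    dr = np.gradient(rows)
    dc = np.gradient(cols)
    norm = np.maximum(np.hypot(dr, dc), 1e-12)
    nr, nc = -dc / norm, dr / norm
    offsets = np.arange(width) - (width - 1) / 2.0
    rr = rows[None, :] + offsets[:, None] * nr[None, :]
    cc = cols[None, :] + offsets[:, None] * nc[None, :]
    kym = np.empty((stack.shape[0], n_samp))
    for f in range(stack.shape[0]):
        samples = ndimage.map_coordinates(stack[f], [rr, cc], order=1, mode="nearest")
        kym[f] = samples.sum(axis=0)
    return Kymograph(I=kym, dt_frame=dt_frame, dx_pixel=pixel_size, channel=channel)


def _soft_sign(f: np.ndarray, width: float) -> np.ndarray:
    """Raised-cosine approximation of sign(f), ramping over |f| <= width."""
    u = np.clip(f / max(width, 1e-12), -1.0, 1.0)
    return np.sin(0.5 * np.pi * u)


def fourier_directional_filter(kym: Kymograph, edge_bins: float = 1.5,
                               static_bins: float = 1.0, clip: bool = True
                               ) -> tuple[Kymograph, Kymograph, Kymograph]:
    """Split a kymograph into anterograde, retrograde and static components.

    In the 2-D Fourier plane a line x = v t (v > 0, anterograde) lives on
    f_t = -v f_x, i.e. in the quadrants where the temporal and spatial
    frequencies have opposite signs; retrograde motion occupies the same-sign
    quadrants.  The masks use raised-cosine edges ``edge_bins`` DFT bins wide
    to limit ringing, and a static band of |f_t| below ``static_bins`` bins.
    The three weights sum to one, so the components reconstruct the input
    exactly; with ``clip`` the negative ripple of each component is clipped
    at zero and the per-pixel excess re-apportioned pro rata among the
    components, conserving the input (the separation neither creates nor
    destroys photon counts).
    """
    I = kym.I
    if not np.all(np.isfinite(I)):
        raise ValueError("kymograph contains non-finite values")
    if I.shape[0] < 8 or I.shape[1] < 8:
        raise ValueError("kymograph must be at least 8x8")
    F = np.fft.fft2(I)
    ft = np.fft.fftfreq(I.shape[0])[:, None]   # cycles per frame
    fx = np.fft.fftfreq(I.shape[1])[None, :]   # cycles per pixel
    dft_t = 1.0 / I.shape[0]
    dft_x = 1.0 / I.shape[1]
    st = _soft_sign(ft, edge_bins * dft_t)
    sx = _soft_sign(fx, edge_bins * dft_x)
    w_static = np.cos(0.5 * np.pi * np.clip(np.abs(ft) / (static_bins * dft_t),
                                            0.0, 1.0)) ** 2
    w_static = np.broadcast_to(w_static, F.shape)
    moving = 1.0 - w_static
    w_antero = moving * 0.5 * (1.0 - st * sx)
    w_retro = moving * 0.5 * (1.0 + st * sx)
    imgs = [np.real(np.fft.ifft2(F * w))
            for w in (w_antero, w_retro, w_static)]
    if clip:
        clipped = [np.clip(img, 0.0, None) for img in imgs]
        total = clipped[0] + clipped[1] + clipped[2]
        target = np.clip(I, 0.0, None)
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(total > 0, target / np.maximum(total, 1e-30), 0.0)
        imgs = [c * scale for c in clipped]
    names = ("antero", "retro", "static")
    return tuple(kym.copy_with(img, channel=f"{kym.channel}:{name}")
                 for img, name in zip(imgs, names))


def assign_moving_intensity(kym: Kymograph, antero: Kymograph, retro: Kymograph,
                            floor: float = 0.02) -> tuple[Kymograph, Kymograph]:
    """Apportion the original intensity between the two moving directions.

    A linear Fourier mask cannot attribute the temporal-DC mass of a pixel
    column to a direction, yet for calibrated quantities (motor counts,
    flux) every photon of a passing train must be counted.  This assigns the
    *original* intensity pixelwise in proportion to the local positive
    moving-component amplitudes; pixels where both moving components are
    below ``floor`` times the image maximum contribute nothing.  Where one
    train crosses another the split is proportional, which is exact for
    linear superpositions of intensity.
    """
    a = np.clip(antero.I, 0.0, None)
    r = np.clip(retro.I, 0.0, None)
    tot = a + r
    lim = floor * max(kym.I.max(), 1e-30)
    with np.errstate(invalid="ignore", divide="ignore"):
        wa = np.where(tot > lim, a / np.maximum(tot, 1e-30), 0.0)
        wr = np.where(tot > lim, r / np.maximum(tot, 1e-30), 0.0)
    return (kym.copy_with(kym.I * wa, channel=f"{kym.channel}:antero"),
            kym.copy_with(kym.I * wr, channel=f"{kym.channel}:retro"))


def extract_train_traces(kym: Kymograph, min_len: int = 5,
                         max_step_nm: float | None = None,
                         threshold_k: float = 3.0,
                         rel_floor: float = 0.15) -> list[TrainTrace]:
    """Ridge-follow intensity maxima frame to frame into train traces.

    Local maxima above median + ``threshold_k`` * MAD (but never below
    ``rel_floor`` of the image maximum, which suppresses directional-filter
    ripple on clean kymographs) are detected per frame with parabolic
    sub-pixel refinement and linked to the nearest trace end within
    ``max_step_nm`` (ties broken by nearest position, then highest
    intensity); traces shorter than ``min_len`` frames are discarded.
    """
    I = kym.I
    if max_step_nm is None:
        max_step_nm = 3000.0 * kym.dt_frame  # generous v_max of 3 um/s
    noise = 1.4826 * np.median(np.abs(I - np.median(I)))
    thr = max(np.median(I) + threshold_k * max(noise, 1e-12),
              rel_floor * I.max())
    active: list[dict] = []
    done: list[dict] = []
    for f in range(I.shape[0]):
        row = I[f]
        peaks, props = signal.find_peaks(row, height=thr)
        # sub-pixel parabolic refinement
        cand = []
        for p in peaks:
            xp = float(p)
            if 0 < p < len(row) - 1:
                denom = row[p - 1] - 2 * row[p] + row[p + 1]
                if denom < 0:
                    xp = p + 0.5 * (row[p - 1] - row[p + 1]) / denom
            cand.append((xp * kym.dx_pixel, float(row[p])))
        used = set()
        new_active = []
        for tr in active:
            best = None
            for ci, (cx, camp) in enumerate(cand):
                if ci in used:
                    continue
                d = abs(cx - tr["x"][-1])
                if d <= max_step_nm:
                    key = (d, -camp)
                    if best is None or key < best[0]:
                        best = (key, ci)
            if best is not None:
                ci = best[1]
                used.add(ci)
                tr["t"].append(f * kym.dt_frame)
                tr["x"].append(cand[ci][0])
                tr["a"].append(cand[ci][1])
                new_active.append(tr)
            else:
                done.append(tr)
        for ci, (cx, camp) in enumerate(cand):
            if ci not in used:
                new_active.append({"t": [f * kym.dt_frame], "x": [cx], "a": [camp]})
        active = new_active
    done.extend(active)
    traces = []
    for i, tr in enumerate(d for d in done if len(d["t"]) >= min_len):
        x = np.array(tr["x"])
        direction = "anterograde" if np.median(np.diff(x)) >= 0 else "retrograde"
        traces.append(TrainTrace(t=np.array(tr["t"]), x=x,
                                 intensity=np.array(tr["a"]),
                                 direction=direction, trace_id=i))
    return traces


def position_velocity_profile(traces: list[TrainTrace], x_edges: np.ndarray | None = None,
                              bin_nm: float = 250.0, L: float = 9000.0):
    """Bin per-trace finite-difference velocities by position.

    Returns a dict with bin centres, mean speed, s.e.m. and count per bin.
    Velocities are |dx/dt| between consecutive samples, assigned to the bin
    of the midpoint position.
    """
    if not traces:
        raise ValueError("need at least one trace")
    if x_edges is None:
        x_edges = np.arange(0.0, L + bin_nm, bin_nm)
    xs, vs = [], []
    for tr in traces:
        if len(tr.t) < 2:
            continue
        v = np.diff(tr.x) / np.diff(tr.t)
        xm = 0.5 * (tr.x[1:] + tr.x[:-1])
        xs.append(xm)
        vs.append(np.abs(v))
    xs = np.concatenate(xs)
    vs = np.concatenate(vs)
    idx = np.digitize(xs, x_edges) - 1
    nb = len(x_edges) - 1
    mean = np.full(nb, np.nan)
    sem = np.full(nb, np.nan)
    n = np.zeros(nb, dtype=int)
    for b in range(nb):
        sel = vs[idx == b]
        n[b] = len(sel)
        if n[b]:
            mean[b] = sel.mean()
            sem[b] = sel.std(ddof=1) / np.sqrt(n[b]) if n[b] > 1 else 0.0
    centers = 0.5 * (x_edges[1:] + x_edges[:-1])
    return {"x_nm": centers, "mean": mean, "sem": sem, "n": n}


def intensity_to_motor_count(intensity, i_single_fluor: float,
                             subunits_per_motor: int = 2):
    """Convert train intensity to a motor count.

    Each motor dimer carries ``subunits_per_motor`` fluorophores (two tagged
    light-intermediate-chain subunits per IFT-dynein), so
    count = intensity / (subunits_per_motor * I_single_fluor).
    """
    if i_single_fluor <= 0:
        raise ValueError("single-fluorophore calibration intensity must be positive")
    return np.asarray(intensity, dtype=float) / (subunits_per_motor * i_single_fluor)


def detect_train_peaks(series: np.ndarray, dt_frame: float, smooth_window: int = 3,
                       prominence_k: float = 3.0):
    """Automated peak detection in an intensity-versus-time profile.

    The series is moving-average smoothed and peaks above ``prominence_k``
    times the MAD noise level are kept.  Returns peak times (s) and the
    frequency peaks / duration (s^-1).
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 5:
        raise ValueError("series must have at least 5 samples")
    kernel = np.ones(smooth_window)
    cover = np.convolve(np.ones_like(series), kernel, mode="same")
    sm = np.convolve(series, kernel, mode="same") / cover
    resid = series - sm
    noise = 1.4826 * np.median(np.abs(resid - np.median(resid)))
    prom = prominence_k * max(noise, 1e-9 * (sm.max() - sm.min() + 1e-30))
    peaks, _ = signal.find_peaks(sm, prominence=prom)
    times = peaks * dt_frame
    duration = len(series) * dt_frame
    return times, len(peaks) / duration


def train_frequencies(kym_antero: Kymograph, kym_retro: Kymograph,
                      x_nm: float, **kwargs) -> dict:
    """Train frequencies per direction at a fixed position, and their ratio."""
    out = {}
    for name, k in (("antero", kym_antero), ("retro", kym_retro)):
        col = int(np.clip(round(x_nm / k.dx_pixel), 0, k.n_pixels - 1))
        _, freq = detect_train_peaks(k.I[:, col], k.dt_frame, **kwargs)
        out[name] = freq
    out["ratio_retro_antero"] = out["retro"] / out["antero"] if out["antero"] > 0 else np.inf
    return out


def compute_flux(kym_directional: Kymograph, v_profile: np.ndarray,
                 i_single_fluor: float, subunits_per_motor: int = 2,
                 max_frames: int | None = None) -> FluxProfile:
    """Motor flux along the cilium from a directionally filtered kymograph.

    motors(x) is the time-integrated, calibration-normalized intensity per
    unit time; flux(x) = motors(x) * v(x).  ``v_profile`` must be sampled on
    the kymograph's pixel grid.  ``max_frames`` restricts the integration to
    the first frames (use 100 when no bleaching correction is applied).
    """
    v_profile = np.asarray(v_profile, dtype=float)
    if v_profile.shape != (kym_directional.n_pixels,):
        raise ValueError("velocity profile grid does not match kymograph pixels")
    I = kym_directional.I if max_frames is None else kym_directional.I[:max_frames]
    duration = I.shape[0] * kym_directional.dt_frame
    integrated = I.sum(axis=0) * kym_directional.dt_frame
    motors = intensity_to_motor_count(integrated, i_single_fluor,
                                      subunits_per_motor) / duration
    return FluxProfile(x_nm=kym_directional.x_nm, motors=motors, v=v_profile,
                       flux=motors * v_profile)
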