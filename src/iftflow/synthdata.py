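"""Ground-truth single-motor trajectories and rendered kymographs/stacks.

The generator emulates the single-molecule and ensemble imaging conditions of
IFT-dynein motility in *C. elegans* phasmid cilia: directed runs at
~1.7 um/s with a transition-zone slow-down, direction-specific turnaround
hazards expressed as a probability density per micrometre travelled,
within-run pauses, reflected diffusion at the ciliary base, stationary
particles, ~150 ms frame sampling and ~40 nm localization noise.  Every
trajectory comes with an exact event log (switch locations/times, pauses) so
downstream estimators can be validated against construction truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Kymograph, PiecewiseSpeed, Trajectory

__all__ = [
    "KineticsConfig",
    "OpticsConfig",
    "TrainGroup",
    "GeneratedTrajectory",
    "simulate_trajectory",
    "simulate_mixture",
    "simulate_train_set",
    "render_kymograph",
    "render_two_channel_kymographs",
    "render_image_stack",
    "straight_spline",
    "trajectories_to_frame",
    "events_to_frame",
]

CLASSES = ("anterograde", "retrograde", "base", "stationary")
# fifth label available in explicit five-class mixtures
TURNAROUND = "turnaround"


@dataclass
class KineticsConfig:
    """Kinetic ground truth for the trajectory generator.

    Lengths in nm, times in s, hazards in um^-1.  The defaults encode the
    study conditions: 9 um cilium, 1.7 um/s runs with a transition-zone dip,
    P_AR = 0.14 um^-1, P_RA = 0.07 um^-1, 150 ms frames, 40 nm localization
    noise, and short bleach-limited observation windows (~1.2 s mean).
    """

    L: float = 9000.0
    v_antero: PiecewiseSpeed = field(
        default_factory=PiecewiseSpeed.with_transition_zone_dip)
    v_retro: PiecewiseSpeed = field(
        default_factory=PiecewiseSpeed.with_transition_zone_dip)
    p_ar: float = 0.14          # anterograde -> retrograde hazard, um^-1
    p_ra: float = 0.07          # retrograde -> anterograde hazard, um^-1
    pause_rate: float = 0.125   # pauses per second within directed runs
    pause_mean: float = 0.7     # mean pause duration, s
    d_base: float = 1.0e5       # base diffusion coefficient, nm^2/s
    base_region: float = 500.0  # axial extent of the base, nm
    class_fractions: dict = field(default_factory=lambda: {
        "anterograde": 0.44, "retrograde": 0.29, "base": 0.15, "stationary": 0.12})
    dt_frame: float = 0.15
    sigma_loc: float = 40.0
    # observation window: duration_min + Exp(duration_mean_extra), capped
    duration_min: float = 0.6
    duration_mean_extra: float = 0.6
    duration_max: float = 6.0
    # fraction of planted directional switches that are anterograde-to-retrograde
    a_to_r_fraction: float = 0.89
    seed: int | None = None

    def validate(self) -> None:
        fr = self.class_fractions
        if abs(sum(fr.values()) - 1.0) > 1e-6:
            raise ValueError("class_fractions must sum to 1")
        for k in fr:
            if k not in CLASSES and k != TURNAROUND:
                raise ValueError(f"unknown class {k!r}")
            if fr[k] < 0:
                raise ValueError("class fractions must be non-negative")
        for name in ("L", "pause_rate", "pause_mean", "d_base", "base_region",
                     "dt_frame", "sigma_loc", "p_ar", "p_ra"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        xs = np.linspace(1.0, self.L - 1.0, 64)
        if np.any(self.v_antero(xs) <= 0) or np.any(self.v_retro(xs) <= 0):
            raise ValueError("speed profiles must be strictly positive inside (0, L)")


@dataclass
class OpticsConfig:
    """Rendering parameters for synthetic kymographs and image stacks."""

    pixel_size: float = 100.0       # nm
    psf_sigma: float = 150.0        # nm
    photons_per_frame: float = 200.0
    background_rate: float = 5.0    # photons / pixel / frame
    bleach_rate: float = 0.0        # s^-1
    bleedthrough_alpha: float = 0.0  # fraction of ch1 signal leaking into ch2
    shot_noise: bool = True
    seed: int | None = None

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not (0.0 <= self.bleedthrough_alpha < 1.0):
            raise ValueError("bleedthrough_alpha must be in [0, 1)")
        if self.psf_sigma < 0 or self.photons_per_frame < 0 or self.background_rate < 0:
            raise ValueError("optics parameters must be non-negative")


@dataclass
class GeneratedTrajectory:
    """A simulated trajectory with its construction truth."""

    trajectory: Trajectory
    events: pd.DataFrame          # columns: id, event, t_s, x_nm
    true_class: str               # drawn class, promoted to 'turnaround' if it turned
    reached_boundary: str | None = None   # 'tip', 'base' or None


@dataclass
class TrainGroup:
    """All motors of one IFT train share a path; metadata records the size."""

    trajectory: Trajectory
    n_motors: int
    direction: str                # 'anterograde' or 'retrograde'
    t_depart: float


def _events_frame(events: list, traj_id: int) -> pd.DataFrame:
    df = pd.DataFrame(events, columns=["event", "t_s", "x_nm"])
    df.insert(0, "id", traj_id)
    return df


def _sample_duration(cfg: KineticsConfig, rng: np.random.Generator) -> float:
    d = cfg.duration_min + rng.exponential(cfg.duration_mean_extra)
    return float(min(d, cfg.duration_max))


def _directed_path(cfg: KineticsConfig, rng: np.random.Generator, x0: float,
                   direction: int, duration: float, hazards: bool = True,
                   n_sub: int = 10):
    """Continuous-time directed run sampled at frame times.

    Motion integrates dx/dt = +/- v(x) on substeps of dt_frame/n_sub.  The
    distance to the next directional switch is drawn from an exponential with
    mean 1/P (per-um hazard of the current direction); pause initiation is a
    Poisson process in run time with exponential durations.  Returns noiseless
    frame positions, the event list, and a boundary flag.
    """
    v_of = {1: cfg.v_antero, -1: cfg.v_retro}
    p_of = {1: cfg.p_ar, -1: cfg.p_ra}

    def draw_turn_dist(d: int) -> float:
        p = p_of[d]
        if not hazards or p <= 0:
            return np.inf
        return rng.exponential(1.0 / p) * 1000.0  # um -> nm

    def draw_pause_clock() -> float:
        if cfg.pause_rate <= 0:
            return np.inf
        return rng.exponential(1.0 / cfg.pause_rate)

    n_frames = max(2, int(round(duration / cfg.dt_frame)) + 1)
    dt_s = cfg.dt_frame / n_sub
    x = float(x0)
    d = direction
    dist_to_turn = draw_turn_dist(d)
    run_until_pause = draw_pause_clock()
    pause_left = 0.0
    events: list = []
    frames = [x]
    boundary = None
    t = 0.0

    for i in range(1, n_frames):
        for _ in range(n_sub):
            if boundary is not None:
                break
            if pause_left > 0.0:
                pause_left = max(0.0, pause_left - dt_s)
                if pause_left == 0.0:
                    events.append(("pause_end", t + dt_s, x))
                t += dt_s
                continue
            if run_until_pause <= 0.0:
                dur = rng.exponential(cfg.pause_mean)
                pause_left = dur
                events.append(("pause_start", t, x))
                run_until_pause = draw_pause_clock()
                t += dt_s
                continue
            v = float(v_of[d](x))
            step = v * dt_s
            if step >= dist_to_turn:
                # switch mid-substep at the exact sampled distance
                x_turn = x + d * dist_to_turn
                t_turn = t + dist_to_turn / v
                events.append(("turn_AR" if d == 1 else "turn_RA", t_turn, x_turn))
                remaining = step - dist_to_turn
                d = -d
                x = x_turn + d * remaining
                dist_to_turn = draw_turn_dist(d)
            else:
                x = x + d * step
                dist_to_turn -= step
            run_until_pause -= dt_s
            t += dt_s
            if x >= cfg.L:
                x = cfg.L
                boundary = "tip"
            elif x <= 0.0:
                x = 0.0
                boundary = "base"
        frames.append(x)
        if boundary is not None and len(frames) >= 2:
            break
    return np.array(frames), events, boundary


def simulate_trajectory(cfg: KineticsConfig, behaviour: str,
                        seed: int | np.random.Generator | None = None,
                        x0: float | None = None, duration: float | None = None,
                        traj_id: int = 0) -> GeneratedTrajectory:
    """Simulate one motor of the given behaviour class.

    ``behaviour`` is one of ``anterograde``, ``retrograde``, ``base``,
    ``stationary`` or ``turnaround``.  Directed classes carry the configured
    turnaround hazards, so an anterograde draw may still switch direction
    mid-track; the returned ``true_class`` is promoted to ``turnaround`` in
    that case.  The ``turnaround`` class plants exactly one switch at a
    uniformly chosen interior frame (>= 3 steps from either end) with hazards
    off, mirroring how observable single-switch tracks arise.
    """
    cfg.validate()
    if behaviour not in CLASSES and behaviour != TURNAROUND:
        raise ValueError(f"invalid class label {behaviour!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    duration = _sample_duration(cfg, rng) if duration is None else float(duration)
    n_frames = max(2, int(round(duration / cfg.dt_frame)) + 1)
    t = np.arange(n_frames) * cfg.dt_frame
    events: list = []
    boundary = None
    true_class = behaviour

    if behaviour in ("anterograde", "retrograde"):
        d = 1 if behaviour == "anterograde" else -1
        if x0 is None:
            x0 = rng.uniform(0.0, cfg.L / 3.0) if d == 1 else rng.uniform(2 * cfg.L / 3.0, cfg.L)
        xs, events, boundary = _directed_path(cfg, rng, x0, d, duration)
        if any(e[0].startswith("turn") for e in events):
            true_class = TURNAROUND
    elif behaviour == TURNAROUND:
        d = 1 if rng.random() < cfg.a_to_r_fraction else -1
        margin = 3
        pause = 0.0 if rng.random() < 0.64 else float(rng.exponential(0.3))
        p_frames = int(round(pause / cfg.dt_frame))
        # moving steps split so both legs satisfy the 3-step observability rule
        n_moving = max(n_frames - 1 - p_frames, 2 * margin + 1)
        k = int(rng.integers(margin, n_moving - margin + 1))
        n_frames = n_moving + p_frames + 1
        t = np.arange(n_frames) * cfg.dt_frame
        v_max = float(max(np.max(cfg.v_antero.knots_v), np.max(cfg.v_retro.knots_v)))
        rise = v_max * k * cfg.dt_frame
        if x0 is None:
            lo, hi = (100.0, max(200.0, cfg.L - rise - 100.0)) if d == 1 else \
                     (min(cfg.L - 200.0, rise + 100.0), cfg.L - 100.0)
            x0 = rng.uniform(lo, max(lo + 1.0, hi))
        quiet = dataclasses.replace(cfg, pause_rate=0.0)
        pre, _e1, b1 = _directed_path(quiet, rng, x0, d, k * cfg.dt_frame,
                                      hazards=False)
        x_turn = float(pre[-1])
        post, _e2, boundary = _directed_path(quiet, rng, x_turn, -d,
                                             (n_moving - k) * cfg.dt_frame,
                                             hazards=False)
        xs = np.concatenate([pre, np.full(p_frames, x_turn), post[1:]])
        t_turn = k * cfg.dt_frame
        events = [("turn_AR" if d == 1 else "turn_RA", t_turn, x_turn)]
        if p_frames:
            events += [("pause_start", t_turn, x_turn),
                       ("pause_end", (k + p_frames) * cfg.dt_frame, x_turn)]
    elif behaviour == "stationary":
        x0 = rng.uniform(0.0, cfg.L) if x0 is None else x0
        xs = np.full(n_frames, float(x0))
    elif behaviour == "base":
        x0 = rng.uniform(0.0, cfg.base_region) if x0 is None else x0
        n_sub = 5
        dt_s = cfg.dt_frame / n_sub
        steps = rng.normal(0.0, np.sqrt(2 * cfg.d_base * dt_s),
                           size=(n_frames - 1) * n_sub)
        path = x0 + np.cumsum(steps)
        # reflect into [0, base_region]
        b = cfg.base_region
        path = np.abs(np.mod(path, 2 * b))
        path = np.where(path > b, 2 * b - path, path)
        xs = np.concatenate([[x0], path[n_sub - 1::n_sub]])
    else:  # pragma: no cover
        raise ValueError(behaviour)

    n = min(len(xs), n_frames)
    x_noisy = xs[:n] + rng.normal(0.0, cfg.sigma_loc, size=n)
    y = rng.normal(0.0, cfg.sigma_loc, size=n)
    traj = Trajectory(t=t[:n], x=x_noisy, y=y, id=traj_id, dt_frame=cfg.dt_frame)
    traj.x_true = xs[:n]  # noiseless path kept for validation
    return GeneratedTrajectory(trajectory=traj, events=_events_frame(events, traj_id),
                               true_class=true_class, reached_boundary=boundary)


def simulate_mixture(cfg: KineticsConfig, n: int,
                     seed: int | np.random.Generator | None = None
                     ) -> list[GeneratedTrajectory]:
    """Draw ``n`` trajectories from the configured class mixture.

    If the mixture contains an explicit ``turnaround`` fraction, directed
    classes are conditioned on not switching within the observation window
    (rejection sampling) so the drawn labels stay construction truth.
    """
    cfg.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = list(cfg.class_fractions)
    probs = np.array([cfg.class_fractions[k] for k in labels], dtype=float)
    probs = probs / probs.sum()
    condition_directed = TURNAROUND in labels
    out = []
    for i in range(n):
        lab = labels[int(rng.choice(len(labels), p=probs))]
        for _attempt in range(50):
            g = simulate_trajectory(cfg, lab, seed=rng, traj_id=i)
            if not (condition_directed and lab in ("anterograde", "retrograde")
                    and g.true_class == TURNAROUND):
                break
        out.append(g)
    return out


def simulate_train_set(cfg: KineticsConfig, duration: float,
                       freq_antero: float = 1.0, freq_retro: float = 1.6,
                       motors_antero: tuple[int, int] = (40, 50),
                       motors_retro: tuple[int, int] = (20, 30),
                       seed: int | np.random.Generator | None = None
                       ) -> list[TrainGroup]:
    """Poisson train departures from base (anterograde) and tip (retrograde).

    Each train is a single shared path traversing the full cilium at the
    configured speed profile; per-train motor counts are drawn uniformly from
    the given inclusive ranges (anterograde trains are larger, retrograde
    trains smaller but more frequent).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if motors_antero[1] < motors_antero[0] or motors_retro[1] < motors_retro[0]:
        raise ValueError("empty motors-per-train distribution")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    groups: list[TrainGroup] = []
    tid = 0
    for direction, freq, mrange in (("anterograde", freq_antero, motors_antero),
                                    ("retrograde", freq_retro, motors_retro)):
        n_trains = rng.poisson(freq * duration)
        departs = np.sort(rng.uniform(0.0, duration, size=n_trains))
        d = 1 if direction == "anterograde" else -1
        x0 = 0.0 if d == 1 else cfg.L
        for t0 in departs:
            transit_cfg = dataclasses.replace(cfg, pause_rate=0.0, sigma_loc=0.0,
                                              p_ar=0.0, p_ra=0.0)
            xs, _ev, _b = _directed_path(transit_cfg, rng, x0, d,
                                         duration=cfg.L / 1000.0 + 2.0)
            n = len(xs)
            k0 = int(round(t0 / cfg.dt_frame))
            t = (k0 + np.arange(n)) * cfg.dt_frame
            traj = Trajectory(t=t, x=xs, y=np.zeros(n), id=tid, dt_frame=cfg.dt_frame)
            groups.append(TrainGroup(trajectory=traj,
                                     n_motors=int(rng.integers(mrange[0], mrange[1] + 1)),
                                     direction=direction, t_depart=float(t0)))
            tid += 1
    return groups


def _splat_lines(kym: np.ndarray, trajs, weights, optics: OpticsConfig,
                 dt_frame: float, x_grid: np.ndarray) -> None:
    """Accumulate Gaussian line-spread contributions of emitting motors."""
    n_frames = kym.shape[0]
    for traj, w in zip(trajs, weights):
        k0 = int(round(traj.t[0] / dt_frame))
        for j in range(len(traj)):
            fr = k0 + j
            if fr < 0 or fr >= n_frames:
                continue
            t_abs = fr * dt_frame
            amp = w * optics.photons_per_frame * np.exp(-optics.bleach_rate * t_abs)
            if amp <= 0:
                continue
            g = np.exp(-0.5 * ((x_grid - traj.x[j]) / optics.psf_sigma) ** 2)
            kym[fr] += amp * g / (optics.psf_sigma * np.sqrt(2 * np.pi)) * \
                (x_grid[1] - x_grid[0])


def render_kymograph(trajectories, optics: OpticsConfig, duration: float,
                     L: float, weights=None,
                     seed: int | np.random.Generator | None = None,
                     channel: str = "ch1") -> Kymograph:
    """Render trajectories into a kymograph (time x axial position).

    Each frame row is the sum of Gaussian line-spread contributions (sigma =
    ``psf_sigma``) of all motors emitting in that frame, attenuated by
    single-exponential bleaching, plus a uniform background; Poisson shot
    noise is applied when ``optics.shot_noise`` is set.
    """
    optics.validate()
    if duration <= 0:
        raise ValueError("duration must be positive")
    trajs = [g.trajectory if hasattr(g, "trajectory") else g for g in trajectories]
    if len(trajs) == 0:
        raise ValueError("empty trajectory list")
    if weights is None:
        weights = [getattr(g, "n_motors", 1.0) for g in trajectories]
    dt = trajs[0].dt_frame
    n_frames = int(round(duration / dt))
    n_px = int(np.ceil(L / optics.pixel_size))
    x_grid = (np.arange(n_px) + 0.5) * optics.pixel_size
    I = np.zeros((n_frames, n_px))
    _splat_lines(I, trajs, weights, optics, dt, x_grid)
    I += optics.background_rate
    if optics.shot_noise:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
            seed if seed is not None else optics.seed)
        I = rng.poisson(I).astype(float)
    return Kymograph(I=I, dt_frame=dt, dx_pixel=optics.pixel_size, channel=channel)


def render_two_channel_kymographs(trajs1, trajs2, optics: OpticsConfig,
                                  duration: float, L: float,
                                  weights1=None, weights2=None,
                                  seed: int | np.random.Generator | None = None
                                  ) -> tuple[Kymograph, Kymograph]:
    """Two-channel rendering with channel-1 -> channel-2 bleed-through.

    The channel-2 expectation is its own signal plus ``bleedthrough_alpha``
    times the channel-1 signal (before background and shot noise).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        seed if seed is not None else optics.seed)
    clean = dataclasses.replace(optics, shot_noise=False, background_rate=0.0)
    k1 = render_kymograph(trajs1, clean, duration, L, weights=weights1, channel="ch1")
    if trajs2:
        k2 = render_kymograph(trajs2, clean, duration, L, weights=weights2, channel="ch2")
        I2 = k2.I
    else:
        I2 = np.zeros_like(k1.I)
    I2 = I2 + optics.bleedthrough_alpha * k1.I
    I1 = k1.I + optics.background_rate
    I2 = I2 + optics.background_rate
    if optics.shot_noise:
        I1 = rng.poisson(I1).astype(float)
        I2 = rng.poisson(I2).astype(float)
    return (Kymograph(I=I1, dt_frame=k1.dt_frame, dx_pixel=k1.dx_pixel, channel="ch1"),
            Kymograph(I=I2, dt_frame=k1.dt_frame, dx_pixel=k1.dx_pixel, channel="ch2"))


def straight_spline(L: float, pixel_size: float, y0_px: float = 0.0,
                    x0_px: float = 0.0) -> np.ndarray:
    """Control points (N x 2, [row, col] in px) of a straight horizontal cilium."""
    n = max(2, int(np.ceil(L / pixel_size)) // 4)
    cols = x0_px + np.linspace(0.0, L / pixel_size, n)
    rows = np.full(n, y0_px)
    return np.column_stack([rows, cols])


def render_image_stack(trajectories, optics: OpticsConfig, duration: float,
                       L: float, shape: tuple[int, int] | None = None,
                       spline_px: np.ndarray | None = None, weights=None,
                       seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Render trajectories into a 2-D time-lapse stack along a ciliary spline.

    ``spline_px`` maps axial position to image coordinates: rows of [row,
    col] control points at equal axial spacing from 0 to L.  The default is a
    straight cilium along the image x-axis, vertically centred.
    """
    optics.validate()
    trajs = [g.trajectory if hasattr(g, "trajectory") else g for g in trajectories]
    if weights is None:
        weights = [getattr(g, "n_motors", 1.0) for g in trajectories]
    dt = trajs[0].dt_frame if trajs else 0.15
    n_frames = int(round(duration / dt))
    px = optics.pixel_size
    if shape is None:
        shape = (15, int(np.ceil(L / px)) + 4)
    H, W = shape
    if spline_px is None:
        spline_px = straight_spline(L, px, y0_px=H / 2.0, x0_px=2.0)
    s_ax = np.linspace(0.0, L, len(spline_px))
    tangent = np.gradient(spline_px, axis=0)
    tangent /= np.maximum(np.linalg.norm(tangent, axis=1, keepdims=True), 1e-12)
    normal = np.column_stack([-tangent[:, 1], tangent[:, 0]])
    stack = np.zeros((n_frames, H, W))
    sig_px = optics.psf_sigma / px
    half = max(2, int(np.ceil(4 * sig_px)))
    for traj, w in zip(trajs, weights):
        k0 = int(round(traj.t[0] / dt))
        for j in range(len(traj)):
            fr = k0 + j
            if fr < 0 or fr >= n_frames:
                continue
            xax = np.clip(traj.x[j], 0.0, L)
            r0 = np.interp(xax, s_ax, spline_px[:, 0])
            c0 = np.interp(xax, s_ax, spline_px[:, 1])
            nr = np.interp(xax, s_ax, normal[:, 0])
            nc = np.interp(xax, s_ax, normal[:, 1])
            r = r0 + nr * traj.y[j] / px
            c = c0 + nc * traj.y[j] / px
            amp = w * optics.photons_per_frame * np.exp(-optics.bleach_rate * fr * dt)
            if amp <= 0:
                continue
            ri, ci = int(round(r)), int(round(c))
            rs = slice(max(0, ri - half), min(H, ri + half + 1))
            cs = slice(max(0, ci - half), min(W, ci + half + 1))
            rr, cc = np.mgrid[rs, cs]
            g = np.exp(-0.5 * (((rr - r) ** 2 + (cc - c) ** 2) / sig_px ** 2))
            stack[fr, rs, cs] += amp * g / (2 * np.pi * sig_px ** 2)
    stack += optics.background_rate
    if optics.shot_noise:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
            seed if seed is not None else optics.seed)
        stack = rng.poisson(stack).astype(float)
    return stack


def trajectories_to_frame(generated: list[GeneratedTrajectory]) -> pd.DataFrame:
    """Flatten trajectories to the CSV dialect id,frame,t_s,x_nm,y_nm."""
    rows = []
    for g in generated:
        tr = g.trajectory
        for j in range(len(tr)):
            rows.append((tr.id, j, tr.t[j], tr.x[j], tr.y[j]))
    return pd.DataFrame(rows, columns=["id", "frame", "t_s", "x_nm", "y_nm"])


def events_to_frame(generated: list[GeneratedTrajectory]) -> pd.DataFrame:
    """Concatenate ground-truth event logs (id,event,t_s,x_nm)."""
    frames = [g.events for g in generated if len(g.events)]
    if not frames:
        return pd.DataFrame(columns=["id", "event", "t_s", "x_nm"])
    return pd.concat(frames, ignore_index=True)[["id", "event", "t_s", "x_nm"]]
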