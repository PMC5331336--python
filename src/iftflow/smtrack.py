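"""Single-molecule detection, linking, classification and turnaround hazards.

Implements the single-particle side of the analysis: spot detection and
linking on photoactivated sparse-emitter stacks, projection onto a ciliary
spline, the event / stationary / pause / turnaround classification rules,
and the turnaround probability densities P_AR and P_RA (switches per
micrometre travelled) with the exponential-survival quantities they imply
(run lengths 1/P, reach probabilities exp(-P L)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import Trajectory, run_length_from_hazard, survival_probability

__all__ = [
    "ClassRules",
    "ClassifiedTrajectory",
    "TurnaroundStats",
    "detect_and_link",
    "project_onto_spline",
    "filter_events",
    "detect_stationary_segments",
    "detect_turnarounds",
    "classify_trajectory",
    "classify_set",
    "class_share_summary",
    "share_percent",
    "turnaround_statistics",
    "pause_statistics",
]


@dataclass
class ClassRules:
    """Classification thresholds.

    The first six fields are the published event rules: an event must last
    600 ms and move 200 nm; sub-50 nm interframe steps over >= 4 frames are
    stationary; a directional switch needs three consecutive same-direction
    steps before and after the turn.  The remaining fields parameterize the
    parts the rules leave open (directionality ratio, the diffusive MSD band,
    the base region used for the diffusive class) and are reported alongside
    results.
    """

    min_event_duration: float = 0.600     # s
    min_event_displacement: float = 200.0  # nm
    stationary_step: float = 50.0          # nm; also the sign-neutral band
    stationary_frames: int = 4
    turn_steps: int = 3
    dt_frame: float = 0.150                # s
    directionality_threshold: float = 0.5  # net displacement / path length
    stationary_cover: float = 0.8          # fraction of frames in one interval
    stationary_sd_factor: float = 1.5      # robust-sd bound, x stationary_step
    msd_band: tuple = (0.1, 1.7)           # log-log slope band for diffusive
    msd_max_lag: int = 5
    msd_min_frames: int = 12               # below this the MSD exponent is not used
    base_region_max: float = 1000.0        # nm; centroid bound for diffusive

    def validate(self) -> None:
        if min(self.min_event_duration, self.min_event_displacement,
               self.stationary_step, self.dt_frame) <= 0:
            raise ValueError("thresholds must be positive")
        if self.stationary_frames < 2 or self.turn_steps < 1:
            raise ValueError("stationary_frames >= 2 and turn_steps >= 1 required")


@dataclass
class TurnEvent:
    """One directional switch: location, timing and pause at the turn."""

    direction: str        # 'AR' or 'RA'
    frame: int            # frame index of the extremum
    t_s: float
    x_nm: float
    pause_s: float


@dataclass
class ClassifiedTrajectory:
    trajectory: Trajectory
    primary_class: str    # anterograde | retrograde | turnaround | base | stationary | rejected
    pauses: list = field(default_factory=list)        # (t_start, t_end) seconds
    turnarounds: list = field(default_factory=list)   # TurnEvent
    d_antero_nm: float = 0.0
    d_retro_nm: float = 0.0
    d_antero_detect_nm: float = 0.0
    d_retro_detect_nm: float = 0.0
    reject_reason: str | None = None


@dataclass
class TurnaroundStats:
    """Turnaround counts, hazards and the survival quantities they imply.

    P = N / D exactly, with sigma_P = sqrt(N) / D (Poisson counting error);
    run lengths 1/P and reach probabilities exp(-P L) carry delta-method
    errors.  Distances are in um; ``L`` is the cilium length in um.
    """

    n_ar: int
    n_ra: int
    d_antero_um: float
    d_retro_um: float
    p_ar: float
    p_ra: float
    p_ar_err: float
    p_ra_err: float
    run_length_antero_um: float
    run_length_retro_um: float
    run_length_antero_err: float
    run_length_retro_err: float
    reach_tip_prob: float
    reach_base_prob: float
    reach_tip_err: float
    reach_base_err: float
    L_um: float = 9.0


# ---------------------------------------------------------------------------
# detection and linking

def detect_and_link(stack: np.ndarray, pixel_size: float, dt_frame: float,
                    sigma_small_px: float = 1.0, sigma_large_px: float = 3.0,
                    threshold_k: float = 4.0, max_disp_nm: float = 700.0,
                    gap_frames: int = 1, min_len: int = 3) -> list[Trajectory]:
    """Detect spots per frame and link them into trajectories.

    Detection: difference-of-Gaussians band-pass, local maxima above
    median + ``threshold_k`` * MAD, refined by an intensity-weighted centroid
    in a small window.  Linking: frame-to-frame nearest neighbour within
    ``max_disp_nm`` with gap closing over at most ``gap_frames`` missed
    frames (gaps are filled by linear interpolation to keep frame spacing
    uniform).  Returned trajectories are in image coordinates: ``x`` is the
    column and ``y`` the row position in nm.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must have at least 2 frames")
    all_spots: list[list[tuple[float, float]]] = []
    for frame in stack:
        bp = ndimage.gaussian_filter(frame, sigma_small_px) - \
            ndimage.gaussian_filter(frame, sigma_large_px)
        noise = 1.4826 * np.median(np.abs(bp - np.median(bp)))
        thr = np.median(bp) + threshold_k * max(noise, 1e-12)
        maxima = (ndimage.maximum_filter(bp, size=3) == bp) & (bp > thr)
        spots = []
        for r, c in zip(*np.nonzero(maxima)):
            w = 3
            rs = slice(max(0, r - w), min(frame.shape[0], r + w + 1))
            cs = slice(max(0, c - w), min(frame.shape[1], c + w + 1))
            patch = bp[rs, cs] - bp[rs, cs].min()
            tot = patch.sum()
            if tot <= 0:
                continue
            rr, cc = np.mgrid[rs, cs]
            spots.append((float((rr * patch).sum() / tot),
                          float((cc * patch).sum() / tot)))
        all_spots.append(spots)

    max_disp_px = max_disp_nm / pixel_size
    active: list[dict] = []
    finished: list[dict] = []
    for f, spots in enumerate(all_spots):
        used = set()
        still_active = []
        for tr in active:
            if f - tr["last_f"] > gap_frames + 1:
                finished.append(tr)
                continue
            best = None
            for si, (r, c) in enumerate(spots):
                if si in used:
                    continue
                d = np.hypot(r - tr["r"][-1], c - tr["c"][-1])
                if d <= max_disp_px * (f - tr["last_f"]):
                    if best is None or d < best[0]:
                        best = (d, si)
            if best is not None:
                si = best[1]
                used.add(si)
                # fill a closed gap by linear interpolation
                for g in range(tr["last_f"] + 1, f):
                    a = (g - tr["last_f"]) / (f - tr["last_f"])
                    tr["r"].append(tr["r"][-1] * (1 - a) + spots[si][0] * a)
                    tr["c"].append(tr["c"][-1] * (1 - a) + spots[si][1] * a)
                    tr["f"].append(g)
                tr["r"].append(spots[si][0])
                tr["c"].append(spots[si][1])
                tr["f"].append(f)
                tr["last_f"] = f
                still_active.append(tr)
            else:
                still_active.append(tr)
        active = still_active
        for si, (r, c) in enumerate(spots):
            if si not in used:
                active.append({"r": [r], "c": [c], "f": [f], "last_f": f})
    finished.extend(active)

    trajs = []
    for i, tr in enumerate(t for t in finished if len(t["f"]) >= min_len):
        f0 = tr["f"][0]
        t = (f0 + np.arange(len(tr["f"]))) * dt_frame
        trajs.append(Trajectory(t=t, x=np.array(tr["c"]) * pixel_size,
                                y=np.array(tr["r"]) * pixel_size, id=i,
                                dt_frame=dt_frame))
    return trajs


def project_onto_spline(traj: Trajectory, spline_px: np.ndarray,
                        pixel_size: float, tube_radius_nm: float = 1000.0,
                        oversample: int = 20) -> tuple[Trajectory, np.ndarray]:
    """Project an image-coordinate trajectory onto a ciliary spline.

    The spline (N x 2 [row, col] control points, px) defines the axial axis:
    the projected ``x`` is the arc length of the nearest spline point (nm,
    0 at the first control point) and ``y`` the signed perpendicular offset.
    Returns the projected trajectory and a boolean mask flagging points
    farther than ``tube_radius_nm`` from the spline.
    """
    pts = np.asarray(spline_px, dtype=float) * pixel_size
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n_dense = max(len(pts) * oversample, 200)
    s_dense = np.linspace(0.0, s[-1], n_dense)
    dense = np.column_stack([np.interp(s_dense, s, pts[:, 0]),
                             np.interp(s_dense, s, pts[:, 1])])
    tree = cKDTree(dense)
    q = np.column_stack([traj.y, traj.x])  # (row, col) in nm
    dist, idx = tree.query(q)
    tang = np.gradient(dense, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    off = q - dense[idx]
    # signed offset: positive on the left of the tangent direction
    cross = tang[idx, 0] * off[:, 1] - tang[idx, 1] * off[:, 0]
    y_signed = np.sign(cross) * dist
    out_of_tube = dist > tube_radius_nm
    proj = Trajectory(t=traj.t.copy(), x=s_dense[idx], y=y_signed, id=traj.id,
                      dt_frame=traj.dt_frame)
    return proj, out_of_tube


# ---------------------------------------------------------------------------
# classification rules

def filter_events(trajectories: list[Trajectory], rules: ClassRules
                  ) -> tuple[list[Trajectory], list[tuple[Trajectory, str]]]:
    """Keep trajectories that qualify as moving events.

    Kept iff duration >= ``min_event_duration`` and the maximum displacement
    from the starting position >= ``min_event_displacement``; rejected
    trajectories are returned with a reason code.
    """
    rules.validate()
    kept, rejected = [], []
    for tr in trajectories:
        if tr.duration < rules.min_event_duration:
            rejected.append((tr, "too_short"))
        elif np.max(np.abs(tr.x - tr.x[0])) < rules.min_event_displacement:
            rejected.append((tr, "displacement"))
        else:
            kept.append(tr)
    return kept, rejected


def detect_stationary_segments(traj: Trajectory, rules: ClassRules
                               ) -> list[tuple[int, int]]:
    """Maximal frame intervals with consecutive sub-threshold steps.

    A run of k consecutive interframe displacements |dx| < stationary_step
    spans k+1 frames; runs spanning >= ``stationary_frames`` frames are
    reported as (first_frame, last_frame) inclusive intervals.
    """
    rules.validate()
    steps = np.abs(np.diff(traj.x))
    small = steps < rules.stationary_step
    intervals = []
    i = 0
    n = len(small)
    while i < n:
        if small[i]:
            j = i
            while j + 1 < n and small[j + 1]:
                j += 1
            if (j - i + 2) >= rules.stationary_frames:
                intervals.append((i, j + 1))
            i = j + 1
        i += 1
    return intervals


def _step_runs(x: np.ndarray, rules: ClassRules):
    """Runs of consecutive same-sign significant steps.

    Steps smaller than ``stationary_step`` are sign-neutral: they neither
    break nor extend a directional run.  Returns a list of
    (sign, count, first_step_idx, last_step_idx).
    """
    steps = np.diff(x)
    signs = np.where(np.abs(steps) < rules.stationary_step, 0,
                     np.sign(steps)).astype(int)
    runs = []
    for i, sg in enumerate(signs):
        if sg == 0:
            continue
        if runs and runs[-1][0] == sg:
            sgn, cnt, first, _ = runs[-1]
            runs[-1] = (sgn, cnt + 1, first, i)
        else:
            runs.append((sg, 1, i, i))
    return runs


def detect_turnarounds(traj: Trajectory, rules: ClassRules) -> list[TurnEvent]:
    """Directional switches: a local extremum in x flanked by directional runs.

    A turn requires at least ``turn_steps`` consecutive same-direction
    significant steps before and after the extremum; sign-neutral
    (sub-threshold) steps between the two runs define the pause at the turn.
    """
    rules.validate()
    if len(traj) < 2 * rules.turn_steps + 1:
        return []
    runs = _step_runs(traj.x, rules)
    events = []
    for r in range(len(runs) - 1):
        s1, c1, _f1, e1 = runs[r]
        s2, c2, f2, _e2 = runs[r + 1]
        if s1 == -s2 and c1 >= rules.turn_steps and c2 >= rules.turn_steps:
            lo, hi = e1 + 1, f2  # frames between the two runs (inclusive)
            seg = traj.x[lo:hi + 1]
            k = int(np.argmax(seg) if s1 > 0 else np.argmin(seg))
            frame = lo + k
            pause = (f2 - (e1 + 1)) * rules.dt_frame
            events.append(TurnEvent(direction="AR" if s1 > 0 else "RA",
                                    frame=frame, t_s=float(traj.t[frame]),
                                    x_nm=float(traj.x[frame]),
                                    pause_s=float(pause)))
    return events


def _msd_loglog_slope(x: np.ndarray, max_lag: int) -> float:
    lags = [lag for lag in range(1, max_lag + 1) if len(x) - lag >= 2]
    if len(lags) < 2:
        return np.nan
    msd = [np.mean((x[lag:] - x[:-lag]) ** 2) for lag in lags]
    msd = np.clip(msd, 1e-12, None)
    return float(np.polyfit(np.log(lags), np.log(msd), 1)[0])


def _directed_distances(traj: Trajectory, turns: list[TurnEvent],
                        rules: ClassRules, x_min: float = 0.0
                        ) -> tuple[float, float, float, float]:
    """Per-direction distance travelled, full and edge-censored.

    Segments run between detected turns (and the trajectory ends); each
    contributes its |net displacement| to the direction of its sign.  The
    censored variant keeps only distance where a switch could have produced
    a detected extremum under the m-steps-before/m-steps-after rule, with m
    counted in *significant* steps (|dx| >= stationary_step) because
    sub-threshold steps are sign-neutral for turn detection: they consume
    frames but neither enable nor carry detectable distance.  A switch
    inside a step lands its extremum on either bounding frame, so the
    detectable window starts and ends at the *midpoints* of the m-th
    significant step from each censored boundary.  Segment ends that
    coincide with a detected turn carry no end margin: detection reached
    exactly up to that extremum.

    ``x_min`` restricts the windows to positions above a cut (used to keep
    the base region, where diffusing motors are routed to their own class,
    out of the hazard denominators).
    """
    bounds = [0] + [ev.frame for ev in turns] + [len(traj) - 1]
    d_a = d_r = d_a_det = d_r_det = 0.0
    m = rules.turn_steps
    x = traj.x
    steps = np.diff(x)
    for k in range(len(bounds) - 1):
        a, b = bounds[k], bounds[k + 1]
        if b <= a:
            continue
        net = x[b] - x[a]
        ends_at_turn = k < len(bounds) - 2
        sig = [j for j in range(a, b)
               if abs(steps[j]) >= rules.stationary_step]
        need = m + (0 if ends_at_turn else m)
        net_det = 0.0
        if len(sig) >= need:
            j0 = sig[m - 1]
            start = 0.5 * (x[j0] + x[j0 + 1])
            if ends_at_turn:
                end = x[b]
            else:
                j1 = sig[-m]
                end = 0.5 * (x[j1] + x[j1 + 1])
            hi, lo = max(start, end), min(start, end)
            net_det = np.sign(end - start) * max(0.0, hi - max(lo, x_min))
        if net >= 0:
            d_a += net
            d_a_det += max(0.0, net_det)
        else:
            d_r += -net
            d_r_det += max(0.0, -net_det)
    return d_a, d_r, d_a_det, d_r_det


def classify_trajectory(traj: Trajectory, rules: ClassRules) -> ClassifiedTrajectory:
    """Assign the primary behaviour class of one axial trajectory.

    Priority: base-confined (stationary or base-diffusive) > turnaround >
    directed (anterograde/retrograde) > stationary > rejected.  The 200 nm
    displacement minimum gates only the moving classes; stationary and
    diffusive tracks need only satisfy the 600 ms duration minimum.  A track
    that never leaves the extended base region cannot be a directed event of
    meaningful extent — and a random walk there readily produces spurious
    three-step reversal patterns — so the confinement test runs first.
    """
    rules.validate()
    out = ClassifiedTrajectory(trajectory=traj, primary_class="rejected")
    if traj.duration < rules.min_event_duration:
        out.reject_reason = "too_short"
        return out
    x = traj.x
    turns = detect_turnarounds(traj, rules)
    stat = detect_stationary_segments(traj, rules)
    pauses = [(float(traj.t[i]), float(traj.t[j])) for i, j in stat]
    max_disp = float(np.max(np.abs(x - x[0])))
    path = float(np.sum(np.abs(np.diff(x))))
    net = float(x[-1] - x[0])
    single_cover = any((j - i + 1) / len(traj) >= rules.stationary_cover
                       for i, j in stat)
    robust_sd = 1.4826 * float(np.median(np.abs(x - np.median(x))))
    span = float(x.max() - x.min())
    noise_like = (robust_sd < rules.stationary_sd_factor * rules.stationary_step
                  and span < rules.min_event_displacement)

    if float(x.max()) <= rules.base_region_max:
        if single_cover or noise_like:
            out.primary_class = "stationary"
        else:
            if len(x) >= rules.msd_min_frames:
                slope = _msd_loglog_slope(x, rules.msd_max_lag)
                in_band = (np.isfinite(slope)
                           and rules.msd_band[0] <= slope <= rules.msd_band[1])
            else:
                # too short for a meaningful MSD exponent; confinement decides
                in_band = True
            if in_band:
                out.primary_class = "base"
            else:
                out.reject_reason = "confined_nondiffusive"
    elif turns and max_disp >= rules.min_event_displacement:
        out.primary_class = "turnaround"
        out.turnarounds = turns
        turn_frames = {ev.frame for ev in turns}
        out.pauses = [p for (i, j), p in zip(stat, pauses)
                      if not any(i <= f <= j for f in turn_frames)]
    elif (max_disp >= rules.min_event_displacement and path > 0
          and abs(net) / path >= rules.directionality_threshold):
        out.primary_class = "anterograde" if net > 0 else "retrograde"
        out.pauses = pauses
    elif single_cover or noise_like:
        out.primary_class = "stationary"
    else:
        out.reject_reason = "unclassified"
    if out.primary_class in ("anterograde", "retrograde", "turnaround"):
        (out.d_antero_nm, out.d_retro_nm,
         out.d_antero_detect_nm, out.d_retro_detect_nm) = \
            _directed_distances(traj, turns if out.primary_class == "turnaround" else [],
                                rules)
    return out


def classify_set(trajectories: list[Trajectory], rules: ClassRules
                 ) -> list[ClassifiedTrajectory]:
    return [classify_trajectory(tr, rules) for tr in trajectories]


def share_percent(count: float, total: float, ndigits: int = 0) -> float:
    """Percentage share of a count, rounded as printed (182/494 -> 37%)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, ndigits)


def class_share_summary(classified: list[ClassifiedTrajectory]) -> dict:
    """Counts and rounded percentage shares per primary class."""
    counts: dict = {}
    for c in classified:
        counts[c.primary_class] = counts.get(c.primary_class, 0) + 1
    total = len(classified)
    return {"n": total, "counts": counts,
            "percent": {k: share_percent(v, total, 1) for k, v in counts.items()}}


def _median_significant_step(classified: list[ClassifiedTrajectory],
                             rules: ClassRules) -> float:
    steps = []
    for c in classified:
        if c.primary_class in ("anterograde", "retrograde", "turnaround"):
            s = np.abs(np.diff(c.trajectory.x))
            steps.extend(s[s >= rules.stationary_step])
    return float(np.median(steps)) if steps else 0.0


def turnaround_statistics(classified: list[ClassifiedTrajectory],
                          L_um: float = 9.0,
                          edge_correction: bool = True,
                          masking_correction: bool = True,
                          exclude_base_region: bool = True,
                          rules: ClassRules | None = None) -> TurnaroundStats:
    """Turnaround hazards from a classified trajectory set.

    P_AR is the number of anterograde-to-retrograde switches divided by the
    total anterograde distance travelled (um^-1); P_RA symmetrically.  Three
    refinements, all derived from the detection and classification rules
    themselves, are applied by default and recommended for short
    bleach-limited tracks:

    * ``edge_correction`` - the denominators count only distance where a
      switch could have produced a detected extremum (three significant
      steps on each side), otherwise the estimator is biased low.
    * ``masking_correction`` - a switch followed by a re-switch within the
      three-step confirmation distance delta leaves no detectable extremum
      (the pair cancels), so the detected rate is P exp(-P_other delta);
      the pair of hazards is recovered by fixed-point iteration, analogous
      to a dead-time correction.
    * ``exclude_base_region`` - switches at, and distance travelled below,
      the extended base region boundary are left out of both numerator and
      denominator: tracks confined there are classified diffusive rather
      than directed, so keeping that region would condition the sample on
      not having turned.

    Errors are Poisson on counts with delta-method propagation to the run
    lengths 1/P and reach probabilities exp(-P L).
    """
    rules = rules if rules is not None else ClassRules()
    x_min = rules.base_region_max if exclude_base_region else 0.0
    n_ar = sum(1 for c in classified for ev in c.turnarounds
               if ev.direction == "AR" and ev.x_nm > x_min)
    n_ra = sum(1 for c in classified for ev in c.turnarounds
               if ev.direction == "RA" and ev.x_nm > x_min)
    if exclude_base_region:
        d_a = d_r = 0.0
        for c in classified:
            if c.primary_class not in ("anterograde", "retrograde", "turnaround"):
                continue
            turns = c.turnarounds if c.primary_class == "turnaround" else []
            da_f, dr_f, da_c, dr_c = _directed_distances(
                c.trajectory, turns, rules, x_min=x_min)
            d_a += (da_c if edge_correction else da_f) / 1000.0
            d_r += (dr_c if edge_correction else dr_f) / 1000.0
    elif edge_correction:
        d_a = sum(c.d_antero_detect_nm for c in classified) / 1000.0
        d_r = sum(c.d_retro_detect_nm for c in classified) / 1000.0
    else:
        d_a = sum(c.d_antero_nm for c in classified) / 1000.0
        d_r = sum(c.d_retro_nm for c in classified) / 1000.0
    if d_a <= 0 or d_r <= 0:
        raise ValueError("zero directed distance: cannot estimate hazards")
    p_ar, p_ra = n_ar / d_a, n_ra / d_r
    corr_a = corr_r = 1.0
    if masking_correction:
        delta = rules.turn_steps * _median_significant_step(classified, rules) / 1000.0
        if delta > 0:
            for _ in range(25):
                p_ar_new = (n_ar / d_a) * np.exp(p_ra * delta)
                p_ra_new = (n_ra / d_r) * np.exp(p_ar * delta)
                if abs(p_ar_new - p_ar) + abs(p_ra_new - p_ra) < 1e-12:
                    p_ar, p_ra = p_ar_new, p_ra_new
                    break
                p_ar, p_ra = p_ar_new, p_ra_new
            corr_a = np.exp(p_ra * delta)
            corr_r = np.exp(p_ar * delta)
    p_ar_err = np.sqrt(n_ar) / d_a * corr_a
    p_ra_err = np.sqrt(n_ra) / d_r * corr_r
    rl_a = run_length_from_hazard(p_ar)
    rl_r = run_length_from_hazard(p_ra)
    rl_a_err = p_ar_err / p_ar ** 2 if p_ar > 0 else np.inf
    rl_r_err = p_ra_err / p_ra ** 2 if p_ra > 0 else np.inf
    reach_tip = survival_probability(p_ar, L_um)
    reach_base = survival_probability(p_ra, L_um)
    return TurnaroundStats(
        n_ar=n_ar, n_ra=n_ra, d_antero_um=d_a, d_retro_um=d_r,
        p_ar=p_ar, p_ra=p_ra, p_ar_err=p_ar_err, p_ra_err=p_ra_err,
        run_length_antero_um=rl_a, run_length_retro_um=rl_r,
        run_length_antero_err=rl_a_err, run_length_retro_err=rl_r_err,
        reach_tip_prob=reach_tip, reach_base_prob=reach_base,
        reach_tip_err=L_um * reach_tip * p_ar_err,
        reach_base_err=L_um * reach_base * p_ra_err, L_um=L_um)


def pause_statistics(classified: list[ClassifiedTrajectory],
                     location_bin_nm: float = 500.0) -> dict:
    """Pause summaries and turnaround histograms.

    Reports mean/max pause duration across directed trajectories, the
    fraction of trajectories per direction that contain a pause, and
    histograms of turnaround locations (bin width ``location_bin_nm``) and
    of pause durations at turns (binned at the frame interval).
    """
    durations = []
    frac = {}
    for direction in ("anterograde", "retrograde"):
        members = [c for c in classified if c.primary_class == direction]
        with_pause = [c for c in members if c.pauses]
        frac[direction] = len(with_pause) / len(members) if members else 0.0
        durations.extend(t1 - t0 for c in members for t0, t1 in c.pauses)
    turns = [ev for c in classified for ev in c.turnarounds]
    turn_x = np.array([ev.x_nm for ev in turns])
    turn_pause = np.array([ev.pause_s for ev in turns])
    dt = classified[0].trajectory.dt_frame if classified else 0.15
    loc_hist = loc_edges = pp_hist = pp_edges = np.array([])
    if len(turns):
        loc_edges = np.arange(0.0, turn_x.max() + location_bin_nm, location_bin_nm)
        loc_hist, loc_edges = np.histogram(turn_x, bins=loc_edges)
        pp_edges = np.arange(0.0, turn_pause.max() + dt, dt)
        if len(pp_edges) < 2:
            pp_edges = np.array([0.0, dt])
        pp_hist, pp_edges = np.histogram(turn_pause, bins=pp_edges)
    return {"mean_pause_s": float(np.mean(durations)) if durations else np.nan,
            "max_pause_s": float(np.max(durations)) if durations else np.nan,
            "n_pauses": len(durations),
            "pause_fraction": frac,
            "turn_location_hist": (loc_hist, loc_edges),
            "turn_pause_hist": (pp_hist, pp_edges)}
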