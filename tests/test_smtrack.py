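"""Event rules, turnaround detection, classification and hazard statistics."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from iftflow.core import Trajectory
from iftflow.smtrack import (ClassRules, ClassifiedTrajectory, TurnEvent,
                             classify_trajectory, detect_and_link,
                             detect_stationary_segments, detect_turnarounds,
                             filter_events, pause_statistics,
                             project_onto_spline, share_percent,
                             turnaround_statistics)
from iftflow.synthdata import (KineticsConfig, OpticsConfig, render_image_stack,
                               simulate_mixture, simulate_trajectory)

from conftest import make_trajectory

DT = 0.15


class TestEventFilter:
    def test_long_displaced_trajectory_kept(self, rules):
        tr = make_trajectory([0, 100, 200, 250, 300])  # 5 frames, 0.6 s, 300 nm
        kept, rejected = filter_events([tr], rules)
        assert kept == [tr] and rejected == []

    def test_short_trajectory_rejected(self, rules):
        tr = make_trajectory([0, 200, 400])  # 0.3 s
        kept, rejected = filter_events([tr], rules)
        assert kept == [] and rejected[0][1] == "too_short"

    def test_small_displacement_rejected(self, rules):
        tr = make_trajectory([0, 30, 60, 90, 120, 150, 100, 50, 20, 0])
        kept, rejected = filter_events([tr], rules)
        assert kept == [] and rejected[0][1] == "displacement"


class TestStationarySegments:
    def test_constant_trajectory_single_full_interval(self, rules):
        tr = make_trajectory(np.zeros(10))
        assert detect_stationary_segments(tr, rules) == [(0, 9)]

    def test_large_steps_no_interval(self, rules):
        tr = make_trajectory(np.cumsum(np.full(10, 60.0)))
        assert detect_stationary_segments(tr, rules) == []

    def test_interrupted_runs_reported_separately(self, rules):
        steps = [10, 10, 10, 80, 10, 10, 10]
        tr = make_trajectory(np.concatenate([[0.0], np.cumsum(steps)]))
        assert detect_stationary_segments(tr, rules) == [(0, 3), (4, 7)]


class TestTurnarounds:
    def test_constructed_extremum(self, rules):
        tr = make_trajectory([0, 200, 400, 600, 400, 200, 0])
        events = detect_turnarounds(tr, rules)
        assert len(events) == 1
        ev = events[0]
        assert ev.direction == "AR"
        assert ev.x_nm == 600.0
        assert ev.pause_s == 0.0

    def test_monotone_trajectory_no_turns(self, rules):
        tr = make_trajectory(np.arange(10) * 200.0)
        assert detect_turnarounds(tr, rules) == []

    def test_pause_at_turn_counted(self, rules):
        x = [0, 200, 400, 600, 800, 800, 800, 800, 600, 400, 200, 0]
        events = detect_turnarounds(make_trajectory(x), rules)
        assert len(events) == 1
        assert events[0].pause_s == pytest.approx(3 * DT)
        assert events[0].x_nm == 800.0

    def test_subthreshold_steps_do_not_break_runs(self, rules):
        x = [0, 200, 230, 430, 630, 430, 230, 30]
        events = detect_turnarounds(make_trajectory(x), rules)
        assert len(events) == 1 and events[0].direction == "AR"

    @given(st.lists(st.sampled_from([-200.0, -100.0, 0.0, 100.0, 200.0]),
                    min_size=7, max_size=25))
    def test_mirror_swaps_directions(self, steps):
        rules = ClassRules(dt_frame=DT)
        x = np.concatenate([[0.0], np.cumsum(steps)])
        ev = detect_turnarounds(make_trajectory(x), rules)
        ev_m = detect_turnarounds(make_trajectory(9000.0 - x), rules)
        assert [e.frame for e in ev] == [e.frame for e in ev_m]
        swap = {"AR": "RA", "RA": "AR"}
        assert [swap[e.direction] for e in ev] == [e.direction for e in ev_m]


class TestClassification:
    def test_noiseless_anterograde(self, rules):
        cfg = KineticsConfig(p_ar=0.0, p_ra=0.0, pause_rate=0.0, sigma_loc=0.0)
        g = simulate_trajectory(cfg, "anterograde", seed=0, x0=2000.0,
                                duration=1.5)
        c = classify_trajectory(g.trajectory, rules)
        assert c.primary_class == "anterograde"
        # for noiseless directed motion distance equals path length exactly
        assert c.d_antero_nm == pytest.approx(
            np.sum(np.abs(np.diff(g.trajectory.x))))

    def test_planted_switch_is_turnaround(self, rules):
        cfg = KineticsConfig(sigma_loc=0.0, class_fractions={
            "anterograde": 0.5, "turnaround": 0.5})
        g = simulate_trajectory(cfg, "turnaround", seed=1, duration=2.0)
        c = classify_trajectory(g.trajectory, rules)
        assert c.primary_class == "turnaround"
        true_dir = "AR" if (g.events["event"] == "turn_AR").any() else "RA"
        assert [ev.direction for ev in c.turnarounds] == [true_dir]

    def test_time_reversal_swaps_directed_labels(self, rules):
        cfg = KineticsConfig(p_ar=0.0, p_ra=0.0, pause_rate=0.0)
        g = simulate_trajectory(cfg, "anterograde", seed=2, x0=2000.0,
                                duration=1.5)
        tr = g.trajectory
        rev = Trajectory(t=tr.t, x=tr.x[::-1].copy(), y=tr.y, dt_frame=tr.dt_frame)
        assert classify_trajectory(tr, rules).primary_class == "anterograde"
        assert classify_trajectory(rev, rules).primary_class == "retrograde"

    def test_class_shares_recovered_on_published_mixture(self, rules):
        # 37/27/16/12/8% anterograde/retrograde/base/stationary/turnaround
        cfg = KineticsConfig(class_fractions={
            "anterograde": 0.37, "retrograde": 0.27, "base": 0.16,
            "stationary": 0.12, "turnaround": 0.08})
        gen = simulate_mixture(cfg, 2000, seed=19)
        true = {}
        rec = {}
        for g in gen:
            true[g.true_class] = true.get(g.true_class, 0) + 1
            c = classify_trajectory(g.trajectory, rules).primary_class
            rec[c] = rec.get(c, 0) + 1
        for cls in true:
            assert abs(rec.get(cls, 0) - true[cls]) / 20.0 <= 3.0


class TestTurnaroundStatistics:
    @staticmethod
    def _dummy(n_ar, n_ra, d_a_um, d_r_um):
        tr = make_trajectory(np.arange(8) * 200.0)
        events = [TurnEvent("AR", 4, 0.6, 500.0, 0.0)] * n_ar + \
                 [TurnEvent("RA", 4, 0.6, 500.0, 0.0)] * n_ra
        return [ClassifiedTrajectory(trajectory=tr, primary_class="turnaround",
                                     turnarounds=events,
                                     d_antero_detect_nm=d_a_um * 1000.0,
                                     d_retro_detect_nm=d_r_um * 1000.0,
                                     d_antero_nm=d_a_um * 1000.0,
                                     d_retro_nm=d_r_um * 1000.0)]

    def test_published_count_arithmetic(self):
        # plain N/D arithmetic on the printed counts, no estimator corrections
        st_ = turnaround_statistics(self._dummy(34, 4, 242.9, 57.1), L_um=9.0,
                                    masking_correction=False,
                                    exclude_base_region=False)
        assert st_.p_ar == pytest.approx(0.140, abs=0.0005)
        assert st_.p_ar_err == pytest.approx(np.sqrt(34) / 242.9, rel=1e-9)
        assert st_.p_ra == pytest.approx(0.070, abs=0.0005)
        assert st_.run_length_antero_um == pytest.approx(1 / st_.p_ar)
        assert round(st_.reach_tip_prob * 100) == 28
        assert round(st_.reach_base_prob * 100) == 53

    def test_zero_turns_give_zero_hazard_and_unit_reach(self):
        st_ = turnaround_statistics(self._dummy(0, 0, 100.0, 100.0), L_um=9.0,
                                    exclude_base_region=False)
        assert st_.p_ar == 0.0 and st_.reach_tip_prob == 1.0

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            turnaround_statistics(self._dummy(1, 1, 0.0, 10.0),
                                  exclude_base_region=False)

    @pytest.mark.parametrize("p_ar,p_ra,seed", [(0.05, 0.05, 1), (0.14, 0.07, 2),
                                                (0.3, 0.14, 3), (0.07, 0.3, 5)])
    def test_estimator_consistency_across_hazards(self, rules, p_ar, p_ra, seed):
        cfg = KineticsConfig(p_ar=p_ar, p_ra=p_ra)
        gen = simulate_mixture(cfg, 600, seed=seed)
        classified = [classify_trajectory(g.trajectory, rules) for g in gen]
        st_ = turnaround_statistics(classified, L_um=9.0)
        assert abs(st_.p_ar - p_ar) <= 2.5 * max(st_.p_ar_err, 0.01)
        assert abs(st_.p_ra - p_ra) <= 2.5 * max(st_.p_ra_err, 0.01)


class TestPauses:
    def test_single_pause_mean(self, rules):
        tr = make_trajectory([0, 200, 400, 600, 610, 620, 615, 800, 1000, 1200])
        c = classify_trajectory(tr, rules)
        stats = pause_statistics([c])
        assert stats["n_pauses"] == 1
        assert stats["mean_pause_s"] == pytest.approx(0.45)

    def test_pauseless_set_has_zero_fraction(self, rules):
        tr = make_trajectory(np.arange(8) * 255.0)
        stats = pause_statistics([classify_trajectory(tr, rules)])
        assert stats["pause_fraction"]["anterograde"] == 0.0
        assert stats["n_pauses"] == 0

    def test_generator_pause_durations_match_truth(self, rules):
        # detected pauses are matched one-to-one against the generator's
        # event log; durations agree within the frame quantization and the
        # recovered mean tracks the mean of the matched true pauses
        cfg = KineticsConfig(pause_rate=2.0, pause_mean=0.7, sigma_loc=10.0,
                             p_ar=0.0, p_ra=0.0, duration_mean_extra=2.0,
                             duration_max=8.0)
        rng = np.random.default_rng(31)
        det, tru = [], []
        for i in range(500):
            g = simulate_trajectory(cfg, "anterograde", seed=rng)
            c = classify_trajectory(g.trajectory, rules)
            ev = g.events
            starts = ev[ev["event"] == "pause_start"]["t_s"].to_numpy()
            ends = ev[ev["event"] == "pause_end"]["t_s"].to_numpy()
            for t0, t1 in c.pauses:
                hit = [(s, e) for s, e in zip(starts, ends)
                       if s < t1 and e > t0]
                if len(hit) == 1:
                    det.append(t1 - t0)
                    tru.append(hit[0][1] - hit[0][0])
        det, tru = np.array(det), np.array(tru)
        assert len(det) > 100
        assert np.mean(np.abs(det - tru)) <= 1.5 * cfg.dt_frame
        assert abs(np.mean(det) - np.mean(tru)) <= 1.5 * cfg.dt_frame


class TestDetectionAndProjection:
    def test_single_bright_motor_tracked(self):
        cfg = KineticsConfig(p_ar=0.0, p_ra=0.0, pause_rate=0.0, sigma_loc=0.0)
        optics = OpticsConfig(photons_per_frame=2000.0, background_rate=5.0)
        g = simulate_trajectory(cfg, "anterograde", seed=5, x0=2000.0,
                                duration=2.0)
        stack = render_image_stack([g.trajectory], optics, duration=2.0,
                                   L=cfg.L, seed=7)
        trajs = detect_and_link(stack, optics.pixel_size, cfg.dt_frame)
        assert len(trajs) == 1
        tr = trajs[0]
        x_true = g.trajectory.x_true[:len(tr)] + 200.0  # spline offset 2 px
        rms = np.sqrt(np.mean((tr.x - x_true) ** 2))
        assert rms <= 40.0

    def test_blank_stack_no_trajectories(self):
        stack = np.full((10, 15, 40), 5.0)
        assert detect_and_link(stack, 100.0, DT) == []

    def test_two_separated_motors_two_tracks(self):
        cfg = KineticsConfig(p_ar=0.0, p_ra=0.0, pause_rate=0.0, sigma_loc=0.0)
        optics = OpticsConfig(photons_per_frame=2000.0, background_rate=5.0)
        g1 = simulate_trajectory(cfg, "anterograde", seed=8, x0=500.0,
                                 duration=2.0)
        g2 = simulate_trajectory(cfg, "anterograde", seed=9, x0=3000.0,
                                 duration=2.0)
        stack = render_image_stack([g1.trajectory, g2.trajectory], optics,
                                   duration=2.0, L=cfg.L, seed=10)
        trajs = detect_and_link(stack, optics.pixel_size, cfg.dt_frame)
        full = [t for t in trajs if len(t) >= 12]
        assert len(full) == 2

    def test_straight_spline_identity(self):
        tr = Trajectory(t=np.arange(5) * DT,
                        x=np.array([0.0, 500.0, 1000.0, 1500.0, 2000.0]),
                        y=np.full(5, 700.0), dt_frame=DT)
        spline = np.column_stack([np.full(20, 7.0), np.linspace(0, 50, 20)])
        proj, out = project_onto_spline(tr, spline, pixel_size=100.0)
        np.testing.assert_allclose(proj.x, tr.x, atol=15.0)  # dense-sample step
        np.testing.assert_allclose(proj.y, 0.0, atol=2.0)
        assert not out.any()

    def test_quarter_circle_arc_length(self):
        R = 3000.0  # nm
        theta = np.linspace(0, np.pi / 2, 50)
        spline = np.column_stack([R / 100.0 * (1 - np.cos(theta)),
                                  R / 100.0 * np.sin(theta)]) + 10.0
        # points on the arc at known arc lengths
        th_pts = np.array([0.2, 0.6, 1.0, 1.4])
        pts_row = (R * (1 - np.cos(th_pts))) / 100.0 + 10.0
        pts_col = (R * np.sin(th_pts)) / 100.0 + 10.0
        tr = Trajectory(t=np.arange(4) * DT, x=pts_col * 100.0,
                        y=pts_row * 100.0, dt_frame=DT)
        proj, out = project_onto_spline(tr, spline, pixel_size=100.0)
        np.testing.assert_allclose(proj.x, R * th_pts, rtol=0.01)
        assert not out.any()

    def test_far_point_flagged(self):
        tr = Trajectory(t=np.arange(2) * DT, x=np.array([100.0, 200.0]),
                        y=np.array([0.0, 5000.0]), dt_frame=DT)
        spline = np.column_stack([np.zeros(10), np.linspace(0, 30, 10)])
        _, out = project_onto_spline(tr, spline, 100.0, tube_radius_nm=1000.0)
        assert out.tolist() == [False, True]


class TestShares:
    def test_published_share_arithmetic(self):
        assert share_percent(182, 494) == 37
        assert share_percent(34, 38) == 89

    def test_invalid_total(self):
        with pytest.raises(ValueError):
            share_percent(1, 0)
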