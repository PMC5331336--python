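"""Kymograph analysis: directional separation, traces, profiles, flux."""

import dataclasses

import numpy as np
import pytest

from iftflow.core import Kymograph
from iftflow.kymo import (build_kymograph, compute_flux, detect_train_peaks,
                          extract_train_traces, fourier_directional_filter,
                          intensity_to_motor_count, position_velocity_profile,
                          train_frequencies)
from iftflow.synthdata import (KineticsConfig, OpticsConfig, render_kymograph,
                               simulate_train_set, straight_spline,
                               render_image_stack)

from conftest import line_trajectory

L = 9000.0
DT = 0.15


def _shift(tr, t0):
    from iftflow.core import Trajectory
    k0 = round(t0 / tr.dt_frame)
    return Trajectory(t=tr.t + k0 * tr.dt_frame, x=tr.x, y=tr.y, id=tr.id,
                      dt_frame=tr.dt_frame)


def render_lines(trajs, duration=6.0, **opt):
    optics = OpticsConfig(shot_noise=False, background_rate=0.0, **opt)
    return render_kymograph(trajs, optics, duration=duration, L=L)


class TestBuildKymograph:
    def test_immobile_emitter_gives_vertical_line(self):
        optics = OpticsConfig(shot_noise=False, background_rate=0.0)
        tr = line_trajectory(4000.0, 0.0, 3.0)
        stack = render_image_stack([tr], optics, duration=3.0, L=L)
        spline = straight_spline(L, optics.pixel_size,
                                 y0_px=stack.shape[1] / 2.0, x0_px=2.0)
        kym = build_kymograph(stack, spline, optics.pixel_size, DT)
        cols = kym.I.argmax(axis=1)
        assert np.all(cols == cols[0])

    def test_moving_emitter_slope(self):
        optics = OpticsConfig(shot_noise=False, background_rate=0.0)
        tr = line_trajectory(500.0, 1700.0, 3.0)
        stack = render_image_stack([tr], optics, duration=3.0, L=L)
        spline = straight_spline(L, optics.pixel_size,
                                 y0_px=stack.shape[1] / 2.0, x0_px=2.0)
        kym = build_kymograph(stack, spline, optics.pixel_size, DT)
        x = kym.I.argmax(axis=1) * kym.dx_pixel
        v = np.polyfit(np.arange(kym.n_frames) * DT, x, 1)[0]
        assert abs(v - 1700.0) / 1700.0 < 0.05

    def test_spline_outside_image_raises(self):
        stack = np.zeros((3, 10, 10))
        spline = np.array([[5.0, -5.0], [5.0, 20.0]])
        with pytest.raises(ValueError):
            build_kymograph(stack, spline, 100.0, DT)


class TestDirectionalFilter:
    def test_pure_anterograde_energy_partition(self):
        kym = render_lines([line_trajectory(0.0, 1700.0, 5.3)])
        a, r, s = fourier_directional_filter(kym)
        ea, er = (a.I ** 2).sum(), (r.I ** 2).sum()
        assert ea / (ea + er) >= 0.95

    def test_time_constant_goes_to_static(self):
        kym = render_lines([line_trajectory(4000.0, 0.0, 6.0)])
        a, r, s = fourier_directional_filter(kym)
        assert (s.I ** 2).sum() / (kym.I ** 2).sum() > 0.999
        assert np.allclose(a.I, 0.0, atol=1e-6 * kym.I.max())
        assert np.allclose(r.I, 0.0, atol=1e-6 * kym.I.max())

    def test_two_line_slope_recovery(self):
        kym = render_lines([line_trajectory(0.0, 1700.0, 5.3),
                            line_trajectory(L, -1700.0, 5.3, tid=1)])
        a, r, s = fourier_directional_filter(kym)
        ta = extract_train_traces(a)
        tr = extract_train_traces(r)
        assert len(ta) == 1 and len(tr) == 1
        assert abs(ta[0].velocity - 1700.0) / 1700.0 < 0.05
        assert abs(tr[0].velocity + 1700.0) / 1700.0 < 0.05

    def test_reconstruction_conserves_input(self):
        rng = np.random.default_rng(0)
        cfg = KineticsConfig()
        groups = simulate_train_set(cfg, 20.0, freq_antero=0.8, freq_retro=1.2,
                                    seed=rng)
        kym = render_kymograph(groups, OpticsConfig(shot_noise=False,
                                                    background_rate=0.0),
                               duration=20.0, L=L)
        a, r, s = fourier_directional_filter(kym)
        resid = np.linalg.norm(a.I + r.I + s.I - kym.I) / np.linalg.norm(kym.I)
        assert resid < 0.05

    def test_non_finite_input_rejected(self):
        bad = Kymograph(np.full((10, 10), np.nan), DT, 100.0)
        with pytest.raises(ValueError):
            fourier_directional_filter(bad)


class TestTraces:
    def test_blank_kymograph_gives_no_traces(self):
        kym = Kymograph(np.zeros((20, 40)), DT, 100.0)
        assert extract_train_traces(kym) == []

    def test_two_parallel_lines_give_two_traces(self):
        # parallel anterograde lines separated by ~6 sigma_psf
        kym = render_lines([line_trajectory(0.0, 1700.0, 5.3),
                            line_trajectory(1000.0, 1700.0, 4.5, tid=1)])
        traces = extract_train_traces(kym)
        assert len(traces) == 2
        for t in traces:
            assert abs(t.velocity - 1700.0) / 1700.0 < 0.05


class TestVelocityProfile:
    def test_constant_speed_flat_profile(self):
        traces = extract_train_traces(render_lines(
            [line_trajectory(0.0, 1700.0, 5.3)]))
        prof = position_velocity_profile(traces, L=L)
        good = prof["n"] >= 2
        assert np.all(np.abs(prof["mean"][good] - 1700.0) / 1700.0 < 0.05)

    def test_two_point_trace_exact(self):
        from iftflow.kymo import TrainTrace
        tr = TrainTrace(t=np.array([0.0, DT]), x=np.array([0.0, 300.0]),
                        intensity=np.array([1.0, 1.0]))
        prof = position_velocity_profile([tr], L=1000.0, bin_nm=1000.0)
        v = prof["mean"][prof["n"] > 0]
        assert v[0] == pytest.approx(300.0 / DT)

    def test_transition_zone_dip_location(self):
        cfg = KineticsConfig()
        groups = simulate_train_set(cfg, 30.0, freq_antero=1.0, freq_retro=0.0,
                                    seed=3)
        kym = render_kymograph(groups, OpticsConfig(shot_noise=False,
                                                    background_rate=0.0),
                               duration=30.0, L=L)
        a, _, _ = fourier_directional_filter(kym)
        prof = position_velocity_profile(extract_train_traces(a), L=L)
        sel = (prof["x_nm"] < 2500) & (prof["n"] >= 5)
        dip = prof["x_nm"][sel][np.nanargmin(prof["mean"][sel])]
        assert abs(dip - 1000.0) <= 250.0  # within one bin of the true dip

    def test_empty_traces_rejected(self):
        with pytest.raises(ValueError):
            position_velocity_profile([])


class TestMotorCounts:
    def test_two_subunit_arithmetic(self):
        assert intensity_to_motor_count(2.0, 1.0) == pytest.approx(1.0)
        assert intensity_to_motor_count(80.0, 1.0) == pytest.approx(40.0)

    def test_rendered_train_count_recovered(self):
        optics = OpticsConfig(shot_noise=True, background_rate=0.0,
                              photons_per_frame=500.0)
        tr = line_trajectory(0.0, 1700.0, 5.3)
        kym = render_kymograph([tr], optics, duration=6.0, L=L,
                               weights=[25.0], seed=8)
        # per-fluorophore peak contribution of this renderer
        per_motor = optics.photons_per_frame * optics.pixel_size / \
            (optics.psf_sigma * np.sqrt(2 * np.pi))
        i_single = per_motor / 2.0
        peak = np.median(kym.I.max(axis=1))
        count = intensity_to_motor_count(peak, i_single)
        assert abs(count - 25.0) / 25.0 < 0.10

    def test_nonpositive_calibration_rejected(self):
        with pytest.raises(ValueError):
            intensity_to_motor_count(5.0, 0.0)


class TestPeaksAndFrequency:
    def test_five_separated_bumps(self):
        t = np.arange(200) * DT
        series = sum(np.exp(-0.5 * ((t - c) / 0.4) ** 2)
                     for c in (3, 9, 15, 21, 27))
        times, freq = detect_train_peaks(series, DT)
        assert len(times) == 5
        assert freq == pytest.approx(5 / (200 * DT))

    def test_flat_series_has_no_peaks(self):
        times, freq = detect_train_peaks(np.ones(50), DT)
        assert len(times) == 0 and freq == 0.0

    def test_departure_frequency_ratio_recovered(self):
        cfg = KineticsConfig()
        duration = 150.0
        groups = simulate_train_set(cfg, duration, freq_antero=0.5,
                                    freq_retro=0.8, seed=21)
        kym = render_kymograph(groups, OpticsConfig(shot_noise=False,
                                                    background_rate=0.0),
                               duration=duration, L=L)
        a, r, _ = fourier_directional_filter(kym)
        out = train_frequencies(a, r, x_nm=4500.0)
        n_a = out["antero"] * duration
        n_r = out["retro"] * duration
        se = out["ratio_retro_antero"] * np.sqrt(1 / n_a + 1 / n_r)
        assert abs(out["ratio_retro_antero"] - 1.6) < 3 * se


class TestFlux:
    def test_equal_throughput_gives_equal_flux(self):
        # equal motor throughput: 45-motor trains at f vs 25-motor at 1.8 f,
        # regular departures so the truth is exactly balanced
        duration = 120.0
        trajs, weights = [], []
        for i, t0 in enumerate(np.arange(0.0, duration, 2.0)):
            trajs.append(line_trajectory(0.0, 1700.0, 5.3, tid=i, ))
            trajs[-1] = _shift(trajs[-1], t0)
            weights.append(45.0)
        for i, t0 in enumerate(np.arange(0.0, duration, 10.0 / 9.0)):
            tr = _shift(line_trajectory(L, -1700.0, 5.3, tid=100 + i), t0)
            trajs.append(tr)
            weights.append(25.0)
        kym = render_kymograph(trajs, OpticsConfig(shot_noise=False,
                                                   background_rate=0.0),
                               duration=duration, L=L, weights=weights)
        from iftflow.kymo import assign_moving_intensity
        a, r, _ = fourier_directional_filter(kym)
        ka, kr = assign_moving_intensity(kym, a, r)
        v = np.full(kym.n_pixels, 1700.0)
        fa = compute_flux(ka, v, i_single_fluor=1.0)
        fr = compute_flux(kr, v, i_single_fluor=1.0)
        sel = (kym.x_nm > 2000) & (kym.x_nm < 7000)
        ratio = fa.flux[sel].sum() / fr.flux[sel].sum()
        assert abs(ratio - 1.0) < 0.10

    def test_blank_kymograph_zero_flux(self):
        kym = Kymograph(np.zeros((20, 30)), DT, 100.0)
        fp = compute_flux(kym, np.full(30, 1700.0), i_single_fluor=1.0)
        assert np.all(fp.flux == 0.0)

    def test_flux_linear_in_motor_number(self):
        tr = line_trajectory(0.0, 1700.0, 5.3)
        optics = OpticsConfig(shot_noise=False, background_rate=0.0)
        k1 = render_kymograph([tr], optics, duration=6.0, L=L, weights=[20.0])
        k2 = render_kymograph([tr], optics, duration=6.0, L=L, weights=[40.0])
        v = np.full(k1.n_pixels, 1700.0)
        f1 = compute_flux(k1, v, 1.0)
        f2 = compute_flux(k2, v, 1.0)
        np.testing.assert_allclose(f2.flux, 2 * f1.flux, rtol=1e-9)

    def test_flux_invariant_under_joint_rescaling(self):
        tr = line_trajectory(0.0, 1700.0, 5.3)
        optics = OpticsConfig(shot_noise=False, background_rate=0.0)
        k = render_kymograph([tr], optics, duration=6.0, L=L)
        v = np.full(k.n_pixels, 1700.0)
        f1 = compute_flux(k, v, 2.0)
        k5 = k.copy_with(5.0 * k.I)
        f5 = compute_flux(k5, v, 10.0)
        np.testing.assert_allclose(f5.flux, f1.flux, rtol=1e-9)

    def test_grid_mismatch_rejected(self):
        kym = Kymograph(np.zeros((10, 30)), DT, 100.0)
        with pytest.raises(ValueError):
            compute_flux(kym, np.ones(10), 1.0)
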