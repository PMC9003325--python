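"""Single-accelerometer event detector, stage by stage."""

import numpy as np
import pytest

import gaitinit as gi
from gaitinit.errors import DetectionError, WindowError
from gaitinit.imu_events import (AlgorithmWindows, detect_apa_change,
                                 detect_apa_onset_axis, detect_heel_strike_imu,
                                 detect_toe_off_imu, find_vertical_peaks,
                                 locate_first_step_peak, select_peak_va_max)
from conftest import zero_noise_spec

FS = 50.0
T_S = 1.0


def brute_force_change_index(seg: np.ndarray, x: np.ndarray,
                             model: str = "line") -> int:
    """Independent exhaustive SSE scan with polyfit line fits."""
    n = len(seg)
    best, best_k = np.inf, None
    deg = 1 if model == "line" else 0
    for k in range(3, n - 2):
        sse = 0.0
        for xx, yy in ((x[:k], seg[:k]), (x[k:], seg[k:])):
            coef = np.polyfit(xx, yy, deg)
            sse += float(np.sum((yy - np.polyval(coef, xx)) ** 2))
        if sse < best - 1e-12:
            best, best_k = sse, k
    return best_k


class TestApaChange:
    def test_matches_brute_force_on_random_signals(self, rng):
        """Production change-point equals an independent exhaustive scan."""
        window = (-0.5, 1.2)
        for _ in range(100):
            n_total = int(3.5 * FS)
            sig = rng.normal(size=n_total)
            if rng.random() < 0.5:   # add a structured break
                b = rng.integers(int(0.7 * FS), int(2.0 * FS))
                sig[b:] += rng.normal(0, 2) + rng.normal(0, 3) * (
                    np.arange(n_total - b) / FS)
            t_change = detect_apa_change(sig, FS, T_S, window)
            seg, i0 = gi.slice_window(sig, FS, T_S + window[0], T_S + window[1])
            x = (i0 + np.arange(len(seg))) / FS
            k_oracle = brute_force_change_index(seg, x)
            assert int(round(t_change * FS)) - i0 == k_oracle

    def test_ramp_onset_located(self):
        t = np.arange(int(3.5 * FS)) / FS
        sig = np.where(t > 1.0, (t - 1.0) * 1.0, 0.0)
        t_change = detect_apa_change(sig, FS, T_S, (-0.5, 1.2))
        assert abs(t_change - 1.0) <= 1.0 / FS

    def test_step_in_mean_located(self):
        t = np.arange(int(3.5 * FS)) / FS
        k = int(1.3 * FS)
        sig = np.zeros_like(t)
        sig[k:] = 1.0
        t_change = detect_apa_change(sig, FS, T_S, (-0.5, 1.2))
        assert abs(t_change - k / FS) <= 1.0 / FS

    def test_pure_line_degenerates_to_earliest_split(self):
        t = np.arange(int(3.5 * FS)) / FS
        t_change = detect_apa_change(0.3 + 2.0 * t, FS, T_S, (-0.5, 1.2))
        seg, i0 = gi.slice_window(0.3 + 2.0 * t, FS, T_S - 0.5, T_S + 1.2)
        assert int(round(t_change * FS)) == i0 + 3   # earliest admissible

    def test_mean_model_variant(self, rng):
        sig = rng.normal(size=int(3.5 * FS))
        sig[int(1.5 * FS):] += 4.0
        t_change = detect_apa_change(sig, FS, T_S, (-0.5, 1.2), model="mean")
        seg, i0 = gi.slice_window(sig, FS, T_S - 0.5, T_S + 1.2)
        x = (i0 + np.arange(len(seg))) / FS
        assert int(round(t_change * FS)) - i0 == brute_force_change_index(
            seg, x, model="mean")

    def test_too_few_samples(self):
        with pytest.raises(WindowError):
            detect_apa_change(np.zeros(40), 4.0, 1.0, (-0.5, 0.6))


class TestApaOnsetAxis:
    def _vshape(self, t_min):
        t = np.arange(int(3.0 * FS)) / FS
        return np.abs(t - t_min)

    def test_unique_local_minimum_found(self):
        onset, flag = detect_apa_onset_axis(self._vshape(0.9), FS, 1.1, T_S)
        assert not flag and onset == pytest.approx(0.9, abs=1 / FS)

    def test_first_minimum_walking_backwards(self):
        t = np.arange(int(3.0 * FS)) / FS
        sig = np.minimum(np.abs(t - 0.6), np.abs(t - 0.95)) + 0.05 * (t - 0.8) ** 2
        onset, flag = detect_apa_onset_axis(sig, FS, 1.1, T_S)
        assert not flag and onset == pytest.approx(0.95, abs=1.5 / FS)

    def test_monotone_signal_flags_window_start(self):
        t = np.arange(int(3.0 * FS)) / FS
        onset, flag = detect_apa_onset_axis(t.copy(), FS, 1.1, T_S)
        assert flag
        assert onset == pytest.approx(max(1.1 - T_S, 1 / FS), abs=1.5 / FS)

    def test_change_outside_trial_raises(self):
        with pytest.raises(WindowError):
            detect_apa_onset_axis(np.zeros(100), FS, 5.0, T_S)


class TestVerticalPeaks:
    def test_peaks_above_percentile_threshold(self):
        fs = 100.0
        t = np.arange(300) / fs
        sig = (0.5 * np.exp(-0.5 * ((t - 1.0) / 0.05) ** 2)
               + 2.0 * np.exp(-0.5 * ((t - 2.0) / 0.05) ** 2))
        peaks = find_vertical_peaks(sig, fs, (0.5, 2.9))
        seg, _ = gi.slice_window(sig, fs, 0.5, 2.9)
        tau1 = 0.01 * (np.percentile(seg, 90) - np.percentile(seg, 10))
        assert len(peaks) == 2
        assert all(a > tau1 for _, a in peaks)
        assert peaks[0][1] == pytest.approx(0.5, rel=0.01)
        assert peaks[1][1] == pytest.approx(2.0, rel=0.01)

    def test_flat_signal_yields_empty_list(self):
        assert find_vertical_peaks(np.zeros(500), 100.0, (0.5, 4.0)) == []

    def test_triangular_peak_apex(self):
        fs = 100.0
        t = np.arange(300) / fs
        sig = np.maximum(0.0, 1.0 - np.abs(t - 1.5) / 0.3)
        peaks = find_vertical_peaks(sig, fs, (0.5, 2.5))
        assert len(peaks) == 1
        assert peaks[0][0] == pytest.approx(1.5, abs=1 / fs)


class TestPeakVaMax:
    def test_max_above_quarter_p95(self):
        window = np.concatenate([np.zeros(400), [1.0, 3.0, 2.0]])
        tau2 = 0.25 * np.percentile(window, 95)
        peaks = [(1.0, 1.0), (2.0, 3.0), (3.0, 2.0)]
        t, a = select_peak_va_max(peaks, window)
        assert a == 3.0 and t == 2.0 and a > tau2

    def test_no_peak_above_threshold_errors(self):
        window = np.full(100, 10.0)      # tau2 = 2.5, peaks all below
        with pytest.raises(DetectionError, match="no Peak_va_max"):
            select_peak_va_max([(1.0, 0.5), (2.0, 1.0)], window)

    def test_tie_broken_to_earliest(self):
        window = np.zeros(100)
        t, a = select_peak_va_max([(1.0, 2.0), (2.0, 2.0)], window)
        assert t == 1.0


class TestFirstStepPeak:
    def test_peak_closest_to_window_closure(self):
        fs = 100.0
        t = np.arange(500) / fs
        sig = (np.exp(-0.5 * ((t - 1.2) / 0.04) ** 2)
               + np.exp(-0.5 * ((t - 1.45) / 0.04) ** 2))
        tp, _ = locate_first_step_peak(sig, fs, peak_va_max_time=2.0)
        assert tp == pytest.approx(1.45, abs=1 / fs)

    def test_no_peak_in_window_errors(self):
        with pytest.raises(DetectionError, match="first-step"):
            locate_first_step_peak(np.zeros(500), 100.0, peak_va_max_time=3.0)


class TestToeOffCrossing:
    def test_symmetric_straddle_interpolates_midpoint(self):
        fs = 140.0
        sig = np.zeros(500)
        k = 176
        sig[:k + 1] = -0.2
        sig[k + 1:] = 0.2
        t = detect_toe_off_imu(sig, fs, i_peak_fs=2.0, search_start=0.5)
        assert t == pytest.approx((k + 0.5) / fs, abs=1e-9)

    def test_asymmetric_straddle_75_percent(self):
        fs = 140.0
        sig = np.zeros(500)
        k = 176
        sig[:k + 1] = -0.3
        sig[k + 1:] = 0.1
        t = detect_toe_off_imu(sig, fs, i_peak_fs=2.0, search_start=0.5)
        assert t == pytest.approx((k + 0.75) / fs, abs=1e-9)

    def test_all_positive_signal_errors(self):
        with pytest.raises(DetectionError, match="toe-off"):
            detect_toe_off_imu(np.ones(500), 140.0, i_peak_fs=2.0,
                               search_start=0.5)


class TestHeelStrikeCrossing:
    def test_linear_rise_crossing_solved_analytically(self):
        fs = 1000.0
        to, ipk, peak = 1.0, 2.2, 1.0
        t = np.arange(int(3 * fs)) / fs
        # linear from -0.2*peak at to to peak at ipk: crosses 0.2*peak at
        # to + (0.4/1.2)*(ipk-to)
        sig = -0.2 * peak + 1.2 * peak * (t - to) / (ipk - to)
        ths = detect_heel_strike_imu(sig, fs, to, ipk, peak)
        assert ths == pytest.approx(to + (0.4 / 1.2) * (ipk - to), abs=2 / fs)

    def test_signal_always_above_level_errors(self):
        with pytest.raises(DetectionError, match="heel-strike"):
            detect_heel_strike_imu(np.ones(500), 140.0, 1.0, 2.0, 1.0)


class TestFullImuPipeline:
    def test_zero_noise_round_trip_pd(self, pd_trial_pair):
        spec, accel, _ = pd_trial_pair
        ev, trace = gi.detect_events_imu(accel, gi.EXTENDED_WINDOWS)
        for got, want in ((ev.apa_onset_s, spec.t_apa),
                          (ev.toe_off_s, spec.t_to),
                          (ev.heel_strike_s, spec.t_hs)):
            assert got == pytest.approx(want, abs=1 / accel.fs)

    def test_event_ordering_enforced(self, pd_trial_pair):
        _, accel, _ = pd_trial_pair
        ev, trace = gi.detect_events_imu(accel, gi.EXTENDED_WINDOWS)
        assert 0 < ev.apa_onset_s < ev.toe_off_s < ev.heel_strike_s
        assert trace.hs_swl <= trace.i_peak_fs

    def test_overall_onset_is_min_over_valid_axes(self, pd_trial_pair):
        _, accel, _ = pd_trial_pair
        onset, trace = gi.detect_apa_onset(accel, gi.EXTENDED_WINDOWS)
        valid = [trace.apa_onset_per_axis[ax] for ax in ("ap", "ml", "v")
                 if trace.apa_axis_flags[ax] == "ok"]
        assert onset == min(valid)

    def test_shift_equivariance(self):
        """Shifting the stimulus shifts absolute times, not relative ones."""
        base = zero_noise_spec(0.45, 1.26, 1.73, t_s=1.0)
        shifted = zero_noise_spec(0.45, 1.26, 1.73, t_s=1.5)
        ev0, _ = gi.detect_events_imu(gi.synthesize_accel(base),
                                      gi.EXTENDED_WINDOWS)
        ev1, _ = gi.detect_events_imu(gi.synthesize_accel(shifted),
                                      gi.EXTENDED_WINDOWS)
        for a, b in ((ev0.apa_onset_s, ev1.apa_onset_s),
                     (ev0.toe_off_s, ev1.toe_off_s),
                     (ev0.heel_strike_s, ev1.heel_strike_s)):
            assert a == pytest.approx(b, abs=1.5 / 140.0)

    def test_flat_trial_fails_atomically(self):
        n = 840
        z = np.zeros(n)
        trial = gi.TriaxialAccelTrial("flat", "s", 140.0, 1.0, z, z, z)
        with pytest.raises(DetectionError):
            gi.detect_events_imu(trial, gi.EXTENDED_WINDOWS)

    def test_amplitude_invariance_of_timing(self):
        evs = []
        for amp in (1.0, 2.0):
            spec = zero_noise_spec(0.45, 1.26, 1.73, apa_amp=amp)
            ev, _ = gi.detect_events_imu(gi.synthesize_accel(spec),
                                         gi.EXTENDED_WINDOWS)
            evs.append(ev)
        assert evs[0].apa_onset_s == pytest.approx(evs[1].apa_onset_s,
                                                   abs=1 / 140.0)

    def test_windows_validation(self):
        with pytest.raises(ValueError):
            AlgorithmWindows(w_apa=(1.2, -0.5))
        with pytest.raises(ValueError):
            AlgorithmWindows(w_first_step=(-1.5, 0.5))
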