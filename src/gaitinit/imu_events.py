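"""Single lower-back-accelerometer gait-initiation event detector.

Three instants are extracted from a band-pass-filtered (0.2–4.5 Hz) triaxial
trunk acceleration trial:

* **APA onset** — per axis, a two-piece straight-line fit locates the sample
  (``APA_change``) where the signal mean and slope change (the split
  minimising the summed residual error inside a window from 0.5 s before to
  1.2 s after the stimulus); from there the algorithm walks backwards to the
  first local minimum. The overall onset is the earliest axis onset.
* **Swing-leg toe-off** — on the vertical axis, positive peaks above a
  percentile-based threshold are collected inside a window after the
  stimulus; the largest (``Peak_va_max``) anchors a 1.5–0.5 s look-back
  window whose latest peak is the first-step peak (``Peak_FS``); toe-off is
  the last negative-to-positive zero crossing before it.
* **Swing-leg heel-strike** — the last upward crossing of 20 % of the
  first-step peak amplitude between toe-off and the first-step peak.

Zero- and level-crossings are sub-sample (linear interpolation between the
straddling samples): at 140 Hz one sample is ~7 ms, the same order as the
agreement this detector is validated to, so rounding to the grid would waste
precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DetectionError, WindowError
from .gi_metrics import GaitEvents
from .signals_io import (ACCEL_BANDPASS, FilterSpec, TriaxialAccelTrial,
                         apply_filter, slice_window)

log = logging.getLogger(__name__)

AXES = ("ap", "ml", "v")


@dataclass(frozen=True)
class AlgorithmWindows:
    """Detection windows, in seconds relative to the stimulus (``w_apa``,
    ``w_peakmax``) or relative to the ``Peak_va_max`` instant
    (``w_first_step``, both offsets negative: a look-back window)."""

    w_apa: tuple[float, float] = (-0.5, 1.2)
    w_peakmax: tuple[float, float] = (0.8, 2.0)
    w_first_step: tuple[float, float] = (-1.5, -0.5)

    def __post_init__(self):
        for name in ("w_apa", "w_peakmax", "w_first_step"):
            lo, hi = getattr(self, name)
            if lo >= hi:
                raise ValueError(f"{name}: start {lo} must precede end {hi}")
        if self.w_first_step[1] >= 0:
            raise ValueError("w_first_step must lie strictly before Peak_va_max")


#: windows with the Peak_va_max search extended to t_s + 3 s, the default for
#: synthetic cohorts (the literal 2 s end cannot hold the dominant vertical
#: peak for heel-strike times around 1.7 s plus the 0.5–1.5 s look-back lead)
EXTENDED_WINDOWS = AlgorithmWindows(w_peakmax=(0.8, 3.0))


@dataclass
class ImuDetectionTrace:
    """Every intermediate landmark of one detection, for diagnostics.
    Times are absolute (trial clock) unless suffixed ``_rel``."""

    apa_change_per_axis: dict[str, float] = field(default_factory=dict)
    apa_onset_per_axis: dict[str, float] = field(default_factory=dict)
    apa_axis_flags: dict[str, str] = field(default_factory=dict)
    apa_onset: float = np.nan
    peaks_va: list[tuple[float, float]] = field(default_factory=list)
    peak_va_max: tuple[float, float] = (np.nan, np.nan)
    i_peak_fs: float = np.nan
    peak_fs: float = np.nan
    to_swl: float = np.nan
    hs_swl: float = np.nan

    def as_dict(self) -> dict:
        return {
            "apa_change_per_axis": dict(self.apa_change_per_axis),
            "apa_onset_per_axis": dict(self.apa_onset_per_axis),
            "apa_axis_flags": dict(self.apa_axis_flags),
            "apa_onset": float(self.apa_onset),
            "peaks_va": [(float(t), float(a)) for t, a in self.peaks_va],
            "peak_va_max": tuple(map(float, self.peak_va_max)),
            "i_peak_fs": float(self.i_peak_fs),
            "peak_fs": float(self.peak_fs),
            "to_swl": float(self.to_swl),
            "hs_swl": float(self.hs_swl),
        }


# ---------------------------------------------------------------------------
# step 1: change of signal mean and slope
# ---------------------------------------------------------------------------

def _segment_sse(x: np.ndarray, y: np.ndarray, model: str) -> float:
    """Residual sum of squares of an OLS line (or constant) fit."""
    n = len(y)
    if n == 0:
        return 0.0
    sy = y.sum()
    syy = (y * y).sum()
    sse_mean = syy - sy * sy / n
    if model == "mean" or n < 2:
        return max(sse_mean, 0.0)
    sx = x.sum()
    sxx = (x * x).sum()
    sxy = (x * y).sum()
    den = sxx - sx * sx / n
    if den <= 1e-18:
        return max(sse_mean, 0.0)
    num = sxy - sx * sy / n
    return max(sse_mean - num * num / den, 0.0)


def detect_apa_change(axis_signal: np.ndarray, fs: float, t_s: float,
                      window: tuple[float, float] = (-0.5, 1.2),
                      model: str = "line") -> float:
    """Time of the split minimising SSE_left + SSE_right of two independent
    straight-line fits inside the APA window.

    ``window`` is relative to the stimulus. Split candidates range over
    interior samples leaving at least 3 samples per side; ties break to the
    earliest time. ``model="mean"`` fits constants instead of lines (a
    sensitivity variant).
    """
    seg, i0 = slice_window(axis_signal, fs, t_s + window[0], t_s + window[1])
    n = len(seg)
    if n < 8:
        raise WindowError(f"APA-change window holds only {n} samples (< 8)")
    x = (i0 + np.arange(n)) / fs
    # prefix sums -> closed-form SSE of each side for every admissible split
    ks = np.arange(3, n - 2)           # right segment starts at k
    sse = np.empty(len(ks))
    for j, k in enumerate(ks):
        sse[j] = (_segment_sse(x[:k], seg[:k], model)
                  + _segment_sse(x[k:], seg[k:], model))
    # ties (within numerical tolerance) break to the earliest split
    tol = 1e-10 * max(1.0, float(sse.max()))
    tied = sse <= sse.min() + tol
    jmin = int(np.argmax(tied))        # first tied index = earliest time
    if np.all(tied):
        log.info("APA-change degenerate: SSE flat across splits; "
                 "earliest admissible split returned")
    t_change = x[ks[jmin]]
    log.info("APA_change at %.4f s (window [%.3f, %.3f] s)",
             t_change, t_s + window[0], t_s + window[1])
    return float(t_change)


def detect_apa_onset_axis(axis_signal: np.ndarray, fs: float,
                          apa_change: float, t_s: float
                          ) -> tuple[float, bool]:
    """Walk backwards from ``apa_change`` to the first strict local minimum.

    The search window spans ``t_s`` seconds before ``apa_change`` (clamped to
    the trial start). Returns ``(onset_time, no_minimum)``; when no interior
    sample is strictly lower than both neighbours the window-start sample is
    returned with the flag set.
    """
    n = len(axis_signal)
    i_change = int(round(apa_change * fs))
    if not 0 <= i_change < n:
        raise WindowError(f"apa_change={apa_change:.4f} s outside the trial")
    i_start = max(int(np.ceil((apa_change - t_s) * fs - 1e-9)), 1)
    if i_change < i_start:
        raise WindowError("apa_change precedes its backward-search window")
    for i in range(min(i_change, n - 2), i_start - 1, -1):
        if axis_signal[i] < axis_signal[i - 1] and axis_signal[i] < axis_signal[i + 1]:
            return i / fs, False
    return i_start / fs, True


def detect_apa_onset(trial: TriaxialAccelTrial,
                     windows: AlgorithmWindows = AlgorithmWindows(),
                     filter_spec: FilterSpec = ACCEL_BANDPASS,
                     model: str = "line",
                     prefiltered: dict[str, np.ndarray] | None = None,
                     ) -> tuple[float, ImuDetectionTrace]:
    """Overall APA onset: the earliest per-axis onset over AP, ML and V.

    Axes whose backward search finds no local minimum are flagged and
    excluded from the minimum; if every axis is flagged the trial carries no
    detectable postural adjustment and detection fails.
    """
    filtered = prefiltered or {ax: apply_filter(sig, trial.fs, filter_spec)
                               for ax, sig in trial.axes().items()}
    trace = ImuDetectionTrace()
    candidates: list[float] = []
    for ax in AXES:
        sig = filtered[ax]
        t_change = detect_apa_change(sig, trial.fs, trial.t_s,
                                     windows.w_apa, model=model)
        onset, no_min = detect_apa_onset_axis(sig, trial.fs, t_change, trial.t_s)
        trace.apa_change_per_axis[ax] = t_change
        trace.apa_onset_per_axis[ax] = onset
        trace.apa_axis_flags[ax] = "no-minimum" if no_min else "ok"
        if no_min:
            log.warning("axis %s: no local minimum before APA_change; "
                        "axis excluded from the overall onset", ax)
        else:
            candidates.append(onset)
    if not candidates:
        raise DetectionError("no axis yielded an APA onset "
                             "(all backward searches degenerate)",
                             stage="apa_onset")
    trace.apa_onset = min(candidates)
    log.info("APA onset at %.4f s (%.4f s after stimulus)",
             trace.apa_onset, trace.apa_onset - trial.t_s)
    return trace.apa_onset, trace


# ---------------------------------------------------------------------------
# toe-off and heel-strike from the vertical axis
# ---------------------------------------------------------------------------

def find_vertical_peaks(v_signal: np.ndarray, fs: float,
                        window: tuple[float, float],
                        pct_lo: float = 10.0, pct_hi: float = 90.0,
                        frac: float = 0.01) -> list[tuple[float, float]]:
    """Strict positive local maxima inside ``window`` (absolute times) with
    amplitude above ``frac`` of the inter-percentile range of the windowed
    values (defaults: 1 % of the P90–P10 range)."""
    seg, i0 = slice_window(v_signal, fs, window[0], window[1])
    if len(seg) < 3:
        return []
    tau1 = frac * (np.percentile(seg, pct_hi) - np.percentile(seg, pct_lo))
    interior = np.arange(1, len(seg) - 1)
    is_peak = (seg[interior] > seg[interior - 1]) & (seg[interior] > seg[interior + 1])
    peaks = [((i0 + i) / fs, float(seg[i]))
             for i in interior[is_peak] if seg[i] > tau1]
    return peaks


def select_peak_va_max(peaks: list[tuple[float, float]],
                       window_signal: np.ndarray,
                       pct: float = 95.0,
                       frac: float = 0.25) -> tuple[float, float]:
    """Among candidate peaks, the one of maximum amplitude above ``frac`` of
    the windowed signal's ``pct``-th percentile (defaults: 1/4 of P95). Ties
    break to the earliest peak."""
    if not peaks:
        raise DetectionError("no candidate vertical peaks", stage="peak_va_max")
    tau2 = frac * np.percentile(np.asarray(window_signal, dtype=float), pct)
    eligible = [(t, a) for t, a in peaks if a > tau2]
    if not eligible:
        raise DetectionError(
            f"no Peak_va_max: no peak exceeds threshold {tau2:.4g}",
            stage="peak_va_max")
    amps = np.array([a for _, a in eligible])
    t, a = eligible[int(np.argmax(amps))]
    log.info("Peak_va_max at %.4f s, amplitude %.4f", t, a)
    return t, a


def locate_first_step_peak(v_signal: np.ndarray, fs: float,
                           peak_va_max_time: float,
                           windows: AlgorithmWindows = AlgorithmWindows(),
                           ) -> tuple[float, float]:
    """First-step peak: among peaks inside the look-back window before
    ``Peak_va_max``, the one closest to the window's end boundary."""
    lead, lag = windows.w_first_step
    w = (peak_va_max_time + lead, peak_va_max_time + lag)
    peaks = find_vertical_peaks(v_signal, fs, w)
    if not peaks:
        raise DetectionError(
            f"no first-step peak in [{w[0]:.3f}, {w[1]:.3f}] s",
            stage="first_step_peak")
    gaps = np.array([w[1] - t for t, _ in peaks])
    t, a = peaks[int(np.argmin(gaps))]
    log.info("I_Peak_FS at %.4f s, Peak_FS %.4f", t, a)
    return t, a


def _last_upward_crossing(v_signal: np.ndarray, fs: float, level: float,
                          t_lo: float, t_hi: float) -> float | None:
    """Last sub-sample upward crossing of ``level`` with the straddling
    samples inside (t_lo, t_hi]."""
    n = len(v_signal)
    i_lo = max(int(np.floor(t_lo * fs)), 0)
    i_hi = min(int(np.ceil(t_hi * fs)), n - 1)
    for i in range(i_hi - 1, i_lo - 1, -1):
        y0, y1 = v_signal[i], v_signal[i + 1]
        if y0 <= level < y1:
            t = (i + (level - y0) / (y1 - y0)) / fs if y1 != y0 else i / fs
            if t_lo < t <= t_hi + 1e-12:
                return t
    return None


def detect_toe_off_imu(v_signal: np.ndarray, fs: float, i_peak_fs: float,
                       search_start: float) -> float:
    """Swing-leg toe-off: the last zero crossing from <= 0 to > 0 in the
    vertical acceleration before the first-step peak, sub-sample by linear
    interpolation. ``search_start`` is the start of the look-back window
    (``Peak_va_max`` time − 1.5 s by default)."""
    t = _last_upward_crossing(v_signal, fs, 0.0, search_start, i_peak_fs)
    if t is None:
        raise DetectionError(
            f"no toe-off zero-crossing in [{search_start:.3f}, "
            f"{i_peak_fs:.3f}] s", stage="toe_off")
    log.info("TO_swl at %.4f s", t)
    return t


def detect_heel_strike_imu(v_signal: np.ndarray, fs: float, to_swl: float,
                           i_peak_fs: float, peak_fs: float) -> float:
    """Swing-leg heel-strike: the last upward crossing of 20 % of the
    first-step peak amplitude between toe-off and the first-step peak."""
    if peak_fs <= 0:
        raise DetectionError("first-step peak amplitude must be positive",
                             stage="heel_strike")
    if not to_swl < i_peak_fs:
        raise DetectionError("toe-off must precede the first-step peak",
                             stage="heel_strike")
    level = 0.2 * peak_fs
    t = _last_upward_crossing(v_signal, fs, level, to_swl, i_peak_fs)
    if t is None:
        raise DetectionError(
            f"no heel-strike crossing of level {level:.4f} in "
            f"({to_swl:.3f}, {i_peak_fs:.3f}] s", stage="heel_strike")
    log.info("HS_swl at %.4f s", t)
    return t


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def detect_events_imu(trial: TriaxialAccelTrial,
                      windows: AlgorithmWindows = AlgorithmWindows(),
                      filter_spec: FilterSpec = ACCEL_BANDPASS,
                      model: str = "line",
                      ) -> tuple[GaitEvents, ImuDetectionTrace]:
    """Run the full single-accelerometer detection chain on one trial.

    Returns events in seconds relative to the stimulus plus the complete
    landmark trace. Fails atomically: any stage error aborts the trial with
    the failing stage named, never returning partial events.
    """
    filtered = {ax: apply_filter(sig, trial.fs, filter_spec)
                for ax, sig in trial.axes().items()}
    apa_onset_abs, trace = detect_apa_onset(
        trial, windows, filter_spec, model=model, prefiltered=filtered)
    v = filtered["v"]
    w_pk = (trial.t_s + windows.w_peakmax[0], trial.t_s + windows.w_peakmax[1])
    seg, _ = slice_window(v, trial.fs, w_pk[0], w_pk[1])
    trace.peaks_va = find_vertical_peaks(v, trial.fs, w_pk)
    trace.peak_va_max = select_peak_va_max(trace.peaks_va, seg)
    trace.i_peak_fs, trace.peak_fs = locate_first_step_peak(
        v, trial.fs, trace.peak_va_max[0], windows)
    trace.to_swl = detect_toe_off_imu(
        v, trial.fs, trace.i_peak_fs,
        search_start=trace.peak_va_max[0] + windows.w_first_step[0])
    trace.hs_swl = detect_heel_strike_imu(
        v, trial.fs, trace.to_swl, trace.i_peak_fs, trace.peak_fs)
    events = GaitEvents(
        apa_onset_s=apa_onset_abs - trial.t_s,
        toe_off_s=trace.to_swl - trial.t_s,
        heel_strike_s=trace.hs_swl - trial.t_s,
        source="imu", trial_id=trial.trial_id, subject_id=trial.subject_id)
    return events, trace
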