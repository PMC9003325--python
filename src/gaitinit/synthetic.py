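"""Synthetic paired gait-initiation trials with known ground-truth events.

The generator emulates the two measurement modalities of a cued
gait-initiation protocol — a trunk accelerometer at 140 Hz and force
platforms at 1000 Hz with a malleolar marker — for subjects whose true
event-time distributions follow published group statistics (Parkinson's
disease with and without freezing of gait, and elderly controls).

Waveforms are morphological templates, not biomechanical simulations: each
template is constructed so that, in the noiseless limit, the documented
detection rules of both systems recover the planted event times exactly
(up to one sample of the respective grid). In particular:

* the anteroposterior/mediolateral acceleration carries a biphasic
  anticipatory lobe whose last pre-change local minimum sits exactly at the
  APA onset;
* the vertical acceleration crosses zero upward exactly at toe-off, crosses
  20 % of the first-step peak exactly at heel-strike, and carries a later
  dominant peak anchoring the look-back windows;
* the CoP path is built in the chord frame of the line joining its positions
  at APA onset and stance toe-off, so the perpendicular-distance apex falls
  exactly at swing toe-off; its velocity crosses zero (positive to negative)
  in both components exactly at APA onset, emerging from a small forward
  pre-stimulus sway;
* the marker anteroposterior velocity is a swing-phase half-sine crossing
  zero downward exactly at heel-strike (with a small recoil afterwards so
  the crossing survives smoothing).

Noise is band-limited Gaussian, rescaled after band-limiting so the stated
standard deviation is the standard deviation actually added.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import FeasibilityError, UsageError
from .imu_events import EXTENDED_WINDOWS, AlgorithmWindows
from .signals_io import ForcePlateTrial, TriaxialAccelTrial, write_trial_csv

# ---------------------------------------------------------------------------
# group parameter sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupParameterSet:
    """Mean(SD) of the three independent timing parameters of a group, in
    seconds. Time-to-toe-off and time-to-heel-strike follow by addition."""

    name: str
    time_to_apa: tuple[float, float]
    apa_duration: tuple[float, float]
    swing_duration: tuple[float, float]


#: published group statistics used as generator defaults (elderly-control
#: APA-duration SD taken from the abstract-level 0.09 figure)
GROUP_PRESETS: dict[str, GroupParameterSet] = {
    "PD": GroupParameterSet("PD", (0.45, 0.12), (0.81, 0.17), (0.47, 0.09)),
    "FOGminus": GroupParameterSet("FOGminus", (0.44, 0.10), (0.88, 0.12),
                                  (0.49, 0.12)),
    "FOGplus": GroupParameterSet("FOGplus", (0.46, 0.13), (0.75, 0.19),
                                 (0.46, 0.06)),
    "ELD": GroupParameterSet("ELD", (0.42, 0.05), (0.59, 0.09), (0.43, 0.07)),
}

#: physiologic/window-feasibility envelope for sampled event times [s]:
#: every trial inside it is detectable under the extended windows
ENVELOPE = {
    "time_to_apa": (0.15, 0.75),
    "apa_duration": (0.20, 1.30),
    "swing_duration": (0.25, 0.72),
    "t_hs": (1.10, 2.28),
}

#: fraction of the group SD assigned to trial-to-trial jitter within a
#: subject (the remainder is between-subject spread)
TRIAL_JITTER_FRACTION = 0.2

#: first-step vertical peak lag after heel-strike [s] (template constant)
FIRST_STEP_PEAK_LAG = 0.15


def _inside_envelope(tta: float, apa: float, swing: float) -> bool:
    return (ENVELOPE["time_to_apa"][0] <= tta <= ENVELOPE["time_to_apa"][1]
            and ENVELOPE["apa_duration"][0] <= apa <= ENVELOPE["apa_duration"][1]
            and ENVELOPE["swing_duration"][0] <= swing
            <= ENVELOPE["swing_duration"][1]
            and ENVELOPE["t_hs"][0] <= tta + apa + swing <= ENVELOPE["t_hs"][1])


def sample_event_times(group: GroupParameterSet, n_subjects: int,
                       n_trials: int = 5,
                       seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Draw per-subject, per-trial true event times.

    Subject-level means come from the group Gaussians; trial-level times add
    Gaussian jitter with SD equal to ``TRIAL_JITTER_FRACTION`` of the group
    SD. Draws outside the feasibility envelope are redrawn, keeping the
    event ordering and the detection windows satisfiable for every trial.
    """
    if n_subjects < 1:
        raise UsageError("need at least one subject")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    params = {"tta": group.time_to_apa, "apa": group.apa_duration,
              "swing": group.swing_duration}
    rows = []
    for s in range(n_subjects):
        for _ in range(10000):
            mu = {k: rng.normal(*params[k]) for k in params}
            if _inside_envelope(mu["tta"], mu["apa"], mu["swing"]):
                break
        else:  # pragma: no cover - envelope is wide relative to the SDs
            raise UsageError("could not draw feasible subject parameters")
        sid = f"{group.name}{s + 1:02d}"
        for k in range(n_trials):
            for _ in range(10000):
                tta = mu["tta"] + rng.normal(
                    0, TRIAL_JITTER_FRACTION * params["tta"][1])
                apa = mu["apa"] + rng.normal(
                    0, TRIAL_JITTER_FRACTION * params["apa"][1])
                swing = mu["swing"] + rng.normal(
                    0, TRIAL_JITTER_FRACTION * params["swing"][1])
                if _inside_envelope(tta, apa, swing):
                    break
            else:  # pragma: no cover
                raise UsageError("could not draw feasible trial times")
            rows.append({"subject_id": sid, "group": group.name,
                         "trial": k + 1, "t_apa": tta, "t_to": tta + apa,
                         "t_hs": tta + apa + swing})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trial specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticTrialSpec:
    """Everything needed to synthesise one paired trial. Event times are in
    seconds relative to the stimulus."""

    t_apa: float
    t_to: float
    t_hs: float
    t_s: float = 1.0
    duration: float = 6.0
    apa_amp: float = 1.0           # AP-axis APA lobe amplitude [m/s^2]
    step_amp: float = 3.0          # first-step vertical peak [m/s^2]
    peakmax_amp: float = 4.5       # dominant vertical peak [m/s^2]
    peakmax_lag: float = 0.7       # dominant peak lag after heel-strike [s]
    noise_sd_accel: float = 0.05   # [m/s^2]
    noise_sd_cop: float = 0.0005   # [m]
    noise_sd_marker: float = 0.0002  # [m]
    double_support: float = 0.15   # heel-strike to stance toe-off [s]
    fs_accel: float = 140.0
    fs_fp: float = 1000.0
    fs_marker: float = 100.0
    swing_side: str = "left"
    seed: int = 0
    trial_id: str = "synthetic"
    subject_id: str = ""

    def __post_init__(self):
        if not 0 < self.t_apa < self.t_to < self.t_hs:
            raise UsageError(
                f"event ordering violated: {self.t_apa}, {self.t_to}, "
                f"{self.t_hs}")
        if not self.peakmax_amp > self.step_amp > 0:
            raise UsageError("need peakmax_amp > step_amp > 0")

    def check_feasible(self, windows: AlgorithmWindows = EXTENDED_WINDOWS):
        """Verify the planted events are reachable by the configured
        detection windows (and fit inside the trial away from filter edge
        transients)."""
        t_pk2 = self.t_hs + self.peakmax_lag
        lo, hi = windows.w_peakmax
        if not lo <= t_pk2 <= hi:
            raise FeasibilityError(
                f"dominant vertical peak at t_s+{t_pk2:.3f} s falls outside "
                f"w_peakmax [{lo}, {hi}] s")
        lead, lag = windows.w_first_step
        first_step = self.t_hs + FIRST_STEP_PEAK_LAG
        if not t_pk2 + lead <= first_step <= t_pk2 + lag:
            raise FeasibilityError(
                f"first-step peak at t_s+{first_step:.3f} s falls outside "
                f"w_first_step [{t_pk2 + lead:.3f}, {t_pk2 + lag:.3f}] s")
        if t_pk2 + lead > self.t_to:
            raise FeasibilityError(
                f"toe-off at t_s+{self.t_to:.3f} s precedes the w_first_step "
                f"search start t_s+{t_pk2 + lead:.3f} s")
        if self.t_s + t_pk2 + 1.45 > self.duration - 0.25:
            raise FeasibilityError(
                "trial too short for the dominant peak and edge guard")
        if not windows.w_apa[0] + 0.05 <= self.t_apa <= windows.w_apa[1] - 0.1:
            raise FeasibilityError(
                f"APA onset at t_s+{self.t_apa:.3f} s too close to the w_apa "
                f"bounds {windows.w_apa}")


def specs_from_times(times: pd.DataFrame, seed: int = 0,
                     **overrides) -> list[SyntheticTrialSpec]:
    """One spec per row of a ``sample_event_times`` table, with per-trial
    seeds derived deterministically from ``seed``."""
    specs = []
    for i, row in enumerate(times.itertuples()):
        specs.append(SyntheticTrialSpec(
            t_apa=row.t_apa, t_to=row.t_to, t_hs=row.t_hs,
            seed=(seed * 100003 + i * 7919) % (2 ** 31),
            trial_id=f"{row.subject_id}_t{row.trial}",
            subject_id=row.subject_id, **overrides))
    return specs


# ---------------------------------------------------------------------------
# waveform primitives
# ---------------------------------------------------------------------------

def _halfsine(t, t0, t1, amp):
    """amp * sin(pi * (t-t0)/(t1-t0)) inside [t0, t1], zero outside."""
    y = np.zeros_like(t)
    m = (t >= t0) & (t <= t1)
    y[m] = amp * np.sin(np.pi * (t[m] - t0) / (t1 - t0))
    return y


def _rise(t, t0, t1, y0, y1):
    """Smooth (sin^2) transition from y0 at t0 to y1 at t1; y0 before, y1
    after."""
    y = np.full_like(t, float(y0))
    m = (t >= t0) & (t <= t1)
    y[m] = y0 + (y1 - y0) * np.sin(0.5 * np.pi * (t[m] - t0) / (t1 - t0)) ** 2
    y[t > t1] = y1
    return y


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float,
                        sd: float, band: tuple[float, float]) -> np.ndarray:
    """Gaussian noise band-limited to ``band`` and rescaled to SD ``sd``."""
    if sd <= 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    hi = min(band[1], 0.45 * fs)
    sos = sps.butter(2, [band[0], hi], btype="bandpass", fs=fs, output="sos")
    shaped = sps.sosfiltfilt(sos, white)
    return shaped * (sd / shaped.std())


# ---------------------------------------------------------------------------
# accelerometer synthesis
# ---------------------------------------------------------------------------

def _apa_lobe(t, t_on, amp, d1=0.35, d2=0.35, hump_w=0.25):
    """Biphasic anticipatory lobe with its last pre-change local minimum
    exactly at ``t_on``.

    A positive hump ends at ``t_on`` and the main positive phase (duration
    ``d1``) starts there; the hump amplitude is chosen so the slopes into
    and out of the minimum match in magnitude, which keeps the minimum at
    ``t_on`` under symmetric (zero-phase) smoothing. A negative phase of
    duration ``d2`` follows.
    """
    hump_amp = amp * hump_w / d1   # slope-matched corner at t_on
    return (_halfsine(t, t_on - hump_w, t_on, hump_amp)
            + _halfsine(t, t_on, t_on + d1, amp)
            - _halfsine(t, t_on + d1, t_on + d1 + d2, 0.5 * amp))


def _vertical_template(t: np.ndarray, spec: SyntheticTrialSpec,
                       to_shift: float = 0.0,
                       hs_shift: float = 0.0) -> np.ndarray:
    """Vertical-axis template (no noise).

    Piecewise in-band construction; the two planted crossings are protected
    against filter distortion: the toe-off zero crossing is slope-matched on
    both sides, and the 20 %-of-peak crossing at heel-strike sits in the
    middle of a linear ramp (a symmetric smoother leaves a straight line
    unchanged away from its endpoints). ``to_shift``/``hs_shift`` displace
    the two crossing knots; the synthesis loop uses them to cancel the
    residual displacement the band-pass conditioning induces, so the
    *filtered* waveform crosses at the planted instants.
    """
    T_to = spec.t_s + spec.t_to + to_shift
    T_hs = spec.t_s + spec.t_hs + hs_shift
    T_hs0 = spec.t_s + spec.t_hs       # peak anchors stay unshifted
    step = spec.step_amp
    gap = spec.t_to - spec.t_apa
    swing = spec.t_hs - spec.t_to
    d_pre = min(0.35, 0.45 * gap)       # pre-swing negative lobe length
    # lobe depth sized so its high-pass rebound supports the swing-phase
    # floor against the leading sag of the first-step peak complex
    # depth capped both absolutely and via the toe-off entry slope, so short
    # postural phases do not produce implausibly steep unloading dips
    a_pre = min(1.2 * step, 10.0 * step * d_pre / np.pi,
                0.18 * step / ((2.0 / np.pi) * d_pre))
    slope_to = a_pre * np.pi / d_pre    # slope entering the toe-off crossing
    shelf = 0.14 * step                 # swing-phase floor: above zero and
    #                                     below the 20 % level by several
    #                                     noise SDs after conditioning
    s0 = 4.0 / 3.0 * step               # linear slope through the HS crossing
    t2 = T_hs - (0.2 * step - shelf) / s0  # linear ramp start (f = shelf)
    t3 = T_hs + 0.05                    # linear ramp end
    L3 = 0.2 * step + s0 * (t3 - T_hs)
    w1 = min(0.10, 0.45 * (t2 - T_to))  # post-toe-off quarter-sine rise
    h1 = slope_to * 2.0 * w1 / np.pi    # continues the toe-off slope
    T_pk1 = T_hs0 + FIRST_STEP_PEAK_LAG  # first-step peak
    T_pk2 = T_hs0 + spec.peakmax_lag     # dominant peak

    v = np.zeros_like(t)
    # vertical anticipatory component: anchors the V-axis change point and
    # backward search at the true onset (the trunk vertical acceleration is
    # not quiet during the postural phase); sized to end before the
    # pre-swing dip so the toe-off crossing is untouched
    T_apa = spec.t_s + spec.t_apa
    d_v = min(0.35, 0.40 * (gap - d_pre))
    if d_v >= 0.15:
        # wide enough to survive the 4.5 Hz conditioning with its minimum
        # in place; for shorter postural phases the pre-swing dip (then
        # inside the APA window) anchors the V-axis search instead
        v += _apa_lobe(t, T_apa, 0.4 * spec.apa_amp, d1=d_v, d2=d_v,
                       hump_w=min(0.25, d_v * 0.7))
    m = (t >= T_to - d_pre) & (t < T_to)
    v[m] = -a_pre * np.sin(np.pi * (t[m] - (T_to - d_pre)) / d_pre)
    m = (t >= T_to) & (t < T_to + w1)
    v[m] = h1 * np.sin(0.5 * np.pi * (t[m] - T_to) / w1)
    m = (t >= T_to + w1) & (t < t2)
    v[m] = shelf + (h1 - shelf) * np.cos(
        0.5 * np.pi * (t[m] - T_to - w1) / max(t2 - T_to - w1, 1e-6)) ** 2
    m = (t >= t2) & (t < t3)
    v[m] = 0.2 * step + s0 * (t[m] - T_hs)
    m = (t >= t3) & (t < T_pk1)
    v[m] = step - (step - L3) * np.cos(
        0.5 * np.pi * (t[m] - t3) / max(T_pk1 - t3, 0.02)) ** 2
    # after the first-step peak the signal swings sharply negative (trunk
    # deceleration): the peak/valley doublet carries little low-frequency
    # content, so the 0.2 Hz high-pass barely displaces the swing baseline
    v1 = 0.5 * step                     # valley depth after the first peak
    v2 = 0.6 * spec.peakmax_amp         # trough depth after the dominant peak
    m = (t >= T_pk1) & (t < T_pk1 + 0.15)
    v[m] = -v1 + (step + v1) * np.cos(
        0.5 * np.pi * (t[m] - T_pk1) / 0.15) ** 2
    m = (t >= T_pk1 + 0.15) & (t < T_pk2 - 0.30)
    v[m] = -v1
    m = (t >= T_pk2 - 0.30) & (t < T_pk2)
    v[m] = -v1 + (spec.peakmax_amp + v1) * np.sin(
        0.5 * np.pi * (t[m] - (T_pk2 - 0.30)) / 0.30) ** 2
    m = (t >= T_pk2) & (t < T_pk2 + 0.30)
    v[m] = -v2 + (spec.peakmax_amp + v2) * np.cos(
        0.5 * np.pi * (t[m] - T_pk2) / 0.30) ** 2
    m = (t >= T_pk2 + 0.30) & (t < T_pk2 + 0.60)
    v[m] = -v2 * np.cos(0.5 * np.pi * (t[m] - (T_pk2 + 0.30)) / 0.30) ** 2
    # wide shallow lobe cancelling the residual signed area, so the
    # high-pass sees a zero-mean transient
    area = float(np.trapezoid(v, t))
    corr_w = 0.8
    corr_amp = -area / (2.0 / np.pi * corr_w)
    m = (t >= T_pk2 + 0.60) & (t < T_pk2 + 0.60 + corr_w)
    v[m] += corr_amp * np.sin(np.pi * (t[m] - (T_pk2 + 0.60)) / corr_w)
    return v


def _calibrated_vertical(t: np.ndarray, spec: SyntheticTrialSpec,
                         n_iter: int = 3) -> np.ndarray:
    """Vertical template with its two crossing knots adjusted so that the
    standard band-pass conditioning reproduces the planted toe-off and
    heel-strike instants on the *filtered* waveform.

    The 0.2 Hz high-pass subtracts a slowly varying local mean, displacing
    level crossings by a template-dependent but deterministic amount; a
    short fixed-point iteration measures the displacement on the filtered
    noiseless template and cancels it.
    """
    from .imu_events import _last_upward_crossing
    from .signals_io import ACCEL_BANDPASS, apply_filter

    fs = spec.fs_accel
    T_to = spec.t_s + spec.t_to
    T_hs = spec.t_s + spec.t_hs
    T_pk1 = T_hs + FIRST_STEP_PEAK_LAG
    swing = spec.t_hs - spec.t_to
    to_shift = hs_shift = 0.0
    v = _vertical_template(t, spec)
    for _ in range(n_iter):
        vf = apply_filter(v, fs, ACCEL_BANDPASS)
        t_cross = _last_upward_crossing(vf, fs, 0.0,
                                        T_to - 0.20, T_to + 0.5 * swing)
        if t_cross is not None:
            to_shift -= t_cross - T_to
        i_pk = slice(int((T_hs - 0.05) * fs), int((T_pk1 + 0.12) * fs))
        level = 0.2 * float(vf[i_pk].max())
        t_cross = _last_upward_crossing(vf, fs, level,
                                        T_to + 0.5 * swing, T_pk1)
        if t_cross is not None:
            hs_shift -= t_cross - T_hs
        to_shift = float(np.clip(to_shift, -0.12, 0.12))
        hs_shift = float(np.clip(hs_shift, -0.12, 0.12))
        v = _vertical_template(t, spec, to_shift, hs_shift)
    return v


def synthesize_accel(spec: SyntheticTrialSpec,
                     windows: AlgorithmWindows = EXTENDED_WINDOWS,
                     ) -> TriaxialAccelTrial:
    """Triaxial accelerometer trial carrying the planted events of ``spec``.

    The AP and ML axes carry the biphasic anticipatory lobe with its
    detectable minimum at the APA onset; the vertical axis is quiet through
    the postural phase and carries the toe-off zero crossing, the
    heel-strike level crossing, the first-step peak and the later dominant
    peak (see ``_vertical_template``).
    """
    spec.check_feasible(windows)
    fs = spec.fs_accel
    n = int(round(spec.duration * fs)) + 1
    t = np.arange(n) / fs
    T_apa = spec.t_s + spec.t_apa

    ap = _apa_lobe(t, T_apa, spec.apa_amp)
    ml = _apa_lobe(t, T_apa, 0.8 * spec.apa_amp)
    v = _calibrated_vertical(t, spec)

    rng = np.random.default_rng(spec.seed)
    band = (0.2, 10.0)
    ap = ap + _band_limited_noise(rng, n, fs, spec.noise_sd_accel, band)
    ml = ml + _band_limited_noise(rng, n, fs, spec.noise_sd_accel, band)
    v = v + _band_limited_noise(rng, n, fs, spec.noise_sd_accel, band)
    return TriaxialAccelTrial(
        trial_id=spec.trial_id, subject_id=spec.subject_id, fs=fs,
        t_s=spec.t_s, ap=ap, ml=ml, v=v)


# ---------------------------------------------------------------------------
# force-platform synthesis
# ---------------------------------------------------------------------------

#: chord-frame geometry of the CoP path [m]
COP_CHORD_END = np.array([0.09, 0.07])   # CoP travel to the stance foot
COP_APEX_PERP = 0.0275                   # perpendicular excursion at toe-off
ONSET_VEL_SLOPE = 1.8                    # CoP velocity slope at onset [m/s^2]
ONSET_LIN_HALFWIDTH = 0.06               # linear velocity zone at onset [s]
APA_TANG_SPEED = 0.10                    # tangential APA speed scale [m/s]
BODY_WEIGHT_N = 700.0
STEP_LENGTH_M = 0.40


def _cumtrapz(y: np.ndarray, fs: float) -> np.ndarray:
    """Trapezoid cumulative integral (no half-sample phase bias)."""
    out = np.zeros_like(y)
    out[1:] = np.cumsum(0.5 * (y[1:] + y[:-1])) / fs
    return out


def _cop_chord_profiles(spec: SyntheticTrialSpec, t: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Tangential u(t) and perpendicular d(t) chord-frame CoP coordinates.

    u carries the forward pre-stimulus sway whose velocity crosses zero
    linearly (slope ``ONSET_VEL_SLOPE``) exactly at APA onset, inside a
    linear zone wide enough that zero-phase smoothing leaves the crossing
    in place; d carries the perpendicular excursion peaking exactly at
    swing toe-off inside a locally symmetric cap and vanishing at both
    chord endpoints, so the CoP positions at APA onset and stance toe-off
    both lie on the chord and the perpendicular distance from the detected
    line is |d| exactly.
    """
    fs = spec.fs_fp
    T_apa = spec.t_s + spec.t_apa
    T_to = spec.t_s + spec.t_to
    T_tos = spec.t_s + spec.t_hs + spec.double_support
    wu = ONSET_LIN_HALFWIDTH
    wd = max(APA_TANG_SPEED / ONSET_VEL_SLOPE, wu)
    sway_speed = ONSET_VEL_SLOPE * wu   # velocity at the sway/onset junction
    t0u = min(spec.t_s - 0.30, T_apa - wu - 0.25)

    u_dot = np.zeros_like(t)
    m = (t >= t0u) & (t < T_apa - wu)
    u_dot[m] = sway_speed * np.sin(
        0.5 * np.pi * (t[m] - t0u) / (T_apa - wu - t0u)) ** 2
    m = (t >= T_apa - wu) & (t < T_apa + wd)
    u_dot[m] = -ONSET_VEL_SLOPE * (t[m] - T_apa)
    m = (t >= T_apa + wd) & (t <= T_to)
    span = max(T_to - (T_apa + wd), 1e-3)
    u_dot[m] = -ONSET_VEL_SLOPE * wd * np.cos(
        0.5 * np.pi * (t[m] - T_apa - wd) / span) ** 2
    u = _cumtrapz(u_dot, fs)
    # bridge the tangential coordinate to the chord end after toe-off
    u_end = float(np.hypot(*COP_CHORD_END))
    i_to = int(np.searchsorted(t, T_to))
    u_at_to = u[i_to]
    m = (t > T_to) & (t <= T_tos - 0.03)
    u[m] = u_at_to + (u_end - u_at_to) * np.sin(
        0.5 * np.pi * (t[m] - T_to) / (T_tos - 0.03 - T_to)) ** 2
    u[t > T_tos - 0.03] = u_end

    # perpendicular excursion: symmetric cap of half-width w_s around the
    # toe-off apex, flanked by C1 tails, so smoothing cannot displace it
    D = COP_APEX_PERP
    w_s = min(0.15, 0.45 * (T_to - T_apa - 0.05),
              0.45 * (T_tos - 0.03 - T_to))
    Dm = 0.55 * D
    d = np.zeros_like(t)
    m = (t >= T_apa + 0.05) & (t < T_to - w_s)
    d[m] = Dm * np.sin(0.5 * np.pi * (t[m] - T_apa - 0.05)
                       / (T_to - w_s - T_apa - 0.05)) ** 2
    m = (t >= T_to - w_s) & (t <= T_to + w_s)
    d[m] = D - (D - Dm) * np.sin(0.5 * np.pi * (t[m] - T_to) / w_s) ** 2
    m = (t > T_to + w_s) & (t <= T_tos - 0.03)
    d[m] = Dm * np.cos(0.5 * np.pi * (t[m] - T_to - w_s)
                       / (T_tos - 0.03 - T_to - w_s)) ** 2
    return u, d


def synthesize_forceplate(spec: SyntheticTrialSpec) -> ForcePlateTrial:
    """Force-platform + marker trial carrying the planted events of ``spec``."""
    spec.check_feasible()
    fs = spec.fs_fp
    n = int(round(spec.duration * fs)) + 1
    t = np.arange(n) / fs
    T_to = spec.t_s + spec.t_to
    T_hs = spec.t_s + spec.t_hs
    T_tos = T_hs + spec.double_support

    chord = COP_CHORD_END / np.hypot(*COP_CHORD_END)
    # normal chosen on the posterior/swing-ward side of the chord: positive
    # d moves the CoP toward the swing leg (ML negative)
    normal = np.array([chord[1], -chord[0]])
    u, d = _cop_chord_profiles(spec, t)
    cop_ap = u * chord[0] + d * normal[0]
    cop_ml = u * chord[1] + d * normal[1]

    grf = np.full(n, BODY_WEIGHT_N)
    m = (t >= T_tos - 0.25) & (t <= T_tos)
    # linear unloading, so the threshold crossing sits within a few ms of
    # the nominal stance toe-off
    grf[m] = BODY_WEIGHT_N * (T_tos - t[m]) / 0.25
    grf[t > T_tos] = 0.0

    # marker: swing-phase half-sine AP velocity, zero exactly at heel-strike,
    # extended 10% of the swing into a small recoil so the crossing is a
    # locally linear sign change (robust to smoothing)
    nm = int(round(spec.duration * spec.fs_marker)) + 1
    tm = np.arange(nm) / spec.fs_marker
    swing = spec.t_hs - spec.t_to
    vmax = STEP_LENGTH_M * np.pi / (2.0 * swing)
    vel = np.zeros(nm)
    m = (tm >= T_to) & (tm <= T_hs + 0.10 * swing)
    vel[m] = vmax * np.sin(np.pi * (tm[m] - T_to) / swing)
    v_rec = vmax * np.sin(np.pi * 1.10)
    m = (tm > T_hs + 0.10 * swing) & (tm <= T_hs + 0.25 * swing)
    vel[m] = v_rec * np.cos(
        0.5 * np.pi * (tm[m] - (T_hs + 0.10 * swing)) / (0.15 * swing)) ** 2
    marker = _cumtrapz(vel, spec.fs_marker)

    rng = np.random.default_rng(spec.seed + 1)
    cop_ap = cop_ap + _band_limited_noise(rng, n, fs, spec.noise_sd_cop,
                                          (0.2, 15.0))
    cop_ml = cop_ml + _band_limited_noise(rng, n, fs, spec.noise_sd_cop,
                                          (0.2, 15.0))
    marker = marker + _band_limited_noise(rng, nm, spec.fs_marker,
                                          spec.noise_sd_marker, (0.2, 10.0))
    return ForcePlateTrial(
        trial_id=spec.trial_id, subject_id=spec.subject_id, fs=fs,
        t_s=spec.t_s, cop_ap=cop_ap, cop_ml=cop_ml, grf_v=grf,
        marker_ap=marker, fs_marker=spec.fs_marker,
        swing_side=spec.swing_side)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(groups: list[tuple[GroupParameterSet, int]],
                    out_dir: str | Path, n_trials: int = 5,
                    noise_sd_accel: float = 0.05,
                    noise_sd_cop: float = 0.0005,
                    seed: int = 7) -> pd.DataFrame:
    """Write per-trial IMU and force-platform CSVs plus ``truth.csv`` for a
    multi-group cohort; returns the truth table. Deterministic under
    ``seed``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    frames = []
    for group, n_subjects in groups:
        times = sample_event_times(group, n_subjects, n_trials, rng)
        specs = specs_from_times(times, seed=seed,
                                 noise_sd_accel=noise_sd_accel,
                                 noise_sd_cop=noise_sd_cop)
        for spec in specs:
            write_trial_csv(synthesize_accel(spec),
                            out / f"{spec.trial_id}_imu.csv")
            write_trial_csv(synthesize_forceplate(spec),
                            out / f"{spec.trial_id}_fp.csv")
        frames.append(times)
    truth = pd.concat(frames, ignore_index=True)
    truth.to_csv(out / "truth.csv", index=False, float_format="%.9g")
    return truth
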