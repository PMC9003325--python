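"""Gold-standard gait-initiation event detection from the force platforms
and the malleolar marker.

Rules (all under the convention AP positive anterior, ML positive toward the
stance limb, so the anticipatory excursion — CoP moving posteriorly and
toward the swing leg — makes both CoP velocity components negative):

* **APA onset** — the first frame at/after the stimulus in which both CoP
  velocity components are negative (optionally for a debounced run of
  frames; measured CoP velocity is noisy).
* **Stance-leg toe-off** — the last frame with vertical GRF at/above an
  unloading threshold (platforms never read exactly zero; default 10 N).
* **Swing-leg toe-off** — the frame between APA onset and stance toe-off at
  which the CoP attains maximum perpendicular distance from the line joining
  its positions at those two instants.
* **Swing-leg heel-strike** — the first downward zero crossing of the
  malleolar marker's anteroposterior velocity after its swing-phase peak
  (starting the search at the peak avoids triggering on pre-swing
  stillness), sub-sample by linear interpolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DetectionError
from .gi_metrics import GaitEvents
from .signals_io import (COP_LOWPASS, FilterSpec, ForcePlateTrial,
                         apply_filter, differentiate)

log = logging.getLogger(__name__)


@dataclass
class CopPath:
    """Filtered CoP coordinates and their velocities on a common time base."""

    times: np.ndarray
    ap: np.ndarray
    ml: np.ndarray
    v_ap: np.ndarray
    v_ml: np.ndarray
    fs: float

    @classmethod
    def from_trial(cls, trial: ForcePlateTrial,
                   filter_spec: FilterSpec = COP_LOWPASS) -> "CopPath":
        ap = apply_filter(trial.cop_ap, trial.fs, filter_spec)
        ml = apply_filter(trial.cop_ml, trial.fs, filter_spec)
        return cls(times=trial.times, ap=ap, ml=ml,
                   v_ap=differentiate(ap, trial.fs),
                   v_ml=differentiate(ml, trial.fs), fs=trial.fs)

    def index_at(self, t: float) -> int:
        return int(round(t * self.fs))


@dataclass(frozen=True)
class FpThresholds:
    """Tunable detection thresholds of the gold-standard rules."""

    debounce_samples: int = 1        # consecutive joint-negative frames
    unload_threshold_n: float = 10.0  # GRF level defining platform vacation
    onset_search_s: float = 2.0      # APA onset must occur within t_s + this


def fp_apa_onset(cop: CopPath, t_s: float, debounce_samples: int = 1,
                 search_s: float = 2.0) -> float:
    """First time at/after the stimulus with both CoP velocity components
    negative for ``debounce_samples`` consecutive frames; returns the first
    frame of that run."""
    i_s = max(int(np.ceil(t_s * cop.fs - 1e-9)), 0)
    i_end = min(int((t_s + search_s) * cop.fs), len(cop.times) - 1)
    neg = (cop.v_ap[i_s:i_end + 1] < 0) & (cop.v_ml[i_s:i_end + 1] < 0)
    run = 0
    for j, flag in enumerate(neg):
        run = run + 1 if flag else 0
        if run >= debounce_samples:
            t = (i_s + j - run + 1) / cop.fs
            log.info("CoP APA onset at %.4f s", t)
            return t
    raise DetectionError(
        f"no CoP APA onset: no {debounce_samples}-frame joint-negative "
        f"velocity run within {search_s} s of the stimulus", stage="apa_onset")


def fp_stance_toe_off(grf_v: np.ndarray, fs: float,
                      unload_threshold_n: float = 10.0) -> float:
    """Time of the last frame with vertical GRF at/above the unloading
    threshold (the platform is vacated afterwards)."""
    grf_v = np.asarray(grf_v, dtype=float)
    loaded = np.nonzero(grf_v >= unload_threshold_n)[0]
    if len(loaded) == 0:
        raise DetectionError("GRF never reaches the loading threshold",
                             stage="stance_toe_off")
    if loaded[-1] == len(grf_v) - 1:
        raise DetectionError("platform never unloads: GRF still above "
                             "threshold at trial end", stage="stance_toe_off")
    t = loaded[-1] / fs
    log.info("stance toe-off at %.4f s", t)
    return t


def fp_swing_toe_off(cop: CopPath, apa_onset: float, t_to_stance: float) -> float:
    """Swing-leg toe-off: the sample between APA onset and stance toe-off at
    maximum perpendicular distance of the CoP from the line joining
    CoP(APA onset) and CoP(stance toe-off). Ties break to the earliest
    sample; a degenerate zero-length line falls back to point distance."""
    if not apa_onset < t_to_stance:
        raise DetectionError("APA onset must precede stance toe-off",
                             stage="swing_toe_off")
    ia, ib = cop.index_at(apa_onset), cop.index_at(t_to_stance)
    if ib - ia < 4:
        raise DetectionError("fewer than 3 samples between APA onset and "
                             "stance toe-off", stage="swing_toe_off")
    a = np.array([cop.ap[ia], cop.ml[ia]])
    b = np.array([cop.ap[ib], cop.ml[ib]])
    pts = np.column_stack([cop.ap[ia + 1:ib], cop.ml[ia + 1:ib]])
    chord = b - a
    norm = np.hypot(*chord)
    if norm < 1e-12:
        log.warning("degenerate CoP chord (A == B); using point distance")
        dist = np.hypot(*(pts - a).T)
    else:
        # |cross product| / |chord| = perpendicular distance
        rel = pts - a
        dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0]) / norm
    if np.ptp(dist) < 1e-12:
        log.warning("collinear CoP path: perpendicular distance flat; "
                    "earliest interior sample returned")
        return (ia + 1) / cop.fs
    t = (ia + 1 + int(np.argmax(dist))) / cop.fs
    log.info("swing toe-off at %.4f s", t)
    return t


def fp_heel_strike(marker_ap: np.ndarray, fs_marker: float, to_swl: float,
                   filter_spec: FilterSpec | None = None) -> float:
    """Swing-leg heel-strike: first downward zero crossing of the marker AP
    velocity after its post-toe-off maximum, sub-sample interpolated.

    The velocity comes from central differences on the raw marker trace:
    optoelectronic traces are already low-noise and heavy smoothing biases
    the zero crossing; pass a ``filter_spec`` to pre-smooth anyway."""
    marker_ap = np.asarray(marker_ap, dtype=float)
    sig = apply_filter(marker_ap, fs_marker, filter_spec) if filter_spec else marker_ap
    vel = differentiate(sig, fs_marker)
    i0 = int(np.ceil(to_swl * fs_marker))
    if i0 >= len(vel) - 1:
        raise DetectionError("marker trace ends before toe-off",
                             stage="heel_strike")
    post = vel[i0:]
    if post.max() <= 0:
        raise DetectionError("marker never moves forward after toe-off",
                             stage="heel_strike")
    ipk = i0 + int(np.argmax(post))
    for i in range(ipk, len(vel) - 1):
        y0, y1 = vel[i], vel[i + 1]
        if y0 > 0 >= y1:
            frac = y0 / (y0 - y1) if y1 != y0 else 0.0
            t = (i + frac) / fs_marker
            log.info("heel-strike at %.4f s", t)
            return t
    raise DetectionError("marker AP velocity never returns to zero",
                         stage="heel_strike")


def infer_swing_side(cop: CopPath, apa_onset: float,
                     side_of_negative_ml: str = "left",
                     horizon_s: float = 0.5,
                     override: str = "unknown") -> str:
    """Swing side from the direction of the first ML CoP excursion after APA
    onset (the anticipatory shift moves the CoP toward the swing leg).
    ``override`` (a declared trial side) wins when not ``"unknown"``."""
    if override != "unknown":
        return override
    i0 = cop.index_at(apa_onset)
    i1 = min(i0 + int(horizon_s * cop.fs), len(cop.ml) - 1)
    excursion = cop.ml[i0:i1 + 1] - cop.ml[i0]
    peak = excursion[np.argmax(np.abs(excursion))]
    if abs(peak) < 1e-9:
        raise DetectionError("zero ML CoP excursion: swing side cannot be "
                             "inferred and must be supplied", stage="swing_side")
    if peak < 0:
        return side_of_negative_ml
    return "right" if side_of_negative_ml == "left" else "left"


def detect_events_fp(trial: ForcePlateTrial,
                     filter_spec: FilterSpec = COP_LOWPASS,
                     thresholds: FpThresholds = FpThresholds(),
                     ) -> GaitEvents:
    """Run the full gold-standard detection chain on one trial; events are
    returned relative to the stimulus. Atomic: any stage failure raises a
    stage-labelled detection error."""
    if trial.marker_ap is None:
        raise DetectionError("marker required for heel-strike",
                             stage="heel_strike")
    cop = CopPath.from_trial(trial, filter_spec)
    apa_onset = fp_apa_onset(cop, trial.t_s, thresholds.debounce_samples,
                             thresholds.onset_search_s)
    t_to_stance = fp_stance_toe_off(trial.grf_v, trial.fs,
                                    thresholds.unload_threshold_n)
    to_swl = fp_swing_toe_off(cop, apa_onset, t_to_stance)
    hs_swl = fp_heel_strike(trial.marker_ap, trial.fs_marker, to_swl)
    if not hs_swl < t_to_stance:
        raise DetectionError(
            f"heel-strike ({hs_swl:.4f} s) not before stance toe-off "
            f"({t_to_stance:.4f} s)", stage="ordering")
    return GaitEvents(
        apa_onset_s=apa_onset - trial.t_s,
        toe_off_s=to_swl - trial.t_s,
        heel_strike_s=hs_swl - trial.t_s,
        source="fp", trial_id=trial.trial_id, subject_id=trial.subject_id)
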