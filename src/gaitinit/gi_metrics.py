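"""Gait-initiation timing metrics.

From the three detected instants (APA onset, swing-leg toe-off, swing-leg
heel-strike, all relative to the "go" stimulus) five timing parameters are
derived per trial and averaged per subject:

* time-to-APA        — stimulus to APA onset (motor planning phase)
* time-to-toe-off    — stimulus to swing-leg toe-off (APA end)
* time-to-heel-strike— stimulus to swing-leg heel-strike
* APA duration       — APA onset to toe-off (postural adjustment phase)
* swing duration     — toe-off to heel-strike (execution phase)
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import UsageError

METRIC_NAMES = ("time_to_apa", "time_to_toe_off", "time_to_heel_strike",
                "apa_duration", "swing_duration")


@dataclass(frozen=True)
class GaitEvents:
    """The three detected gait-initiation instants of one trial, in seconds
    relative to the stimulus. Ordering 0 < APA onset < toe-off < heel-strike
    is enforced at construction."""

    apa_onset_s: float
    toe_off_s: float
    heel_strike_s: float
    source: str = "imu"          # "imu" | "fp"
    trial_id: str = ""
    subject_id: str = ""

    def __post_init__(self):
        for f in ("apa_onset_s", "toe_off_s", "heel_strike_s"):
            object.__setattr__(self, f, float(getattr(self, f)))
        if not (0.0 < self.apa_onset_s < self.toe_off_s < self.heel_strike_s):
            raise UsageError(
                f"event ordering violated: apa_onset={self.apa_onset_s:.4f}, "
                f"toe_off={self.toe_off_s:.4f}, "
                f"heel_strike={self.heel_strike_s:.4f} "
                f"(trial {self.trial_id!r}, source {self.source})")
        if self.source not in ("imu", "fp"):
            raise UsageError(f"source must be 'imu' or 'fp', got {self.source!r}")


@dataclass(frozen=True)
class GIMetrics:
    """The five timing metrics of one trial (``n_trials=1``) or one subject
    (mean over trials)."""

    time_to_apa: float
    time_to_toe_off: float
    time_to_heel_strike: float
    apa_duration: float
    swing_duration: float
    n_trials: int = 1
    subject_id: str = ""
    source: str = "imu"

    def __post_init__(self):
        for f in METRIC_NAMES:
            object.__setattr__(self, f, float(getattr(self, f)))
        if not all(getattr(self, m) > 0 for m in METRIC_NAMES):
            raise UsageError("all gait-initiation metrics must be positive")

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def compute_metrics(events: GaitEvents) -> GIMetrics:
    """Derive the five timing metrics of a single trial from its events."""
    return GIMetrics(
        time_to_apa=events.apa_onset_s,
        time_to_toe_off=events.toe_off_s,
        time_to_heel_strike=events.heel_strike_s,
        apa_duration=events.toe_off_s - events.apa_onset_s,
        swing_duration=events.heel_strike_s - events.toe_off_s,
        n_trials=1, subject_id=events.subject_id, source=events.source)


def metrics_frame(metrics_list: list["GIMetrics"]):
    """Per-subject metrics table (one row per subject x source), the CSV
    layout consumed by the agreement tooling."""
    import pandas as pd
    return pd.DataFrame(
        [{"subject_id": m.subject_id, "source": m.source,
          "n_trials": m.n_trials, **m.as_dict()} for m in metrics_list])


def average_over_trials(metrics_list: list[GIMetrics]) -> GIMetrics:
    """Per-subject mean of each metric over the trials that produced events.

    The additive identities (APA duration = time-to-toe-off − time-to-APA,
    swing duration = time-to-heel-strike − time-to-toe-off) hold exactly for
    arithmetic means, so the averaged object satisfies them too.
    """
    if not metrics_list:
        raise UsageError("cannot average an empty list of trial metrics")
    subject = metrics_list[0].subject_id
    source = metrics_list[0].source
    if any(m.subject_id != subject or m.source != source for m in metrics_list):
        raise UsageError("cannot average metrics across subjects or sources")
    k = len(metrics_list)
    means = {name: sum(getattr(m, name) for m in metrics_list) / k
             for name in METRIC_NAMES}
    return GIMetrics(**means, n_trials=k, subject_id=subject, source=source)
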