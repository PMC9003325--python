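"""End-to-end synthetic validation study.

Convenience layer chaining the generator, both detectors, per-subject
averaging and the agreement statistics, mirroring the validation protocol:
a cohort of subjects performs five cued gait-initiation trials each,
recorded simultaneously by the wearable and the gold-standard system; the
five timing metrics are averaged per subject and the two systems compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DetectionError, GaitInitError
from .forceplate_events import FpThresholds, detect_events_fp
from .gi_metrics import (METRIC_NAMES, GIMetrics, average_over_trials,
                         compute_metrics)
from .imu_events import EXTENDED_WINDOWS, AlgorithmWindows, detect_events_imu
from .stats import AgreementReport, agreement_report
from .synthetic import (GROUP_PRESETS, GroupParameterSet, sample_event_times,
                        specs_from_times, synthesize_accel,
                        synthesize_forceplate)

log = logging.getLogger(__name__)


@dataclass
class StudyResult:
    """Everything a validation run produces."""

    truth: pd.DataFrame                      # planted per-trial event times
    events: pd.DataFrame                     # detected per-trial events
    subject_metrics: dict[str, list[GIMetrics]]   # per source
    group_means: pd.DataFrame                # per group x source x metric
    agreement: AgreementReport | None
    n_failed: dict[str, int] = field(default_factory=dict)

    def group_mean(self, group: str, metric: str, source: str = "imu") -> float:
        df = self.group_means
        row = df[(df["group"] == group) & (df["source"] == source)]
        return float(row[metric].iloc[0])


def sample_cohort_times(groups: list[tuple[GroupParameterSet, int]],
                        n_trials: int = 5, seed: int = 7) -> pd.DataFrame:
    """Truth table for a multi-group cohort drawn from one seeded stream."""
    rng = np.random.default_rng(seed)
    return pd.concat(
        [sample_event_times(g, n, n_trials, rng) for g, n in groups],
        ignore_index=True)


def run_study(groups: list[tuple[GroupParameterSet, int]] | None = None,
              n_trials: int = 5, seed: int = 7,
              windows: AlgorithmWindows = EXTENDED_WINDOWS,
              sources: tuple[str, ...] = ("imu", "fp"),
              fp_thresholds: FpThresholds = FpThresholds(),
              **spec_overrides) -> StudyResult:
    """Generate a paired cohort, run the requested detectors on every trial,
    average per subject and (when both sources run) compute the agreement
    report.

    Defaults reproduce the published cohort shape: 25 PD-like and 8
    elderly-control-like subjects, five trials each.
    """
    if groups is None:
        groups = [(GROUP_PRESETS["PD"], 25), (GROUP_PRESETS["ELD"], 8)]
    truth = sample_cohort_times(groups, n_trials, seed)
    specs = specs_from_times(truth, seed=seed, **spec_overrides)

    rows = []
    n_failed = {s: 0 for s in sources}
    for spec, truth_row in zip(specs, truth.itertuples()):
        if "imu" in sources:
            try:
                ev, _ = detect_events_imu(synthesize_accel(spec, windows),
                                          windows)
                rows.append(_event_row(truth_row, ev, "imu"))
            except GaitInitError as exc:
                n_failed["imu"] += 1
                log.warning("imu detection failed for %s: %s",
                            spec.trial_id, exc)
        if "fp" in sources:
            try:
                ev = detect_events_fp(synthesize_forceplate(spec),
                                      thresholds=fp_thresholds)
                rows.append(_event_row(truth_row, ev, "fp"))
            except GaitInitError as exc:
                n_failed["fp"] += 1
                log.warning("fp detection failed for %s: %s",
                            spec.trial_id, exc)
    events = pd.DataFrame(rows)

    subject_metrics: dict[str, list[GIMetrics]] = {}
    for source in sources:
        per_subject = []
        sub = events[events["source"] == source]
        for sid, grp in sub.groupby("subject_id"):
            trials = [compute_metrics(_row_events(r, source)) for r in
                      grp.itertuples()]
            per_subject.append(average_over_trials(trials))
        subject_metrics[source] = per_subject

    group_means = _group_means(events, truth, subject_metrics)
    agreement = None
    if "imu" in sources and "fp" in sources:
        agreement = agreement_report(subject_metrics["imu"],
                                     subject_metrics["fp"])
    return StudyResult(truth=truth, events=events,
                       subject_metrics=subject_metrics,
                       group_means=group_means, agreement=agreement,
                       n_failed=n_failed)


def _event_row(truth_row, ev, source) -> dict:
    return {"subject_id": truth_row.subject_id, "group": truth_row.group,
            "trial": truth_row.trial, "source": source,
            "apa_onset_s": ev.apa_onset_s, "toe_off_s": ev.toe_off_s,
            "heel_strike_s": ev.heel_strike_s,
            "true_apa": truth_row.t_apa, "true_to": truth_row.t_to,
            "true_hs": truth_row.t_hs}


def _row_events(r, source):
    from .gi_metrics import GaitEvents
    return GaitEvents(apa_onset_s=r.apa_onset_s, toe_off_s=r.toe_off_s,
                      heel_strike_s=r.heel_strike_s, source=source,
                      trial_id=f"{r.subject_id}_t{r.trial}",
                      subject_id=r.subject_id)


def _group_means(events, truth, subject_metrics) -> pd.DataFrame:
    group_of = dict(zip(truth["subject_id"], truth["group"]))
    rows = []
    for source, metrics in subject_metrics.items():
        by_group: dict[str, list[GIMetrics]] = {}
        for m in metrics:
            by_group.setdefault(group_of[m.subject_id], []).append(m)
        for gname, ms in by_group.items():
            row = {"group": gname, "source": source, "n_subjects": len(ms)}
            for name in METRIC_NAMES:
                vals = np.array([getattr(m, name) for m in ms])
                row[name] = vals.mean()
                row[name + "_sd"] = vals.std(ddof=1) if len(ms) > 1 else 0.0
            rows.append(row)
    return pd.DataFrame(rows)


def event_errors(events: pd.DataFrame) -> pd.DataFrame:
    """Per-trial detection errors (detected − true) in seconds, by source."""
    df = events.copy()
    df["err_apa"] = df["apa_onset_s"] - df["true_apa"]
    df["err_to"] = df["toe_off_s"] - df["true_to"]
    df["err_hs"] = df["heel_strike_s"] - df["true_hs"]
    return df
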