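"""Trial data model, CSV readers/writers and the shared signal-conditioning
front end.

Two measurement modalities are represented:

* :class:`TriaxialAccelTrial` — a trunk-worn accelerometer trial (AP/ML/V
  axes, default 140 Hz) with the auditory "go" stimulus time ``t_s`` on the
  trial clock.
* :class:`ForcePlateTrial` — the gold-standard trial: centre-of-pressure
  (CoP) coordinates and vertical ground-reaction force at 1000 Hz, plus the
  swing-side malleolar marker anteroposterior position at its own rate.

Conventions (asserted throughout the package):

* time is in seconds on a per-trial clock starting at the first sample;
  detected events are reported relative to ``t_s``;
* the internal acceleration unit is m/s² (``g`` accepted on input);
* CoP axes: AP positive anterior, ML positive toward the stance limb;
* the first and last 0.25 s of any filtered signal are edge transient and
  must not be touched by detection windows.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import FormatError, SignalLengthError, WindowError

G_MS2 = 9.80665
#: leading/trailing span of a filtered signal regarded as edge transient [s]
EDGE_GUARD_S = 0.25


# ---------------------------------------------------------------------------
# filter specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter design of the single-pass prototype.

    ``zero_phase`` applies the filter forward and backward (``filtfilt``)
    so pure delays cancel; the quoted cut-offs are design cut-offs of the
    single-pass prototype (two-pass application squares the magnitude
    response).
    """

    kind: str = "band-pass"          # "band-pass" | "low-pass"
    order: int = 4
    low_hz: float | None = 0.2
    high_hz: float = 4.5
    zero_phase: bool = True

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.kind not in ("band-pass", "low-pass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.kind == "band-pass":
            if self.low_hz is None or not 0 < self.low_hz < self.high_hz:
                raise ValueError("band-pass needs 0 < low_hz < high_hz")

    def validate_for(self, fs: float) -> None:
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"high cut-off {self.high_hz} Hz not below Nyquist ({fs / 2} Hz)")


#: default trunk-acceleration conditioning: 4th-order 0.2–4.5 Hz band-pass
ACCEL_BANDPASS = FilterSpec("band-pass", 4, 0.2, 4.5, True)
#: default CoP conditioning: 4th-order zero-lag 10 Hz low-pass
COP_LOWPASS = FilterSpec("low-pass", 4, None, 10.0, True)


# ---------------------------------------------------------------------------
# trial containers
# ---------------------------------------------------------------------------

def _as_f8(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


@dataclass
class TriaxialAccelTrial:
    """One accelerometer trial: AP/ML/V series in m/s² at ``fs`` Hz."""

    trial_id: str
    subject_id: str
    fs: float
    t_s: float
    ap: np.ndarray
    ml: np.ndarray
    v: np.ndarray
    units_in: str = "ms2"

    def __post_init__(self):
        self.ap, self.ml, self.v = map(_as_f8, (self.ap, self.ml, self.v))
        if not (len(self.ap) == len(self.ml) == len(self.v)):
            raise FormatError("ap, ml, v must have identical length")
        if self.fs <= 0:
            raise FormatError("fs must be positive")
        if self.units_in not in ("g", "ms2"):
            raise FormatError(f"units_in must be 'g' or 'ms2', got {self.units_in!r}")
        if self.units_in == "g":
            # convert once at load; keep the declared input unit on record
            self.ap = self.ap * G_MS2
            self.ml = self.ml * G_MS2
            self.v = self.v * G_MS2
            object.__setattr__(self, "_converted_from_g", True)
        if len(self.ap) < self.fs * 4:
            raise WindowError(
                f"trial {self.trial_id!r}: length {len(self.ap)} samples "
                f"< 4 s at {self.fs} Hz; analysis windows cannot fit")
        if not (0.5 <= self.t_s <= self.duration - 2.0):
            raise WindowError(
                f"trial {self.trial_id!r}: t_s={self.t_s} must lie in "
                f"[0.5, duration-2] = [0.5, {self.duration - 2.0:.3f}] s")

    @property
    def n(self) -> int:
        return len(self.ap)

    @property
    def duration(self) -> float:
        return (self.n - 1) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.fs

    def axes(self) -> dict[str, np.ndarray]:
        return {"ap": self.ap, "ml": self.ml, "v": self.v}


@dataclass
class ForcePlateTrial:
    """One gold-standard trial: CoP path, vertical GRF and the swing-side
    malleolar marker AP position (carried at its own rate ``fs_marker``)."""

    trial_id: str
    subject_id: str
    fs: float
    t_s: float
    cop_ap: np.ndarray
    cop_ml: np.ndarray
    grf_v: np.ndarray
    marker_ap: np.ndarray | None = None
    fs_marker: float | None = None
    swing_side: str = "unknown"
    unload_threshold_n: float = 10.0

    def __post_init__(self):
        self.cop_ap, self.cop_ml, self.grf_v = map(
            _as_f8, (self.cop_ap, self.cop_ml, self.grf_v))
        if self.marker_ap is not None:
            self.marker_ap = _as_f8(self.marker_ap)
            if self.fs_marker is None or self.fs_marker <= 0:
                raise FormatError("fs_marker required when marker_ap is present")
        if not (len(self.cop_ap) == len(self.cop_ml) == len(self.grf_v)):
            raise FormatError("cop_ap, cop_ml, grf_v must have identical length")
        if self.fs <= 0:
            raise FormatError("fs must be positive")
        if self.swing_side not in ("left", "right", "unknown"):
            raise FormatError(f"swing_side must be left|right|unknown, got "
                              f"{self.swing_side!r}")
        if np.any(self.grf_v < 0):
            raise FormatError("grf_v must be non-negative everywhere")
        if self.grf_v[-1] >= self.unload_threshold_n:
            raise FormatError(
                f"trial {self.trial_id!r}: grf_v ends at {self.grf_v[-1]:.1f} N, "
                f"above the unloading threshold ({self.unload_threshold_n} N); "
                "stance toe-off is undefined")

    @property
    def n(self) -> int:
        return len(self.cop_ap)

    @property
    def duration(self) -> float:
        return (self.n - 1) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.fs


# ---------------------------------------------------------------------------
# signal conditioning
# ---------------------------------------------------------------------------

def apply_filter(signal: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Filter ``signal`` with the Butterworth design in ``spec``.

    Zero-phase specs use forward-backward application, so a symmetric pulse
    keeps its argmax time. Returns a same-length array.
    """
    signal = _as_f8(signal)
    spec.validate_for(fs)
    if len(signal) <= 3 * spec.order + 1:
        raise SignalLengthError(
            f"signal of {len(signal)} samples too short for order-{spec.order} "
            "filtering")
    if spec.kind == "band-pass":
        sos = sps.butter(spec.order, [spec.low_hz, spec.high_hz],
                         btype="bandpass", fs=fs, output="sos")
    else:
        sos = sps.butter(spec.order, spec.high_hz, btype="lowpass",
                         fs=fs, output="sos")
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, signal)
    return sps.sosfilt(sos, signal)


def differentiate(signal: np.ndarray, fs: float) -> np.ndarray:
    """First time derivative: central differences in the interior, one-sided
    at the ends; same length as the input, units per second."""
    signal = _as_f8(signal)
    if len(signal) < 3:
        raise SignalLengthError("need at least 3 samples to differentiate")
    return np.gradient(signal, 1.0 / fs)


def slice_window(signal: np.ndarray, fs: float, t_start: float, t_end: float,
                 t0: float = 0.0) -> tuple[np.ndarray, int]:
    """Samples whose times lie in the closed interval [t_start, t_end].

    Sample ``i`` sits at time ``t0 + i/fs`` on the trial clock. Returns the
    slice and the absolute index of its first sample so detected indices map
    back to the full trial.
    """
    signal = _as_f8(signal)
    if t_start >= t_end:
        raise WindowError(f"empty window [{t_start}, {t_end}]")
    n = len(signal)
    # first index with time >= t_start, last with time <= t_end
    i0 = int(np.ceil((t_start - t0) * fs - 1e-9))
    i1 = int(np.floor((t_end - t0) * fs + 1e-9))
    if i0 < 0 or i1 >= n:
        raise WindowError(
            f"window [{t_start}, {t_end}] s outside trial "
            f"[{t0}, {t0 + (n - 1) / fs:.4f}] s")
    if i1 < i0:
        raise WindowError(f"window [{t_start}, {t_end}] contains no samples")
    return signal[i0:i1 + 1], i0


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------
# Trial CSV dialect: leading comment lines "# key=value" carry metadata,
# followed by a regular CSV table. IMU files need fs/t_s/units and columns
# time,ap,ml,v; force-platform files need fs/fs_marker/t_s/swing_side and
# columns time,cop_ap,cop_ml,grf_v with a separate marker file time,marker_ap.

def _parse_header(path: Path) -> tuple[dict[str, str], str]:
    meta: dict[str, str] = {}
    body_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if "=" in stripped:
                    key, _, val = stripped.partition("=")
                    meta[key.strip()] = val.strip()
            else:
                body_lines.append(line)
    return meta, "".join(body_lines)


def _read_table(path: Path, required: list[str]) -> tuple[dict[str, str], pd.DataFrame]:
    if not Path(path).exists():
        raise FormatError(f"no such file: {path}")
    meta, body = _parse_header(Path(path))
    try:
        df = pd.read_csv(io.StringIO(body))
    except Exception as exc:  # malformed CSV body
        raise FormatError(f"{path}: cannot parse CSV table: {exc}") from exc
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col}")
    t = df["time"].to_numpy(dtype=float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: non-monotone time column")
    return meta, df


def _meta_float(meta: dict[str, str], key: str, path) -> float:
    if key not in meta:
        raise FormatError(f"{path}: missing header field '# {key}='")
    try:
        return float(meta[key])
    except ValueError as exc:
        raise FormatError(f"{path}: header field {key}={meta[key]!r} "
                          "is not a number") from exc


def default_marker_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_name(p.stem + "_marker" + p.suffix)


def read_trial_csv(path: str | Path, kind: str,
                   marker_path: str | Path | None = None):
    """Read a trial CSV. ``kind`` is ``"imu"`` or ``"forceplate"``.

    For force-platform trials the malleolar marker trace is read from
    ``marker_path`` (default: ``<stem>_marker.csv`` next to the trial file)
    when present.
    """
    path = Path(path)
    if kind == "imu":
        meta, df = _read_table(path, ["time", "ap", "ml", "v"])
        units = meta.get("units", "ms2")
        return TriaxialAccelTrial(
            trial_id=meta.get("trial_id", path.stem),
            subject_id=meta.get("subject_id", ""),
            fs=_meta_float(meta, "fs", path),
            t_s=_meta_float(meta, "t_s", path),
            ap=df["ap"].to_numpy(), ml=df["ml"].to_numpy(),
            v=df["v"].to_numpy(), units_in=units)
    if kind == "forceplate":
        meta, df = _read_table(path, ["time", "cop_ap", "cop_ml", "grf_v"])
        marker_path = Path(marker_path) if marker_path else default_marker_path(path)
        marker = None
        fs_marker = None
        if marker_path.exists():
            mmeta, mdf = _read_table(marker_path, ["time", "marker_ap"])
            marker = mdf["marker_ap"].to_numpy()
            fs_marker = _meta_float({**meta, **mmeta}, "fs_marker", marker_path)
        return ForcePlateTrial(
            trial_id=meta.get("trial_id", path.stem),
            subject_id=meta.get("subject_id", ""),
            fs=_meta_float(meta, "fs", path),
            t_s=_meta_float(meta, "t_s", path),
            cop_ap=df["cop_ap"].to_numpy(), cop_ml=df["cop_ml"].to_numpy(),
            grf_v=df["grf_v"].to_numpy(),
            marker_ap=marker, fs_marker=fs_marker,
            swing_side=meta.get("swing_side", "unknown"))
    raise ValueError(f"kind must be 'imu' or 'forceplate', got {kind!r}")


def write_trial_csv(trial, path: str | Path,
                    marker_path: str | Path | None = None) -> None:
    """Write a trial in the package's CSV dialect (9 significant digits, so
    a read/write round-trip reproduces every numeric field)."""
    path = Path(path)
    fmt = "%.9g"
    if isinstance(trial, TriaxialAccelTrial):
        header = (f"# trial_id={trial.trial_id}\n# subject_id={trial.subject_id}\n"
                  f"# fs={fmt % trial.fs}\n# t_s={fmt % trial.t_s}\n# units=ms2\n")
        df = pd.DataFrame({"time": trial.times, "ap": trial.ap,
                           "ml": trial.ml, "v": trial.v})
    elif isinstance(trial, ForcePlateTrial):
        header = (f"# trial_id={trial.trial_id}\n# subject_id={trial.subject_id}\n"
                  f"# fs={fmt % trial.fs}\n"
                  f"# fs_marker={fmt % (trial.fs_marker or 0)}\n"
                  f"# t_s={fmt % trial.t_s}\n# swing_side={trial.swing_side}\n")
        df = pd.DataFrame({"time": trial.times, "cop_ap": trial.cop_ap,
                           "cop_ml": trial.cop_ml, "grf_v": trial.grf_v})
        if trial.marker_ap is not None:
            mp = Path(marker_path) if marker_path else default_marker_path(path)
            mtimes = np.arange(len(trial.marker_ap)) / trial.fs_marker
            mdf = pd.DataFrame({"time": mtimes, "marker_ap": trial.marker_ap})
            with open(mp, "w") as fh:
                fh.write(f"# trial_id={trial.trial_id}\n"
                         f"# fs_marker={fmt % trial.fs_marker}\n")
                mdf.to_csv(fh, index=False, float_format=fmt)
    else:
        raise TypeError(f"cannot write object of type {type(trial).__name__}")
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format=fmt)
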