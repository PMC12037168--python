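"""Joystick signal I/O: ADC calibration, smoothing, re-baselining and choice detection.

The rig digitizes each joystick axis with a 10-bit ADC: integer codes 0
(0 volts) through 1023 (5 volts), resting near mid-scale.  Per-box linear
calibrations convert codes to millimeters of displacement.  Downstream
analyses operate on :class:`PositionTrace` objects — time-stamped 2-D
position streams in mm, with +x anterior (push), -x posterior (pull) and
+y upward.

Event logs are flat TSV files, one timestamped record per line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AdcSample",
    "Calibration",
    "PositionTrace",
    "EventRecord",
    "ChoiceRecord",
    "EVENT_KINDS",
    "adc_to_mm",
    "code_to_volts",
    "moving_average",
    "rebaseline",
    "detect_choice",
    "read_event_log",
    "write_event_log",
    "read_trace_csv",
    "write_trace_csv",
    "read_calibration",
    "write_calibration",
]


@dataclass(frozen=True)
class AdcSample:
    """One raw joystick sample: time in ms plus 10-bit codes per axis."""

    t: int
    x_code: int
    y_code: int


@dataclass(frozen=True)
class Calibration:
    """Per-box linear map from ADC counts to millimeters.

    ``slope_*`` is mm per ADC count; ``offset_*`` shifts the result in mm.
    ``center_code`` is the code treated as the mechanical rest point
    (mid-scale 512 by default; physical sticks rest near ~500).
    """

    box_id: str = "box0"
    slope_x: float = 0.1
    slope_y: float = 0.1
    offset_x: float = 0.0
    offset_y: float = 0.0
    adc_full_scale_volts: float = 5.0
    adc_max_code: int = 1023
    center_code: int = 512

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope_x) and self.slope_x != 0):
            raise ValueError("slope_x must be finite and nonzero")
        if not (np.isfinite(self.slope_y) and self.slope_y != 0):
            raise ValueError("slope_y must be finite and nonzero")
        if self.adc_max_code < 1:
            raise ValueError("adc_max_code must be >= 1")


@dataclass
class PositionTrace:
    """Time-ordered 2-D joystick positions in mm.

    ``x`` is anteroposterior (positive = anterior = push), ``y`` is
    dorsoventral (positive = up).  ``baseline_x``/``baseline_y`` record the
    baseline that was subtracted, if :func:`rebaseline` has been applied.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    baseline_x: float = 0.0
    baseline_y: float = 0.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)


EVENT_KINDS = frozenset(
    {
        "session_start",
        "trial_start",
        "joystick_extend",
        "joystick_retract",
        "cue_on",
        "go_cue",
        "choice_push",
        "choice_pull",
        "reward",
        "omission",
        "premature",
        "white_noise_on",
        "lick",
        "iti_start",
        "block_reversal",
        "session_end",
    }
)


@dataclass(frozen=True)
class EventRecord:
    """One timestamped task event with an optional key=value payload."""

    t: int
    kind: str
    payload: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind: {self.kind!r}")


@dataclass(frozen=True)
class ChoiceRecord:
    """Result of threshold-crossing choice detection."""

    direction: str  # 'push' | 'pull' | 'none'
    t_cross: float | None = None


def code_to_volts(code, cal: Calibration = Calibration()) -> np.ndarray | float:
    """Map ADC codes to volts: 0 -> 0 V, adc_max_code -> full scale."""
    return cal.adc_full_scale_volts * np.asarray(code, dtype=float) / cal.adc_max_code


def adc_to_mm(samples: Sequence[AdcSample], cal: Calibration) -> PositionTrace:
    """Calibrate raw ADC samples to a millimeter position trace.

    x_mm = slope_x * (x_code - center_code) + offset_x, and analogously
    for y.  Codes outside [0, adc_max_code] reject the whole stream.
    """
    t = np.array([s.t for s in samples], dtype=float)
    xc = np.array([s.x_code for s in samples], dtype=float)
    yc = np.array([s.y_code for s in samples], dtype=float)
    for name, codes in (("x", xc), ("y", yc)):
        if codes.size and (codes.min() < 0 or codes.max() > cal.adc_max_code):
            raise ValueError(
                f"{name}_code outside [0, {cal.adc_max_code}] in sample stream"
            )
    x = cal.slope_x * (xc - cal.center_code) + cal.offset_x
    y = cal.slope_y * (yc - cal.center_code) + cal.offset_y
    return PositionTrace(t=t, x=x, y=y)


def moving_average(trace: PositionTrace, window: float = 20.0) -> PositionTrace:
    """Causal (trailing) moving average over ``window`` ms.

    Each output sample is the mean of the input samples with timestamps in
    (t_i - window, t_i].  This mirrors what a real-time controller computes;
    the output time base is unchanged.  The rig default is 20 ms.
    """
    n = len(trace)
    if n == 0:
        return PositionTrace(t=trace.t, x=trace.x, y=trace.y)
    if n > 1 and window < np.min(np.diff(trace.t)):
        raise ValueError("window must cover at least one sample interval")
    # trailing-window index: first j with t_j > t_i - window
    starts = np.searchsorted(trace.t, trace.t - window, side="right")
    idx = np.arange(n)
    cx = np.concatenate(([0.0], np.cumsum(trace.x)))
    cy = np.concatenate(([0.0], np.cumsum(trace.y)))
    counts = idx + 1 - starts
    x = (cx[idx + 1] - cx[starts]) / counts
    y = (cy[idx + 1] - cy[starts]) / counts
    return PositionTrace(
        t=trace.t.copy(), x=x, y=y,
        baseline_x=trace.baseline_x, baseline_y=trace.baseline_y,
    )


def rebaseline(trace: PositionTrace, baseline_window: float = 50.0) -> PositionTrace:
    """Re-reference a trace to its own initial baseline.

    Baseline = mean position over the first ``baseline_window`` ms after the
    first sample (fresh baseline reads are taken whenever the joystick is
    re-extended, to absorb slow drift).  Returns displacement from baseline.
    """
    if len(trace) == 0:
        return trace
    mask = trace.t < trace.t[0] + baseline_window
    if mask.all() and trace.t[-1] - trace.t[0] < baseline_window:
        warnings.warn(
            "trace shorter than baseline window; using all samples",
            stacklevel=2,
        )
    bx = float(trace.x[mask].mean())
    by = float(trace.y[mask].mean())
    return PositionTrace(
        t=trace.t.copy(), x=trace.x - bx, y=trace.y - by,
        baseline_x=bx, baseline_y=by,
    )


def detect_choice(
    trace: PositionTrace, threshold: float = 3.0, axis: str = "anteroposterior"
) -> ChoiceRecord:
    """First threshold crossing of the anteroposterior axis.

    Deviations strictly greater than ``threshold`` mm from baseline register
    as a choice: push if +x crosses first, pull if -x does.  The rig value
    task uses 3 mm.  Samples after the first crossing are irrelevant.
    """
    if axis != "anteroposterior":
        raise ValueError("only the anteroposterior axis registers choices")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    beyond = np.abs(trace.x) > threshold
    hits = np.flatnonzero(beyond)
    if hits.size == 0:
        return ChoiceRecord("none", None)
    i = hits[0]
    direction = "push" if trace.x[i] > 0 else "pull"
    return ChoiceRecord(direction, float(trace.t[i]))


# ---------------------------------------------------------------------------
# Event-log TSV round trip:  t_ms <TAB> kind <TAB> key=value;key=value
# ---------------------------------------------------------------------------

def _format_payload(payload: dict) -> str:
    return ";".join(f"{k}={payload[k]}" for k in payload)


def _parse_payload(text: str) -> dict:
    payload: dict = {}
    if not text:
        return payload
    for item in text.split(";"):
        k, _, v = item.partition("=")
        payload[k] = v
    return payload


def write_event_log(events: Iterable[EventRecord], path) -> None:
    """Serialize events as TSV; canonical form round-trips byte-stably."""
    lines = []
    for ev in events:
        lines.append(f"{int(ev.t)}\t{ev.kind}\t{_format_payload(ev.payload)}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_event_log(path) -> list[EventRecord]:
    """Parse a TSV event log; malformed lines and unknown kinds raise."""
    events: list[EventRecord] = []
    prev_t = None
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"malformed event line {lineno}: {line!r}")
        try:
            t = int(parts[0])
        except ValueError as exc:
            raise ValueError(f"bad timestamp on line {lineno}: {parts[0]!r}") from exc
        kind = parts[1]
        if kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {kind!r} on line {lineno}")
        if prev_t is not None and t < prev_t:
            raise ValueError(f"non-monotone timestamp on line {lineno}")
        prev_t = t
        events.append(EventRecord(t=t, kind=kind, payload=_parse_payload(parts[2])))
    return events


# ---------------------------------------------------------------------------
# Trace CSV and calibration files
# ---------------------------------------------------------------------------

def write_trace_csv(trace: PositionTrace, path) -> None:
    """Write a trace as CSV with header ``t_ms,x_mm,y_mm``."""
    pd.DataFrame({"t_ms": trace.t, "x_mm": trace.x, "y_mm": trace.y}).to_csv(
        path, index=False
    )


def read_trace_csv(path, cal: Calibration | None = None) -> PositionTrace:
    """Read a trace CSV (``t_ms,x_mm,y_mm`` or raw ``t_ms,x_code,y_code``).

    Raw-code files require a :class:`Calibration` to convert to mm.
    """
    df = pd.read_csv(path)
    if {"x_mm", "y_mm"}.issubset(df.columns):
        return PositionTrace(
            t=df["t_ms"].to_numpy(), x=df["x_mm"].to_numpy(), y=df["y_mm"].to_numpy()
        )
    if {"x_code", "y_code"}.issubset(df.columns):
        if cal is None:
            raise ValueError("raw ADC trace requires a Calibration")
        samples = [
            AdcSample(int(r.t_ms), int(r.x_code), int(r.y_code))
            for r in df.itertuples()
        ]
        return adc_to_mm(samples, cal)
    raise ValueError("trace CSV must have x_mm,y_mm or x_code,y_code columns")


def write_calibration(cal: Calibration, path) -> None:
    """Write a calibration as flat ``key=value`` text."""
    fields = (
        "box_id", "slope_x", "slope_y", "offset_x", "offset_y",
        "adc_full_scale_volts", "adc_max_code", "center_code",
    )
    Path(path).write_text(
        "\n".join(f"{k}={getattr(cal, k)}" for k in fields) + "\n"
    )


def read_calibration(path) -> Calibration:
    kwargs: dict = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        k, _, v = line.partition("=")
        k = k.strip()
        v = v.strip()
        if k == "box_id":
            kwargs[k] = v
        elif k in ("adc_max_code", "center_code"):
            kwargs[k] = int(v)
        else:
            kwargs[k] = float(v)
    return Calibration(**kwargs)
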