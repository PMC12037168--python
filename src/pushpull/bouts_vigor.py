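"""Movement-bout segmentation and per-trial vigor readouts.

The value task constrains joystick motion to the anteroposterior axis, so
a trial reduces to a 1-D position trace.  Deliberating animals produce
several sub-threshold excursions ("movement bouts") before the decisive,
threshold-crossing bout.  A bout is a unidirectional velocity episode
that (1) starts above an initiation speed of 7.5 mm/s, (2) sustains
> 2.5 mm/s in one direction for more than 50 ms, and (3) ends at a
velocity sign change, at the speed floor, or when the joystick retracts.

Per-trial readouts: peak displacement, bout count, directional
consistency (fraction of bouts in the majority direction), mean speed of
the decisive bout, total path length, and choice latency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import PositionTrace

__all__ = [
    "Bout",
    "TrialKinematics",
    "velocity_trace",
    "segment_bouts",
    "directional_consistency",
    "trial_vigor_metrics",
    "INITIATION_SPEED_MM_S",
    "SUSTAIN_SPEED_MM_S",
    "SUSTAIN_MS",
]

INITIATION_SPEED_MM_S = 7.5
SUSTAIN_SPEED_MM_S = 2.5
SUSTAIN_MS = 50.0


@dataclass
class Bout:
    """One unidirectional movement episode on the anteroposterior axis."""

    t_start: float
    t_end: float
    direction: str  # 'push' | 'pull'
    peak_speed: float  # mm/s, unsigned
    displacement: float  # mm, signed (positive = push)
    is_decisive: bool = False

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("bout must have positive duration")
        if self.peak_speed <= 0:
            raise ValueError("peak speed must be positive")
        if self.displacement > 0 and self.direction != "push":
            raise ValueError("positive displacement implies push")
        if self.displacement < 0 and self.direction != "pull":
            raise ValueError("negative displacement implies pull")

    @property
    def duration_ms(self) -> float:
        return self.t_end - self.t_start

    def contains(self, t: float) -> bool:
        return self.t_start <= t <= self.t_end


@dataclass
class TrialKinematics:
    """Vigor and kinematic readouts for one trial."""

    peak_displacement: float
    n_bouts: int
    directional_consistency: float | None
    decisive_mean_velocity: float | None
    path_length: float
    choice_latency: float | None
    decisive_fallback: bool = False


def velocity_trace(trace: PositionTrace) -> np.ndarray:
    """Signed anteroposterior velocity (mm/s) on the trace's time base.

    Central finite differences on interior samples, one-sided at the
    endpoints.  The trace should already be 20 ms-smoothed and
    re-baselined so the speed thresholds are meaningful.
    """
    if len(trace) < 3:
        raise ValueError("need at least 3 samples to differentiate")
    return np.gradient(trace.x, trace.t) * 1000.0


def segment_bouts(
    v: np.ndarray,
    t: np.ndarray | None = None,
    retract_t: float | None = None,
    dt_ms: float = 1.0,
    initiation: float = INITIATION_SPEED_MM_S,
    sustain: float = SUSTAIN_SPEED_MM_S,
    sustain_ms: float = SUSTAIN_MS,
    x: np.ndarray | None = None,
) -> list[Bout]:
    """Segment a velocity sequence into movement bouts.

    A candidate episode is a maximal run of samples moving in one
    direction with |v| strictly above the sustain floor; it becomes a
    bout when it contains at least one sample strictly above the
    initiation speed and its floor-to-floor span strictly exceeds
    ``sustain_ms``.  Episodes close at a velocity sign change, at the
    sustain floor, or at ``retract_t``; a sign change can immediately
    open an opposite-direction episode.  Bouts are non-overlapping and
    time-ordered.
    """
    v = np.asarray(v, dtype=float)
    if t is None:
        t = np.arange(len(v), dtype=float) * dt_ms
    else:
        t = np.asarray(t, dtype=float)
    if retract_t is not None:
        keep = t <= retract_t
        v, t = v[keep], t[keep]
        if x is not None:
            x = np.asarray(x, dtype=float)[keep]
    bouts: list[Bout] = []
    n = len(v)
    i = 0
    while i < n:
        if abs(v[i]) > sustain:
            sgn = np.sign(v[i])
            j = i
            while j + 1 < n and abs(v[j + 1]) > sustain and np.sign(v[j + 1]) == sgn:
                j += 1
            initiated = bool(np.any(np.abs(v[i : j + 1]) > initiation))
            if initiated and t[j] - t[i] > sustain_ms:
                direction = "push" if sgn > 0 else "pull"
                if x is not None:
                    disp = float(x[j] - x[i])
                    # numerical zero-crossings can leave a hair of the
                    # wrong sign; clamp to the bout's direction
                    if disp * sgn <= 0:
                        disp = sgn * 1e-9
                else:
                    disp = float(np.trapezoid(v[i : j + 1], t[i : j + 1]) / 1000.0)
                    if disp * sgn <= 0:
                        disp = sgn * 1e-9
                bouts.append(
                    Bout(
                        t_start=float(t[i]),
                        t_end=float(t[j]),
                        direction=direction,
                        peak_speed=float(np.abs(v[i : j + 1]).max()),
                        displacement=disp,
                    )
                )
            i = j + 1
        else:
            i += 1
    return bouts


def directional_consistency(bouts: list[Bout]) -> float:
    """Fraction of bouts in the most frequent direction; 1 = all one way."""
    if not bouts:
        raise ValueError("directional consistency undefined with no bouts")
    n_push = sum(b.direction == "push" for b in bouts)
    return max(n_push, len(bouts) - n_push) / len(bouts)


def trial_vigor_metrics(
    trace: PositionTrace,
    bouts: list[Bout],
    t_go: float,
    t_choice: float | None,
    v: np.ndarray | None = None,
) -> TrialKinematics:
    """Assemble the per-trial vigor readouts.

    The decisive bout is the bout whose span contains the threshold
    crossing ``t_choice``; if smoothing pushed the crossing outside every
    bout, the nearest preceding bout is used and flagged.
    """
    if v is None:
        v = velocity_trace(trace)
    peak = float(np.abs(trace.x).max()) if len(trace) else 0.0
    path = float(np.abs(np.diff(trace.x)).sum())
    decisive = None
    fallback = False
    if t_choice is not None and bouts:
        for b in bouts:
            if b.contains(t_choice):
                decisive = b
                break
        if decisive is None:
            preceding = [b for b in bouts if b.t_start <= t_choice]
            if preceding:
                decisive = preceding[-1]
                fallback = True
    dec_v = None
    if decisive is not None:
        decisive.is_decisive = True
        mask = (trace.t >= decisive.t_start) & (trace.t <= decisive.t_end)
        dec_v = float(np.abs(v[mask]).mean())
    consistency = directional_consistency(bouts) if bouts else None
    return TrialKinematics(
        peak_displacement=peak,
        n_bouts=len(bouts),
        directional_consistency=consistency,
        decisive_mean_velocity=dec_v,
        path_length=path,
        choice_latency=(t_choice - t_go) if t_choice is not None else None,
        decisive_fallback=fallback,
    )
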