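"""Deterministic-given-seed state machines for the two behavioral paradigms.

Auditory-motor 2AFC
    A 2-5 s pretrial interval precedes a 500 ms tone (12 kHz -> push,
    5 kHz -> pull, each with five overtones).  The animal has a 5 s window
    to displace the joystick; a correct displacement triggers reward after
    a 200 ms delay, anything else is an omission punished with white noise
    and a reset ITI.  Sessions cap at 30 min or 100 rewards, whichever
    comes first; a daily run trains both single associations back to back.

Two-armed bandit (value task)
    After the joystick extends and a 100 ms wait, a GO cue opens a 10 s
    response window.  An anteroposterior displacement of >3 mm registers a
    choice; reward is Bernoulli(0.8) on the current high side and
    Bernoulli(0.2) on the low side.  Blocks last 17 rewarded trials plus a
    Geometric(p=0.4) extension, then the high side reverses without any
    cue.  In the changing-volume phase the per-reward volume is redrawn
    from {2, 4, 8} ul at each reversal.  Outcomes: rewarded, unrewarded,
    omission (no choice in the window; white noise + 15 s timeout) and
    premature (choice before GO; same punishment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .agents import PULL, PUSH, BoutSpec, generate_ap_trace
from .signal_io import EventRecord, PositionTrace, detect_choice, moving_average

__all__ = [
    "AuditoryMotorConfig",
    "ValueTaskConfig",
    "TrialRecord",
    "SessionLog",
    "TracePolicy",
    "draw_block_length",
    "assign_reward",
    "run_bandit_session",
    "run_auditory_session",
    "run_auditory_day",
    "synthesize_tone",
    "write_wav",
]


@dataclass(frozen=True)
class AuditoryMotorConfig:
    """Auditory-motor discrimination task constants (times in the units named)."""

    iti_range_s: tuple[float, float] = (2.0, 5.0)
    cue_ms: int = 500
    response_window_s: float = 5.0
    reward_delay_ms: int = 200
    noise_on_omission_s: float = 5.0
    session_max_min: float = 30.0
    session_max_rewards: int = 100
    reward_ul: float = 10.0
    high_tone_hz: float = 12000.0
    low_tone_hz: float = 5000.0
    n_overtones: int = 5
    high_tone_action: str = PUSH
    low_tone_action: str = PULL
    # the rig spec leaves the displacement threshold as a free parameter
    threshold_mm: float | None = None

    def __post_init__(self) -> None:
        if self.high_tone_action == self.low_tone_action:
            raise ValueError("tone actions must be distinct")
        for v in (self.cue_ms, self.response_window_s, self.reward_delay_ms,
                  self.session_max_min):
            if v <= 0:
                raise ValueError("durations must be positive")


@dataclass(frozen=True)
class ValueTaskConfig:
    """Two-armed bandit task constants."""

    pre_go_wait_ms: int = 100
    response_window_s: float = 10.0
    iti_range_s: tuple[float, float] = (2.5, 8.0)
    timeout_s: float = 15.0
    p_high: float = 0.8
    p_low: float = 0.2
    block_min_rewarded: int = 17
    block_geom_p: float = 0.4
    volumes_ul: tuple[float, ...] = (2.0, 4.0, 8.0)
    choice_threshold_mm: float = 3.0
    changing_volume: bool = False
    fixed_volume_ul: float = 4.0

    def __post_init__(self) -> None:
        if not (0 < self.p_low < self.p_high <= 1):
            raise ValueError("need 0 < p_low < p_high <= 1")
        if self.block_min_rewarded < 1:
            raise ValueError("block_min_rewarded must be >= 1")
        if not (0 < self.block_geom_p < 1):
            raise ValueError("block_geom_p must be in (0, 1)")


@dataclass(frozen=True)
class TrialRecord:
    index: int
    block_id: int
    high_side: str
    volume_ul: float
    cue: str  # 'high' | 'low' | 'none'
    choice: str  # 'push' | 'pull' | 'none'
    outcome: str  # 'rewarded' | 'unrewarded' | 'omission' | 'premature'
    choice_latency_ms: float | None
    trace_ref: int | None = None

    def __post_init__(self) -> None:
        if self.outcome == "omission" and self.choice != "none":
            raise ValueError("omission implies no registered choice")
        if self.outcome in ("rewarded", "unrewarded") and self.choice == "none":
            raise ValueError(f"{self.outcome} requires a registered choice")


@dataclass
class SessionLog:
    """One simulated session: config snapshot, trials, events, traces, seed."""

    config: object
    trials: list[TrialRecord] = field(default_factory=list)
    events: list[EventRecord] = field(default_factory=list)
    traces: list[PositionTrace] = field(default_factory=list)
    rng_seed: int | None = None

    @property
    def n_rewards(self) -> int:
        return sum(t.outcome == "rewarded" for t in self.trials)

    def outcome_counts(self) -> dict:
        counts = {"rewarded": 0, "unrewarded": 0, "omission": 0, "premature": 0}
        for t in self.trials:
            counts[t.outcome] += 1
        return counts


def draw_block_length(p: float, min_rewarded: int, rng: np.random.Generator) -> int:
    """Rewarded-trial count before a reversal: min + Geometric(p) on {0,1,...}.

    numpy's Geometric lives on {1, 2, ...} (number of trials to first
    success), so subtract 1 to get the number-of-failures convention, under
    which the printed minimum block length is attainable.
    """
    if not (0 < p < 1):
        if p >= 1:
            return min_rewarded
        raise ValueError("p must be in (0, 1)")
    return int(min_rewarded + rng.geometric(p) - 1)


def assign_reward(
    choice: str, high_side: str, cfg: ValueTaskConfig, rng: np.random.Generator
) -> bool:
    """Bernoulli reward draw: p_high on the high side, p_low otherwise."""
    if choice not in (PUSH, PULL):
        raise ValueError("reward assignment requires a registered choice")
    p = cfg.p_high if choice == high_side else cfg.p_low
    return bool(rng.random() < p)


class TracePolicy:
    """Generates per-trial anteroposterior traces for the bandit engine.

    A trial's trace is a sequence of sub-threshold deliberation bouts
    followed (on choice trials) by a supra-threshold decisive bout.
    ``uncertainty`` in [0, 1] scales deliberation: more bouts in mixed
    directions, hence more path length and lower directional consistency.
    Vigor coupling enters through ``extra_displacement_mm`` (added to the
    decisive bout) and ``latency_offset_ms`` (subtracted from the base
    latency), both clamped to keep the trial physical.
    """

    def __init__(
        self,
        base_latency_ms: float = 900.0,
        base_displacement_mm: float = 4.5,
        deliberation_rate: float = 3.0,
        mixing: float = 0.5,
        noise_mm: float = 0.02,
        tail_ms: int = 300,
    ):
        self.base_latency_ms = base_latency_ms
        self.base_displacement_mm = base_displacement_mm
        self.deliberation_rate = deliberation_rate
        self.mixing = mixing
        self.noise_mm = noise_mm
        self.tail_ms = tail_ms

    def build(
        self,
        choice: str,
        t_go_ms: float,
        window_ms: float,
        rng: np.random.Generator,
        uncertainty: float = 0.5,
        extra_displacement_mm: float = 0.0,
        latency_offset_ms: float = 0.0,
        premature: bool = False,
    ) -> tuple[PositionTrace, float]:
        """Return (trace, total_duration_ms); trace starts at joystick extend."""
        latency = max(self.base_latency_ms - latency_offset_ms, 250.0)
        latency *= 0.8 + 0.4 * rng.random()
        bouts: list[BoutSpec] = []
        if premature and choice in (PUSH, PULL):
            # cross well before the GO cue: fast decisive bout from the start
            disp = max(self.base_displacement_mm + extra_displacement_mm, 3.6)
            dur = 110.0 + 20.0 * rng.random()
            peak = 1500.0 * disp / dur  # disp sits mid-range of the profile
            bouts.append(BoutSpec(5.0, choice, peak, dur, disp))
            total = 5.0 + dur + self.tail_ms
            trace = generate_ap_trace(
                bouts, n_ms=int(np.ceil(total)) + 1,
                noise_mm=self.noise_mm, rng=rng,
            )
            return trace, total
        t_cross_target = t_go_ms + latency
        # deliberation bouts in the pre-decision span, paired out-and-back
        n_delib = rng.poisson(self.deliberation_rate * uncertainty)
        span_end = t_cross_target - 220.0
        cursor = 60.0
        for _ in range(n_delib):
            if cursor + 240.0 >= span_end:
                break
            d = PUSH if rng.random() < self.mixing else PULL
            amp = 0.4 + 0.8 * rng.random()  # mm, well below threshold
            dur = 90.0 + 40.0 * rng.random()
            peak = 2000.0 * amp / dur  # raised-cosine: disp = peak*dur/2000
            out = BoutSpec(cursor, d, peak, dur, None)
            back = BoutSpec(
                cursor + dur + 10.0,
                PULL if d == PUSH else PUSH,
                peak,
                dur,
                None,
            )
            bouts.extend([out, back])
            cursor += 2 * dur + 40.0 + rng.random() * 120.0
        if choice in (PUSH, PULL):
            disp = max(self.base_displacement_mm + extra_displacement_mm, 3.6)
            # uncertain trials end in brisker decisive bouts (shorter, faster)
            dur = 140.0 + 100.0 * (1.0 - uncertainty) + 40.0 * rng.random()
            peak = 1500.0 * disp / dur  # disp = 2/3 of peak*dur: mid-profile
            onset = max(t_cross_target - 0.55 * dur, cursor + 20.0)
            bouts.append(BoutSpec(onset, choice, peak, dur, disp))
            total = onset + dur + self.tail_ms
        else:
            total = t_go_ms + window_ms
        n_ms = int(np.ceil(total)) + 1
        trace = generate_ap_trace(
            sorted(bouts, key=lambda b: b.onset_ms),
            n_ms=n_ms,
            noise_mm=self.noise_mm,
            rng=rng,
        )
        return trace, float(n_ms)


def _choice_uncertainty(agent) -> float:
    dq = getattr(agent, "abs_delta_q", None)
    if dq is None:
        return 0.5
    return float(np.clip(1.0 - dq, 0.0, 1.0))


def run_bandit_session(
    agent,
    cfg: ValueTaskConfig,
    n_trials: int,
    rng: np.random.Generator | int,
    trace_policy: TracePolicy | None = None,
    p_omit: float = 0.0,
    p_premature: float = 0.0,
) -> SessionLog:
    """Simulate a bandit session of ``n_trials`` trials.

    With a :class:`TracePolicy`, every trial gets a synthetic joystick
    trace and the choice is registered by running the real-time chain
    (20 ms moving average, re-baseline, >threshold crossing) on it —
    the engine then classifies the trial from the detected crossing, so
    outcome labels are guaranteed consistent with the trace.  Without a
    policy the agent's intent is taken directly (fast path).
    """
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng) if seed is not None else rng
    log = SessionLog(config=cfg, rng_seed=seed)
    t = 0
    log.events.append(EventRecord(t, "session_start", {"task": "bandit"}))
    high_side = PUSH if rng.random() < 0.5 else PULL
    block_id = 0
    block_target = draw_block_length(cfg.block_geom_p, cfg.block_min_rewarded, rng)
    block_rewarded = 0
    volume = (
        float(rng.choice(cfg.volumes_ul)) if cfg.changing_volume
        else cfg.fixed_volume_ul
    )
    window_ms = cfg.response_window_s * 1000.0

    for i in range(n_trials):
        log.events.append(
            EventRecord(t, "trial_start", {"block_id": block_id, "high_side": high_side})
        )
        log.events.append(EventRecord(t, "joystick_extend", {}))
        t_go = t + cfg.pre_go_wait_ms
        log.events.append(EventRecord(t_go, "go_cue", {}))

        u = rng.random()
        premature = u < p_premature
        omit = (not premature) and (u < p_premature + p_omit)
        intent = "none" if omit else agent.choose(rng, high_side=high_side)

        choice, latency, trace_ref = intent, None, None
        if trace_policy is not None:
            uncert = _choice_uncertainty(agent)
            extra_mm, lat_off = 0.0, 0.0
            params = getattr(agent, "params", None)
            if params is not None:
                tv = getattr(agent, "total_value", 0.0)
                extra_mm = params.vigor_gain * tv
                lat_off = params.latency_gain * tv
            trace, dur_ms = trace_policy.build(
                intent,
                t_go_ms=float(cfg.pre_go_wait_ms),
                window_ms=window_ms,
                rng=rng,
                uncertainty=uncert,
                extra_displacement_mm=extra_mm,
                latency_offset_ms=lat_off,
                premature=premature,
            )
            smoothed = moving_average(trace, 20.0)
            rec = detect_choice(smoothed, cfg.choice_threshold_mm)
            choice = rec.direction
            if rec.t_cross is not None:
                latency = rec.t_cross - cfg.pre_go_wait_ms
            log.traces.append(trace)
            trace_ref = len(log.traces) - 1
            premature = rec.t_cross is not None and rec.t_cross < cfg.pre_go_wait_ms
        else:
            if not omit and not premature:
                latency = float(rng.uniform(300, 3000))
            dur_ms = (
                cfg.pre_go_wait_ms + (latency or window_ms)
                + (300.0 if not omit else 0.0)
            )

        if premature and choice != "none":
            outcome = "premature"
            log.events.append(EventRecord(int(t_go), "premature", {}))
            log.events.append(EventRecord(int(t_go), "white_noise_on", {}))
            t = int(t + dur_ms + cfg.timeout_s * 1000)
        elif choice == "none":
            outcome = "omission"
            t_end = t + cfg.pre_go_wait_ms + window_ms
            log.events.append(EventRecord(int(t_end), "omission", {}))
            log.events.append(EventRecord(int(t_end), "white_noise_on", {}))
            t = int(t_end + cfg.timeout_s * 1000)
        else:
            t_choice = int(t + dur_ms)
            log.events.append(EventRecord(t_choice, f"choice_{choice}", {}))
            rewarded = assign_reward(choice, high_side, cfg, rng)
            try:
                agent.update(choice, int(rewarded), volume_ul=volume)
            except TypeError:
                agent.update(choice, int(rewarded))
            if rewarded:
                outcome = "rewarded"
                block_rewarded += 1
                log.events.append(
                    EventRecord(t_choice, "reward", {"volume_ul": volume})
                )
            else:
                outcome = "unrewarded"
            iti = rng.uniform(*cfg.iti_range_s) * 1000
            log.events.append(EventRecord(t_choice, "iti_start", {}))
            t = int(t_choice + iti)
        log.events.append(EventRecord(t, "joystick_retract", {}))

        log.trials.append(
            TrialRecord(
                index=i,
                block_id=block_id,
                high_side=high_side,
                volume_ul=volume,
                cue="none",
                choice=choice if outcome != "premature" else choice,
                outcome=outcome,
                choice_latency_ms=latency,
                trace_ref=trace_ref,
            )
        )

        if block_rewarded >= block_target:
            high_side = PULL if high_side == PUSH else PUSH
            block_id += 1
            block_rewarded = 0
            block_target = draw_block_length(
                cfg.block_geom_p, cfg.block_min_rewarded, rng
            )
            if cfg.changing_volume:
                volume = float(rng.choice(cfg.volumes_ul))
            log.events.append(
                EventRecord(t, "block_reversal", {"block_id": block_id,
                                                  "high_side": high_side})
            )
    log.events.append(EventRecord(t, "session_end", {}))
    return log


def run_auditory_session(
    agent,
    cfg: AuditoryMotorConfig,
    rng: np.random.Generator | int,
    cue_set: Sequence[str] = ("high", "low"),
) -> SessionLog:
    """Simulate one auditory-motor session.

    ``cue_set`` restricts the presented tones — single-association phases
    pass ("high",) or ("low",).  The agent maps a cue to (action,
    latency_ms) or None; a correct action within the response window earns
    a reward after the delay, anything else is an omission with white
    noise and a reset ITI.  The session halts at the reward cap or the
    time cap, whichever first.
    """
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng) if seed is not None else rng
    log = SessionLog(config=cfg, rng_seed=seed)
    t = 0
    max_ms = cfg.session_max_min * 60_000
    log.events.append(EventRecord(t, "session_start", {"task": "auditory"}))
    i = 0
    while log.n_rewards < cfg.session_max_rewards:
        iti = rng.uniform(*cfg.iti_range_s) * 1000
        t = int(t + iti)
        if t >= max_ms:
            t = int(max_ms)
            break
        log.events.append(EventRecord(t, "trial_start", {"cue_set": "/".join(cue_set)}))
        cue = cue_set[0] if len(cue_set) == 1 else str(rng.choice(list(cue_set)))
        correct = cfg.high_tone_action if cue == "high" else cfg.low_tone_action
        log.events.append(EventRecord(t, "cue_on", {"cue": cue}))
        t_cue_end = t + cfg.cue_ms
        resp = agent.respond(cue, rng) if hasattr(agent, "respond") else None
        window_ms = cfg.response_window_s * 1000
        if resp is not None:
            action, lat = resp
            lat = float(min(max(lat, 1.0), window_ms))
        else:
            action, lat = "none", None
        if action == correct and lat is not None:
            t_choice = int(t_cue_end + lat)
            log.events.append(EventRecord(t_choice, f"choice_{action}", {}))
            t_rew = t_choice + cfg.reward_delay_ms
            log.events.append(
                EventRecord(t_rew, "reward", {"volume_ul": cfg.reward_ul})
            )
            outcome = "rewarded"
            latency = lat
            choice = action
            t = t_rew
        else:
            # wrong or absent displacement: omission, noise, reset ITI
            t_end = int(t_cue_end + window_ms)
            if action in (PUSH, PULL) and lat is not None:
                log.events.append(
                    EventRecord(int(t_cue_end + lat), f"choice_{action}", {})
                )
                choice = action
                latency = lat
            else:
                choice = "none"
                latency = None
            log.events.append(EventRecord(t_end, "omission", {}))
            log.events.append(EventRecord(t_end, "white_noise_on", {}))
            outcome = "omission"
            t = int(t_end + cfg.noise_on_omission_s * 1000)
        log.trials.append(
            TrialRecord(
                index=i,
                block_id=0,
                high_side="none",
                volume_ul=cfg.reward_ul if outcome == "rewarded" else 0.0,
                cue=cue,
                choice=choice,
                outcome=outcome,
                choice_latency_ms=latency,
            )
        )
        i += 1
        if t >= max_ms:
            break
    log.events.append(EventRecord(int(min(t, max_ms)), "session_end", {}))
    return log


def run_auditory_day(
    agent, cfg: AuditoryMotorConfig, rng: np.random.Generator | int,
    order: Sequence[str] = ("low", "high"),
) -> tuple[list[SessionLog], float]:
    """Run the two daily single-association phases back to back.

    Returns the two session logs and the total water dispensed in ml.
    Training alternates phase order across days; pass ``order`` accordingly.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    logs = [run_auditory_session(agent, cfg, rng, cue_set=(phase,)) for phase in order]
    total_ul = sum(log.n_rewards * cfg.reward_ul for log in logs)
    return logs, total_ul / 1000.0


# ---------------------------------------------------------------------------
# Tone synthesis
# ---------------------------------------------------------------------------

def synthesize_tone(
    fundamental_hz: float,
    n_overtones: int = 5,
    dur_ms: float = 500.0,
    sample_rate_hz: float = 96000.0,
) -> np.ndarray:
    """Harmonic-stack cue tone, peak-normalized to unit amplitude.

    Sums sinusoids at k * fundamental for k = 1 .. n_overtones + 1 with
    amplitudes 1/k.  Harmonics at or above Nyquist are dropped with a
    warning rather than aliased.
    """
    if fundamental_hz <= 0:
        raise ValueError("fundamental must be positive")
    n = int(round(dur_ms * sample_rate_hz / 1000.0))
    t = np.arange(n) / sample_rate_hz
    wave = np.zeros(n)
    dropped = 0
    for k in range(1, n_overtones + 2):
        f = k * fundamental_hz
        if f >= sample_rate_hz / 2:
            dropped += 1
            continue
        wave += np.sin(2 * np.pi * f * t) / k
    if dropped:
        warnings.warn(
            f"{dropped} harmonic(s) above Nyquist dropped", stacklevel=2
        )
    peak = np.abs(wave).max()
    return wave / peak if peak > 0 else wave


def write_wav(waveform: np.ndarray, path, sample_rate_hz: int = 96000) -> None:
    """Write a unit-amplitude waveform as 16-bit PCM WAV."""
    import wave as _wave

    pcm = np.clip(waveform, -1.0, 1.0)
    pcm = (pcm * 32767).astype("<i2")
    with _wave.open(str(path), "wb") as fh:
        fh.setnchannels(1)
        fh.setsampwidth(2)
        fh.setframerate(sample_rate_hz)
        fh.writeframes(pcm.tobytes())
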