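"""Virtual behaving agents and synthetic trajectory generators.

Agents supply a choice policy for the simulated tasks; the trajectory
generators supply controllable ground truth for the kinematics and
movement-bout analyses:

* :func:`generate_trajectory_2d` — styled 2-D push/pull reaches whose
  tortuosity, explored area and speed vary with a learning-stage scalar
  (0 = naive, 1 = expert).  Pushes are biased downward-forward, pulls
  upward-backward, matching how mice actually displace the stick.
* :func:`generate_ap_trace` — 1-D anteroposterior traces composed of
  programmed movement bouts with smooth cosine-ramp velocity profiles,
  the closed-loop fixture for bout segmentation.

The value model is a two-parameter forgetting Q-learner: the chosen
action's value moves toward the reward by rate ``alpha`` while the
unchosen action's value decays toward zero at the same rate
("nondifferential" forgetting); choices are softmax in the value
difference with inverse temperature ``beta``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .signal_io import PositionTrace

__all__ = [
    "QAgentParams",
    "AgentState",
    "TrajectoryStyle",
    "BoutSpec",
    "softmax_choice_prob",
    "q_update",
    "wsls_policy",
    "QAgent",
    "WslsAgent",
    "OracleAgent",
    "RandomAgent",
    "AlwaysAgent",
    "generate_trajectory_2d",
    "generate_ap_trace",
    "make_agent",
]

PUSH, PULL = "push", "pull"


@dataclass(frozen=True)
class QAgentParams:
    """Parameters of the forgetting Q-learner plus optional vigor coupling.

    alpha : shared learning/forgetting rate in (0, 1].
    beta : softmax inverse temperature, >= 0.
    q_init : initial value of both actions.
    vigor_gain : extra peak displacement (mm) per unit total value
        (q_push + q_pull); models value-invigorated movement.
    latency_gain : reduction in choice latency (ms) per unit total value.
    """

    alpha: float = 0.5
    beta: float = 3.0
    q_init: float = 0.0
    vigor_gain: float = 0.0
    latency_gain: float = 0.0
    # subjective reward scaling by volume (r * volume / max volume); off by
    # default so the fitted model's {0,1} reward convention holds exactly
    volume_sensitive: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclass(frozen=True)
class AgentState:
    q_push: float = 0.0
    q_pull: float = 0.0


def softmax_choice_prob(state: AgentState, params: QAgentParams) -> float:
    """P(push) = logistic(beta * (q_push - q_pull))."""
    z = params.beta * (state.q_push - state.q_pull)
    # logistic via stable branches
    if z >= 0:
        return 1.0 / (1.0 + np.exp(-z))
    ez = np.exp(z)
    return ez / (1.0 + ez)


def q_update(
    state: AgentState, choice: str, reward: float, params: QAgentParams
) -> AgentState:
    """One forgetting-Q update.

    Chosen action: Q <- Q + alpha (r - Q).  Unchosen action decays toward
    zero at the same rate: Q <- (1 - alpha) Q.
    """
    if choice not in (PUSH, PULL):
        raise ValueError(f"choice must be push or pull, got {choice!r}")
    a = params.alpha
    if choice == PUSH:
        return AgentState(
            q_push=state.q_push + a * (reward - state.q_push),
            q_pull=(1 - a) * state.q_pull,
        )
    return AgentState(
        q_push=(1 - a) * state.q_push,
        q_pull=state.q_pull + a * (reward - state.q_pull),
    )


def wsls_policy(prev_choice: str | None, prev_reward: int | None, rng=None) -> str:
    """Win-stay/lose-switch: repeat after reward, switch otherwise.

    With no previous trial, choose at random (rng required then).
    """
    if prev_choice is None:
        if rng is None:
            raise ValueError("first trial needs an rng")
        return PUSH if rng.random() < 0.5 else PULL
    if prev_reward:
        return prev_choice
    return PULL if prev_choice == PUSH else PUSH


class QAgent:
    """Softmax forgetting-Q agent for the bandit task."""

    def __init__(self, params: QAgentParams | None = None):
        self.params = params or QAgentParams()
        self.state = AgentState(self.params.q_init, self.params.q_init)

    def choose(self, rng: np.random.Generator, high_side: str | None = None) -> str:
        p = softmax_choice_prob(self.state, self.params)
        return PUSH if rng.random() < p else PULL

    def update(self, choice: str, reward: int, volume_ul: float | None = None,
               max_volume_ul: float = 8.0) -> None:
        r = float(reward)
        if self.params.volume_sensitive and volume_ul is not None:
            r *= volume_ul / max_volume_ul
        self.state = q_update(self.state, choice, r, self.params)

    @property
    def total_value(self) -> float:
        return self.state.q_push + self.state.q_pull

    @property
    def abs_delta_q(self) -> float:
        return abs(self.state.q_push - self.state.q_pull)


class WslsAgent:
    """Deterministic win-stay/lose-switch except a random first trial."""

    def __init__(self):
        self.prev_choice: str | None = None
        self.prev_reward: int | None = None

    def choose(self, rng, high_side=None) -> str:
        return wsls_policy(self.prev_choice, self.prev_reward, rng)

    def update(self, choice: str, reward: int) -> None:
        self.prev_choice = choice
        self.prev_reward = reward


class OracleAgent:
    """Always chooses the current high-probability side (tracks reversals)."""

    def choose(self, rng, high_side=None) -> str:
        if high_side is None:
            raise ValueError("oracle agent needs the current high side")
        return high_side

    def update(self, choice, reward) -> None:
        pass


class RandomAgent:
    """Unbiased coin-flip chooser; the value-free null."""

    def choose(self, rng, high_side=None) -> str:
        return PUSH if rng.random() < 0.5 else PULL

    def update(self, choice, reward) -> None:
        pass


class AlwaysAgent:
    """Always emits one fixed action."""

    def __init__(self, action: str = PUSH):
        if action not in (PUSH, PULL):
            raise ValueError("action must be push or pull")
        self.action = action

    def choose(self, rng, high_side=None) -> str:
        return self.action

    def update(self, choice, reward) -> None:
        pass


class PerfectAuditoryAgent:
    """Always performs the cued action with a plausible latency."""

    def __init__(
        self,
        high_action: str = PUSH,
        low_action: str = PULL,
        latency_range_ms: tuple[float, float] = (300.0, 800.0),
    ):
        self.high_action = high_action
        self.low_action = low_action
        self.latency_range_ms = latency_range_ms

    def respond(self, cue: str, rng) -> tuple[str, float]:
        action = self.high_action if cue == "high" else self.low_action
        return action, float(rng.uniform(*self.latency_range_ms))


class NoResponseAgent:
    """Never moves the joystick; every trial is an omission."""

    def respond(self, cue, rng):
        return None


def make_agent(name: str, **kwargs):
    """Agent factory used by the CLI: q | wsls | oracle | random | always."""
    name = name.lower()
    if name == "q":
        params = QAgentParams(
            alpha=kwargs.get("alpha", 0.5),
            beta=kwargs.get("beta", 3.0),
            vigor_gain=kwargs.get("vigor_gain", 0.0),
            latency_gain=kwargs.get("latency_gain", 0.0),
        )
        return QAgent(params)
    if name == "wsls":
        return WslsAgent()
    if name == "oracle":
        return OracleAgent()
    if name == "random":
        return RandomAgent()
    if name == "always":
        return AlwaysAgent(kwargs.get("action", PUSH))
    if name == "perfect":
        return PerfectAuditoryAgent()
    if name == "none":
        return NoResponseAgent()
    raise ValueError(f"unknown agent {name!r}")


# ---------------------------------------------------------------------------
# Synthetic trajectory generators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectoryStyle:
    """Generative knobs for 2-D reach trajectories.

    ``stage`` interpolates naive (0) to expert (1) motor execution: the
    effective lateral jitter is jitter_mm * (1 - stage) and the effective
    speed is speed_mm_s * (0.25 + 0.75 * stage), so jitter shrinks and
    speed grows monotonically with learning.
    """

    stage: float = 1.0
    jitter_mm: float = 2.0
    speed_mm_s: float = 40.0
    target_displacement_mm: float = 4.0
    direction: str = PUSH

    def __post_init__(self) -> None:
        if not (0 <= self.stage <= 1):
            raise ValueError("stage must be in [0, 1]")
        if self.direction not in (PUSH, PULL):
            raise ValueError("direction must be push or pull")


def generate_trajectory_2d(
    style: TrajectoryStyle, rng: np.random.Generator, dt_ms: float = 1.0
) -> PositionTrace:
    """Synthesize one out-and-back 2-D reach.

    The path runs from the origin to a target point and back at the styled
    effective speed, with smoothed Gaussian jitter added perpendicular to
    and along the path.  Pushes head anterior and slightly downward
    (+x, -y); pulls posterior and slightly upward (-x, +y).
    """
    jitter = style.jitter_mm * (1.0 - style.stage)
    speed = style.speed_mm_s * (0.25 + 0.75 * style.stage)
    sign = 1.0 if style.direction == PUSH else -1.0
    # downward-forward push / upward-backward pull: |dy| = 40% of |dx|
    target = np.array(
        [sign * style.target_displacement_mm, -sign * 0.4 * style.target_displacement_mm]
    )
    dist = float(np.linalg.norm(target))
    n_leg = max(int(round(dist / speed * 1000.0 / dt_ms)), 2)
    s = np.linspace(0.0, 1.0, n_leg, endpoint=False)
    out = np.outer(s, target)
    back = np.outer(1.0 - s, target)
    pts = np.vstack([out, back, [[0.0, 0.0]]])
    if jitter > 0:
        raw = rng.normal(0.0, jitter, size=pts.shape)
        # box-smooth so jitter looks like wavering, not white noise
        k = max(n_leg // 8, 2)
        kernel = np.ones(k) / k
        sm = np.column_stack(
            [np.convolve(raw[:, j], kernel, mode="same") for j in range(2)]
        )
        # pin endpoints so the reach still starts/ends at rest
        w = np.sin(np.pi * np.linspace(0, 1, len(pts))) ** 2
        pts = pts + sm * w[:, None]
    t = np.arange(len(pts), dtype=float) * dt_ms
    return PositionTrace(t=t, x=pts[:, 0], y=pts[:, 1])


@dataclass(frozen=True)
class BoutSpec:
    """Programmed movement bout for synthetic anteroposterior traces.

    The velocity profile is a cosine ramp up, optional plateau at
    ``peak_speed_mm_s``, and cosine ramp down, so displacement can range
    over [peak*dur/2, peak*dur).  With ``displacement_mm=None`` the profile
    is a pure raised cosine and displacement = peak * dur / 2.
    """

    onset_ms: float
    direction: str
    peak_speed_mm_s: float
    duration_ms: float
    displacement_mm: float | None = None

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")
        if self.peak_speed_mm_s <= 0:
            raise ValueError("peak speed must be positive")
        if self.direction not in (PUSH, PULL):
            raise ValueError("direction must be push or pull")
        if self.displacement_mm is not None:
            if self.displacement_mm <= 0:
                raise ValueError("displacement magnitude must be positive")
            peak_dist = self.peak_speed_mm_s * self.duration_ms / 1000.0
            if not (peak_dist / 2 <= self.displacement_mm < peak_dist):
                raise ValueError(
                    "displacement must lie in [peak*dur/2, peak*dur) "
                    "for a ramp-plateau-ramp profile"
                )

    @property
    def signed_displacement(self) -> float:
        d = (
            self.displacement_mm
            if self.displacement_mm is not None
            else self.peak_speed_mm_s * self.duration_ms / 2000.0
        )
        return d if self.direction == PUSH else -d

    def speed_profile(self, t_ms: np.ndarray) -> np.ndarray:
        """Unsigned speed (mm/s) at times ``t_ms`` relative to onset."""
        dur = self.duration_ms
        peak = self.peak_speed_mm_s
        disp = abs(self.signed_displacement) * 1000.0  # mm -> mm/s*ms units
        # ramp length r solves disp = peak*(dur - r); plateau = dur - 2r
        r = dur - disp / peak
        v = np.zeros_like(t_ms, dtype=float)
        inside = (t_ms >= 0) & (t_ms <= dur)
        tt = t_ms[inside]
        vv = np.full(tt.shape, peak)
        up = tt < r
        vv[up] = peak * 0.5 * (1 - np.cos(np.pi * tt[up] / r)) if r > 0 else peak
        down = tt > dur - r
        if r > 0:
            vv[down] = peak * 0.5 * (1 - np.cos(np.pi * (dur - tt[down]) / r))
        v[inside] = vv
        return v


def generate_ap_trace(
    bouts: Sequence[BoutSpec],
    n_ms: int,
    noise_mm: float = 0.0,
    rng: np.random.Generator | None = None,
    dt_ms: float = 1.0,
) -> PositionTrace:
    """Build a 1-D anteroposterior trace from programmed bouts plus noise.

    Bouts must not overlap in time.  Position is the running integral of
    the signed bout velocities; Gaussian baseline noise of scale
    ``noise_mm`` is added on top.  ``y`` is identically zero (the value
    task physically constrains motion to the AP axis).
    """
    order = sorted(bouts, key=lambda b: b.onset_ms)
    for a, b in zip(order, order[1:]):
        if a.onset_ms + a.duration_ms > b.onset_ms:
            raise ValueError("bouts overlap in time")
    t = np.arange(0, n_ms, dt_ms, dtype=float)
    v = np.zeros_like(t)
    for spec in order:
        sgn = 1.0 if spec.direction == PUSH else -1.0
        v += sgn * spec.speed_profile(t - spec.onset_ms)
    x = np.cumsum(v) * dt_ms / 1000.0
    if noise_mm > 0:
        if rng is None:
            raise ValueError("noise requires an rng")
        x = x + rng.normal(0.0, noise_mm, size=x.shape)
    return PositionTrace(t=t, x=x, y=np.zeros_like(t))
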