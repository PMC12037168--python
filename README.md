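# pushpull

Simulation and analysis toolkit for head-fixed mouse joystick behavior.

Joystick (manipulandum) tasks give rodent neuroscience something lever
presses and licks cannot: a continuous 2-D readout of how a choice is
executed, not just which choice was made.  `pushpull` re-creates the
computational core of such a platform for two paradigms —

* an **auditory-motor 2AFC** task, where a 12 kHz tone (plus five
  overtones) cues a push and a 5 kHz tone cues a pull of the joystick,
  and
* a **two-armed bandit** value task, where push and pull are rewarded
  with probabilities 80 % : 20 % that reverse, un-cued, after each block
  of 17 + Geometric(p = 0.4) rewarded trials —

together with the full analysis chain used on the resulting trajectories:
signal calibration and choice detection, trajectory kinematics,
movement-bout segmentation, and value-model fitting.  Everything runs on
simulated agents and synthetic trajectories, so no animal data is needed
to exercise, test, or extend any analysis.

The package is a library first: import it, or start from the narrative
scripts in `examples/`.  A thin `pushpull` CLI wraps the common
simulate → analyze → report workflows.

## What it computes

**Signal chain** (`pushpull.signal_io`).  10-bit ADC codes (0–1023 over
0–5 V; rest near mid-scale) are calibrated per box to millimeters,
smoothed with the controller's causal 20 ms moving average, re-baselined
against drift at each joystick extension, and monitored for the
anteroposterior threshold crossing (> 3 mm in the value task) that
registers a push or pull.  Convention: +x = anterior = push, +y = up.

**Task engines** (`pushpull.task_engine`).  Deterministic-given-seed
state machines for both paradigms, including ITI/timeout scheduling,
the four bandit trial outcomes (rewarded / unrewarded / omission /
premature), block reversals, the changing-volume phase (2, 4, 8 µl per
block), session caps (30 min or 100 rewards for the auditory task), and
harmonic-stack cue-tone synthesis.

**Kinematics** (`pushpull.kinematics`).  Per-trajectory tortuosity
(path length ÷ first-to-last chord), discrete Fréchet distance
(dynamic-programming, with session means over all trajectory pairs),
movement velocity to the point of maximum displacement, explored area
over a 1 × 1 mm occupancy grid, and circular angular deviation
√(2 (1 − R̄)) ∈ [0, √2].

**Bouts and vigor** (`pushpull.bouts_vigor`).  Velocity-based
segmentation of anteroposterior traces into movement bouts
(initiation > 7.5 mm/s, sustained > 2.5 mm/s for > 50 ms, one
direction), and per-trial readouts: peak displacement, bout count,
directional consistency = n(bouts in majority direction)/n(bouts),
decisive-bout mean velocity, path length, choice latency.

**Value models** (`pushpull.value_models`).  A two-parameter Q-learner
with nondifferential forgetting — chosen action
Q ← Q + α (r − Q), unchosen action Q ← (1 − α) Q, softmax choice
P(push) = σ(β (Q_push − Q_pull)) — fit by grid search plus Nelder–Mead
refinement; |ΔQ| uncertainty splits; win-stay/lose-switch rates; lagged
logistic regression of choice repetition on outcome history; and
rank-based trend tests of vigor against reward volume and uncertainty.

**Agents and generators** (`pushpull.agents`).  Q-learning, WSLS,
oracle, random and fixed-action agents; styled 2-D reach generation
whose tortuosity/spread/speed track a learning-stage parameter; and
programmed-bout 1-D trace generation used as segmentation ground truth.

## Worked example

```bash
python examples/02_bandit_qagent.py
```

```
completed trials: 2000, rewarded fraction 0.640
fitted alpha = 0.506 (true 0.5), beta = 3.00 (true 3.0), NLL = 831.6
P(stay | win) = 0.898, P(switch | lose) = 0.402
lag-1 regression: rewarded weight +2.18, unrewarded weight +0.40
```

A softmax forgetting-Q agent (α = 0.5, β = 3) plays 2,000 bandit trials;
the maximum-likelihood refit lands on the generative parameters, the
agent stays after wins far more than after losses, and the positive
rewarded-outcome regression weight shows past rewards pulling the next
choice toward repetition.  The other examples cover the auditory session
(`01`), learning-stage kinematics (`03`), bout segmentation and the
uncertainty signature of vigor (`04`), and the raw ADC signal chain
(`05`).

CLI equivalents:

```bash
pushpull simulate bandit --agent q --alpha 0.5 --beta 3 --trials 500 --seed 7 --out run/
pushpull fit qmodel --session run/session0_trials.tsv --out fit.json
pushpull report --bundle run/
pushpull tone --freq 5000 --out low.wav
```

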