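"""Simulate one expert day of the auditory-motor discrimination task.

Two single-association phases (low tone -> pull, high tone -> push) run
back to back, each ending at the 100-reward session cap with 10 ul per
reward, so a perfect performer earns 2 ml of water in a day.
"""

from pushpull import agents, task_engine

cfg = task_engine.AuditoryMotorConfig(threshold_mm=3.0)
logs, total_ml = task_engine.run_auditory_day(
    agents.PerfectAuditoryAgent(), cfg, rng=7, order=("low", "high")
)

for phase, log in zip(("low->pull", "high->push"), logs):
    minutes = log.events[-1].t / 60_000
    print(
        f"phase {phase}: {len(log.trials)} trials, {log.n_rewards} rewards "
        f"in {minutes:.1f} simulated minutes"
    )
print(f"total water dispensed: {total_ml:.1f} ml")
# Each phase stops exactly at the reward cap; the daily total of 200
# correct trials at 10 ul/reward is the 2 ml an expert animal consumes.
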