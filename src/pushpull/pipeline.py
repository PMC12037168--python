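"""Simulate -> analyze -> report orchestration with explicit seeding.

:func:`run_experiment` executes a :class:`RunConfig` end to end and
writes an artifact bundle: session trial/event tables, per-trial trace
CSVs, kinematics and bout metrics, a Q-model fit, and a manifest that
records the config hash, seeds and package version so any bundle can be
regenerated bit-for-bit.  :func:`report` condenses a bundle into the
summary tables matching the standard figure panels (learning trends,
vigor by volume, uncertainty contrasts).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import agents as _agents
from . import bouts_vigor, kinematics, signal_io, task_engine, value_models

__all__ = ["RunConfig", "run_experiment", "report", "bandit_trial_kinematics"]


@dataclass
class RunConfig:
    """One reproducible simulation + analysis run."""

    task: str = "bandit"  # 'bandit' | 'auditory'
    agent: str = "q"
    agent_kwargs: dict = field(default_factory=dict)
    n_trials: int = 500
    n_sessions: int = 1
    seed: int = 0
    out_dir: str = "run_out"
    changing_volume: bool = False
    with_traces: bool = True
    analyses: tuple[str, ...] = ("bouts", "fit", "value")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _trials_frame(log: task_engine.SessionLog) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "index": t.index,
                "block_id": t.block_id,
                "high_side": t.high_side,
                "volume_ul": t.volume_ul,
                "cue": t.cue,
                "choice": t.choice,
                "outcome": t.outcome,
                "choice_latency_ms": t.choice_latency_ms,
                "trace_ref": t.trace_ref,
            }
            for t in log.trials
        ]
    )


def bandit_trial_kinematics(
    log: task_engine.SessionLog, smooth_ms: float = 20.0
) -> list[bouts_vigor.TrialKinematics | None]:
    """Run the bout/vigor chain on every traced trial of a bandit session.

    Each trace passes through the same real-time chain the engine used
    (20 ms moving average), then central-difference velocity, bout
    segmentation and the per-trial readouts.  Trials without a trace get
    None.
    """
    out: list[bouts_vigor.TrialKinematics | None] = []
    cfg = log.config
    for tr in log.trials:
        if tr.trace_ref is None:
            out.append(None)
            continue
        trace = log.traces[tr.trace_ref]
        sm = signal_io.moving_average(trace, smooth_ms)
        v = bouts_vigor.velocity_trace(sm)
        bouts = bouts_vigor.segment_bouts(v, t=sm.t, x=sm.x)
        rec = signal_io.detect_choice(sm, cfg.choice_threshold_mm)
        out.append(
            bouts_vigor.trial_vigor_metrics(
                sm, bouts, t_go=cfg.pre_go_wait_ms, t_choice=rec.t_cross, v=v
            )
        )
    return out


def run_experiment(cfg: RunConfig) -> dict:
    """Execute a run config; returns the manifest (also written to disk)."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.config_hash(),
        "version": __version__,
        "sessions": [],
        "status": "running",
    }
    try:
        for s in range(cfg.n_sessions):
            seed = cfg.seed + s
            rng = np.random.default_rng(seed)
            agent = _agents.make_agent(cfg.agent, **cfg.agent_kwargs)
            entry: dict = {"session": s, "seed": seed}
            if cfg.task == "bandit":
                task_cfg = task_engine.ValueTaskConfig(
                    changing_volume=cfg.changing_volume
                )
                policy = task_engine.TracePolicy() if cfg.with_traces else None
                log = task_engine.run_bandit_session(
                    agent, task_cfg, cfg.n_trials, rng, trace_policy=policy
                )
            elif cfg.task == "auditory":
                task_cfg = task_engine.AuditoryMotorConfig(threshold_mm=3.0)
                log = task_engine.run_auditory_session(agent, task_cfg, rng)
            else:
                raise ValueError(f"unknown task {cfg.task!r}")

            trials_path = out_dir / f"session{s}_trials.tsv"
            _trials_frame(log).to_csv(trials_path, sep="\t", index=False)
            events_path = out_dir / f"session{s}_events.tsv"
            signal_io.write_event_log(log.events, events_path)
            entry["trials"] = trials_path.name
            entry["events"] = events_path.name

            if cfg.task == "bandit" and cfg.with_traces and "bouts" in cfg.analyses:
                kin = bandit_trial_kinematics(log)
                rows = []
                for t, k in zip(log.trials, kin):
                    if k is None:
                        continue
                    rows.append(
                        {
                            "trial": t.index,
                            "peak_displacement": k.peak_displacement,
                            "n_bouts": k.n_bouts,
                            "directional_consistency": k.directional_consistency,
                            "decisive_mean_velocity": k.decisive_mean_velocity,
                            "path_length": k.path_length,
                            "choice_latency": k.choice_latency,
                        }
                    )
                kin_path = out_dir / f"session{s}_trial_kinematics.csv"
                pd.DataFrame(rows).to_csv(kin_path, index=False)
                entry["trial_kinematics"] = kin_path.name
            else:
                kin = None

            if cfg.task == "bandit" and "fit" in cfg.analyses:
                series = value_models.series_from_session(log, attach_kinematics=kin)
                if len(series) >= 2 and len(set(series.choices)) == 2:
                    fit = value_models.fit_q_model(series)
                    fit_path = out_dir / f"session{s}_fit.json"
                    fit_path.write_text(
                        json.dumps(
                            {
                                "alpha_hat": fit.alpha_hat,
                                "beta_hat": fit.beta_hat,
                                "neg_log_likelihood": fit.neg_log_likelihood,
                            },
                            indent=2,
                        )
                    )
                    q_path = out_dir / f"session{s}_qtraj.csv"
                    pd.DataFrame(
                        {
                            "q_push": fit.q_push,
                            "q_pull": fit.q_pull,
                            "delta_q": fit.delta_q,
                        }
                    ).to_csv(q_path, index=False)
                    entry["fit"] = fit_path.name
                    entry["q_trajectories"] = q_path.name
            manifest["sessions"].append(entry)
        manifest["status"] = "complete"
    except Exception as exc:  # keep completed artifacts, mark the failure
        manifest["status"] = f"failed: {exc}"
        raise
    finally:
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def report(bundle_dir) -> dict[str, pd.DataFrame]:
    """Summarize a run bundle into per-figure-analogue tables.

    Missing inputs become named omissions rather than errors; an empty
    bundle yields tables with explicit no-data rows.  Regeneration from
    the same bundle is idempotent.
    """
    bundle_dir = Path(bundle_dir)
    tables: dict[str, pd.DataFrame] = {}
    manifest_path = bundle_dir / "manifest.json"
    if not manifest_path.exists():
        tables["omissions"] = pd.DataFrame([{"missing": "manifest.json"}])
        return tables
    manifest = json.loads(manifest_path.read_text())
    omissions = []

    perf_rows, vigor_rows, fit_rows = [], [], []
    for entry in manifest.get("sessions", []):
        s = entry["session"]
        tpath = bundle_dir / entry.get("trials", "")
        if not tpath.exists():
            omissions.append(f"session{s} trials")
            continue
        trials = pd.read_csv(tpath, sep="\t")
        counts = trials["outcome"].value_counts()
        perf_rows.append(
            {
                "session": s,
                "n_trials": len(trials),
                "rewarded": int(counts.get("rewarded", 0)),
                "unrewarded": int(counts.get("unrewarded", 0)),
                "omission": int(counts.get("omission", 0)),
                "premature": int(counts.get("premature", 0)),
            }
        )
        kpath = bundle_dir / entry.get("trial_kinematics", "_none_")
        if kpath.exists():
            kin = pd.read_csv(kpath)
            merged = trials.merge(kin, left_on="index", right_on="trial")
            for vol, g in merged.groupby("volume_ul"):
                vigor_rows.append(
                    {
                        "session": s,
                        "volume_ul": vol,
                        "median_peak_displacement": g["peak_displacement"].median(),
                        "median_choice_latency": g["choice_latency"].median(),
                        "n": len(g),
                    }
                )
        else:
            omissions.append(f"session{s} kinematics")
        fpath = bundle_dir / entry.get("fit", "_none_")
        if fpath.exists():
            fit = json.loads(fpath.read_text())
            fit_rows.append({"session": s, **fit})
        else:
            omissions.append(f"session{s} fit")

    tables["performance"] = (
        pd.DataFrame(perf_rows)
        if perf_rows
        else pd.DataFrame([{"session": "no data"}])
    )
    tables["vigor_by_volume"] = (
        pd.DataFrame(vigor_rows)
        if vigor_rows
        else pd.DataFrame([{"session": "no data"}])
    )
    tables["q_fits"] = (
        pd.DataFrame(fit_rows) if fit_rows else pd.DataFrame([{"session": "no data"}])
    )
    if omissions:
        tables["omissions"] = pd.DataFrame({"missing": omissions})
    for name, df in tables.items():
        df.to_csv(bundle_dir / f"report_{name}.csv", index=False)
    return tables
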