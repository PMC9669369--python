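"""End-to-end workflow: synthesize -> preprocess -> train -> predict -> control.

A single seeded configuration drives every stage, so a run directory can be
reproduced bit-identically from its manifest.  The workflow mirrors how the
system would be used online: estimate the subject's intended joint
trajectory from the sEMG envelope, then track that estimate with each
controller under a chosen disturbance.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import afnn, control, evaluation, preprocess, synth
from .dataio import write_timeseries
from .trajectory import JOINTS, JointTrajectory

__all__ = ["RunConfig", "run_pipeline", "train_estimator"]

log = logging.getLogger("myodyn")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (one section per stage)."""

    seed: int = 42
    synth: dict = field(default_factory=dict)
    filters: dict = field(default_factory=dict)
    afnn: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    controller: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    train_fraction: float = 0.8
    write_raw: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "synth": dict(self.synth),
            "filters": dict(self.filters),
            "afnn": dict(self.afnn),
            "noise": dict(self.noise),
            "controller": dict(self.controller),
            "simulate": dict(self.simulate),
            "train_fraction": self.train_fraction,
            "write_raw": self.write_raw,
        }

    # section -> typed configs ------------------------------------------------

    def synth_config(self) -> synth.SynthConfig:
        kw = dict(self.synth)
        kw.setdefault("seed", self.seed)
        if "joint_ranges" in kw:
            kw["joint_ranges"] = {k: tuple(v) for k, v in kw["joint_ranges"].items()}
        return synth.SynthConfig(**kw)

    def filter_config(self) -> preprocess.FilterConfig:
        return preprocess.FilterConfig(**self.filters)

    def train_config(self) -> tuple[int, afnn.TrainConfig]:
        kw = dict(self.afnn)
        L = int(kw.pop("L", 10))
        kw.setdefault("seed", self.seed)
        return L, afnn.TrainConfig(**kw)

    def noise_spec(self) -> control.NoiseSpec:
        kw = dict(self.noise)
        kw.setdefault("seed", self.seed)
        return control.NoiseSpec(**kw)


def train_estimator(
    env: preprocess.EnvelopeFeatures,
    traj: JointTrajectory,
    L: int = 10,
    cfg: afnn.TrainConfig | None = None,
    train_fraction: float = 0.8,
) -> tuple[afnn.AFNNModel, list[float], dict]:
    """Chronological train/held-out split, fit, and held-out metrics.

    Returns (model, loss history, held-out metrics report).  The split is
    chronological (first fraction trains) so the held-out segment probes
    genuinely unseen movement phases.
    """
    X = env.table.values()
    Y = traj.angles()
    n = min(len(X), len(Y))
    X, Y = X[:n], Y[:n]
    n_train = int(round(n * train_fraction))
    if not 1 <= n_train < n:
        raise ValueError(f"train fraction {train_fraction} leaves no held-out data")
    model, history = afnn.fit(X[:n_train], Y[:n_train], L=L, cfg=cfg)
    pred = afnn.predict(model, X[n_train:])
    actual = JointTrajectory.from_arrays(Y[n_train:], rate=traj.rate)
    estimated = JointTrajectory.from_arrays(pred, rate=traj.rate)
    report = evaluation.metrics_report(actual, estimated)
    return model, history, report


def _timed(name: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    log.info("stage %-12s %.2f s", name, time.perf_counter() - t0)
    return out


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the full workflow and write all artifacts into ``outdir``.

    Artifacts: trajectory/envelope/prediction CSVs, one simulation CSV per
    controller, ``metrics.json`` (estimator + tracking metrics) and
    ``manifest.json`` (config echo + seed).  Rerunning with the same
    manifest reproduces every numeric output bit-identically.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    scfg = config.synth_config()
    raw, traj = _timed("synth", synth.make_dataset, scfg)
    if config.write_raw:
        write_timeseries(raw.table, outdir / "raw_emg.csv")
    write_timeseries(traj.table, outdir / "trajectory_actual.csv")

    env = _timed("preprocess", preprocess.process_recording, raw, config.filter_config())
    write_timeseries(env.table, outdir / "envelope.csv")

    L, tcfg = config.train_config()
    model, history, holdout = _timed(
        "train", train_estimator, env, traj, L, tcfg, config.train_fraction
    )
    afnn.save_model(model, outdir / "model.json")

    predicted = _timed("predict", afnn.predict_trajectory, model, env)
    write_timeseries(predicted.table, outdir / "trajectory_predicted.csv")

    sim_kw = dict(config.simulate)
    dt = float(sim_kw.get("dt", 1e-3))
    duration = sim_kw.get("duration")
    theta0 = sim_kw.get("theta0", "start")
    problem = control.TrackingProblem.from_trajectory(
        predicted, dt=dt, duration=duration, theta0=theta0
    )
    ckw = dict(config.controller)
    noise = config.noise_spec()
    results = _timed("simulate", control.compare_controllers, problem, noise, **ckw)
    tracking = {}
    for name, res in results.items():
        write_timeseries(res.to_table(), outdir / f"sim_{name}.csv")
        tracking[name] = res.summary()

    metrics = {
        "estimator_holdout": holdout,
        "final_training_loss": history[-1],
        "n_training_iterations": len(history),
        "tracking": tracking,
    }
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    manifest = {"config": config.to_dict(), "package": "myodyn"}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
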