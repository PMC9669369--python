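"""Seeded generator of joint trajectories and surrogate raw sEMG.

The recordings the estimator was designed for are not publicly deposited, so
this module emulates their statistical structure: smooth quasi-periodic
flexion-extension trajectories for shoulder/elbow/wrist within physiological
ranges, a six-muscle agonist/antagonist activation pattern derived from the
kinematics, and per-channel raw sEMG built as an amplitude-modulated
band-limited (20-500 Hz) Gaussian carrier with optional 50 Hz power-line
interference and a white noise floor.

The activation model is posture-driven: the agonist of each pair carries the
positive part of the joint's normalized angular excursion from mid-range and
the antagonist the negative part, on top of a common tonic baseline.  Tonic,
posture-proportional activation is what slow sagittal-plane flexion-extension
against gravity predominantly produces, and it makes the envelope -> angle
map well-posed for a memoryless estimator (the instantaneous velocity, by
contrast, does not determine the angle).  A velocity-driven mode is kept as
an option for experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal as sps

from .dataio import TimeSeriesTable
from .preprocess import MUSCLES, RawEMG
from .trajectory import JOINTS, JointTrajectory

__all__ = [
    "SynthConfig",
    "generate_trajectory",
    "activation_from_kinematics",
    "generate_raw_emg",
    "make_dataset",
]

#: Default physiological ranges in degrees.
DEFAULT_RANGES = {"shoulder": (0.0, 90.0), "elbow": (0.0, 120.0), "wrist": (-60.0, 60.0)}

#: Agonist/antagonist channel per joint (agonist drives positive excursion).
MUSCLE_PAIRS = {
    "shoulder": ("anterior_deltoid", "posterior_deltoid"),
    "elbow": ("biceps_brachii", "triceps_brachii"),
    "wrist": ("flexor_carpi_radialis", "extensor_carpi_radialis"),
}


@dataclass
class SynthConfig:
    """Study conditions for the synthetic recordings.

    Defaults mirror the acquisition setup being emulated: 100 s of movement,
    sEMG at 2 kHz, joint angles at 100 Hz, carrier energy in 20-500 Hz.
    ``interference_amp`` is the 50 Hz amplitude relative to a unit-RMS
    carrier at full activation; ``noise_floor`` likewise.  ``baseline`` is
    the tonic activation level common to all six muscles.
    """

    duration: float = 100.0
    rate_emg: float = 2000.0
    rate_angle: float = 100.0
    joint_ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))
    n_sinusoids: int = 3
    period_range: tuple = (2.0, 20.0)
    carrier_band: tuple = (20.0, 500.0)
    interference_amp: float = 0.0
    baseline: float = 0.1
    noise_floor: float = 0.01
    activation_mode: str = "angle"  # or "velocity"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        ratio = self.rate_emg / self.rate_angle
        if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
            raise ValueError(
                f"rate_emg ({self.rate_emg}) must be a positive integer multiple "
                f"of rate_angle ({self.rate_angle})"
            )
        for joint in JOINTS:
            lo, hi = self.joint_ranges[joint]
            if not lo < hi:
                raise ValueError(f"{joint} range must have low < high, got ({lo}, {hi})")
        if self.activation_mode not in ("angle", "velocity"):
            raise ValueError(f"unknown activation_mode {self.activation_mode!r}")
        if not 0 <= self.baseline < 1:
            raise ValueError("baseline must lie in [0, 1)")

    @property
    def subsample_ratio(self) -> int:
        return int(round(self.rate_emg / self.rate_angle))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["joint_ranges"] = {k: list(v) for k, v in self.joint_ranges.items()}
        d["period_range"] = list(self.period_range)
        d["carrier_band"] = list(self.carrier_band)
        return d


def _rng(cfg: SynthConfig, stage: int) -> np.random.Generator:
    # independent, reproducible streams per generation stage
    return np.random.default_rng([cfg.seed, stage])


def generate_trajectory(cfg: SynthConfig | None = None) -> JointTrajectory:
    """Smooth sum-of-sinusoids trajectory, affinely mapped into each range.

    Per joint, ``n_sinusoids`` components with periods drawn from
    ``period_range`` and random amplitudes/phases are summed and rescaled by
    the analytic amplitude bound, guaranteeing every sample stays inside the
    configured range.  The returned trajectory carries exact analytic
    angle/velocity callables.
    """
    cfg = cfg or SynthConfig()
    rng = _rng(cfg, 0)
    params = []  # per joint: (amps, omegas, phases, mid, half)
    for joint in JOINTS:
        lo, hi = cfg.joint_ranges[joint]
        periods = rng.uniform(*cfg.period_range, cfg.n_sinusoids)
        amps = rng.uniform(0.5, 1.0, cfg.n_sinusoids)
        phases = rng.uniform(0.0, 2.0 * np.pi, cfg.n_sinusoids)
        params.append(
            (amps, 2.0 * np.pi / periods, phases, 0.5 * (lo + hi), 0.5 * (hi - lo))
        )

    def theta_fn(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        cols = []
        for amps, om, ph, mid, half in params:
            s = np.sum(amps[:, None] * np.sin(om[:, None] * t[None, :] + ph[:, None]), axis=0) \
                if t.ndim else np.sum(amps * np.sin(om * t + ph))
            cols.append(mid + half * s / amps.sum())
        return np.stack(cols, axis=-1)

    def theta_dot_fn(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        cols = []
        for amps, om, ph, mid, half in params:
            s = np.sum((amps * om)[:, None] * np.cos(om[:, None] * t[None, :] + ph[:, None]), axis=0) \
                if t.ndim else np.sum(amps * om * np.cos(om * t + ph))
            cols.append(half * s / amps.sum())
        return np.stack(cols, axis=-1)

    n = int(round(cfg.duration * cfg.rate_angle))
    t = np.arange(n) / cfg.rate_angle
    return JointTrajectory.from_arrays(
        theta_fn(t), rate=cfg.rate_angle, theta_fn=theta_fn, theta_dot_fn=theta_dot_fn
    )


def activation_from_kinematics(traj: JointTrajectory, cfg: SynthConfig | None = None) -> TimeSeriesTable:
    """Six-channel muscle activation in [0, 1] at the angle rate.

    For each joint's agonist/antagonist pair the drive is the normalized
    excursion from mid-range (``"angle"`` mode, default) or the normalized
    angular velocity (``"velocity"`` mode); the agonist takes the rectified
    positive part, the antagonist the negative part, both on top of the
    tonic ``baseline``.  A neutral mid-range static pose therefore yields
    baseline activation on all channels, and flipping the drive's sign
    exactly swaps the pair.
    """
    cfg = cfg or SynthConfig()
    angles = traj.angles()
    cols = {name: None for name in MUSCLES}
    gain = 1.0 - cfg.baseline
    for j, joint in enumerate(JOINTS):
        lo, hi = cfg.joint_ranges[joint]
        mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
        if cfg.activation_mode == "angle":
            drive = (angles[:, j] - mid) / half
        else:
            vel = traj.velocities()[:, j]
            vmax = np.max(np.abs(vel))
            drive = vel / vmax if vmax > 0 else np.zeros_like(vel)
        agonist, antagonist = MUSCLE_PAIRS[joint]
        cols[agonist] = np.clip(cfg.baseline + gain * np.clip(drive, 0.0, None), 0.0, 1.0)
        cols[antagonist] = np.clip(cfg.baseline + gain * np.clip(-drive, 0.0, None), 0.0, 1.0)
    return TimeSeriesTable(
        rate=traj.rate, data=pd.DataFrame({m: cols[m] for m in MUSCLES}), t0=traj.table.t0
    )


def _band_limited_carrier(n: int, rate: float, band: tuple, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band`` Hz."""
    white = rng.standard_normal(n)
    nyq = rate / 2.0
    hi = min(band[1], 0.99 * nyq)
    sos = sps.butter(4, [band[0], hi], btype="bandpass", fs=rate, output="sos")
    x = sps.sosfilt(sos, white)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def generate_raw_emg(activation: TimeSeriesTable, cfg: SynthConfig | None = None) -> RawEMG:
    """Amplitude-modulated surrogate sEMG at the EMG rate.

    ``raw = a_up(t) * carrier(t) + interference_amp * sin(2 pi 50 t) + floor * white``
    with the activation linearly upsampled to ``rate_emg`` and an independent
    unit-RMS band-limited carrier per channel, so channel RMS tracks the
    activation level.
    """
    cfg = cfg or SynthConfig()
    ratio = cfg.subsample_ratio
    n_out = activation.n * ratio
    t = activation.t0 + np.arange(n_out) / cfg.rate_emg
    t_act = activation.times()
    rng = _rng(cfg, 1)
    interference = cfg.interference_amp * np.sin(2.0 * np.pi * 50.0 * t)
    cols = {}
    for name in MUSCLES:
        a_up = np.interp(t, t_act, activation.channel(name))
        carrier = _band_limited_carrier(n_out, cfg.rate_emg, cfg.carrier_band, rng)
        floor = cfg.noise_floor * rng.standard_normal(n_out)
        cols[name] = a_up * carrier + interference + floor
    table = TimeSeriesTable(rate=cfg.rate_emg, data=pd.DataFrame(cols), t0=activation.t0)
    return RawEMG(table=table)


def make_dataset(cfg: SynthConfig | None = None) -> tuple[RawEMG, JointTrajectory]:
    """Time-aligned (raw sEMG, joint trajectory) pair under one seed."""
    cfg = cfg or SynthConfig()
    traj = generate_trajectory(cfg)
    act = activation_from_kinematics(traj, cfg)
    raw = generate_raw_emg(act, cfg)
    return raw, traj
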