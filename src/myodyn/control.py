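"""Tracking controllers, disturbance models and the closed-loop simulator.

The tracking task is joint-space: drive the limb angles theta(t) to a
desired trajectory theta_d(t) produced by the intention estimator.  The loop
is kinematic -- the controller output u is a joint-velocity command and
disturbances n(t) enter additively at the velocity level:

    theta'(t) = u(t) + n(t)

Four laws are provided (gains in the package defaults are the study's
stated settings gamma = 100 1/s, lambda = 200 1/s^2, PID 10 / 0.5 / 0.2):

* ZNN (zeroing neural network):  u = theta_d' + gamma e, which imposes the
  exponential error dynamics e' = -gamma e (a general PD law);
* NSZNN (noise-suppressing ZNN): u = theta_d' + gamma e + lambda int e dt,
  imposing e' = -gamma e - lambda int e -- the integral term annihilates
  constant disturbances and bounds ramp disturbances at slope/lambda (a
  general PID law);
* GNN (gradient network):        u = gamma e -- no derivative feedforward,
  hence a lag of theta_d'/gamma on time-varying targets;
* PID on the error with backward-difference derivative (discrete-time).

The smooth laws (GNN/ZNN/NSZNN) are ordinary differential equations and are
integrated by fixed-step RK4 with the disturbance held constant over each
step; "euler" is available for comparison.  The PID law is inherently
discrete (finite-difference derivative, running-sum integral) and always
steps forward-Euler.  Closed forms for the ZNN decay and the NSZNN steady
state serve as independent oracles for the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd

from .dataio import TimeSeriesTable
from .evaluation import rmse
from .trajectory import JOINTS, JointTrajectory

__all__ = [
    "ControllerSpec",
    "NoiseSpec",
    "TrackingProblem",
    "SimulationResult",
    "znn_law",
    "nsznn_law",
    "gnn_law",
    "pid_law",
    "noise_value",
    "simulate",
    "compare_controllers",
    "znn_error_closed_form",
    "nsznn_steady_state",
    "CONTROLLERS",
]

CONTROLLERS = ("pid", "gnn", "znn", "nsznn")
NOISE_KINDS = ("none", "constant", "linear", "random")


@dataclass
class ControllerSpec:
    """Controller type and gains (defaults: the study's stated settings)."""

    type: str = "nsznn"
    gamma: float = 100.0  # 1/s
    lam: float = 200.0  # 1/s^2
    kp: float = 10.0
    ki: float = 0.5
    kd: float = 0.2

    def __post_init__(self) -> None:
        if self.type not in CONTROLLERS:
            raise ValueError(f"controller type must be one of {CONTROLLERS}")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.type == "nsznn" and self.lam <= 0:
            raise ValueError("lambda must be positive for the NSZNN controller")
        if min(self.kp, self.ki, self.kd) < 0:
            raise ValueError("PID gains must be nonnegative")


@dataclass
class NoiseSpec:
    """Additive velocity-level disturbance (deg/s).

    ``constant``: n = c.  ``linear``: n = a t (unbounded ramp).  ``random``:
    i.i.d. uniform per joint per step on [low, high]; by default [0, r], a
    bounded nonnegative disturbance whose mean r/2 the integral-enhanced
    controller suppresses (set ``low=-r`` for a zero-mean variant).
    """

    kind: str = "none"
    c: float = 1.0
    a: float = 1.0
    r: float = 1.0
    low: float | None = None
    high: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in NOISE_KINDS:
            raise ValueError(f"noise kind must be one of {NOISE_KINDS}")
        if self.r < 0:
            raise ValueError("random amplitude r must be nonnegative")
        if self.low is None:
            self.low = 0.0
        if self.high is None:
            self.high = self.r

    def to_dict(self) -> dict:
        return asdict(self)


def noise_value(spec: NoiseSpec, t: float, rng: np.random.Generator | None = None) -> np.ndarray:
    """Disturbance sample for all three joints at time ``t``."""
    if spec.kind == "none":
        return np.zeros(3)
    if spec.kind == "constant":
        return np.full(3, spec.c)
    if spec.kind == "linear":
        return np.full(3, spec.a * t)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    return rng.uniform(spec.low, spec.high, 3)


@dataclass
class TrackingProblem:
    """Desired trajectory (continuous-time callables), initial state and grid.

    ``theta_d``/``theta_d_dot`` map time (s) to degrees / deg/s per joint.
    ``theta0`` defaults to zero on all joints, which produces the initial
    transient of a limb starting away from the reference.
    """

    theta_d: Callable[[float], np.ndarray]
    theta_d_dot: Callable[[float], np.ndarray]
    duration: float
    dt: float = 1e-3
    theta0: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        self.theta0 = np.asarray(self.theta0, dtype=float)

    @classmethod
    def from_trajectory(
        cls,
        traj: JointTrajectory,
        dt: float = 1e-3,
        duration: float | None = None,
        theta0: np.ndarray | str | None = None,
    ) -> "TrackingProblem":
        """Track a sampled/analytic trajectory; ``theta0="start"`` begins on it."""
        fn, dfn = traj.continuous()
        if duration is None:
            duration = (traj.n - 1) / traj.rate
        if isinstance(theta0, str):
            if theta0 != "start":
                raise ValueError("theta0 string must be 'start'")
            theta0 = np.asarray(fn(0.0), dtype=float)
        elif theta0 is None:
            theta0 = np.zeros(3)
        return cls(theta_d=fn, theta_d_dot=dfn, duration=duration, dt=dt, theta0=theta0)


@dataclass
class SimulationResult:
    """Closed-loop run: time grid, desired/actual angles, errors, per-joint RMSE."""

    t: np.ndarray
    theta_d: np.ndarray
    theta: np.ndarray
    error: np.ndarray
    rmse: np.ndarray
    controller: ControllerSpec
    noise: NoiseSpec
    dt: float

    def to_table(self) -> TimeSeriesTable:
        cols: dict[str, np.ndarray] = {}
        for j, joint in enumerate(JOINTS):
            cols[f"{joint}_desired"] = self.theta_d[:, j]
            cols[f"{joint}_actual"] = self.theta[:, j]
            cols[f"{joint}_error"] = self.error[:, j]
        return TimeSeriesTable(rate=1.0 / self.dt, data=pd.DataFrame(cols), t0=float(self.t[0]))

    def summary(self) -> dict:
        return {
            "controller": self.controller.type,
            "noise": self.noise.kind,
            "dt": self.dt,
            "duration": float(self.t[-1]),
            "rmse_deg": {joint: float(self.rmse[j]) for j, joint in enumerate(JOINTS)},
        }


# ---------------------------------------------------------------------------
# control laws (pure functions, degrees / seconds)


def znn_law(theta_d, theta_d_dot, theta, gamma: float) -> np.ndarray:
    """Velocity command theta_d' + gamma (theta_d - theta): e' = -gamma e."""
    return np.asarray(theta_d_dot, float) + gamma * (np.asarray(theta_d, float) - np.asarray(theta, float))


def nsznn_law(theta_d, theta_d_dot, theta, int_e, gamma: float, lam: float) -> np.ndarray:
    """ZNN law plus lambda * (accumulated error integral, deg s)."""
    return znn_law(theta_d, theta_d_dot, theta, gamma) + lam * np.asarray(int_e, float)


def gnn_law(theta_d, theta, gamma: float) -> np.ndarray:
    """Gradient-descent law gamma (theta_d - theta): no feedforward term."""
    return gamma * (np.asarray(theta_d, float) - np.asarray(theta, float))


def pid_law(e, int_e, de_dt, kp: float, ki: float, kd: float) -> np.ndarray:
    """Textbook PID on the tracking error."""
    return kp * np.asarray(e, float) + ki * np.asarray(int_e, float) + kd * np.asarray(de_dt, float)


# ---------------------------------------------------------------------------
# closed-form oracles


def znn_error_closed_form(e0, gamma: float, t) -> np.ndarray:
    """Exact solution of e' = -gamma e: e0 exp(-gamma t)."""
    return np.asarray(e0, float) * np.exp(-gamma * np.asarray(t, float))


def nsznn_steady_state(noise: NoiseSpec, gamma: float, lam: float) -> float:
    """Asymptotic tracking error of the integral-enhanced dynamics.

    With e'' + gamma e' + lambda e = n'(t): no or constant disturbance gives
    e -> 0, a ramp of slope ``a`` gives e -> a / lambda, and bounded random
    disturbance leaves a zero-mean residual (its mean is rejected like a
    constant).
    """
    if gamma <= 0 or lam <= 0:
        raise ValueError("gamma and lambda must be positive")
    if noise.kind in ("none", "constant", "random"):
        return 0.0
    if noise.kind == "linear":
        return noise.a / lam
    raise ValueError(f"unsupported noise kind {noise.kind!r}")


# ---------------------------------------------------------------------------
# simulator


class SimulationDivergedError(RuntimeError):
    """State became non-finite (carries step index and controller type)."""


def _noise_sequence(spec: NoiseSpec, t_grid: np.ndarray) -> np.ndarray:
    """Per-step held disturbance samples, shape (len(t_grid), 3)."""
    n = len(t_grid)
    if spec.kind == "none":
        return np.zeros((n, 3))
    if spec.kind == "constant":
        return np.full((n, 3), spec.c)
    if spec.kind == "linear":
        return spec.a * t_grid[:, None] * np.ones((1, 3))
    rng = np.random.default_rng(spec.seed)
    return rng.uniform(spec.low, spec.high, (n, 3))


def simulate(
    problem: TrackingProblem,
    ctrl: ControllerSpec,
    noise: NoiseSpec | None = None,
    method: str = "rk4",
) -> SimulationResult:
    """Closed-loop rollout of theta' = u + n on a fixed grid.

    The disturbance is sampled once per step (at the step's start) and held
    constant across the step, for both integrators; random noise is
    seed-deterministic.  The desired trajectory and its derivative are
    evaluated up front on a half-step grid (needed by the RK4 midpoints).
    Per-joint RMSE is computed over the full horizon.
    """
    noise = noise or NoiseSpec()
    if method not in ("rk4", "euler"):
        raise ValueError(f"unknown integration method {method!r}")
    n_steps = int(round(problem.duration / problem.dt))
    dt = problem.dt
    t_grid = np.arange(n_steps + 1) * dt
    t_half = np.arange(2 * n_steps + 1) * (dt / 2.0)
    thd_h = np.asarray(problem.theta_d(t_half), float).reshape(len(t_half), 3)
    dthd_h = np.asarray(problem.theta_d_dot(t_half), float).reshape(len(t_half), 3)
    noise_seq = _noise_sequence(noise, t_grid[:-1])
    theta_d_hist = thd_h[::2]
    theta_hist = np.empty((n_steps + 1, 3))
    gam, lam = ctrl.gamma, ctrl.lam

    if ctrl.type == "pid":
        kp, ki, kd = ctrl.kp, ctrl.ki, ctrl.kd
        th = problem.theta0.copy()
        int_e = np.zeros(3)
        e_prev = np.zeros(3)
        for k in range(n_steps):
            theta_hist[k] = th
            e = theta_d_hist[k] - th
            int_e = int_e + e * dt
            de = (e - e_prev) / dt
            e_prev = e
            u = kp * e + ki * int_e + kd * de
            th = th + dt * (u + noise_seq[k])
        theta_hist[n_steps] = th
    else:
        # state: theta, plus the running error integral for nsznn
        th = problem.theta0.copy()
        ie = np.zeros(3)
        has_ff = ctrl.type in ("znn", "nsznn")
        has_int = ctrl.type == "nsznn"

        def rhs(i_half, th, ie, n):
            dth = gam * (thd_h[i_half] - th) + n
            if has_ff:
                dth = dth + dthd_h[i_half]
            if has_int:
                dth = dth + lam * ie
                return dth, thd_h[i_half] - th
            return dth, None

        for k in range(n_steps):
            theta_hist[k] = th
            n = noise_seq[k]
            i = 2 * k
            if method == "euler":
                dth, dei = rhs(i, th, ie, n)
                th = th + dt * dth
                if has_int:
                    ie = ie + dt * dei
            else:
                k1, l1 = rhs(i, th, ie, n)
                if has_int:
                    k2, l2 = rhs(i + 1, th + dt / 2 * k1, ie + dt / 2 * l1, n)
                    k3, l3 = rhs(i + 1, th + dt / 2 * k2, ie + dt / 2 * l2, n)
                    k4, l4 = rhs(i + 2, th + dt * k3, ie + dt * l3, n)
                    ie = ie + dt / 6 * (l1 + 2 * l2 + 2 * l3 + l4)
                else:
                    k2, _ = rhs(i + 1, th + dt / 2 * k1, ie, n)
                    k3, _ = rhs(i + 1, th + dt / 2 * k2, ie, n)
                    k4, _ = rhs(i + 2, th + dt * k3, ie, n)
                th = th + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        theta_hist[n_steps] = th
    if not np.all(np.isfinite(theta_hist)):
        bad = int(np.argwhere(~np.isfinite(theta_hist))[0, 0])
        raise SimulationDivergedError(
            f"{ctrl.type} state non-finite at step {bad} (t={bad * dt:.4f}s)"
        )

    error = theta_d_hist - theta_hist
    per_joint = np.array([rmse(theta_d_hist[:, j], theta_hist[:, j]) for j in range(3)])
    return SimulationResult(
        t=t_grid, theta_d=theta_d_hist, theta=theta_hist, error=error,
        rmse=per_joint, controller=ctrl, noise=noise, dt=dt,
    )


def compare_controllers(
    problem: TrackingProblem,
    noise: NoiseSpec | None = None,
    gamma: float = 100.0,
    lam: float = 200.0,
    kp: float = 10.0,
    ki: float = 0.5,
    kd: float = 0.2,
    method: str = "rk4",
) -> dict[str, SimulationResult]:
    """Run all four controllers on the same problem and disturbance sequence.

    Each controller sees an identically seeded disturbance stream, so the
    comparison differs only in the control law.
    """
    out: dict[str, SimulationResult] = {}
    for name in CONTROLLERS:
        spec = ControllerSpec(type=name, gamma=gamma, lam=lam, kp=kp, ki=ki, kd=kd)
        out[name] = simulate(problem, spec, noise, method=method)
    return out
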