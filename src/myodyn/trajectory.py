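"""Three-joint angle trajectories (shoulder, elbow, wrist), in degrees."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .dataio import TimeSeriesTable, InvalidTableError

__all__ = ["JOINTS", "JointTrajectory"]

#: Joint order used throughout the package.
JOINTS = ("shoulder", "elbow", "wrist")


@dataclass
class JointTrajectory:
    """Sampled 3-joint angle series, optionally backed by analytic functions.

    ``theta_fn``/``theta_dot_fn`` map a time (s, scalar or array) to angles
    (deg) / angular velocities (deg/s) with one column per joint; when absent,
    continuous-time evaluation falls back to a cubic-spline interpolant of
    the samples.
    """

    table: TimeSeriesTable
    theta_fn: Callable[[np.ndarray], np.ndarray] | None = None
    theta_dot_fn: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if tuple(self.table.channel_names) != JOINTS:
            raise InvalidTableError(
                f"JointTrajectory needs the channels {list(JOINTS)}, "
                f"got {self.table.channel_names}"
            )

    @property
    def rate(self) -> float:
        return self.table.rate

    @property
    def n(self) -> int:
        return self.table.n

    def times(self) -> np.ndarray:
        return self.table.times()

    def angles(self) -> np.ndarray:
        """(n, 3) array of joint angles in degrees."""
        return self.table.values()

    def velocities(self) -> np.ndarray:
        """(n, 3) angular velocities in deg/s (analytic when available)."""
        if self.theta_dot_fn is not None:
            return np.asarray(self.theta_dot_fn(self.times()), dtype=float)
        ang = self.angles()
        return np.gradient(ang, 1.0 / self.rate, axis=0)

    def continuous(self) -> tuple[Callable, Callable]:
        """Callables ``theta(t), theta_dot(t)`` for continuous-time tracking."""
        if self.theta_fn is not None and self.theta_dot_fn is not None:
            return self.theta_fn, self.theta_dot_fn
        spline = CubicSpline(self.times(), self.angles(), axis=0)
        return spline, spline.derivative()

    @classmethod
    def from_arrays(
        cls,
        angles: np.ndarray,
        rate: float,
        t0: float = 0.0,
        theta_fn: Callable | None = None,
        theta_dot_fn: Callable | None = None,
    ) -> "JointTrajectory":
        angles = np.asarray(angles, dtype=float)
        if angles.ndim != 2 or angles.shape[1] != len(JOINTS):
            raise InvalidTableError(f"angles must be (n, 3), got {angles.shape}")
        table = TimeSeriesTable(
            rate=rate, data=pd.DataFrame(dict(zip(JOINTS, angles.T))), t0=t0
        )
        return cls(table=table, theta_fn=theta_fn, theta_dot_fn=theta_dot_fn)
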