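"""Accuracy metrics: RMSE and the variance-ratio coefficient of determination.

R^2 here is ``1 - Var(actual - estimated) / Var(actual)`` with population
(1/N) variances.  Note this form is blind to a constant offset between the
two series (the variance of a constant is zero), which differs from the
sum-of-squares R^2; it can be negative when the error variance exceeds the
signal variance.
"""

from __future__ import annotations

import numpy as np

from .trajectory import JOINTS, JointTrajectory

__all__ = ["rmse", "r_squared", "metrics_report", "ConstantSeriesError"]


class ConstantSeriesError(ValueError):
    """R^2 is undefined when the actual series has zero variance."""


def _pair(actual, estimated, min_len: int) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(actual, dtype=float).ravel()
    e = np.asarray(estimated, dtype=float).ravel()
    if a.shape != e.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {e.shape}")
    if a.size < min_len:
        raise ValueError(f"need at least {min_len} samples, got {a.size}")
    return a, e


def rmse(actual, estimated) -> float:
    """Root-mean-square error, same units as the inputs."""
    a, e = _pair(actual, estimated, 1)
    return float(np.sqrt(np.mean((a - e) ** 2)))


def r_squared(actual, estimated) -> float:
    """1 - Var(actual - estimated) / Var(actual), population variance."""
    a, e = _pair(actual, estimated, 2)
    va = np.var(a)
    if va <= 0:
        raise ConstantSeriesError("R^2 undefined: actual series is constant")
    return float(1.0 - np.var(a - e) / va)


def metrics_report(actual: JointTrajectory, estimated: JointTrajectory) -> dict:
    """Per-joint RMSE (deg) and R^2, plus the sample count."""
    a = actual.angles()
    e = estimated.angles()
    if a.shape != e.shape:
        raise ValueError(f"trajectory shape mismatch: {a.shape} vs {e.shape}")
    report: dict = {"n_samples": int(a.shape[0]), "rmse": {}, "r_squared": {}}
    for j, joint in enumerate(JOINTS):
        report["rmse"][joint] = rmse(a[:, j], e[:, j])
        report["r_squared"][joint] = r_squared(a[:, j], e[:, j])
    return report
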