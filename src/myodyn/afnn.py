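"""Adaptive fuzzy neural network (AFNN) joint-angle estimator.

A zero-order Takagi-Sugeno fuzzy system mapping the 6-channel sEMG envelope
to the 3 joint angles, sample by sample.  Each of the L fuzzy rules carries:

* input-dependent membership centers  mu_ij = sigma(-(b_ij x_i + c_ij / (2 s_ij)))
  where sigma is the logistic function (so mu in (0,1) on the normalized
  input domain);
* Gaussian memberships  phi_ij = exp(-((x_i - mu_ij) / s_ij)^2);
* a constant consequent vector f_j in R^3.

The output is the activation-weighted average of the consequents,

    y = sum_j f_j w_j / sum_j w_j,      w_j = prod_i phi_ij,

i.e. a convex combination of the rows of ``f``.  Rule activations are
computed in log space with the maximum exponent subtracted, so the
normalization never underflows to 0/0.

Training (full-batch gradient descent on the mean squared error in
normalized [0,1] space) adapts ``f``, ``b`` and ``c``; the widths ``s``
stay at their initialization.  Inputs and targets are min-max normalized;
predictions are mapped back through the stored statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .preprocess import EnvelopeFeatures
from .trajectory import JOINTS, JointTrajectory

__all__ = [
    "NormStats",
    "AFNNModel",
    "TrainConfig",
    "normalize",
    "denormalize",
    "centers",
    "membership",
    "forward",
    "loss",
    "gradients",
    "train",
    "init_model",
    "fit",
    "predict",
    "predict_trajectory",
    "save_model",
    "load_model",
    "TrainingDivergedError",
]


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during training (carries the iteration index)."""


# ---------------------------------------------------------------------------
# normalization


@dataclass
class NormStats:
    """Per-dimension affine statistics: normalized = (x - loc) / scale."""

    loc: np.ndarray
    scale: np.ndarray

    def to_dict(self) -> dict:
        return {"loc": self.loc.tolist(), "scale": self.scale.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "NormStats":
        return cls(loc=np.asarray(d["loc"], float), scale=np.asarray(d["scale"], float))


def normalize(data: np.ndarray, stats: NormStats | None = None) -> tuple[np.ndarray, NormStats]:
    """Min-max normalize columns to [0, 1]; constant columns map to 0.5.

    When ``stats`` is omitted it is computed from ``data`` (training pass);
    otherwise the given statistics are applied (inference pass).
    """
    data = np.asarray(data, dtype=float)
    if data.size == 0:
        raise ValueError("cannot normalize empty data")
    if data.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {data.shape}")
    if stats is None:
        lo = data.min(axis=0)
        hi = data.max(axis=0)
        scale = hi - lo
        const = scale <= 0
        # constant dimension: unit scale, loc shifted so the value maps to 0.5
        scale = np.where(const, 1.0, scale)
        loc = np.where(const, lo - 0.5, lo)
        stats = NormStats(loc=loc, scale=scale)
    if stats.loc.shape[0] != data.shape[1]:
        raise ValueError(
            f"stats dimension {stats.loc.shape[0]} != data dimension {data.shape[1]}"
        )
    return (data - stats.loc) / stats.scale, stats


def denormalize(data: np.ndarray, stats: NormStats) -> np.ndarray:
    """Exact inverse of :func:`normalize` under the given statistics."""
    if stats is None:
        raise ValueError("denormalize requires normalization statistics")
    return np.asarray(data, dtype=float) * stats.scale + stats.loc


# ---------------------------------------------------------------------------
# model


@dataclass
class AFNNModel:
    """Parameters of the fuzzy-rule base plus normalization statistics.

    Shapes: ``f`` (L, n_out); ``b``, ``c``, ``sigma`` (n_in, L).
    """

    f: np.ndarray
    b: np.ndarray
    c: np.ndarray
    sigma: np.ndarray
    norm_in: NormStats | None = None
    norm_out: NormStats | None = None

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.b.shape != self.c.shape or self.b.shape != self.sigma.shape:
            raise ValueError("b, c, sigma must share the shape (n_in, L)")
        if self.f.shape[0] != self.b.shape[1]:
            raise ValueError(
                f"f has {self.f.shape[0]} rules but b/c/sigma have {self.b.shape[1]}"
            )
        if self.L < 1:
            raise ValueError("need at least one fuzzy rule")
        if np.any(self.sigma <= 0):
            raise ValueError("all membership widths must be positive")

    @property
    def L(self) -> int:
        return self.b.shape[1]

    @property
    def n_in(self) -> int:
        return self.b.shape[0]

    @property
    def n_out(self) -> int:
        return self.f.shape[1]


@dataclass
class TrainConfig:
    """Full-batch gradient-descent settings (iteration cap, loss threshold)."""

    maxstep: int = 1000
    tol: float = 1e-10
    learning_rate: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.maxstep < 1:
            raise ValueError("maxstep must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def _as_batch(x: np.ndarray, n_in: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != n_in:
        raise ValueError(f"input dimension {x.shape[1]} != model n_in {n_in}")
    return x


def centers(model: AFNNModel, x: np.ndarray) -> np.ndarray:
    """Input-dependent membership centers, mu in (0, 1).

    ``mu_ij = 1 / (1 + exp(b_ij x_i + c_ij / (2 sigma_ij)))``, evaluated with
    an overflow-safe logistic.  For a batch input the result has shape
    (S, n_in, L); for a single vector, (n_in, L).
    """
    X = _as_batch(x, model.n_in)
    a = model.b[None] * X[:, :, None] + (model.c / (2.0 * model.sigma))[None]
    mu = expit(-a)  # overflow-safe logistic on both tails
    return mu if np.asarray(x).ndim > 1 else mu[0]


def membership(model: AFNNModel, x: np.ndarray) -> np.ndarray:
    """Gaussian memberships phi_ij = exp(-((x_i - mu_ij)/sigma_ij)^2) in (0, 1]."""
    X = _as_batch(x, model.n_in)
    mu = centers(model, X)
    d = (X[:, :, None] - mu) / model.sigma[None]
    phi = np.exp(-(d**2))
    return phi if np.asarray(x).ndim > 1 else phi[0]


def _rule_weights(model: AFNNModel, X: np.ndarray) -> np.ndarray:
    """Normalized rule activations (S, L); log-space softmax, never 0/0."""
    mu = centers(model, X)
    d = (X[:, :, None] - mu) / model.sigma[None]
    logw = -(d**2).sum(axis=1)  # (S, L)
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    return w / w.sum(axis=1, keepdims=True)


def forward(model: AFNNModel, x: np.ndarray) -> np.ndarray:
    """Model output in the normalized domain: convex combination of rows of f."""
    X = _as_batch(x, model.n_in)
    y = _rule_weights(model, X) @ model.f
    return y if np.asarray(x).ndim > 1 else y[0]


def loss(model: AFNNModel, X: np.ndarray, Y: np.ndarray) -> float:
    """Mean squared error over samples and outputs (normalized space)."""
    X = _as_batch(X, model.n_in)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    if Y.shape != (X.shape[0], model.n_out):
        raise ValueError(f"target shape {Y.shape} != ({X.shape[0]}, {model.n_out})")
    r = forward(model, X) - Y
    return float(np.mean(r**2))


def gradients(model: AFNNModel, X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradients of the MSE loss w.r.t. (f, b, c).

    Backpropagates through the normalized rule activations (softmax over log
    activations), the Gaussian memberships and the logistic centers.
    """
    X = _as_batch(X, model.n_in)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    S = X.shape[0]
    sig = model.sigma[None]  # (1, n_in, L)
    mu = centers(model, X)  # (S, n_in, L)
    d = (X[:, :, None] - mu) / sig
    logw = -(d**2).sum(axis=1)
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    w /= w.sum(axis=1, keepdims=True)  # (S, L)
    yhat = w @ model.f  # (S, n_out)
    dEdy = 2.0 * (yhat - Y) / (S * model.n_out)  # (S, n_out)
    gf = w.T @ dEdy  # (L, n_out)
    # softmax backprop: dy_k/dz_j = w_j (f_jk - y_k)
    g = w * (dEdy @ model.f.T - np.einsum("sk,sk->s", dEdy, yhat)[:, None])  # (S, L)
    dEdd = g[:, None, :] * (-2.0 * d)  # (S, n_in, L)
    dEdmu = dEdd * (-1.0 / sig)
    dEda = dEdmu * (-mu * (1.0 - mu))  # centers: mu = logistic(-a)
    gb = (dEda * X[:, :, None]).sum(axis=0)
    gc = dEda.sum(axis=0) / (2.0 * model.sigma)
    return gf, gb, gc


def init_model(
    n_in: int,
    n_out: int,
    L: int,
    Y: np.ndarray | None = None,
    seed: int = 0,
) -> AFNNModel:
    """Seeded initialization on the normalized domain.

    Consequents start as small uniform noise around the (normalized) output
    mean; the center parameters b, c start near zero so every membership
    center sits near 0.5; widths are fixed at 0.5.
    """
    rng = np.random.default_rng(seed)
    ymean = 0.5 if Y is None else np.asarray(Y, float).mean(axis=0)
    f = np.broadcast_to(ymean, (L, n_out)).copy() + rng.uniform(-0.05, 0.05, (L, n_out))
    b = rng.normal(0.0, 0.1, (n_in, L))
    c = rng.normal(0.0, 0.1, (n_in, L))
    sigma = np.full((n_in, L), 0.5)
    return AFNNModel(f=f, b=b, c=c, sigma=sigma)


def train(
    model: AFNNModel,
    X: np.ndarray,
    Y: np.ndarray,
    cfg: TrainConfig | None = None,
) -> tuple[AFNNModel, list[float]]:
    """Full-batch gradient descent on (f, b, c); returns (model, loss history).

    ``X`` and ``Y`` must already be normalized.  Stops when the loss falls
    below ``cfg.tol`` or after ``cfg.maxstep`` iterations.  Deterministic:
    no randomness beyond the caller-fixed initialization.
    """
    cfg = cfg or TrainConfig()
    m = AFNNModel(
        f=model.f.copy(), b=model.b.copy(), c=model.c.copy(), sigma=model.sigma.copy(),
        norm_in=model.norm_in, norm_out=model.norm_out,
    )
    history: list[float] = []
    for step in range(cfg.maxstep):
        e = loss(m, X, Y)
        if not np.isfinite(e):
            raise TrainingDivergedError(f"loss became non-finite at iteration {step}")
        history.append(e)
        if e <= cfg.tol:
            break
        gf, gb, gc = gradients(m, X, Y)
        m.f -= cfg.learning_rate * gf
        m.b -= cfg.learning_rate * gb
        m.c -= cfg.learning_rate * gc
    return m, history


def fit(
    X_raw: np.ndarray,
    Y_raw: np.ndarray,
    L: int = 10,
    cfg: TrainConfig | None = None,
) -> tuple[AFNNModel, list[float]]:
    """Normalize raw (envelope, angle) data, initialize and train a model."""
    cfg = cfg or TrainConfig()
    Xn, sx = normalize(np.asarray(X_raw, float))
    Yn, sy = normalize(np.asarray(Y_raw, float))
    model = init_model(Xn.shape[1], Yn.shape[1], L, Y=Yn, seed=cfg.seed)
    model.norm_in, model.norm_out = sx, sy
    return train(model, Xn, Yn, cfg)


def predict(model: AFNNModel, X_raw: np.ndarray) -> np.ndarray:
    """Raw-domain prediction: normalize, forward, denormalize."""
    if model.norm_in is None or model.norm_out is None:
        raise ValueError("model has no normalization statistics; train via fit()")
    Xn, _ = normalize(np.asarray(X_raw, float), model.norm_in)
    return denormalize(forward(model, Xn), model.norm_out)


def predict_trajectory(model: AFNNModel, env: EnvelopeFeatures) -> JointTrajectory:
    """Estimate the 3-joint angle trajectory from an envelope record."""
    if env.table.data.shape[1] != model.n_in:
        raise ValueError(
            f"envelope has {env.table.data.shape[1]} channels, model expects {model.n_in}"
        )
    angles = predict(model, env.table.values())
    return JointTrajectory.from_arrays(angles, rate=env.rate, t0=env.table.t0)


# ---------------------------------------------------------------------------
# serialization


def save_model(model: AFNNModel, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "f": model.f.tolist(),
        "b": model.b.tolist(),
        "c": model.c.tolist(),
        "sigma": model.sigma.tolist(),
        "norm_in": model.norm_in.to_dict() if model.norm_in else None,
        "norm_out": model.norm_out.to_dict() if model.norm_out else None,
    }
    path.write_text(json.dumps(doc))
    return path


def load_model(path: str | Path) -> AFNNModel:
    doc = json.loads(Path(path).read_text())
    return AFNNModel(
        f=np.asarray(doc["f"], float),
        b=np.asarray(doc["b"], float),
        c=np.asarray(doc["c"], float),
        sigma=np.asarray(doc["sigma"], float),
        norm_in=NormStats.from_dict(doc["norm_in"]) if doc["norm_in"] else None,
        norm_out=NormStats.from_dict(doc["norm_out"]) if doc["norm_out"] else None,
    )
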