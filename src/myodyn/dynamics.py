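"""Three-link planar Lagrangian model of the upper limb (sagittal plane).

Links: upper arm, forearm, hand, chained by shoulder, elbow and wrist
joints.  Joint angles are relative to the previous link, zero meaning the
limb hangs vertically; the public API takes degrees (package convention),
radians are used internally.  The rigid-body equations are

    M(theta) theta'' + C(theta, theta') theta' + G(theta) = tau,

with ``M`` built from the center-of-mass Jacobians, ``C`` from Christoffel
symbols (so that dM/dt - 2C is skew-symmetric) and ``G`` as the gradient of
the potential energy.  Partial derivatives of ``M`` are obtained by
complex-step differentiation, which is exact to machine precision.

Default link parameters come from standard adult anthropometry (the model is
used structurally by the controllers; all values are configurable):
upper arm 2.0 kg / 0.30 m, forearm 1.5 kg / 0.25 m, hand 0.5 kg / 0.18 m,
center of mass at mid-length, thin-rod inertia m l^2 / 12.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LimbParams",
    "JointState",
    "mass_matrix",
    "coriolis_matrix",
    "gravity_vector",
    "potential_energy",
    "kinetic_energy",
    "inverse_dynamics",
    "forward_dynamics",
]

_D2R = np.pi / 180.0


@dataclass
class LimbParams:
    """Per-link mass (kg), length (m), COM distance (m), inertia (kg m^2)."""

    masses: tuple = (2.0, 1.5, 0.5)
    lengths: tuple = (0.30, 0.25, 0.18)
    com: tuple | None = None  # default: mid-length
    inertias: tuple | None = None  # default: rod m l^2 / 12
    gravity: float = 9.81

    def __post_init__(self) -> None:
        if self.com is None:
            self.com = tuple(l / 2.0 for l in self.lengths)
        if self.inertias is None:
            self.inertias = tuple(
                m * l**2 / 12.0 for m, l in zip(self.masses, self.lengths)
            )
        if len(self.masses) != 3 or len(self.lengths) != 3:
            raise ValueError("exactly three links are modeled")
        if any(m <= 0 for m in self.masses) or any(l <= 0 for l in self.lengths):
            raise ValueError("masses and lengths must be positive")
        if any(not (0 < r <= l) for r, l in zip(self.com, self.lengths)):
            raise ValueError("COM distances must lie in (0, length]")
        if any(i < 0 for i in self.inertias):
            raise ValueError("inertias must be nonnegative")


@dataclass
class JointState:
    """Joint angles (deg), velocities (deg/s) and accelerations (deg/s^2)."""

    theta: np.ndarray
    theta_dot: np.ndarray = field(default_factory=lambda: np.zeros(3))
    theta_ddot: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.theta_dot = np.asarray(self.theta_dot, dtype=float)
        self.theta_ddot = np.asarray(self.theta_ddot, dtype=float)
        for v in (self.theta, self.theta_dot, self.theta_ddot):
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError("joint state needs three finite entries per field")


# ---------------------------------------------------------------------------
# internals (radians; complex-safe for complex-step differentiation)


def _com_jacobians(p: LimbParams, th):
    """COM linear Jacobians J_i (2x3) and COM heights y_ci, absolute angles."""
    phi = np.cumsum(th)  # absolute link angles from downward vertical
    jacs = []
    heights = []
    for i in range(3):
        coef = [p.lengths[k] for k in range(i)] + [p.com[i]]
        J = np.zeros((2, 3), dtype=np.asarray(th).dtype)
        y = 0.0
        for k in range(i + 1):
            # segment k contributes to columns j <= k
            ck, sk = np.cos(phi[k]), np.sin(phi[k])
            for j in range(k + 1):
                J[0, j] += coef[k] * ck
                J[1, j] += coef[k] * sk
            y = y - coef[k] * ck
        jacs.append(J)
        heights.append(y)
    return jacs, heights, phi


def _mass_matrix_rad(p: LimbParams, th) -> np.ndarray:
    jacs, _, _ = _com_jacobians(p, th)
    M = np.zeros((3, 3), dtype=np.asarray(th).dtype)
    for i in range(3):
        M += p.masses[i] * (jacs[i].T @ jacs[i])
        ones = np.zeros((3, 3))
        ones[: i + 1, : i + 1] = 1.0  # omega_i = sum_{k<=i} theta_dot_k
        M = M + p.inertias[i] * ones
    return M


def _dM_dtheta_rad(p: LimbParams, th: np.ndarray) -> np.ndarray:
    """dM[k][i,j] = dM_ij / dtheta_k via complex-step (machine precision)."""
    h = 1e-20
    out = np.zeros((3, 3, 3))
    for k in range(3):
        thc = th.astype(complex)
        thc[k] += 1j * h
        out[k] = _mass_matrix_rad(p, thc).imag / h
    return out


def _coriolis_rad(p: LimbParams, th: np.ndarray, thd: np.ndarray) -> np.ndarray:
    dM = _dM_dtheta_rad(p, th)
    C = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            # Christoffel symbols of the first kind
            C[i, j] = 0.5 * np.sum(
                (dM[:, i, j] + dM[j, i, :] - dM[i, j, :]) * thd
            )
    return C


def _gravity_rad(p: LimbParams, th) -> np.ndarray:
    # G = dV/dtheta with V = sum_i m_i g y_ci; row 1 of J_i is d(y_ci)/dtheta
    jacs, _, _ = _com_jacobians(p, th)
    G = np.zeros(3, dtype=np.asarray(th).dtype)
    for i in range(3):
        G = G + p.masses[i] * p.gravity * jacs[i][1]
    return G


# ---------------------------------------------------------------------------
# public API (degrees in, SI out)


def mass_matrix(p: LimbParams, theta_deg: np.ndarray) -> np.ndarray:
    """Symmetric positive-definite inertia matrix (kg m^2)."""
    return _mass_matrix_rad(p, np.asarray(theta_deg, dtype=float) * _D2R)


def coriolis_matrix(p: LimbParams, theta_deg: np.ndarray, theta_dot_deg: np.ndarray) -> np.ndarray:
    """Coriolis/centrifugal matrix such that dM/dt - 2C is skew-symmetric.

    ``theta_dot_deg`` in deg/s; the returned C multiplies velocities in rad/s.
    """
    th = np.asarray(theta_deg, dtype=float) * _D2R
    thd = np.asarray(theta_dot_deg, dtype=float) * _D2R
    return _coriolis_rad(p, th, thd)


def gravity_vector(p: LimbParams, theta_deg: np.ndarray) -> np.ndarray:
    """Gravity torque vector (N m); zero at the hanging equilibrium."""
    return _gravity_rad(p, np.asarray(theta_deg, dtype=float) * _D2R)


def potential_energy(p: LimbParams, theta_deg: np.ndarray) -> float:
    """Gravitational potential energy (J), zero datum at the pivot height."""
    th = np.asarray(theta_deg, dtype=float) * _D2R
    _, heights, _ = _com_jacobians(p, th)
    return float(sum(m * p.gravity * y for m, y in zip(p.masses, heights)))


def kinetic_energy(p: LimbParams, theta_deg: np.ndarray, theta_dot_deg: np.ndarray) -> float:
    """Total kinetic energy (J) for the given state."""
    th = np.asarray(theta_deg, dtype=float) * _D2R
    thd = np.asarray(theta_dot_deg, dtype=float) * _D2R
    return float(0.5 * thd @ _mass_matrix_rad(p, th) @ thd)


def inverse_dynamics(p: LimbParams, state: JointState) -> np.ndarray:
    """Joint torques (N m) producing the given accelerations."""
    th = state.theta * _D2R
    thd = state.theta_dot * _D2R
    thdd = state.theta_ddot * _D2R
    M = _mass_matrix_rad(p, th)
    C = _coriolis_rad(p, th, thd)
    G = _gravity_rad(p, th)
    return M @ thdd + C @ thd + G


def forward_dynamics(
    p: LimbParams, theta_deg: np.ndarray, theta_dot_deg: np.ndarray, tau: np.ndarray
) -> np.ndarray:
    """Joint accelerations (deg/s^2) under the given torques (N m)."""
    th = np.asarray(theta_deg, dtype=float) * _D2R
    thd = np.asarray(theta_dot_deg, dtype=float) * _D2R
    M = _mass_matrix_rad(p, th)
    C = _coriolis_rad(p, th, thd)
    G = _gravity_rad(p, th)
    thdd = np.linalg.solve(M, np.asarray(tau, dtype=float) - C @ thd - G)
    return thdd / _D2R
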