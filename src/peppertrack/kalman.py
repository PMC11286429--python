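"""Constant-velocity Kalman filter for per-track box motion.

State is the 8-vector (cx, cy, a, h, vcx, vcy, va, vh): box center in
pixels, aspect ratio w/h, height in pixels, and their per-frame
velocities.  The measurement is the first four components.  One frame is
one time unit; camera ego-motion is absorbed by the velocity states
(control input is identically zero).

Noise is height-proportional so that gating behaves the same for near
and far fruit: position-like standard deviations scale as
``std_weight_position * h`` and velocity-like ones as
``std_weight_velocity * h``; the dimensionless aspect channel uses small
constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

NDIM = 4  # measured components: cx, cy, a, h


class NumericalFailure(RuntimeError):
    """Innovation covariance was not positive definite."""


def _transition_matrix() -> np.ndarray:
    f = np.eye(2 * NDIM)
    for i in range(NDIM):
        f[i, NDIM + i] = 1.0  # dt = 1 frame
    return f


def _measurement_matrix() -> np.ndarray:
    return np.eye(NDIM, 2 * NDIM)


@dataclass
class KalmanModel:
    """Model matrices and noise builders for the constant-velocity filter.

    std_weight_position / std_weight_velocity control the height-scaled
    process and measurement noise; aspect-channel standard deviations
    are fixed small constants (dimensionless channel).
    """

    std_weight_position: float = 1.0 / 20.0
    std_weight_velocity: float = 1.0 / 160.0
    aspect_process_std: float = 1e-2
    aspect_velocity_std: float = 1e-5
    aspect_measurement_std: float = 1e-1
    F: np.ndarray = field(default_factory=_transition_matrix)
    H: np.ndarray = field(default_factory=_measurement_matrix)

    def process_noise(self, mean: np.ndarray) -> np.ndarray:
        """Qt for one predict step, built from the current state height."""
        h = mean[3]
        std = [
            self.std_weight_position * h,
            self.std_weight_position * h,
            self.aspect_process_std,
            self.std_weight_position * h,
            self.std_weight_velocity * h,
            self.std_weight_velocity * h,
            self.aspect_velocity_std,
            self.std_weight_velocity * h,
        ]
        return np.diag(np.square(std))

    def measurement_noise(self, mean: np.ndarray) -> np.ndarray:
        """Rt for one update, built from the predicted state height."""
        h = mean[3]
        std = [
            self.std_weight_position * h,
            self.std_weight_position * h,
            self.aspect_measurement_std,
            self.std_weight_position * h,
        ]
        return np.diag(np.square(std))


@dataclass
class KalmanState:
    """Mean and covariance of one tracked box."""

    mean: np.ndarray  # (8,)
    covariance: np.ndarray  # (8, 8)


@dataclass
class UpdateIntermediates:
    """Residual and gain of one measurement update, kept for diagnostics."""

    residual: np.ndarray  # (4,)
    gain: np.ndarray  # (8, 4)


def initiate(measurement: np.ndarray, model: KalmanModel | None = None) -> KalmanState:
    """Start a new track state from an unmatched detection.

    Position components copy the measurement; velocities start at zero
    with a deliberately wide covariance so the first updates can pull
    them quickly.
    """
    model = model or KalmanModel()
    measurement = np.asarray(measurement, dtype=float)
    mean = np.concatenate([measurement, np.zeros(NDIM)])
    h = measurement[3]
    std = [
        2 * model.std_weight_position * h,
        2 * model.std_weight_position * h,
        1e-2,
        2 * model.std_weight_position * h,
        10 * model.std_weight_velocity * h,
        10 * model.std_weight_velocity * h,
        1e-5,
        10 * model.std_weight_velocity * h,
    ]
    return KalmanState(mean=mean, covariance=np.diag(np.square(std)))


def predict(state: KalmanState, model: KalmanModel | None = None) -> KalmanState:
    """One-step prediction: mean' = F mean; P' = F P Fᵀ + Qt."""
    model = model or KalmanModel()
    mean = model.F @ state.mean
    cov = model.F @ state.covariance @ model.F.T + model.process_noise(state.mean)
    cov = 0.5 * (cov + cov.T)  # enforce symmetry against roundoff
    return KalmanState(mean=mean, covariance=cov)


def update(
    state: KalmanState, measurement: np.ndarray, model: KalmanModel | None = None
) -> tuple[KalmanState, UpdateIntermediates]:
    """Measurement update via Cholesky-factored gain solve.

    Returns the posterior state together with the residual and gain.
    The gain is obtained by solving S Kᵀ = H Pᵀ with a symmetric
    factorization of the innovation covariance S = H P Hᵀ + Rt instead
    of forming S⁻¹ explicitly.
    """
    model = model or KalmanModel()
    measurement = np.asarray(measurement, dtype=float)
    projected_mean = model.H @ state.mean
    s = model.H @ state.covariance @ model.H.T + model.measurement_noise(state.mean)
    try:
        chol = scipy.linalg.cho_factor(s, lower=True, check_finite=False)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - Rt > 0 prevents this
        raise NumericalFailure("innovation covariance not positive definite") from exc
    gain = scipy.linalg.cho_solve(
        chol, (state.covariance @ model.H.T).T, check_finite=False
    ).T
    residual = measurement - projected_mean
    mean = state.mean + gain @ residual
    cov = (np.eye(2 * NDIM) - gain @ model.H) @ state.covariance
    cov = 0.5 * (cov + cov.T)
    return KalmanState(mean=mean, covariance=cov), UpdateIntermediates(residual, gain)


def gating_distance(
    state: KalmanState, measurements: np.ndarray, model: KalmanModel | None = None
) -> np.ndarray:
    """Squared Mahalanobis distance of each measurement from the predicted box.

    d S⁻¹ dᵀ with d = z − H x̂ and S = H P Hᵀ + Rt, computed through a
    triangular solve.  The 0.95 χ² quantile at 4 dof (9.4877) is the
    conventional gate on these values.
    """
    model = model or KalmanModel()
    measurements = np.atleast_2d(np.asarray(measurements, dtype=float))
    projected_mean = model.H @ state.mean
    s = model.H @ state.covariance @ model.H.T + model.measurement_noise(state.mean)
    try:
        chol = np.linalg.cholesky(s)
    except np.linalg.LinAlgError as exc:
        raise NumericalFailure("gating covariance not positive definite") from exc
    d = measurements - projected_mean
    z = scipy.linalg.solve_triangular(
        chol, d.T, lower=True, check_finite=False, overwrite_b=True
    )
    return np.sum(z * z, axis=0)
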