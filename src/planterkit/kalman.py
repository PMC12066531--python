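"""Constant-velocity Kalman filter over box states, ByteTrack-style.

The state is the 8-vector ``(cx, cy, a, h, vcx, vcy, va, vh)`` — box center,
aspect ratio (w/h), height, and their per-frame velocities.  Process and
measurement noise are scaled by the current box height, so uncertainty grows
with apparent object size; the weights (1/20 for positions, 1/160 for
velocities) are the ones published with the ByteTrack/SORT family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Box

_NDIM = 4
_STD_POS = 1.0 / 20.0
_STD_VEL = 1.0 / 160.0

# Transition: x_{t+1} = F x_t with unit time step.
_F = np.eye(2 * _NDIM)
_F[:_NDIM, _NDIM:] = np.eye(_NDIM)
# Measurement picks out (cx, cy, a, h).
_H = np.eye(_NDIM, 2 * _NDIM)


@dataclass
class KalmanState:
    """Gaussian belief over one track's box state."""

    mean: np.ndarray  # (8,)
    covariance: np.ndarray  # (8, 8), symmetric PSD

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(2 * _NDIM)
        self.covariance = np.asarray(self.covariance, dtype=float).reshape(
            2 * _NDIM, 2 * _NDIM
        )

    def box(self) -> Box:
        """Project the mean to a corner-form box."""
        cx, cy, a, h = self.mean[:_NDIM]
        if h <= 0:
            raise ValueError(f"state projects to non-positive height {h}")
        w = a * h
        return Box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)


def _check_psd(cov: np.ndarray) -> None:
    if not np.allclose(cov, cov.T, atol=1e-8):
        raise ValueError("covariance is not symmetric")
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() < -1e-8:
        raise ValueError(f"covariance is not PSD (min eigenvalue {eigvals.min():.3g})")


def box_to_measurement(box: Box) -> np.ndarray:
    cx, cy = box.center
    return np.array([cx, cy, box.width / box.height, box.height])


def initiate(box: Box) -> KalmanState:
    """Start a new track belief from a single observed box, zero velocity."""
    z = box_to_measurement(box)
    mean = np.concatenate([z, np.zeros(_NDIM)])
    h = z[3]
    std = np.array(
        [2 * _STD_POS * h, 2 * _STD_POS * h, 1e-2, 2 * _STD_POS * h,
         10 * _STD_VEL * h, 10 * _STD_VEL * h, 1e-5, 10 * _STD_VEL * h]
    )
    return KalmanState(mean, np.diag(std**2))


def predict(state: KalmanState) -> KalmanState:
    """Advance the belief one frame under the constant-velocity model."""
    _check_psd(state.covariance)
    h = max(state.mean[3], 1e-6)
    std = np.array(
        [_STD_POS * h, _STD_POS * h, 1e-2, _STD_POS * h,
         _STD_VEL * h, _STD_VEL * h, 1e-5, _STD_VEL * h]
    )
    q = np.diag(std**2)
    mean = _F @ state.mean
    cov = _F @ state.covariance @ _F.T + q
    return KalmanState(mean, cov)


def update(state: KalmanState, observation: Box) -> KalmanState:
    """Condition the belief on an observed box (linear-Gaussian update)."""
    z = box_to_measurement(observation)
    h = max(state.mean[3], 1e-6)
    std = np.array([_STD_POS * h, _STD_POS * h, 1e-1, _STD_POS * h])
    r = np.diag(std**2)

    s = _H @ state.covariance @ _H.T + r  # innovation covariance
    if abs(np.linalg.det(s)) < 1e-30:
        raise np.linalg.LinAlgError("singular innovation covariance")
    k = np.linalg.solve(s.T, (_H @ state.covariance.T)).T  # Kalman gain
    innovation = z - _H @ state.mean
    mean = state.mean + k @ innovation
    cov = state.covariance - k @ s @ k.T
    cov = 0.5 * (cov + cov.T)  # keep symmetric against round-off
    return KalmanState(mean, cov)
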