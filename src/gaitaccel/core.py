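"""Shared containers and rotation conventions.

Frames and conventions used throughout the package:

* **Sensor (body) frame** — fixed to the device strapped to the shank:
  x lateral, y anterior, z along the shank with *down* positive.
* **Reference (world) frame** — right-handed, z vertical and chosen so the
  gravity vector is ``g_o = (0, 0, +g)``; at the standing calibration pose
  the sensor frame coincides with the reference frame.
* **Pose** — roll ``phi`` / pitch ``theta`` / yaw ``psi`` about the reference
  x / y / z axes, counterclockwise positive, and
  ``R0 = Rz(psi) @ Ry(theta) @ Rx(phi)`` maps sensor coordinates to reference
  coordinates.  A reference-frame vector ``v`` seen by the sensor is
  ``R0.T @ v``; in particular gravity in the sensor frame is ``R0.T @ g_o``.

Angles are radians everywhere in memory; file I/O converts to degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigurationError, InvalidInputError

GRAVITY_DEFAULT = 9.8
"""Gravity constant [m/s^2] used unless overridden (matches the pose model)."""

COV_FLOOR = 1e-9
"""Floor applied to adaptive noise variances to keep Q and R positive definite."""


def as_vector3(v, name: str = "vector") -> np.ndarray:
    """Coerce to a finite float array of shape (3,) or (N, 3)."""
    arr = np.asarray(v, dtype=float)
    if arr.shape != (3,) and (arr.ndim != 2 or arr.shape[1] != 3):
        raise InvalidInputError(f"{name} must have shape (3,) or (N, 3), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return arr


def rot_x(phi):
    phi = np.asarray(phi, dtype=float)
    c, s = np.cos(phi), np.sin(phi)
    o, z = np.ones_like(c), np.zeros_like(c)
    return np.stack(
        [np.stack([o, z, z], -1), np.stack([z, c, -s], -1), np.stack([z, s, c], -1)], -2
    )


def rot_y(theta):
    theta = np.asarray(theta, dtype=float)
    c, s = np.cos(theta), np.sin(theta)
    o, z = np.ones_like(c), np.zeros_like(c)
    return np.stack(
        [np.stack([c, z, s], -1), np.stack([z, o, z], -1), np.stack([-s, z, c], -1)], -2
    )


def rot_z(psi):
    psi = np.asarray(psi, dtype=float)
    c, s = np.cos(psi), np.sin(psi)
    o, z = np.ones_like(c), np.zeros_like(c)
    return np.stack(
        [np.stack([c, -s, z], -1), np.stack([s, c, z], -1), np.stack([z, z, o], -1)], -2
    )


def rotation_matrix(roll, pitch, yaw) -> np.ndarray:
    """Body-to-reference rotation ``R0 = Rz(yaw) @ Ry(pitch) @ Rx(roll)``.

    Accepts scalars or equal-length arrays; returns (3, 3) or (N, 3, 3).
    """
    return rot_z(yaw) @ rot_y(pitch) @ rot_x(roll)


def wrap_angle(a):
    """Wrap angle(s) to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(a, dtype=float), 2.0 * np.pi)


@dataclass(frozen=True)
class SensorGeometry:
    """Position of the sensor relative to the knee-joint center, sensor frame [m].

    Defaults follow the shank-mounted protocol: the sensor sits on the anterior
    face of the shank, 5 cm anterior (ry = -0.05) and ~20 cm distal
    (rz in [-0.215, -0.190], default midpoint) of the knee center.
    """

    r: tuple = (0.0, -0.05, -0.2025)

    def __post_init__(self):
        arr = np.asarray(self.r, dtype=float)
        if arr.shape != (3,):
            raise ConfigurationError(f"sensor offset r must be length 3, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ConfigurationError("sensor offset r must be finite")
        if np.linalg.norm(arr) == 0.0:
            raise ConfigurationError("sensor offset r must be non-zero")
        object.__setattr__(self, "r", tuple(arr))

    @property
    def r_vec(self) -> np.ndarray:
        return np.asarray(self.r, dtype=float)


@dataclass(frozen=True)
class DifferentiatorSpec:
    """Pseudo-differentiator ``D(s) = s / (1 + n s)`` configuration.

    ``n`` [s] is the time constant (default 0.01) and ``dt`` [s] the sampling
    interval (default 0.01, i.e. 100 Hz).  ``causal=False`` selects the
    zero-phase offline realization; ``causal=True`` the bilinear IIR one.
    """

    n: float = 0.01
    dt: float = 0.01
    causal: bool = False

    def __post_init__(self):
        if not (self.n > 0.0 and math.isfinite(self.n)):
            raise ConfigurationError(f"time constant n must be > 0, got {self.n}")
        if not (self.dt > 0.0 and math.isfinite(self.dt)):
            raise ConfigurationError(f"sampling interval dt must be > 0, got {self.dt}")

    @property
    def transient_samples(self) -> int:
        """Number of warm-up samples flagged as transient: ceil(5 n / dt)."""
        return int(math.ceil(5.0 * self.n / self.dt))


@dataclass
class ImuSeries:
    """Uniformly sampled 9-axis record: gyro [rad/s], accel [m/s^2], mag [a.u.]."""

    dt: float
    gyro: np.ndarray
    accel: np.ndarray
    mag: np.ndarray
    t0: float = 0.0

    def __post_init__(self):
        self.gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
        self.accel = np.atleast_2d(np.asarray(self.accel, dtype=float))
        self.mag = np.atleast_2d(np.asarray(self.mag, dtype=float))
        n = len(self.gyro)
        if n < 2:
            raise InvalidInputError("ImuSeries needs at least 2 samples")
        for name, arr in (("gyro", self.gyro), ("accel", self.accel), ("mag", self.mag)):
            if arr.shape != (n, 3):
                raise InvalidInputError(f"{name} must have shape ({n}, 3), got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise InvalidInputError(f"{name} contains non-finite values")
        if not (self.dt > 0.0):
            raise InvalidInputError(f"dt must be > 0, got {self.dt}")

    def __len__(self) -> int:
        return len(self.gyro)

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self))

    @property
    def duration(self) -> float:
        return self.dt * (len(self) - 1)


@dataclass
class EulerPoseSeries:
    """Roll/pitch/yaw trajectory [rad] with per-step filter diagnostics.

    ``angles`` has columns (roll, pitch, yaw).  Diagnostics are aligned 1:1
    with the samples; index 0 holds the initialization (zero innovation).
    """

    dt: float
    angles: np.ndarray
    t0: float = 0.0
    innovation: Optional[np.ndarray] = None        # (N, 4)
    innovation_cov: Optional[np.ndarray] = None    # (N, 4, 4)
    gain: Optional[np.ndarray] = None              # (N, 3, 4)
    state_cov: Optional[np.ndarray] = None         # (N, 3, 3)
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        self.angles = np.atleast_2d(np.asarray(self.angles, dtype=float))
        if self.angles.shape[1] != 3:
            raise InvalidInputError(f"angles must have 3 columns, got {self.angles.shape}")

    def __len__(self) -> int:
        return len(self.angles)

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self))

    @property
    def roll(self) -> np.ndarray:
        return self.angles[:, 0]

    @property
    def pitch(self) -> np.ndarray:
        return self.angles[:, 1]

    @property
    def yaw(self) -> np.ndarray:
        return self.angles[:, 2]

    def validate_covariances(self, tol: float = 1e-9) -> None:
        """Assert every stored state covariance is symmetric PSD within tol."""
        if self.state_cov is None:
            return
        asym = np.max(np.abs(self.state_cov - np.swapaxes(self.state_cov, -1, -2)))
        if asym > tol:
            raise InvalidInputError(f"state covariance asymmetry {asym:.2e} exceeds {tol:.0e}")
        eig = np.linalg.eigvalsh(0.5 * (self.state_cov + np.swapaxes(self.state_cov, -1, -2)))
        if eig.min() < -tol:
            raise InvalidInputError(f"state covariance eigenvalue {eig.min():.2e} below -{tol:.0e}")


@dataclass
class AccelComponentSeries:
    """Per-sample four-way split of the accelerometer output, sensor frame [m/s^2].

    The identity ``gravitational + centrifugal + tangential + translational
    + coriolis == raw`` holds to machine precision by construction; the
    Coriolis term is identically zero under the fixed-offset assumption but
    kept as an explicit field so the bookkeeping is visible.
    """

    dt: float
    gravitational: np.ndarray
    centrifugal: np.ndarray
    tangential: np.ndarray
    translational: np.ndarray
    coriolis: np.ndarray
    raw: np.ndarray
    t0: float = 0.0
    transient_samples: int = 0

    def __len__(self) -> int:
        return len(self.raw)

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self))

    def identity_residual(self) -> np.ndarray:
        """Per-sample residual of the component-sum identity (should be ~0)."""
        total = (
            self.gravitational
            + self.centrifugal
            + self.tangential
            + self.translational
            + self.coriolis
        )
        return total - self.raw
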