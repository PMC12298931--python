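"""Rigid-body acceleration decomposition for a joint-mounted sensor.

The accelerometer on a shank-mounted IMU reads the sum of five terms in the
sensor frame::

    A = A_tra + A_cen + A_tan + A_col + g_i

* ``A_cen = w x (w x r)``   centrifugal, from knee rotation rate ``w``;
* ``A_tan = dw/dt x r``     tangential, from knee angular acceleration;
* ``g_i  = R0.T @ (0,0,g)`` gravity seen by the tilted sensor;
* ``A_col = 2 w x dr/dt``   Coriolis — identically zero here because the
  sensor-to-knee offset ``r`` is fixed on the segment;
* ``A_tra``                 translational acceleration of the knee-joint
  center, the remainder, reflecting motion of more proximal segments.

The angular acceleration is obtained from the gyroscope with the
pseudo-differentiator ``D(s) = s / (1 + n s)``; see :func:`differentiate_gyro`
for the discrete realization.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .core import (
    GRAVITY_DEFAULT,
    AccelComponentSeries,
    DifferentiatorSpec,
    EulerPoseSeries,
    ImuSeries,
    SensorGeometry,
    as_vector3,
)
from .errors import AlignmentError, InvalidInputError

__all__ = [
    "centrifugal_acceleration",
    "tangential_acceleration",
    "differentiate_gyro",
    "gravity_in_sensor_frame",
    "decompose_acceleration",
]


def centrifugal_acceleration(omega, geometry: SensorGeometry) -> np.ndarray:
    """Centrifugal acceleration ``w x (w x r)`` [m/s^2], component form.

    ``omega`` is the gyroscope output [rad/s], shape (3,) or (N, 3).
    """
    w = as_vector3(omega, "omega")
    rx, ry, rz = geometry.r
    wx, wy, wz = w[..., 0], w[..., 1], w[..., 2]
    # expanded double cross product, written out component by component
    ax = (-wy * wy - wz * wz) * rx + wx * wy * ry + wx * wz * rz
    ay = wx * wy * rx + (-wz * wz - wx * wx) * ry + wy * wz * rz
    az = wx * wz * rx + wy * wz * ry + (-wx * wx - wy * wy) * rz
    return np.stack([ax, ay, az], axis=-1)


def tangential_acceleration(omega_dot, geometry: SensorGeometry) -> np.ndarray:
    """Tangential acceleration ``dw/dt x r`` [m/s^2], component form."""
    wd = as_vector3(omega_dot, "omega_dot")
    rx, ry, rz = geometry.r
    dwx, dwy, dwz = wd[..., 0], wd[..., 1], wd[..., 2]
    ax = -dwz * ry + dwy * rz
    ay = dwz * rx - dwx * rz
    az = -dwy * rx + dwx * ry
    return np.stack([ax, ay, az], axis=-1)


def differentiate_gyro(series, spec: DifferentiatorSpec | None = None) -> np.ndarray:
    """Apply the pseudo-differentiator ``D(s) = s/(1+ns)`` per axis.

    Input is a uniformly sampled series, shape (N,) or (N, C); output has the
    same shape and units-per-second.

    Two discrete realizations are provided:

    * default (``spec.causal=False``): zero-phase realization whose magnitude
      response equals ``|D(jw)| = w / sqrt(1 + (n w)^2)`` below half the
      Nyquist rate (raised-cosine band-edge roll-off above), built in the
      frequency domain on a full even extension of the record.  Intended
      for recorded (offline) gait data: it has no phase lag, which would
      otherwise dominate the tangential-acceleration error.
    * ``spec.causal=True``: bilinear (Tustin) IIR discretization of D(s),
      initialized at the first sample, for streaming use.

    The first ``spec.transient_samples`` samples (and, for the zero-phase
    variant, the mirrored tail) carry edge transients; downstream statistics
    may exclude them.
    """
    if spec is None:
        spec = DifferentiatorSpec()
    x = np.asarray(series, dtype=float)
    if x.shape[0] < 2:
        raise InvalidInputError("series must have at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("series contains non-finite values")
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]

    if spec.causal:
        b, a = signal.bilinear([1.0, 0.0], [spec.n, 1.0], fs=1.0 / spec.dt)
        zi = signal.lfilter_zi(b, a)
        y = np.empty_like(x)
        for c in range(x.shape[1]):
            y[:, c], _ = signal.lfilter(b, a, x[:, c], zi=zi * x[0, c])
    else:
        n_samp = x.shape[0]
        # full even extension (length 2N-2): circularly continuous everywhere,
        # so the spectral filter sees no wrap-around jump; the residual slope
        # kinks at the two folds decay within ~5n of the record edges
        xe = np.concatenate([x, x[-2:0:-1]], axis=0)
        w = 2.0 * np.pi * np.fft.rfftfreq(xe.shape[0], d=spec.dt)
        h = 1j * w / np.sqrt(1.0 + (spec.n * w) ** 2)
        # raised-cosine roll-off over the top half of the digital band:
        # suppresses Gibbs ringing from band-edge content the discrete grid
        # cannot represent; the response below 0.5 Nyquist is untouched
        w_nyq = np.pi / spec.dt
        hi = w > 0.5 * w_nyq
        h[hi] *= 0.5 * (1.0 + np.cos(np.pi * (w[hi] - 0.5 * w_nyq) / (0.5 * w_nyq)))
        y = np.fft.irfft(np.fft.rfft(xe, axis=0) * h[:, None], xe.shape[0], axis=0)
        y = y[:n_samp]

    return y[:, 0] if squeeze else y


def gravity_in_sensor_frame(pose, gravity_constant: float = GRAVITY_DEFAULT) -> np.ndarray:
    """Gravity vector expressed in the sensor frame: ``R0.T @ (0, 0, g)``.

    ``pose`` is (roll, pitch, yaw) [rad], shape (3,) or (N, 3).  The result
    has norm exactly ``gravity_constant`` (rotations preserve norm)::

        g_i = g * (-sin(pitch), sin(roll) cos(pitch), cos(roll) cos(pitch))
    """
    p = as_vector3(pose, "pose")
    roll, pitch = p[..., 0], p[..., 1]
    g = float(gravity_constant)
    return np.stack(
        [
            -g * np.sin(pitch),
            g * np.sin(roll) * np.cos(pitch),
            g * np.cos(roll) * np.cos(pitch),
        ],
        axis=-1,
    )


def decompose_acceleration(
    imu: ImuSeries,
    poses: EulerPoseSeries,
    geometry: SensorGeometry | None = None,
    spec: DifferentiatorSpec | None = None,
    gravity_constant: float = GRAVITY_DEFAULT,
) -> AccelComponentSeries:
    """Split the accelerometer record into its five components.

    ``imu`` and ``poses`` must be sample-aligned (same length and dt).  The
    translational component is defined as the remainder
    ``A - (A_cen + A_tan + g_i)``, so the component-sum identity holds to
    machine precision by construction.
    """
    if geometry is None:
        geometry = SensorGeometry()
    if spec is None:
        spec = DifferentiatorSpec(dt=imu.dt)
    if len(imu) != len(poses):
        raise AlignmentError(f"imu has {len(imu)} samples but poses has {len(poses)}")
    if abs(imu.dt - poses.dt) > 1e-9 * imu.dt:
        raise AlignmentError(f"imu dt {imu.dt} and poses dt {poses.dt} differ")
    if abs(spec.dt - imu.dt) > 1e-9 * imu.dt:
        raise AlignmentError(f"differentiator dt {spec.dt} does not match record dt {imu.dt}")

    omega_dot = differentiate_gyro(imu.gyro, spec)
    cen = centrifugal_acceleration(imu.gyro, geometry)
    tan = tangential_acceleration(omega_dot, geometry)
    grav = gravity_in_sensor_frame(poses.angles, gravity_constant)
    col = np.zeros_like(cen)  # fixed sensor offset: Coriolis term vanishes
    tra = imu.accel - cen - tan - grav - col
    return AccelComponentSeries(
        dt=imu.dt,
        t0=imu.t0,
        gravitational=grav,
        centrifugal=cen,
        tangential=tan,
        translational=tra,
        coriolis=col,
        raw=imu.accel.copy(),
        transient_samples=spec.transient_samples,
    )

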