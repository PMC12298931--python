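"""Pose fusion: adaptive extended Kalman filter on Euler angles.

State is ``x = (yaw, pitch, roll)`` [rad].  The state equation integrates the
Euler-rate kinematics driven by the gyroscope (forward Euler over one sample);
the 4-dimensional observation stacks the tilt-compensated compass heading and
the three accelerometer axes, whose noise-free prediction is gravity rotated
into the sensor frame.

Both noise covariances adapt to the sensor output:

* process:      ``Q = (a |w|^2 + b) I_3`` — rotation excites model error;
* observation:  ``R = diag(Om, Oa, Oa, Oa)`` with
  ``Om = c (|m_c|^2 - m_bar) + d`` and
  ``Oa = e (Ax^2 + Ay^2 + (Az - g)^2) + f`` — the gravity observation is
  distrusted exactly when the specific force deviates from rest, i.e. when
  motion acceleration contaminates it.

The six coefficients (a..f) are tuned by maximizing the innovation
log-likelihood of the filtered record (:func:`innovation_log_likelihood`,
:func:`tune_noise_parameters`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import optimize

from .core import (
    COV_FLOOR,
    GRAVITY_DEFAULT,
    EulerPoseSeries,
    ImuSeries,
    as_vector3,
    wrap_angle,
)
from .errors import (
    ConfigurationError,
    DegenerateInputError,
    InvalidInputError,
    NumericalError,
    UndefinedHeadingError,
)

__all__ = [
    "NoiseTuningParams",
    "LikelihoodReport",
    "TuningResult",
    "initial_tilt_from_accel",
    "tilt_compensate_and_yaw",
    "state_transition",
    "observation_model",
    "compute_jacobians",
    "adaptive_process_noise",
    "adaptive_observation_noise",
    "ekf_step",
    "run_pose_estimation",
    "innovation_log_likelihood",
    "tune_noise_parameters",
]

#: default initial state covariance: (10 deg)^2 yaw, (5 deg)^2 pitch/roll,
#: the accuracy scale of the accel/mag initialization
P0_DEFAULT = np.diag(np.radians([10.0, 5.0, 5.0]) ** 2)

PITCH_GUARD_DEG = 89.0


@dataclass(frozen=True)
class NoiseTuningParams:
    """Adaptive-noise coefficients.

    ``a, b`` scale the process noise from the squared gyro norm; ``c, d``
    the heading-observation noise from the corrected-field norm deviation;
    ``e, f`` the gravity-observation noise from the specific-force deviation.
    ``b, d, f`` are additive floors and must be positive.  ``mag_norm_ref``
    is the record-average of the squared corrected-field norm (computed from
    the record when left None).
    """

    a: float = 1e-8
    b: float = 1e-9
    c: float = 0.05
    d: float = 1e-2
    e: float = 5.0
    f: float = 1.0
    mag_norm_ref: Optional[float] = None

    def __post_init__(self):
        for name in ("b", "d", "f"):
            if not (getattr(self, name) > 0.0):
                raise ConfigurationError(f"noise floor {name} must be > 0")
        for name in ("a", "c", "e"):
            if getattr(self, name) < 0.0:
                raise ConfigurationError(f"coefficient {name} must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d, self.e, self.f])

    @classmethod
    def from_array(cls, arr, mag_norm_ref=None) -> "NoiseTuningParams":
        a, b, c, d, e, f = (float(v) for v in arr)
        return cls(a=a, b=b, c=c, d=d, e=e, f=f, mag_norm_ref=mag_norm_ref)


@dataclass
class LikelihoodReport:
    """Innovation log-likelihood of a filtered record."""

    ll: float
    n_steps: int
    per_step: np.ndarray


@dataclass
class TuningResult:
    """Outcome of log-likelihood tuning."""

    params: NoiseTuningParams
    ll_initial: float
    ll_final: float
    n_evaluations: int
    converged: bool
    trace: list


def initial_tilt_from_accel(accel_at_rest) -> tuple[float, float]:
    """Roll and pitch [rad] from the gravity direction of a static accelerometer.

    ``roll = atan2(Ay, Az)``, ``pitch = atan2(-Ax, sqrt(Ay^2 + Az^2))``,
    both in (-pi, pi).
    """
    a = as_vector3(accel_at_rest, "accel")
    if a.ndim != 1:
        raise InvalidInputError("initial tilt expects a single 3-vector")
    if np.linalg.norm(a) == 0.0:
        raise DegenerateInputError("zero accelerometer vector: tilt undefined")
    roll = math.atan2(a[1], a[2])
    pitch = math.atan2(-a[0], math.hypot(a[1], a[2]))
    return roll, pitch


def tilt_rotation(roll: float, pitch: float) -> np.ndarray:
    """Tilt-compensation matrix ``Ry(pitch) @ Rx(roll)`` (a rotation)."""
    cp, sp = math.cos(pitch), math.sin(pitch)
    cr, sr = math.cos(roll), math.sin(roll)
    return np.array(
        [
            [cp, sr * sp, cr * sp],
            [0.0, cr, -sr],
            [-sp, sr * cp, cr * cp],
        ]
    )


def tilt_compensate_and_yaw(mag, roll: float, pitch: float) -> tuple[np.ndarray, float]:
    """De-tilt the magnetometer reading and read the heading from it.

    Returns ``(m_c, yaw)`` with ``m_c`` the corrected field (same norm as the
    raw reading) and ``yaw = atan2(-m_c_y, m_c_x)`` in (-pi, pi).
    """
    m = as_vector3(mag, "mag")
    if m.ndim != 1:
        raise InvalidInputError("tilt compensation expects a single 3-vector")
    if np.linalg.norm(m) == 0.0:
        raise DegenerateInputError("zero magnetometer vector")
    m_c = tilt_rotation(roll, pitch) @ m
    if m_c[0] == 0.0 and m_c[1] == 0.0:
        raise UndefinedHeadingError("horizontal field components vanish; heading undefined")
    yaw = math.atan2(-m_c[1], m_c[0])
    return m_c, yaw


def _euler_rates(state, gyro):
    """Euler-angle rates (psi_dot, theta_dot, phi_dot) from body rates."""
    psi, theta, phi = state
    wx, wy, wz = gyro
    guard = math.radians(PITCH_GUARD_DEG)
    theta_c = min(max(theta, -guard), guard)  # gimbal guard on sec/tan
    sec = 1.0 / math.cos(theta_c)
    tan = math.tan(theta_c)
    sphi, cphi = math.sin(phi), math.cos(phi)
    return (
        sphi * sec * wy + cphi * sec * wz,
        cphi * wy - sphi * wz,
        wx + sphi * tan * wy + cphi * tan * wz,
    ), abs(theta) > guard


def state_transition(state, gyro, dt: float) -> np.ndarray:
    """One forward-Euler step of the Euler-rate kinematics.

    ``state`` is (yaw, pitch, roll); ``gyro`` the body rates [rad/s].
    """
    state = np.asarray(state, dtype=float)
    gyro = as_vector3(gyro, "gyro")
    rates, _ = _euler_rates(state, gyro)
    return state + dt * np.asarray(rates)


def observation_model(state, gravity_constant: float = GRAVITY_DEFAULT) -> np.ndarray:
    """Predicted observation ``(yaw, g_sensor_x, g_sensor_y, g_sensor_z)``."""
    psi, theta, phi = (float(v) for v in state)
    g = float(gravity_constant)
    return np.array(
        [
            psi,
            -g * math.sin(theta),
            g * math.sin(phi) * math.cos(theta),
            g * math.cos(phi) * math.cos(theta),
        ]
    )


def compute_jacobians(
    state, gyro, dt: float, gravity_constant: float = GRAVITY_DEFAULT
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic Jacobians of the state map F and observation map H.

    Returns ``(f, h)`` with shapes (3, 3) and (4, 3); differentiation is with
    respect to the state (yaw, pitch, roll).
    """
    psi, theta, phi = (float(v) for v in np.asarray(state, dtype=float))
    wx, wy, wz = (float(v) for v in as_vector3(gyro, "gyro"))
    g = float(gravity_constant)
    guard = math.radians(PITCH_GUARD_DEG)
    theta_c = min(max(theta, -guard), guard)
    sec = 1.0 / math.cos(theta_c)
    tan = math.tan(theta_c)
    sphi, cphi = math.sin(phi), math.cos(phi)

    f = np.eye(3)
    # d psi_dot / d(theta, phi)
    f[0, 1] = dt * (sphi * sec * tan * wy + cphi * sec * tan * wz)
    f[0, 2] = dt * (cphi * sec * wy - sphi * sec * wz)
    # d theta_dot / d phi
    f[1, 2] = dt * (-sphi * wy - cphi * wz)
    # d phi_dot / d(theta, phi)
    f[2, 1] = dt * (sphi * sec * sec * wy + cphi * sec * sec * wz)
    f[2, 2] = 1.0 + dt * (cphi * tan * wy - sphi * tan * wz)

    st, ct = math.sin(theta), math.cos(theta)
    h = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, -g * ct, 0.0],
            [0.0, -g * sphi * st, g * cphi * ct],
            [0.0, -g * cphi * st, -g * sphi * ct],
        ]
    )
    return f, h


def adaptive_process_noise(gyro, params: NoiseTuningParams) -> np.ndarray:
    """Process covariance ``Q = (a |w|^2 + b) I_3``."""
    w = as_vector3(gyro, "gyro")
    omega = max(params.a * float(np.dot(w, w)) + params.b, COV_FLOOR)
    return np.diag([omega, omega, omega])


def adaptive_observation_noise(
    accel,
    mag_corrected,
    params: NoiseTuningParams,
    gravity_constant: float = GRAVITY_DEFAULT,
    floor: float = COV_FLOOR,
) -> np.ndarray:
    """Observation covariance ``R = diag(Om, Oa, Oa, Oa)``.

    ``Om`` grows with the deviation of the corrected-field power from its
    record average ``m_bar`` (magnetic disturbance); ``Oa`` with the deviation
    of the specific force from rest (motion acceleration).  Entries are
    floored at ``floor`` to stay positive definite.
    """
    a = as_vector3(accel, "accel")
    m_c = as_vector3(mag_corrected, "mag_corrected")
    m_bar = params.mag_norm_ref
    if m_bar is None:
        m_bar = float(np.dot(m_c, m_c))
    om = params.c * (float(np.dot(m_c, m_c)) - m_bar) + params.d
    g = float(gravity_constant)
    oa = params.e * (a[0] ** 2 + a[1] ** 2 + (a[2] - g) ** 2) + params.f
    om = max(om, floor)
    oa = max(oa, floor)
    return np.diag([om, oa, oa, oa])


def _update(x_pred, P_pred, y, R, gravity_constant, h=None):
    """Measurement update; returns (x, P, V, B, K)."""
    if h is None:
        _, h = compute_jacobians(x_pred, np.zeros(3), 0.0, gravity_constant)
    V = y - observation_model(x_pred, gravity_constant)
    V[0] = wrap_angle(V[0])  # heading innovation lives on the circle
    B = h @ P_pred @ h.T + R
    B = 0.5 * (B + B.T)
    try:
        K = np.linalg.solve(B, h @ P_pred).T
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            f"singular innovation covariance (cond={np.linalg.cond(B):.2e})"
        ) from exc
    x = x_pred + K @ V
    P = (np.eye(3) - K @ h) @ P_pred
    P = 0.5 * (P + P.T)
    return x, P, V, B, K


def ekf_step(
    state,
    P,
    y,
    gyro,
    dt: float,
    params: NoiseTuningParams,
    gravity_constant: float = GRAVITY_DEFAULT,
    mag_corrected_sq: Optional[float] = None,
):
    """One predict/update cycle.

    ``y = (yaw_from_mag, Ax, Ay, Az)`` is the assembled observation.
    ``mag_corrected_sq`` feeds the heading-noise adaptation; when None the
    heading variance reduces to its floor ``d``.  Returns
    ``(state, P, V, B, K)``.
    """
    state = np.asarray(state, dtype=float)
    P = np.asarray(P, dtype=float)
    y = np.asarray(y, dtype=float)
    gyro = as_vector3(gyro, "gyro")

    Q = adaptive_process_noise(gyro, params)
    f, _ = compute_jacobians(state, gyro, dt, gravity_constant)
    x_pred = state_transition(state, gyro, dt)
    P_pred = f @ P @ f.T + Q

    m_bar = params.mag_norm_ref
    msq = mag_corrected_sq if mag_corrected_sq is not None else (m_bar or 0.0)
    om = max(params.c * (msq - (m_bar if m_bar is not None else msq)) + params.d, COV_FLOOR)
    g = float(gravity_constant)
    oa = max(params.e * (y[1] ** 2 + y[2] ** 2 + (y[3] - g) ** 2) + params.f, COV_FLOOR)
    R = np.diag([om, oa, oa, oa])

    _, h = compute_jacobians(x_pred, gyro, dt, gravity_constant)
    return _update(x_pred, P_pred, y, R, gravity_constant, h=h)


def _initialize(imu: ImuSeries, calibration_window: float, warnings: list):
    """Average the static head of the record and solve the initial pose."""
    n_cal = int(round(calibration_window / imu.dt))
    if n_cal > len(imu):
        raise InvalidInputError(
            f"calibration window {calibration_window} s exceeds record "
            f"length {imu.duration:.2f} s"
        )
    n_cal = max(n_cal, 1)
    gyro_rms = float(np.sqrt(np.mean(imu.gyro[:n_cal] ** 2)))
    if gyro_rms > 0.05:
        warnings.append(
            f"calibration window not static: gyro RMS {gyro_rms:.3f} rad/s > 0.05"
        )
    accel0 = imu.accel[:n_cal].mean(axis=0)
    mag0 = imu.mag[:n_cal].mean(axis=0)
    roll0, pitch0 = initial_tilt_from_accel(accel0)
    _, yaw0 = tilt_compensate_and_yaw(mag0, roll0, pitch0)
    return np.array([yaw0, pitch0, roll0])


def run_pose_estimation(
    imu: ImuSeries,
    params: NoiseTuningParams | None = None,
    calibration_window: float = 5.0,
    gravity_constant: float = GRAVITY_DEFAULT,
    P0: Optional[np.ndarray] = None,
) -> EulerPoseSeries:
    """Filter a whole record into a roll/pitch/yaw trajectory.

    The record must start with ~``calibration_window`` seconds of standing
    (the measurement protocol): the window average of the accelerometer and
    magnetometer fixes the initial state.  Output is aligned 1:1 with the
    input and carries the per-step innovation diagnostics needed for
    log-likelihood tuning.
    """
    if params is None:
        params = NoiseTuningParams()
    warnings: list = []
    x = _initialize(imu, calibration_window, warnings)
    P = P0_DEFAULT.copy() if P0 is None else np.asarray(P0, dtype=float).copy()
    if params.mag_norm_ref is None:
        params = replace(params, mag_norm_ref=float(np.mean(np.sum(imu.mag**2, axis=1))))

    n = len(imu)
    dt = imu.dt
    g = float(gravity_constant)
    states = np.empty((n, 3))
    V_hist = np.zeros((n, 4))
    B_hist = np.zeros((n, 4, 4))
    K_hist = np.zeros((n, 3, 4))
    P_hist = np.zeros((n, 3, 3))
    states[0] = x
    P_hist[0] = P
    B_hist[0] = np.eye(4)
    guard_hits = 0

    a_coef, b_coef = params.a, params.b
    c_coef, d_coef = params.c, params.d
    e_coef, f_coef = params.e, params.f
    m_bar = params.mag_norm_ref
    eye3 = np.eye(3)

    gyro = imu.gyro
    accel = imu.accel
    mag = imu.mag

    for t in range(1, n):
        w = gyro[t - 1]
        # prediction
        rates, guarded = _euler_rates(x, w)
        guard_hits += guarded
        x_pred = x + dt * np.asarray(rates)
        f_jac, _ = compute_jacobians(x, w, dt, g)
        q = max(a_coef * float(w @ w) + b_coef, COV_FLOOR)
        P_pred = f_jac @ P @ f_jac.T + q * eye3

        # observation: de-tilt the compass with the predicted attitude
        m_c = tilt_rotation(x_pred[2], x_pred[1]) @ mag[t]
        if m_c[0] == 0.0 and m_c[1] == 0.0:
            raise NumericalError(f"heading undefined at sample {t}")
        psi_m = math.atan2(-m_c[1], m_c[0])
        a_t = accel[t]
        y = np.array([psi_m, a_t[0], a_t[1], a_t[2]])

        om = max(c_coef * (float(m_c @ m_c) - m_bar) + d_coef, COV_FLOOR)
        oa = max(
            e_coef * (a_t[0] ** 2 + a_t[1] ** 2 + (a_t[2] - g) ** 2) + f_coef,
            COV_FLOOR,
        )
        R = np.diag([om, oa, oa, oa])
        _, h_jac = compute_jacobians(x_pred, w, dt, g)
        try:
            x, P, V, B, K = _update(x_pred, P_pred, y, R, g, h=h_jac)
        except NumericalError as exc:
            raise NumericalError(f"at sample {t} (t={imu.t0 + t * dt:.2f} s): {exc}") from exc
        states[t] = x
        V_hist[t] = V
        B_hist[t] = B
        K_hist[t] = K
        P_hist[t] = P

    if guard_hits:
        warnings.append(f"gimbal guard engaged at {guard_hits} prediction steps")

    # state order (yaw, pitch, roll) -> output columns (roll, pitch, yaw)
    angles = states[:, ::-1].copy()
    return EulerPoseSeries(
        dt=dt,
        t0=imu.t0,
        angles=angles,
        innovation=V_hist,
        innovation_cov=B_hist,
        gain=K_hist,
        state_cov=P_hist,
        warnings=warnings,
    )


def innovation_log_likelihood(poses: EulerPoseSeries) -> LikelihoodReport:
    """Multivariate innovation log-likelihood of a filtered record.

    ``LL = -(N d / 2) ln(2 pi) - 1/2 sum_j [ ln det B_j + V_j' B_j^-1 V_j ]``
    over the N update steps (the initialization sample is excluded); reduces
    to the scalar per-dimension form when B is diagonal.
    """
    if poses.innovation is None or poses.innovation_cov is None:
        raise InvalidInputError("pose series carries no innovation diagnostics")
    V = poses.innovation[1:]
    B = poses.innovation_cov[1:]
    n = len(V)
    if n == 0:
        raise InvalidInputError("no update steps recorded")
    dim = V.shape[1]
    try:
        np.linalg.cholesky(0.5 * (B + np.swapaxes(B, -1, -2)))
    except np.linalg.LinAlgError as exc:
        raise NumericalError("innovation covariance not positive definite") from exc
    _, logdet = np.linalg.slogdet(B)
    quad = np.einsum("ni,ni->n", V, np.linalg.solve(B, V[..., None])[..., 0])
    per_step = -0.5 * dim * math.log(2.0 * math.pi) - 0.5 * (logdet + quad)
    return LikelihoodReport(ll=float(per_step.sum()), n_steps=n, per_step=per_step)


def _ll_of(imu, params, calibration_window, gravity_constant) -> float:
    poses = run_pose_estimation(
        imu, params, calibration_window=calibration_window, gravity_constant=gravity_constant
    )
    return innovation_log_likelihood(poses).ll


def _moment_matched_start(
    imu, initial, m_bar, calibration_window, gravity_constant
) -> np.ndarray:
    """Method-of-moments warm start for the observation coefficients.

    One filter pass under the initial parameters yields innovations; regressing
    their squares on the adaptation regressors (field-power deviation for the
    heading row, specific-force deviation for the gravity rows) gives
    first-shot (c, d) and (e, f).  The process coefficients are kept at their
    initial values — they are only weakly identified from a single pass.
    """
    poses = run_pose_estimation(
        imu, initial, calibration_window=calibration_window,
        gravity_constant=gravity_constant,
    )
    V = poses.innovation[1:]
    g = float(gravity_constant)
    acc = imu.accel[1:]
    dev2 = acc[:, 0] ** 2 + acc[:, 1] ** 2 + (acc[:, 2] - g) ** 2
    # |m_c| equals |m_raw| (the de-tilt matrix is a rotation)
    msq_dev = np.sum(imu.mag[1:] ** 2, axis=1) - m_bar

    def fit(y2, x):
        A = np.column_stack([x, np.ones_like(x)])
        slope, intercept = np.linalg.lstsq(A, y2, rcond=None)[0]
        return max(float(slope), 0.0), max(float(intercept), 1e-8)

    c0, d0 = fit(V[:, 0] ** 2, msq_dev)
    e0, f0 = fit((V[:, 1:] ** 2).ravel(), np.repeat(dev2, 3))
    return np.log(np.array([initial.a, initial.b, max(c0, 1e-12), d0,
                            max(e0, 1e-12), f0]))


def tune_noise_parameters(
    imu: ImuSeries,
    initial: NoiseTuningParams | None = None,
    calibration_window: float = 5.0,
    gravity_constant: float = GRAVITY_DEFAULT,
    max_evals: int = 500,
    probe_factor: float = 10.0,
    n_polish: int = 8,
) -> TuningResult:
    """Maximize the innovation log-likelihood over (a, b, c, d, e, f).

    A method-of-moments warm start seeds a derivative-free simplex
    (Nelder--Mead) on log-parameters (positivity by construction), followed by
    axis probes at ``x probe_factor`` and ``/ probe_factor`` of each tuned
    coefficient; any improving probe restarts the simplex there (at most
    ``n_polish`` times).  The returned parameters are the best evaluated
    anywhere, so the tuned log-likelihood never falls below the starting one.
    """
    if initial is None:
        initial = NoiseTuningParams()
    m_bar = initial.mag_norm_ref
    if m_bar is None:
        m_bar = float(np.mean(np.sum(imu.mag**2, axis=1)))

    trace: list = []
    best = {"ll": -np.inf, "logp": np.log(initial.as_array())}
    n_evals = 0

    def objective(logp):
        nonlocal n_evals
        n_evals += 1
        logp = np.clip(logp, -45.0, 45.0)  # keep exp() finite; flat beyond
        try:
            params = NoiseTuningParams.from_array(np.exp(logp), mag_norm_ref=m_bar)
            ll = _ll_of(imu, params, calibration_window, gravity_constant)
        except (NumericalError, ConfigurationError, InvalidInputError,
                FloatingPointError, OverflowError):
            return 1e12
        if not math.isfinite(ll):
            return 1e12
        trace.append((n_evals, float(ll), np.exp(logp).tolist()))
        if ll > best["ll"]:
            best["ll"] = ll
            best["logp"] = np.array(logp, dtype=float)
        return -ll

    x0 = np.log(initial.as_array())
    ll_initial = -objective(x0)
    try:
        warm = _moment_matched_start(imu, replace(initial, mag_norm_ref=m_bar),
                                     m_bar, calibration_window, gravity_constant)
        objective(warm)
    except (NumericalError, ConfigurationError, InvalidInputError):
        pass
    converged = False
    step = math.log(probe_factor)

    for _ in range(1 + n_polish):
        budget = max_evals - n_evals
        if budget <= 13:
            break
        res = optimize.minimize(
            objective,
            best["logp"],
            method="Nelder-Mead",
            options={"maxfev": budget - 12, "xatol": 1e-3, "fatol": 1e-3, "adaptive": True},
        )
        # axis probes: x10 / /10 on each coefficient of the current best;
        # any improvement restarts the simplex from the improved point
        improved = False
        base = best["logp"].copy()
        for k in range(6):
            for sgn in (+1.0, -1.0):
                probe = base.copy()
                probe[k] += sgn * step
                if -objective(probe) > best["ll"] + 1e-9:
                    improved = True
        if not improved:
            converged = bool(res.success)
            break

    params = NoiseTuningParams.from_array(np.exp(best["logp"]), mag_norm_ref=m_bar)
    return TuningResult(
        params=params,
        ll_initial=float(ll_initial),
        ll_final=float(best["ll"]),
        n_evaluations=n_evals,
        converged=converged,
        trace=trace,
    )
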