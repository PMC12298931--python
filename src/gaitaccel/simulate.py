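"""Synthetic gait ground truth and 9-axis IMU synthesis.

The generator emulates the measurement protocol: the subject stands for 5 s,
ramps into steady walking at 90 steps/min paced by a metronome, and keeps
walking; the sensor sits on the anterior mid-shank, below the knee center.

Kinematic model (chosen for exact, closed-form derivatives):

* the shank's sagittal inclination follows a 4-harmonic Fourier angular-rate
  profile fitted to the classic shank-gyro shape — a dominant positive
  mid-swing peak flanked by troughs placed *analytically* at foot contact
  (0% cycle) and toe-off (60% cycle), which defines the ground-truth events;
* the hip (thigh) angle is a single-harmonic sagittal oscillation; the knee
  angle is their difference and stays in a physiological range;
* small frontal/transverse shank rotations exercise pitch and yaw;
* the pelvis (hip joint center) translates forward at the stride-determined
  speed with small vertical (2/cycle) and lateral (1/cycle) oscillations;
* a C2 smoothstep envelope takes every oscillatory term from standing to
  steady gait over one ramp cycle.

Everything downstream is assembled exactly: body rates from the Euler-rate
kinematics, knee-center world acceleration from analytic second derivatives,
and the accelerometer output as the sum
``A = R0.T a_knee + w x (w x r) + dw/dt x r + R0.T g_o`` (Coriolis zero by
construction, the sensor offset being fixed), so the synthesized components
satisfy the decomposition identity to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
import numpy as np

from .core import (
    GRAVITY_DEFAULT,
    AccelComponentSeries,
    EulerPoseSeries,
    ImuSeries,
    SensorGeometry,
    rotation_matrix,
)
from .decomposition import centrifugal_acceleration, tangential_acceleration
from .errors import ConfigurationError
from .gait import GaitEvents

__all__ = [
    "GaitModelParams",
    "SyntheticGroundTruth",
    "generate_leg_trajectory",
    "synthesize_imu",
    "ground_truth_components",
    "simulate_gait",
]

#: Shank sagittal angular-rate Fourier pairs (cos, sin) per harmonic [rad/s].
#: Fitted once to the canonical shank-gyro template under the analytic
#: constraints d(rate)/dt = 0 at 0% and 60% cycle (event troughs) and a
#: -1.10 rad stance excursion; harmonics capped at 4 to keep the waveform
#: inside the differentiator's resolution.
SHANK_RATE_COEFFS = (
    (0.509507, -2.576489),
    (-1.349654, -0.790085),
    (-0.805280, 0.507759),
    (0.214986, 0.658342),
)


@dataclass(frozen=True)
class GaitModelParams:
    """Simulator configuration; defaults are the walking-protocol conditions.

    Cadence 90 steps/min (two steps per cycle -> 4/3 s cycle), stride 1.5 m
    (1.125 m/s, inside the protocol's 1.05-1.2 m/s range), toe-off at 60% of
    the cycle, 5 s of standing calibration, noiseless sensors.  ``seed``
    fixes all randomness.
    """

    cadence: float = 90.0            # steps/min; one cycle = two steps
    n_cycles: int = 10               # steady cycles (events cover these)
    dt: float = 0.01                 # sampling interval [s] (100 Hz)
    calibration_time: float = 5.0    # standing head of the record [s]
    ramp_cycles: float = 1.0         # standing -> steady-gait blend [cycles]
    tail_time: float = 0.3           # walking continues past the last event [s]
    stride_length: float = 1.5       # forward travel per cycle [m]
    thigh_length: float = 0.41       # hip-to-knee segment length [m]

    shank_angle0: float = 0.30       # shank inclination at foot contact [rad]
    shank_rate_coeffs: tuple = SHANK_RATE_COEFFS
    hip_mean: float = 0.12           # hip-angle offset [rad]
    hip_amp: float = 0.30            # hip-angle amplitude [rad]
    hip_phase: float = 0.20          # hip-angle phase [rad]
    pitch_amp: float = 0.035         # frontal-plane shank oscillation [rad]
    pitch_phase: float = 1.0
    yaw_amp: float = 0.07            # transverse-plane shank oscillation [rad]
    yaw_phase: float = -0.5
    pelvis_vertical_amp: float = 0.02   # [m], 2 per cycle
    pelvis_lateral_amp: float = 0.03    # [m], 1 per cycle
    pelvis_foreaft_amp: float = 0.01    # [m], 2 per cycle
    toe_off_fraction: float = 0.60

    geometry: SensorGeometry = field(default_factory=SensorGeometry)
    gravity: float = GRAVITY_DEFAULT
    mag_dip_deg: float = 0.0         # magnetic inclination below horizontal
    gyro_noise_std: float = 0.0      # [rad/s]
    accel_noise_std: float = 0.0     # [m/s^2]
    mag_noise_frac: float = 0.0      # fraction of field magnitude
    gyro_bias: tuple = (0.0, 0.0, 0.0)  # constant bias [rad/s]
    seed: int = 0

    def __post_init__(self):
        if not (self.cadence > 0):
            raise ConfigurationError("cadence must be > 0")
        if not (self.dt > 0):
            raise ConfigurationError("dt must be > 0")
        if self.n_cycles < 1:
            raise ConfigurationError("n_cycles must be >= 1")
        if not (self.thigh_length > 0):
            raise ConfigurationError("thigh_length must be > 0")
        if not (0.0 < self.toe_off_fraction < 1.0):
            raise ConfigurationError("toe_off_fraction must be in (0, 1)")

    @property
    def cycle_time(self) -> float:
        return 120.0 / self.cadence

    def with_sensor_noise(
        self, gyro: float = 0.01, accel: float = 0.1, mag_frac: float = 0.01, seed=None
    ) -> "GaitModelParams":
        """Copy with realistic sensor noise (gyro rad/s, accel m/s^2, mag frac)."""
        return replace(
            self,
            gyro_noise_std=gyro,
            accel_noise_std=accel,
            mag_noise_frac=mag_frac,
            seed=self.seed if seed is None else seed,
        )


@dataclass
class SyntheticGroundTruth:
    """Exact simulator state paired with the signals it implies."""

    dt: float
    t: np.ndarray
    poses: EulerPoseSeries            # true roll/pitch/yaw [rad]
    euler_rates: np.ndarray           # (N, 3) d/dt of (roll, pitch, yaw)
    omega_body: np.ndarray            # (N, 3) body rates [rad/s]
    omega_dot_body: np.ndarray        # (N, 3) body angular acceleration
    knee_accel_world: np.ndarray      # (N, 3) knee-center acceleration, world
    knee_accel_sensor: np.ndarray     # (N, 3) same in sensor frame (= A_tra)
    components: AccelComponentSeries  # exact decomposition truth
    mag_ideal: np.ndarray             # (N, 3) noise-free magnetometer
    events: GaitEvents
    params: GaitModelParams


def _smoothstep(t, t_start, duration):
    """Quintic C2 smoothstep and its two derivatives."""
    if duration <= 0:
        w = (np.asarray(t) >= t_start).astype(float)
        return w, np.zeros_like(w), np.zeros_like(w)
    u = np.clip((np.asarray(t, dtype=float) - t_start) / duration, 0.0, 1.0)
    w = u**3 * (10.0 - 15.0 * u + 6.0 * u**2)
    d1 = 30.0 * u**2 * (1.0 - u) ** 2 / duration
    d2 = 60.0 * u * (1.0 - u) * (1.0 - 2.0 * u) / duration**2
    return w, d1, d2


def _env_product(env, f):
    """(w f)'' bookkeeping: returns value and two time derivatives."""
    w, w1, w2 = env
    v, v1, v2 = f
    return (w * v, w1 * v + w * v1, w2 * v + 2.0 * w1 * v1 + w * v2)


def _harmonic(x, omega_t, amp, mult, phase):
    """amp * sin(2 pi mult x + phase) with time derivatives (x = t/T)."""
    arg = 2.0 * np.pi * mult * x + phase
    w = mult * omega_t
    return (amp * np.sin(arg), amp * w * np.cos(arg), -amp * w**2 * np.sin(arg))


def _shank_signals(x, T, params):
    """Sagittal shank angle from the frozen rate coefficients, with derivatives."""
    val = np.full_like(x, params.shank_angle0)
    d1 = np.zeros_like(x)
    d2 = np.zeros_like(x)
    for m, (cm, dm) in enumerate(params.shank_rate_coeffs, start=1):
        w = 2.0 * np.pi * m
        s, c = np.sin(w * x), np.cos(w * x)
        val += T * (cm * s + dm * (1.0 - c)) / w
        d1 += cm * c + dm * s
        d2 += (w / T) * (-cm * s + dm * c)
    return val, d1, d2


def generate_leg_trajectory(params: GaitModelParams | None = None) -> SyntheticGroundTruth:
    """Build the closed-form gait kinematics and exact acceleration truth."""
    if params is None:
        params = GaitModelParams()
    T = params.cycle_time
    t_walk = params.calibration_time
    ramp = params.ramp_cycles * T
    t_end = t_walk + ramp + params.n_cycles * T + params.tail_time
    n = int(round(t_end / params.dt)) + 1
    t = params.dt * np.arange(n)
    x = (t - t_walk) / T  # cycle phase (negative while standing; envelope is 0)
    omega_t = 2.0 * np.pi / T

    env = _smoothstep(t, t_walk, ramp)

    sigma = _env_product(env, _shank_signals(x, T, params))
    hip_arg = 2.0 * np.pi * x - params.hip_phase
    hip_gait = (
        params.hip_mean + params.hip_amp * np.cos(hip_arg),
        -params.hip_amp * omega_t * np.sin(hip_arg),
        -params.hip_amp * omega_t**2 * np.cos(hip_arg),
    )
    hip = _env_product(env, hip_gait)

    roll = tuple(-v for v in sigma)  # shank forward inclination = negative roll
    pitch = _env_product(env, _harmonic(x, omega_t, params.pitch_amp, 1.0, params.pitch_phase))
    yaw = _env_product(env, _harmonic(x, omega_t, params.yaw_amp, 1.0, params.yaw_phase))

    phi, phi1, phi2 = roll
    th, th1, th2 = pitch
    ps, ps1, ps2 = yaw

    sph, cph = np.sin(phi), np.cos(phi)
    sth, cth = np.sin(th), np.cos(th)

    # body rates from Euler rates (inverse of the sec/tan kinematics)
    wx = phi1 - ps1 * sth
    wy = th1 * cph + ps1 * cth * sph
    wz = -th1 * sph + ps1 * cth * cph
    omega_body = np.stack([wx, wy, wz], axis=-1)

    wx_d = phi2 - ps2 * sth - ps1 * th1 * cth
    wy_d = (
        th2 * cph
        - th1 * phi1 * sph
        + ps2 * cth * sph
        + ps1 * (-th1 * sth * sph + phi1 * cth * cph)
    )
    wz_d = (
        -th2 * sph
        - th1 * phi1 * cph
        + ps2 * cth * cph
        + ps1 * (-th1 * sth * cph - phi1 * cth * sph)
    )
    omega_dot = np.stack([wx_d, wy_d, wz_d], axis=-1)

    # hip-joint-center (pelvis) world acceleration; world frame: x lateral,
    # y anterior, z down
    v0 = params.stride_length / T
    lat = _env_product(env, _harmonic(x, omega_t, params.pelvis_lateral_amp, 1.0, 0.3))
    vert = _env_product(env, _harmonic(x, omega_t, params.pelvis_vertical_amp, 2.0, 0.8))
    fore = _env_product(env, _harmonic(x, omega_t, params.pelvis_foreaft_amp, 2.0, 0.0))
    hip_acc_world = np.stack(
        [lat[2], v0 * env[1] + fore[2], vert[2]], axis=-1
    )

    # knee center = hip + L_t * (0, sin h, cos h); exact second derivative
    h, h1, h2 = hip
    sh, chh = np.sin(h), np.cos(h)
    knee_acc_world = hip_acc_world + params.thigh_length * np.stack(
        [np.zeros_like(h), h2 * chh - h1**2 * sh, -h2 * sh - h1**2 * chh], axis=-1
    )

    R0 = rotation_matrix(phi, th, ps)
    knee_acc_sensor = np.einsum("nji,nj->ni", R0, knee_acc_world)

    cen = centrifugal_acceleration(omega_body, params.geometry)
    tan = tangential_acceleration(omega_dot, params.geometry)
    g_o = np.array([0.0, 0.0, params.gravity])
    grav = np.einsum("nji,j->ni", R0, g_o)
    raw = knee_acc_sensor + cen + tan + grav
    components = AccelComponentSeries(
        dt=params.dt,
        gravitational=grav,
        centrifugal=cen,
        tangential=tan,
        translational=knee_acc_sensor,
        coriolis=np.zeros_like(cen),
        raw=raw,
        transient_samples=0,
    )

    dip = math.radians(params.mag_dip_deg)
    m_ref = np.array([math.cos(dip), 0.0, math.sin(dip)])
    mag_ideal = np.einsum("nji,j->ni", R0, m_ref)

    t_first = t_walk + ramp
    contacts = t_first + T * np.arange(params.n_cycles + 1)
    toe_offs = t_first + T * (np.arange(params.n_cycles) + params.toe_off_fraction)
    events = GaitEvents(foot_contacts=contacts, toe_offs=toe_offs)

    poses = EulerPoseSeries(dt=params.dt, angles=np.stack([phi, th, ps], axis=-1))
    return SyntheticGroundTruth(
        dt=params.dt,
        t=t,
        poses=poses,
        euler_rates=np.stack([phi1, th1, ps1], axis=-1),
        omega_body=omega_body,
        omega_dot_body=omega_dot,
        knee_accel_world=knee_acc_world,
        knee_accel_sensor=knee_acc_sensor,
        components=components,
        mag_ideal=mag_ideal,
        events=events,
        params=params,
    )


def ground_truth_components(truth: SyntheticGroundTruth) -> AccelComponentSeries:
    """The exact per-sample component vectors used in synthesis."""
    return truth.components


def synthesize_imu(
    truth: SyntheticGroundTruth, params: GaitModelParams | None = None
) -> ImuSeries:
    """Ideal 9-axis signals from the ground truth, plus configured noise.

    gyro = body rates (+ bias + white noise); accel = the exact component sum
    (+ white noise); mag = reference field in the sensor frame (+ white noise
    scaled to the field magnitude).  Seeded and reproducible.
    """
    if params is None:
        params = truth.params
    rng = np.random.default_rng(params.seed)
    n = len(truth.t)
    gyro = truth.omega_body + np.asarray(params.gyro_bias, dtype=float)
    accel = truth.components.raw.copy()
    mag = truth.mag_ideal.copy()
    if params.gyro_noise_std > 0:
        gyro = gyro + rng.normal(0.0, params.gyro_noise_std, (n, 3))
    if params.accel_noise_std > 0:
        accel = accel + rng.normal(0.0, params.accel_noise_std, (n, 3))
    if params.mag_noise_frac > 0:
        scale = params.mag_noise_frac * float(np.linalg.norm(mag[0]))
        mag = mag + rng.normal(0.0, scale, (n, 3))
    return ImuSeries(dt=params.dt, gyro=gyro, accel=accel, mag=mag)


def simulate_gait(
    params: GaitModelParams | None = None,
) -> tuple[ImuSeries, SyntheticGroundTruth]:
    """Convenience: ground truth plus the synthesized IMU record."""
    if params is None:
        params = GaitModelParams()
    truth = generate_leg_trajectory(params)
    return synthesize_imu(truth, params), truth
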