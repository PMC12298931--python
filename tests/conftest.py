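import numpy as np
import pytest

from gaitaccel import run_pose_estimation
from gaitaccel.simulate import GaitModelParams, simulate_gait


@pytest.fixture(scope="session")
def gait_noiseless():
    """Default walking record (10 steady cycles, seed 1) with ground truth."""
    imu, truth = simulate_gait(GaitModelParams(n_cycles=10, seed=1))
    return imu, truth


@pytest.fixture(scope="session")
def gait_poses(gait_noiseless):
    """Filtered pose trajectory of the default noiseless record."""
    imu, _ = gait_noiseless
    return run_pose_estimation(imu)


@pytest.fixture(scope="session")
def gait_noisy():
    """Short walking record with realistic sensor noise."""
    params = GaitModelParams(n_cycles=3, seed=7).with_sensor_noise()
    imu, truth = simulate_gait(params)
    return imu, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def constant_roll_truth(rate=1.5, duration=3.0, dt=0.01, params=None):
    """Hand-built ground truth: pure constant-rate knee rotation about sensor x.

    The knee center is fixed in the world, so the sensor point moves on a
    circle: its world acceleration is purely centripetal+tangential and the
    true translational component is identically zero.
    """
    from gaitaccel.core import AccelComponentSeries, EulerPoseSeries, rotation_matrix
    from gaitaccel.decomposition import centrifugal_acceleration, tangential_acceleration
    from gaitaccel.gait import GaitEvents
    from gaitaccel.simulate import GaitModelParams, SyntheticGroundTruth

    if params is None:
        params = GaitModelParams()
    n = int(round(duration / dt)) + 1
    t = dt * np.arange(n)
    roll = rate * t
    zeros = np.zeros(n)
    angles = np.stack([roll, zeros, zeros], axis=-1)
    omega = np.stack([np.full(n, rate), zeros, zeros], axis=-1)
    omega_dot = np.zeros((n, 3))
    R0 = rotation_matrix(roll, zeros, zeros)
    grav = np.einsum("nji,j->ni", R0, np.array([0.0, 0.0, params.gravity]))
    cen = centrifugal_acceleration(omega, params.geometry)
    tan = tangential_acceleration(omega_dot, params.geometry)
    comp = AccelComponentSeries(
        dt=dt,
        gravitational=grav,
        centrifugal=cen,
        tangential=tan,
        translational=np.zeros((n, 3)),
        coriolis=np.zeros((n, 3)),
        raw=grav + cen + tan,
    )
    dip = np.radians(params.mag_dip_deg)
    m_ref = np.array([np.cos(dip), 0.0, np.sin(dip)])
    return SyntheticGroundTruth(
        dt=dt,
        t=t,
        poses=EulerPoseSeries(dt=dt, angles=angles),
        euler_rates=np.stack([np.full(n, rate), zeros, zeros], axis=-1),
        omega_body=omega,
        omega_dot_body=omega_dot,
        knee_accel_world=np.zeros((n, 3)),
        knee_accel_sensor=np.zeros((n, 3)),
        components=comp,
        mag_ideal=np.einsum("nji,j->ni", R0, m_ref),
        events=GaitEvents(foot_contacts=[0.0, duration], toe_offs=[0.6 * duration]),
        params=params,
    )
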