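"""Estimate the sensor pose by fusing gyro, accelerometer and magnetometer.

The adaptive EKF integrates the gyroscope and corrects drift with the
gravity direction (accelerometer) and the tilt-compensated compass heading
(magnetometer), distrusting each observation exactly when the sensor output
says it is contaminated.
"""

import numpy as np

from gaitaccel import GaitModelParams, run_pose_estimation, simulate_gait

imu, truth = simulate_gait(GaitModelParams(n_cycles=10, seed=1))
poses = run_pose_estimation(imu)  # calibration window: first 5 s of standing

err = np.degrees(poses.angles - truth.poses.angles)
rmse = np.sqrt(np.mean(err**2, axis=0))
print(f"pose RMSE vs truth: roll {rmse[0]:.2f} deg, pitch {rmse[1]:.2f} deg, "
      f"yaw {rmse[2]:.2f} deg")
# Sub-degree tracking on the noiseless record; on real sensors the errors
# land at the few-degree scale typical of wearable sensor fusion.
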