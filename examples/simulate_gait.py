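"""Generate a synthetic walking record and look at what it contains.

The simulator emulates the measurement protocol: 5 s of standing, then
steady walking at 90 steps/min with the sensor on the anterior mid-shank.
It returns both the 9-axis record and the exact ground truth behind it.
"""

import numpy as np

from gaitaccel import GaitModelParams, simulate_gait

params = GaitModelParams(n_cycles=10, seed=1)
imu, truth = simulate_gait(params)

print(f"record: {len(imu)} samples at {1/imu.dt:.0f} Hz ({imu.duration:.1f} s)")
print(f"cycle time: {params.cycle_time:.3f} s  (cadence {params.cadence:.0f} steps/min)")
print(f"foot contacts: {np.round(truth.events.foot_contacts[:4], 2)} ...")
print(f"toe-offs:      {np.round(truth.events.toe_offs[:4], 2)} ...")
print(f"peak sagittal gyro: {np.abs(imu.gyro[:, 0]).max():.2f} rad/s")
print(f"roll range: {np.degrees(truth.poses.roll.min()):.1f} .. "
      f"{np.degrees(truth.poses.roll.max()):.1f} deg")
# The peak gyro is the mid-swing shank rotation; the roll range is the
# sagittal shank excursion between terminal swing and toe-off.
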