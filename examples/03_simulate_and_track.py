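"""Full IMU closure: simulate, calibrate, track, compare to ground truth.

The simulator emits 8 quaternion streams (pelvis, thorax, thighs, calves,
feet) at 60 Hz, each in its own fusion frame with a private uniform-random
heading -- exactly what magnetometer-free IMUs produce.  The anatomical
calibration recovers every heading from the neutral standing segment, and
tracking then reproduces the commanded joint angles.
"""

import numpy as np

from gaitbox import calibrate, track
from gaitbox.simulate import GaitProfile, NoiseModel, simulate_session

profile = GaitProfile()        # 121.8 cm/s, 59 cm steps, 35 deg hip range
session, traj = simulate_session(profile, NoiseModel.headings_only(),
                                 n_strides=6, modality="imu", seed=42)

cal = calibrate(session, traj.skeleton, frame0=traj.truth.calibration_frame)
print("recovered heading corrections (deg):")
for name, dev in cal.devices.items():
    print(f"  {name:10s} alpha = {dev.alpha:8.2f}")

series = track(session, cal, traj.skeleton)
worst = max(np.abs(series.euler[b] - traj.eulers[b]).max() for b in traj.eulers)
print(f"\nmax |tracked - commanded| joint angle over all bones/frames: {worst:.2e} deg")
print("despite per-sensor headings spread over the full circle, the tracked")
print("angles match the commanded curves to numerical precision -- the")
print("magnetometer is fully replaced by the calibration pose.")
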