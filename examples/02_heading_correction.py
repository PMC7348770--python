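"""Magnetometer-free heading correction for a single sensor.

Without magnetometers each IMU's fusion frame has an arbitrary heading.
During the static calibration pose, one axis of each sensor is known to be
ground-parallel at a known angle from the pelvis sensor's projected Y axis
(e.g. 90 degrees for a thigh sensor on the outer thigh).  The measured
deviation from that expectation is the heading correction alpha.
"""

import numpy as np

from gaitbox import HeadingAssumption, heading_alpha, heading_rotation
from gaitbox.rotations import yaw_rotation
from gaitbox.simulate import _mount_matrix

# a thigh sensor whose fusion frame is yawed so that its projected Y axis
# measures 83 degrees from the pelvis reference instead of the expected 90
assumption = HeadingAssumption("thigh_R", axis="Y", expected=90.0)
pelvis_reading = _mount_matrix("Y", 0.0, 0.0)
thigh_reading = yaw_rotation(83.0 - 90.0) @ _mount_matrix("Y", 90.0, 20.0)

alpha = heading_alpha(thigh_reading, pelvis_reading, assumption)
print(f"measured 83 deg where 90 deg was expected -> alpha = {alpha:.1f} deg")
print("heading correction matrix (rotation about the vertical axis):")
print(np.array_str(heading_rotation(alpha), precision=4, suppress_small=True))

# the correction recovers an arbitrary injected heading offset exactly
rng = np.random.default_rng(0)
beta = rng.uniform(0, 360)
sensor = yaw_rotation(-beta) @ _mount_matrix("Y", 90.0, -15.0)
recovered = heading_alpha(sensor, pelvis_reading, assumption) % 360
print(f"\ninjected heading offset {beta:.2f} deg -> recovered {recovered:.2f} deg")
print("so a sensor whose magnetometer-free heading is completely random is")
print("re-aligned from the static pose alone.")
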