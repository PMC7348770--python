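{
  "description": "Reference three-marker cluster set of the 15-device full-body optical configuration; marker-to-marker distances in mm and the camera system's mean marker positioning error.",
  "positioning_error_mm": 0.34,
  "rigid_bodies": [
    {"name": "head", "side": null, "d12_mm": 132.2, "d13_mm": 116.0, "d23_mm": 151.4},
    {"name": "upper_arm_R", "side": "R", "d12_mm": 99.0, "d13_mm": 92.1, "d23_mm": 134.0},
    {"name": "upper_arm_L", "side": "L", "d12_mm": 113.7, "d13_mm": 91.6, "d23_mm": 117.1},
    {"name": "forearm_R", "side": "R", "d12_mm": 104.4, "d13_mm": 81.3, "d23_mm": 95.6},
    {"name": "forearm_L", "side": "L", "d12_mm": 116.3, "d13_mm": 75.3, "d23_mm": 85.7},
    {"name": "hand_R", "side": "R", "d12_mm": 128.2, "d13_mm": 69.4, "d23_mm": 146.3},
    {"name": "hand_L", "side": "L", "d12_mm": 70.3, "d13_mm": 120.3, "d23_mm": 135.6},
    {"name": "thorax", "side": null, "d12_mm": 140.1, "d13_mm": 108.7, "d23_mm": 169.9},
    {"name": "pelvis", "side": null, "d12_mm": 180.6, "d13_mm": 105.3, "d23_mm": 163.0},
    {"name": "thigh_R", "side": "R", "d12_mm": 126.2, "d13_mm": 114.8, "d23_mm": 99.6},
    {"name": "thigh_L", "side": "L", "d12_mm": 95.4, "d13_mm": 105.2, "d23_mm": 122.3},
    {"name": "calf_R", "side": "R", "d12_mm": 95.5, "d13_mm": 109.7, "d23_mm": 75.7},
    {"name": "calf_L", "side": "L", "d12_mm": 126.3, "d13_mm": 70.1, "d23_mm": 82.4},
    {"name": "foot_R", "side": "R", "d12_mm": 63.9, "d13_mm": 107.0, "d23_mm": 83.1},
    {"name": "foot_L", "side": "L", "d12_mm": 114.0, "d13_mm": 64.1, "d23_mm": 94.1}
  ]
}
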