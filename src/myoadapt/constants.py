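"""Shared vocabulary of the control problem.

Six hand-motion classes, three sagittal-plane limb poses and three external
loads; the acquisition model is an 8-channel armband sampling EMG at 200 Hz
(8-bit signed) and orientation quaternions at 50 Hz.
"""

MOTIONS: tuple[str, ...] = ("oh", "ch", "wp", "ws", "pg", "r")
"""Hand-motion classes: open hand, closed hand, wrist pronation,
wrist supination, pinch grip, rest."""

ACTIVE_MOTIONS: tuple[str, ...] = ("oh", "ch", "wp", "ws", "pg")

POSES: tuple[int, ...] = (1, 2, 3)
"""Limb poses: 1 — arm hanging (0° summed flexion), 2 — 90° elbow flexion,
3 — 135° shoulder flexion."""

LOADS: tuple[int, ...] = (0, 400, 600)
"""External loads in grams worn on the hand."""

EMG_RATE = 200.0   # Hz
IMU_RATE = 50.0    # Hz
N_CHANNELS = 8
EMG_MIN, EMG_MAX = -128, 127

N_FEATURES = 33    # 4 time-domain features x 8 channels + absolute X Euler angle
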