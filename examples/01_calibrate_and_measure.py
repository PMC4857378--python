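"""Calibrate pixels to centimetres and measure a spinal curvature index.

Four points of known position on the calibration support are marked in
the image; an affine pixel-to-cm map is fitted and applied to three
sagittal landmarks (upper limit vertebra, curve apex, lower limit
vertebra) to compute the cervical curvature index CI = 100 f/x.
"""

from posturekit import (
    CurvatureRegion,
    LandmarkFrame,
    ProtocolConfig,
    fit_calibration,
    measure_frame,
)

# calibration support: a 20 x 40 cm frame imaged at roughly 10 px/cm,
# with a slight camera tilt and the image v axis pointing down
marks = [
    ((102.0, 880.0), (0.0, 0.0)),     # bottom-left corner of the support
    ((301.5, 884.0), (20.0, 0.0)),    # bottom-right
    ((98.0, 478.5), (0.0, 40.0)),     # top-left
    ((298.0, 482.0), (20.0, 40.0)),   # top-right
]
model = fit_calibration(marks)
print(f"fitted {model.family} map from {model.n_marks} marks, "
      f"residual RMS {model.residual_rms:.3f} cm")

# one annotated sagittal frame: C7 and T3 bound the cervical curve, the
# apex sits a few pixels off the chord
frame = LandmarkFrame(
    frame_index=0,
    landmarks={"C7": (210.0, 600.0), "apex": (232.0, 552.0), "T3": (215.0, 500.0)},
)
protocol = ProtocolConfig(
    regions=(CurvatureRegion("cervical_ci", upper_limit="T3", apex="apex",
                             lower_limit="C7"),),
)
result = measure_frame(frame, model, protocol)
print(f"cervical curvature index: {result.values['cervical_ci']:.2f}")
print("(x is the chord between the limit vertebrae in cm, f the apex's")
print(" perpendicular offset; CI = 100 f/x, so ~20 means the apex bulges")
print(" by a fifth of the chord length)")
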