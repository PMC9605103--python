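"""Helical-axis extraction and anatomical decomposition of a rigid motion.

Composes a screw (a rotation about a known spatial line plus a slide
along it), extracts the helical axis back from the resulting rigid
transform, and decomposes the rotation into flexion-extension,
radial-ulnar deviation and pro-/supination angles in a radius-like
frame.
"""

import numpy as np

from wristkin import AnatomicalFrame, decompose_rotation, helical_axis, screw_transform

# a flexion-dominant screw: axis mostly along the radius frame's Y (FE) axis
direction = np.array([0.1, 0.95, 0.25])
direction /= np.linalg.norm(direction)
point = np.array([10.0, 5.0, -3.0])
point -= (point @ direction) * direction  # canonical point on the axis
transform = screw_transform(direction, point, angle_deg=35.0, slide_mm=1.2)

radius_frame = AnatomicalFrame(np.zeros(3), [1, 0, 0], [0, 1, 0], [0, 0, 1])
ha = helical_axis(transform, motion_reference_axis=radius_frame.y_axis)
dec = decompose_rotation(transform.rotation, radius_frame)

print(f"rotation angle about the HA: {ha.angle_deg:8.3f} deg   (input 35.0)")
print(f"translation along the HA:    {ha.translation_along:8.3f} mm    (input 1.2)")
print(f"axis direction:              {np.round(ha.direction, 4)}")
print(f"axis point (p . n = 0):      {np.round(ha.axis_point, 4)} mm")
print()
print(f"decomposed FE / RUD / PS:    {dec.fe_deg:+.2f} / {dec.rud_deg:+.2f} / "
      f"{dec.ps_deg:+.2f} deg")
print()
print("The FE component dominates because the screw axis is nearly the")
print("frame's Y axis; the positive sign means flexion by convention.")
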