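"""Centerline spline, arc length and Frenet slice frames.

Fits the piecewise cubic through hand-picked nodes, measures its length and
places cross-section frames every 1.04 mm, as the segmentation protocol does.
"""

import numpy as np

import vtseg as v

# nodes roughly tracing a vocal-tract-like bend (world mm)
nodes = [[80.0, 60.0, 20.0],
         [70.0, 60.0, 45.0],
         [55.0, 60.0, 62.0],
         [35.0, 60.0, 70.0],
         [15.0, 60.0, 72.0]]
spline = v.fit_spline(nodes)

L = v.arc_length(spline)
frames = v.frames_along(spline, step_mm=1.04)

print(f"centerline length:   {L:7.2f} mm")
print(f"frames at 1.04 mm:   {len(frames)}  (= floor(L/1.04)+1)")

f = frames[len(frames) // 2]
M = np.stack([f.axis_x, f.axis_y, f.axis_z])
print(f"mid-frame origin:    {np.round(f.origin, 2)}")
print(f"orthonormality err:  {np.abs(M @ M.T - np.eye(3)).max():.2e}")
angles = [np.degrees(np.arccos(np.clip(np.dot(a.axis_x, b.axis_x), -1, 1)))
          for a, b in zip(frames, frames[1:])]
print(f"max frame twist:     {max(angles):.2f} deg between adjacent slices")
# Orthonormal frames make each slice transform rigid, so in-plane pixel
# distances are world distances; small twist means the deviation energy can
# compare contours on adjacent slices meaningfully.
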