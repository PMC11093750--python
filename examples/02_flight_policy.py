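"""The corrective flight policy: steering back to a centerline.

Starts an agent 0.3 um off a straight centerline, misaligned by 30 degrees,
and iterates [closed-form corrective steering -> exact parabola step].  The
distance to the centerline should fall below 10% of the initial offset
within three convergence distances of arc length.
"""

import numpy as np

from emflight import FrameState, StepConfig, adaptive_step, complete_frame, \
    fit_bspline, integrate_parabola
from emflight.geometry import FramedCurve
from emflight.tracing import OracleSteerer

nodes = np.stack([np.linspace(0, 30, 12), np.zeros(12), np.zeros(12)], axis=1)
framed = FramedCurve(fit_bspline(nodes, degree=4))

s_c = 0.5  # convergence distance, um
delta = 0.3  # initial offset, um
ang = np.deg2rad(30)
f = complete_frame([np.cos(ang), np.sin(ang), 0.0])
state = FrameState(np.array([5.0, delta, 0.0]), f.t, f.n1, f.n2)

steerer = OracleSteerer(framed, s_c=s_c, kappa_max=None)
cfg = StepConfig(d=0.02)
arc = 0.0
print("arc[um]  offset[um]")
while arc < 3 * s_c:
    steer, _ = steerer.steer(state, None)
    ds = adaptive_step(steer.kappa, cfg)
    state = integrate_parabola(state, steer, ds)
    arc += ds
    if abs((arc / s_c) % 0.5) < ds / s_c:
        off = np.hypot(state.position[1], state.position[2])
        print(f"{arc:7.2f}  {off:9.5f}")

final = np.hypot(state.position[1], state.position[2])
print(f"final offset {final:.5f} um = {100 * final / delta:.2f}% of the initial "
      f"{delta} um (converged: {final < 0.1 * delta})")
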