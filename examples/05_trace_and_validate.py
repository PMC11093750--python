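"""Flight tracing with bidirectional validation.

Uses the analytic flight policy as a steering oracle to (a) trace a 20 um
tube end to end, and (b) show how backward validation rejects a flight that
merged onto a crossing distractor at an X junction.
"""

import numpy as np

from emflight import FrameState, StepConfig, fit_bspline
from emflight.geometry import FramedCurve
from emflight.tracing import (
    OracleSteerer,
    SkeletonTarget,
    StopRules,
    trace,
    validate_bidirectional,
)

STEP = StepConfig(d=0.02, f=2.0)

# (a) straight tube, seeded slightly off-center
nodes = np.stack([np.linspace(0, 22, 12), np.zeros(12), np.zeros(12)], axis=1)
tube = FramedCurve(fit_bspline(nodes, degree=4))
steerer = OracleSteerer(tube, s_c=0.4)
seed = tube.frame_at(0.5)
seed = FrameState(seed.position + 0.05 * seed.n1, seed.t, seed.n1, seed.n2)
target = SkeletonTarget(np.array([[21.5, 0, 0]]), np.array([1]), radius=0.2)
fwd = trace(steerer, None, seed, STEP, StopRules(max_steps=3000, target=target))
print(f"tube flight: {fwd.stop_reason} after {fwd.arc_length:.1f} um, "
      f"max lateral deviation {np.abs(fwd.positions[:, 1:]).max():.3f} um")

seed_target = SkeletonTarget(np.array([[1.0, 0, 0]]), np.array([0]), radius=0.3)
vt = validate_bidirectional(steerer, None, fwd, seed_target, step_cfg=STEP,
                            stop_rules=StopRules(max_steps=3000))
print(f"backward validation on the tube: agreed = {vt.agreed}")

# (b) X junction: the forward flight follows the crossing distractor B
b_nodes = np.stack([
    np.full(12, 5.0) + np.linspace(-5, 5, 12) * 0.3,
    np.linspace(-5, 5, 12), np.zeros(12),
], axis=1)
distractor = FramedCurve(fit_bspline(b_nodes, degree=4))
merged = OracleSteerer(distractor, s_c=0.4)  # simulates a merge onto B
seed_b = distractor.frame_at(0.5)
t_b = SkeletonTarget(distractor.curve.position(
    np.linspace(0.9, 1.0, 5) * distractor.length), np.full(5, 2), radius=0.3)
fwd_b = trace(merged, None, seed_b, STEP, StopRules(max_steps=4000, target=t_b))
seed_on_a = SkeletonTarget(np.array([[1.0, 0.0, 0.0]]), np.array([0]), radius=0.3)
vt_b = validate_bidirectional(merged, None, fwd_b, seed_on_a, step_cfg=STEP,
                              stop_rules=StopRules(max_steps=4000))
print(f"merged flight at the X junction: forward {fwd_b.stop_reason}, "
      f"validation agreed = {vt_b.agreed} (the backward flight returns along "
      f"the distractor, so the connection is rejected)")
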