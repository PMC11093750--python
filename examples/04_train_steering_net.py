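"""Training the steering CNN on policy targets from a synthetic scene.

Samples off-centerline poses with corrective-steering targets, trains the
test-scale network for a short run, and reports the held-out curvature
error.  (A short demonstration run — the test suite trains longer.)
"""

import numpy as np

from emflight import SceneConfig, generate_scene
from emflight.model import TrainConfig, build_and_init, test_scale_config, train
from emflight.policy import PerturbLimits
from emflight.sampling import PatchGeometry
from emflight.workflows import curvature_error, make_training_data

scene = generate_scene(SceneConfig(
    shape=(140, 140, 256), voxel_size_nm=(28, 28, 40), n_neurites=10,
    radius_range=(0.15, 0.28), tortuosity=0.07, varicosity_rate=0.2,
    noise_sigma=0.04, min_separation_factor=2.0,
), seed=11)
lens = np.array([n.length for n in scene.neurites])
held = [int(np.argsort(lens)[-1]), int(np.argsort(lens)[-2])]
train_idx = [i for i in range(len(lens)) if i not in held]

geom = PatchGeometry(shape=(48, 48, 8), p=1.0, z_spacing=0.04375)
limits = PerturbLimits(max_offset=0.16, max_angle=np.deg2rad(20))
patches, states, targets = make_training_data(
    scene, geom, 600, seed=1, neurite_indices=train_idx, limits=limits,
    on_centerline_fraction=0.3, offset_radius_factor=0.4, s_c_floor=0.12,
)
kmag = np.hypot(targets[:, 0], targets[:, 1])
print(f"{len(patches)} samples; median target curvature {np.median(kmag):.2f} 1/um; "
      f"median membrane distance {np.median(targets[:, 2]):.2f} um")

net = build_and_init(test_scale_config(), seed=0)
net, hist = train(net, patches, targets, TrainConfig(
    batch_size=24, max_updates=400, learning_rate=1e-3, lr_final=2e-4, seed=0,
))
print(f"training MSE: {np.mean(hist['mse'][:20]):.3f} -> {np.mean(hist['mse'][-20:]):.3f}")

err = curvature_error(net, scene, geom, held, n_eval=50, seed=2,
                      limits=limits, offset_radius_factor=0.4)
print(f"median held-out curvature error after this short run: {err:.3f} 1/um")
print("(longer training as in the test suite reaches ~0.4 1/um on these scenes)")
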