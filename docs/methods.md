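# Methods

`emflight` traces neurite centerlines through volumetric EM data by
*flight*: an agent carries a pose (position plus an orthonormal frame),
looks at a small neurite-aligned image patch, predicts how the neurite
bends, and advances along that bend. This note describes the model, the
numerical choices, the synthetic data the package is validated on, and the
limits of what those validations show.

## Steering geometry

The agent's frame is a Bishop (rotation-minimizing) frame: tangent **t**
and two normals **n1**, **n2** that never spin about **t**. Its evolution
along arc length *s* is

    dγ/ds = t,   dt/ds = k1 n1 + k2 n2,   dn1/ds = −k1 t,   dn2/ds = −k2 t,

so two signed curvatures (k1, k2) — the steering commands — fully describe
the local bend; κ = √(k1² + k2²). Rotations of (n1, n2) about **t**, and
the flip n2 → −n2, applied jointly to the frame and to (k1, k2), leave the
traced curve unchanged; this invariance is used for training augmentation
(exact quarter-turn/flip index permutations of the patch) and for the
random-rotation inference mode.

Centerlines are degree-4 B-splines (C³), built with SciPy either as exact
interpolants or, for jittery manual annotations, as least-squares fits on
clamped knots with interior-knot refinement. Arc length is tabulated by
per-cell 10-point Gauss–Legendre quadrature (~1e−10 relative) and inverted
with Newton refinement. Frames are transported by the double-reflection
method on a dense internal grid.

Two single-step integrators are provided:

* **Forward Euler + Gram–Schmidt** (order t, n1, n2), first-order.
* **Exact parabola advance**: one steering prediction defines the parabola
  x(σ) = pos + σ t + σ²/2 k. The arc-length equation is solved by Newton to
  1e−12 (closed-form speed integrand, 16-point Gauss), and because the
  parabola is planar the rotation-minimizing normals are transported in
  closed form (the component along the plane normal is conserved). The
  general form `advance_parabola` accepts a curvature vector with a
  tangential component, which is what continuing a *fixed* parabola from a
  non-vertex point requires; the tests use this to verify exact
  composition of half-steps, which forward Euler visibly fails.

Steps are curvature-adaptive: ‖γ̇‖Δt = f·d / (1 + (p/2)κ), with d the
smallest voxel dimension (11.24 nm for the reference voxel size), p = 1 µm
the projection-plane size and f ∈ [1, 5] a throughput factor.

## Flight policy

Training does not imitate on-centerline flight only: the policy maps an
off-centerline, misaligned pose to the steering that minimizes the
predicted future gap ‖Γ + s_c T + (s_c²/2) K‖ at a convergence distance
s_c, giving the closed form

    k̲ = P_{n̲1,n̲2}( (2/s_c²)(Γ + s_c t) + k ).

s_c is set dynamically to the distance to the plasma membrane along the
flight direction (ray marching at ¼ voxel spacing through the trilinearly
interpolated mask), floored at one step length (the closed form diverges as
s_c → 0) and capped at the patch's axial field of view. This makes the
learned behaviour membrane-avoiding. Targets are clipped at κ_max = 2/p =
2 µm⁻¹: tighter turns are unresolvable within the field of view and the
step-size formula already halves steps there. The membrane distance itself
is an auxiliary regression target.

Off-centerline training poses are drawn uniformly in the normal disc
(default up to 0.4–0.8 of the local radius, rejection-sampled into the
mask) and uniformly in a cone about the tangent (default 20–45°). These
magnitudes are free parameters of the method; the defaults cover the
recoverable-state regime the policy is intended for.

## Patch sampling

The network input is a 96 × 96 × 16 block sampled on the frame: in-plane
axes along n1, n2 (plane size p = 1 µm, spacing p/96), third axis along
**t** with the agent at the centre of the fourth plane — more context ahead
than behind, which matters inside varicosities where the exit must be
seen. Samples are trilinear in physical coordinates (voxel centres at
half-integer multiples of the anisotropic voxel size); out-of-bounds
samples take the volume mean (a neutral value that avoids fake dark
edges), and a patch with more than half its samples out of bounds signals
that the flight left the volume. Intensities are normalized per patch to
zero mean and unit variance (ε = 1e−6); the test-scale profile uses
48 × 48 × 8 at the same plane size.

## Steering network

A compact 3D CNN implemented directly in NumPy (im2col convolutions
backed by BLAS matmuls, hand-written backward passes): seven strided 3³
convolutions (widths 24, 32, 48, 64, 96, 128, 128) reducing 96 × 96 × 16
to a single 128-vector, one dropout layer (rate 0.5), three fully
connected layers (96, 64, 48) and a linear 3-output head (k1, k2, membrane
distance). Hidden layers are He-initialized, the head Glorot-initialized;
ELU is the default nonlinearity with ReLU available. The loss is MSE plus
L2 weight decay; curvature targets are scaled by p/2 before the loss so
the three outputs share dynamic range. Adam (default lr 1e−4 full scale,
1e−3 test scale, optional linear decay) and RMSProp-with-momentum are
provided. Training is deterministic under a seed.

Placing the *single* dropout layer after the conv stack is an
architectural constraint, not a convenience: Monte-Carlo-dropout inference
shares all convolutional computation across the M stochastic passes and
repeats only the small head. With the widths above, `count_flops`
(MAC = 2 FLOPs) gives ~0.98% overhead for M = 128 — the architecture is
deliberately shaped so this stays below 2%, and widening the head or
leaving the conv stack spatially unreduced breaks that bound.

`predict` uses weight-scaled dropout expectation; `predict_symmetrized`
averages predictions over the 8 exact rotation/flip symmetries (mapping
curvatures back before averaging), a variance reduction used in
evaluation. Note the weight-scaling expectation differs slightly from the
true MC mean because the head is nonlinear; the MC-convergence test uses a
large-M empirical mean as its reference for exactly this reason.

## Uncertainty, direction selection, validation

Per pose, M = 128 MC-dropout samples of (k1, k2) give the score
u = √(largest eigenvalue of the 2 × 2 covariance) / mean κ — scale
invariant, +∞ when the mean curvature vanishes. For direction selection
(spine heads come with no orientation), I = 256 Fibonacci-sphere
orientations are scored and angularly smoothed with weights
w_ij = ⟨t_i|t_j⟩¹⁶ gated at 30°, normalized over neighbours, and
û_i = u_i/2 + ½ Σ_j ŵ_ij u_j. (Writing u_i instead of u_j inside the sum
would collapse the whole expression to û_i = u_i, since the weights sum to
one — only the neighbour form actually smooths anything.) The best
orientation is the û-minimizer; a second candidate is the û-minimizer
among orientations more than 110° away.

A forward flight that reached another object is validated by flying
backward from the reached point: the return flight must re-enter the seed
object and stay within 0.25 µm of the forward path for ≥80% of its points
(both thresholds are package decisions; the underlying requirement is only
that forward continuations be confirmed backward). Tracing uncertainty
combines directions as min(max-over-steps(forward), max-over-steps
(backward)); corrections are applied up to a percentile of that
distribution, trading split resolution against introduced mergers.

Stop rules for recurrent inference: leaving the volume, reaching a target
object, a step budget, re-entering the own path (self-loop radius defaults
to 0.4 × lag × step so straight flight cannot trigger it), and a
low-confidence stop when the predicted membrane distance stays below one
step length for 5 consecutive steps. Split-resolution flights are
additionally capped at 5 µm of arc length: split gaps are local, and long
wandering flights are far more likely to manufacture mergers than to
resolve genuine splits.

## Evaluation metrics

**Reset-based model selection** runs the tracer along unbranched
ground-truth branches from both ends with two threshold tiers
(experimental: 1.0 µm / 60°; reset: 2.0 µm / 120° — both tiers are free
parameters of the metric; the defaults are package choices and are always
echoed in reports). Beyond the first tier progress is not credited; beyond the
second the state resets to the last good ground-truth point and the reset
counts as two errors (one split + one merge), reported per mm.

**Split/merge evaluation**: fragments map to ground-truth neurites by
nearest-node overlap within 1 µm; split counting is gated to agglomerates
overlapping a neurite by more than 2.5 µm of path (dust suppression), and
splits per neurite = gated agglomerates − 1, floored at zero. Merge errors
are detected geometrically as excursions beyond 2.2 µm from the source
neurite. For link-based agglomerations they are counted per *contact*:
counting per component against a single dominant source overcounts as soon
as legitimate corrections chain two pre-existing merge components — we
observed exactly this failure mode, and the per-contact rule also explains
the 0.5 weighting of pre-existing mergers (each contact is seen from both
of its neurites) versus 1.0 for tracing-introduced mergers (sparse
evaluations cannot see the partner object). Excursions shorter than the
threshold are a documented blind spot. Spine-head attachment reports
recall = correct/attachable and precision = correct/attached, with
manually unattachable heads left unattached counted as true negatives.

## Synthetic scenes

The fixture generator emulates what the method actually relies on:
tubular neurites (radius 0.05–1 µm) as spline-smoothed random walks with
per-point radii, fusiform varicosities (2–3× radius over ~0.5 µm), a dark
~20 nm membrane shell around a bright lumen (0.7 vs 0.2 vs 0.35
extracellular on [0, 1], Gaussian σ = 0.04–0.05 noise — contrast ≫ 3σ so
membrane ray-casting is well posed), anisotropic voxels (default
11.24 × 11.24 × 28 nm³), optional per-section misalignment shifts, and a
spine fixture (0.45 µm trunk, 70 nm neck, 0.22 µm head). Voxels are
assigned to the nearest centerline sample, which makes per-neurite masks
disjoint by construction. Everything is deterministic under a seed.

What the generator does *not* emulate: organelle/texture statistics,
myelin, staining gradients, or real-data artifact morphology. Passing
tests on these scenes validates the geometry, policy, training loop,
inference machinery and metrics — not performance on real tissue.

The toy agglomeration corrupts ground truth constructively: Poisson-placed
cuts (splits) and nearest-neighbour cross-neurite links (mergers), each
recorded, so metric implementations are checked for *exact* agreement with
the induced counts.

## Test-scale profile and known limitations

CPU-scale runs use 48 × 48 × 8 patches, a 4-conv network (8, 16, 24, 32
channels), scenes of ~10 tubes (radius 0.15–0.28 µm, tortuosity 0.07,
σ = 0.04) in ~4 × 4 × 10 µm³ volumes, ~1.8k training samples and ~2k
updates — sizes chosen so a full train-and-evaluate cycle is a
few minutes per seed.

At this scale the network demonstrably learns the steering mapping
(median held-out curvature error ~0.42 µm⁻¹ against a zero-prediction
baseline of ~0.56 µm⁻¹) and, more importantly, supports validated split
resolution with zero introduced mergers on the toy agglomerations. The
residual curvature error is generalization-limited, not
optimization-limited: training MSE continues to fall while held-out error
plateaus, and it is insensitive to dropout rate, axial field-of-view
depth, update count and training-set size within this budget. Gentle
bends are the hard case — at ~20 nm pixels a κ = 0.5 µm⁻¹ bend displaces
the lumen by under a pixel across the patch depth, so precise absolute
curvature recovery on thin, gently curving tubes requires substantially
more training data/compute than the test-scale budget provides. We chose
not to soften the scenes (straighter or fatter tubes would make the
number look better while testing less).

Other limitations: closed curves and C⁰ corners are out of scope; the
evaluation assumes well-separated ground-truth neurites when checking
exact counts; sub-threshold (< 2.2 µm) merge excursions are invisible to
the merge detector by design.
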