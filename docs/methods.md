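# Methods

This note records the models, numerical methods, parameter choices, and
known limitations of `gaitaug`, in the order data flows through the package.

## Planar musculoskeletal model (`gaitaug.msk`)

**Segments and coordinates.** Seven rigid segments — a combined
head-arms-trunk (HAT) segment and a thigh, shank, and single-segment foot
per leg — connected by six sagittal hinge joints. Generalized coordinates
q = [x, y, φ_trunk, hip_R, knee_R, ankle_R, hip_L, knee_L, ankle_L]: the
hip point translates, all angles are counterclockwise-positive and add along
the chain (global X anterior, Y up). Hip flexion is positive, the knee is 0
at full extension with flexion negative, ankle dorsiflexion is positive.
Gyroscope output is the counterclockwise segment rate (the medial-lateral
axis of a right-side-mounted sensor points left, out of the sagittal plane).

**Anthropometric scaling.** Segment masses, lengths, COM offsets, and radii
of gyration come from an embedded standard fraction table (HAT 0.678·BW /
0.288·BH, thigh 0.100·BW / 0.245·BH, shank 0.0465·BW / 0.246·BH, foot
0.0145·BW / 0.152·BH; mass fractions sum to exactly 1, so the model's total
mass is the subject's body weight by construction). Muscle maximum forces
scale with BW/75 kg, muscle and contact geometry with BH/1.75 m.

**Muscles.** Sixteen Hill-type muscles (iliopsoas, glutei, hamstrings,
rectus femoris, vasti, gastrocnemius, soleus, tibialis anterior per leg) act
through constant signed moment arms; musculotendon length is affine in the
joint angles (l_mt = l_ref − Σ r_j q_j). The contractile element has a
Gaussian active force-length curve (width 0.45 l_opt), a smooth monotone
force-velocity factor f_v(v) = 1 + 0.5·tanh 4v + 0.5·tanh 2v saturating at
[0, 2] with v normalized by 10 l_opt/s, a quadratic parallel-elastic force,
and first-order activation dynamics (τ_act 10 ms, τ_deact 40 ms, smoothly
blended). The series tendon is linear in strain (maximum isometric force at
4% strain) with a smooth positive-part engagement so all residuals are
differentiable. Fiber dynamics are posed implicitly as tendon/fiber force
equilibrium — the natural form for collocation. Reference forces, optimal
fiber lengths, and slack lengths are generic adult values exposed in
`msk/params.py`; they are configuration, not fitted quantities.

**Torque-driven mode.** For fast desk-scale work the sixteen muscles can be
replaced by six ideal joint torques (control u dimensionless in ±5, torque =
u · 0.05·BW·g·BH ≈ u·64 N·m for a 75 kg/1.75 m subject; effort = mean
squared u). State dimension drops from 58 to 26. All structural and
dynamical properties except muscle-specific ones hold in both modes.

**Contact.** Two contact points per foot (heel, toe) with two first-order
deformation states each. The vertical deformation tracks the smoothed
penetration depth (time constant 10 ms) and drives a linear spring
(10⁵ N/m·BW/75) with bounded velocity damping — the damping factor lives in
(1−ζ, 1+ζ) with ζ = 0.75, so the vertical force is non-negative whenever
the deformation is (which the dynamics and state bounds maintain). The
horizontal state is a shear spring charged by the contact-point velocity
while loaded and relaxed in flight; its force is saturated by a tanh inside
the friction cone, so |F_x| ≤ μ·F_y holds identically (μ = 1). The
smoothing scales (1 mm penetration, 10 N force regularizer, 0.2 m/s damping
velocity) were chosen for solver conditioning; at those scales a standing
model bears body weight to machine precision.

**Passive joints.** C¹ quadratic hinge moments outside a generous free
range (exactly zero inside it) plus light viscous damping (0.3 N·m·s).

**Verification.** The dynamics are tested against closed-form oracles:
free-fall closes the equations of motion exactly; passive airborne motion
conserves mechanical energy to 10⁻⁵ relative under high-order integration;
static standing supports exactly body weight; the friction cone holds on
random states; and the left-right mirror operator is an involution that
commutes with the full residual.

## Gait-cycle distributions (`gaitaug.sampler`)

Cycle vectors concatenate hip/knee/ankle angles (rad), A-P and vertical GRF
(body-weight units), 100 points each, plus the speed — 501 entries in a
single layout table that assembly, disassembly, and target splitting all
index through. Fitting uses the sample mean and unbiased sample covariance;
with ~30 cycles in 501 dimensions the covariance is rank-deficient, so
sampling goes through an eigendecomposition with negative eigenvalues
clipped at zero and stays in the support subspace. Sampled speeds are
clipped to [0.5, 6] m/s and samples whose peak vertical GRF falls below
0.5 BW are redrawn (normal tails occasionally produce untrackable targets);
rejections are counted. Target variances are floored at 10⁻⁴ × (0.5 rad)²
for angles and 10⁻⁴ × (1 BW)² for GRFs so the tracking weight 1/σ² stays
finite.

Node convention: the collocation nodes k = 1..N sit at times kT/N; the
node-0 state is produced by the symmetry closure. Targets for node k are
therefore read at cycle point k·(50/N) (right leg) and 50 + k·(50/N) (left
leg, wrapping periodically); the quadrature runs over nodes 1..N.

## Tracking optimal control (`gaitaug.ocp`)

**Transcription.** Decision variables are the states and controls at nodes
1..N plus the free half-cycle duration T ∈ [0.2, 0.9] s (N×(58+16)+1 = 3701
variables at the full 50-node muscle-driven profile). Dynamics are imposed
with the Backward Euler rule f(x_k, (x_k−x_{k−1})/h, u_k) = 0; the node-1
block closes the cycle through x_0 = mirror(x_N) − v·T·e_x, making it the
symmetry/periodicity constraint (58 rows). The objective averages the
variance-normalized tracking error over the 10 tracked channels (six joint
angles, four BW-normalized GRFs) and the squared controls
(W_effort = 0.1), plus W_reg = 10⁻⁵ times the time-averaged sum of squared
finite-difference derivatives of all states and controls, each scaled by its
bound range for unit invariance. Residual rows are scaled (forces by BW·g,
torques by 0.1·BW·g·BH) so the feasibility tolerance of 10⁻⁴ is meaningful
across blocks.

**Derivatives.** The Jacobian of the full per-node residual stack is
evaluated by colored finite differences: a Backward-Euler block depends only
on nodes k and k−1 (node 1 additionally on node N and T), so perturbing one
variable index at all even nodes and then at all odd nodes identifies every
entry — 2(n_x+n_u)+1 perturbed points per Jacobian regardless of N, all
evaluated in a single vectorized dynamics call. N is required to be even.

**Solver.** A quadratic-penalty homotopy on the exact least-squares merit
Σ r_obj² + ρ‖c‖² with ρ ∈ {10², 10⁴, 10⁶, 10⁸}: each stage runs a projected
Levenberg-Marquardt iteration on the sparse normal equations (box bounds by
projection), warm-starting the next; if the final stage has not reached
feasibility 10⁻⁴, an SVD-based trust-region least-squares polish finishes
it. Convergence is declared only when the scaled dynamics and symmetry
residuals are within 10⁻⁴ at every node; non-converged problems are flagged
and, in pool generation, redrawn (up to 3 samples) with failure counts
logged. The initial guess reconstructs a full-body motion from the targets
themselves (below), which is essential for reliable convergence.

**Verification.** The module's primary oracle is the self-consistency round
trip: extracting the tracked channels of a converged simulation as new
targets (σ = 2° / 0.05 BW) and re-solving from the standard initial guess
recovers the joint angles to well under 2° RMSE. Restarting a solve from
its own solution never worsens the objective (the solver is budget-limited,
so the first solve need not sit at the exact optimum). Shrinking the target
σ verifiably tightens the achieved tracking.

**Desk vs full profile, and a limitation.** Torque-driven problems at
N = 16–50 solve reliably in seconds to minutes on one CPU; grid refinement
(solve N = 20, interpolate, re-solve N = 50) roughly halves the cost of
fine-grid solutions. The 58-state muscle-driven NLP is implemented and runs
through the same path but stalls above the 10⁻⁴ feasibility target at these
iteration budgets (its stiff tendon-equilibrium rows need an exact-Hessian
interior-point treatment to be economical); `solve_ocp` reports this
honestly as `failed`. All shipped experiments and tests therefore use the
torque-driven mode, which produces the same tracked channels and labels.

## Virtual inertial sensors (`gaitaug.imu`)

Sensor positions are fixed offsets in the segment frame (defaults emulate a
lower-back, lateral thigh/shank, and foot-dorsum placement; per-subject
positions are configuration). Gyroscope output is the chain sum of angular
rates; accelerometer output is the specific force — the second time
derivative of the sensor-point world trajectory minus gravity, rotated into
the segment frame — which automatically contains the tangential and
centripetal terms. Cycles are periodic up to the forward translation, so
derivatives are spectral (FFT) after removing the secular term; the test
suite pins this against an independent refined-grid central-difference
oracle to within 1% of peak (measured: ≲0.1%). In quiet standing every
accelerometer reads (0, +g) and every gyroscope zero, which fixes all sign
conventions observably.

## Kinematic reconstruction and inverse dynamics (`gaitaug.motion`)

To turn bare angle/GRF cycles into full-body motions without an optimal
control solve (for the synthetic benchmark's sensor data and the fast
simulated pool), the trunk translation is integrated spectrally from the
total GRF (both legs, the left shifted half a cycle), which is dynamically
consistent with the forces and yields the familiar pelvis excursions; the
mean hip height is set to 0.97 × leg length and trunk pitch is a small
step-frequency oscillation. Stride time falls linearly with speed (1.45 −
0.25·v s walking, 0.80 − 0.033·v s running, clamped). Net joint moments
follow from inverse dynamics with the measured GRFs applied at a centre of
pressure progressing linearly heel-to-toe over stance. The reconstruction
does not enforce foot-ground contact; its residual root forces are absorbed
by the unactuated trunk, which chiefly perturbs the hip moment (visibly
noisier than the distal moments, as expected for this class of model).

## Convolutional estimator (`gaitaug.cnn`)

Architecture and training exactly as configured by `CNNConfig` defaults:
5×3/64 conv → 2×2 pool → 5×3/128 conv → 2×2 pool → flatten (9600) → dense
100 (ReLU) → dense 100 (linear); Adam at 10⁻³, MSE loss, batch 64, 1000
epochs, L2 10⁻³ on both dense kernels (configurable to final-layer-only),
per-epoch reshuffling, per-channel min-max normalization fitted on the
training pool and reused at test time (constant channels map to 0; test
values may leave [0, 1]). Targets stay in physical units. The implementation
is numpy (im2col convolutions, analytic backprop), deterministic per seed
under a fixed thread configuration; gradients are verified against finite
differences and capacity by 5-cycle overfit tests on all eight variables.
A `CNNConfig.desk()` profile (8/16 filters, fewer epochs) keeps sweep
experiments tractable on one CPU; an optional grid-search routine over the
architecture hyperparameters exists but is not run by default. Neither
dropout nor early stopping is enabled.

## Evaluation (`gaitaug.experiment`, `gaitaug.metrics`)

RMSE is reported in degrees (angles), %BW·BH (moments, error/(BW·g·BH)×100),
and %BW (GRFs); GRFs are scored over stance only, detected as the first
contiguous run of reference vertical GRF ≥ 5% BW (force-plate timing being
unavailable for synthetic data; threshold configurable). Correlations are
averaged via the Fisher z-transform with |r| = 1 clipped under a warning. A
relative-RMSE variant (RMSE / reference range) is provided; its definition
is this package's own. Augmentation ratios are named by the
simulated:measured multiplier {0, 1, 3, 7, 15} (total set 1–16× measured);
simulated cycles are drawn equally per training subject and gait (group
counts differ by ≤ 1), only ever from training subjects, and train/test
subject disjointness is asserted on every run. Pooled metrics combine all
test cycles before averaging over seeds; LOSO CV holds out each training
subject in turn with the same hyperparameters.

**Simulated pools.** `make_simulated_pool` offers the optimal-control path
(dynamically consistent, slow) and a resynthesis path (sampled cycle vectors
→ kinematic reconstruction → inverse-dynamics moments → noise-free virtual
sensors). Both are noise-free, preserving the measured/simulated gap; the
sweep experiments and the augmentation acceptance check use the resynthesis
pool so they fit a single-CPU budget, while the OCP path is exercised at
small counts.

## Synthetic benchmark (`gaitaug.synth`)

The generator emulates the cohort shape of a typical multi-speed gait
protocol: subjects with BW ~ U(55, 95) kg and BH ~ U(1.60, 1.92) m, three
walking bands (0.9–1.0, 1.2–1.4, 1.8–2.0 m/s) and three running bands
(3.1–3.3, 3.9–4.1, 4.7–4.9 m/s), ten trials per band by default. Angle and
GRF cycles come from smooth bump/harmonic templates whose coefficients vary
with speed (walking vertical GRF double-peaked with ~62% stance, running
single-peaked with ~36% stance and an impact bump), modulated per subject
(amplitude, offsets, timing, trunk lean) and per trial (low-order Fourier
perturbations; bounded multiplicative GRF jitter). Every vertical GRF is
non-negative, exactly zero in swing, and rescaled so its full-cycle mean is
0.5 BW per leg — the steady-gait impulse balance. Moments come from inverse
dynamics, sensor channels from the virtual IMU; *measured* cycles then
receive white sensor noise (accelerometer SD 0.3–0.6 m/s², gyroscope
0.03–0.06 rad/s) and a step-frequency soft-tissue artifact (3–7% of channel
peak) — the reality gap that simulated cycles deliberately lack. Everything
is deterministic per seed, down to byte-identical tables.

What passing tests on this benchmark do and do not show: they demonstrate
that the pipeline's mechanics are correct end to end and that the
augmentation *direction* (simulated data reduces joint-angle error when
measured data is scarce) emerges under a controlled reality gap. They say
nothing about error magnitudes on real populations, real soft-tissue
dynamics, sensor mounting variation, or pathological gait — the templates
are deliberately generic and make no claim of matching any cohort.

## Desk-scale profiles used by the shipped checks

The test suite and `scripts/acceptance.py` use: 4–5 subjects × 3 trials per
band; torque-driven tracking at N = 20 (refined to N = 50 for the
full-cycle expansion check); desk CNNs (8/16 filters) with 40 epochs for
sweeps and 500 for capacity checks; 5 seeds and ratios {0, 3} with two
training subjects for the augmentation comparison. These sizes are the
package's reference desk configuration; all of them are ordinary function
arguments, and the full-scale values (1,000 samples per distribution, 50
nodes, muscle-driven dynamics, 64/128 filters, 1,000 epochs, 10 seeds,
ratios up to 15) remain the documented defaults of the corresponding
config objects.
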