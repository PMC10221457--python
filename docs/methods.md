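# Methods

## Problem

Surface EMG (sEMG) of the muscles crossing the knee carries the wearer's
motion intention 30–150 ms before the limb moves, which makes it attractive
as a control signal for wearable robots.  `emgknee` estimates the continuous
knee flexion/extension angle during walking from five muscles — rectus
femoris (RF), vastus medialis (VM), vastus lateralis (VL) and the medial and
lateral gastrocnemii (GM, GL) — recorded at 2000 Hz, with the reference knee
angle derived at 100 Hz from three sagittal-plane markers (A on the thigh,
B at the knee centre, C on the shank).

## Preprocessing chain

Per channel, offline:

1. **Band-pass** 20–500 Hz, 4th-order Butterworth, removing DC offset,
   motion artifact and out-of-band noise.
2. **Full-wave rectification.**
3. **Low-pass** 6 Hz, 4th-order Butterworth — the linear envelope.
4. **Min–max normalization** to [0, 1].
5. **Average feature (AF)**: per non-overlapping window of M = 10 samples,
   `AF = Σ x(j) / ((M−1)·Δt)` with Δt = 1/2000 s.  The AF series (200 Hz) is
   then min–max normalized per channel, restoring the unit interval the
   kernels assume — the `(M−1)Δt` divisor is a fixed linear scale
   (amplitude/second) that min–max normalization makes immaterial.
6. **Knee angle** per frame: `φ = arccos(V_AB·V_BC / (|V_AB||V_BC|))` in
   degrees, with the cosine clamped to [−1, 1] against round-off.  0° means
   thigh and shank collinear.
7. **Gait-cycle segmentation** at prominent knee-angle minima (heel-strike
   proxy): peaks of the negated angle with prominence ≥ 5° and minimum
   spacing `min_cycle_s` = 0.8 s.  Trace endpoints are eligible boundaries,
   so bouts that begin/end at heel strike keep their edge cycles; data
   before the first and after the last detected boundary (transition phases)
   are dropped.  Explicit boundary lists are accepted as an alternative.
8. **Time normalization**: each cycle is linearly interpolated onto 100
   equally spaced phase points; AF features are interpolated onto the same
   phase instants from their window-centre timestamps.

All Butterworth stages run forward–backward (zero phase), appropriate for
offline analysis; this doubles the effective order.  Zero-phase filtering
lets the envelope undershoot zero slightly, so it is clipped at 0 before
normalization (envelopes are physically non-negative).

Choices the acquisition description leaves open, all config-exposed
(`PreprocessConfig`): normalization scope is per channel over the whole
recording (preserving relative effort across cycles; per-cycle is
available), AF windows do not overlap (stride = M, the simplest reading of
"sliding windows" combined with resampling), and the low-pass default is
6 Hz within the quoted 5–10 Hz band.

The model input at each phase point is the 5-vector of normalized AF values
— one per muscle, no phase index — and the target is the knee angle in
degrees.

## Multiple-kernel relevance vector regression

The regression model is `t = y(x) + ξ`, ξ ~ N(0, σ² = 1/β), with

    y(x) = Σ_u w_u K(x, x_u) + w_0

over kernel basis functions centred on the training inputs.  The kernel is a
fixed convex combination

    K_MK = 0.8·exp(−γ₁‖x−z‖²) + 0.17·(γ₂ xᵀz + c)^d + 0.03·tanh(γ₃ xᵀz + c)

with γ₁ = 0.01, γ₂ = γ₃ = 0.005, c = 0.01, d = 0.02.  The polynomial
"degree" d is a real exponent, evaluated as a real power with a positivity
guard on its base; with unit-interval features and positive γ, c the base is
always positive.  The sigmoid kernel (hence the mixture) is not positive
semidefinite; none of the machinery below requires PSD kernels, since the
kernel only generates basis functions of a linear-in-parameters model.  The
published parameter table lists the two γ values without assignment; the
Gaussian kernel dominates the mixture, so it receives 0.01.  A single shared
c and d are used.  Kernel weights are fixed, not learned.

Each weight carries its own prior precision α_u (automatic relevance
determination).  Hyperparameters are estimated by type-II maximum
likelihood with the classic full evidence-maximisation re-estimates
(posterior `Σ = (A + βΦᵀΦ)⁻¹`, `μ = βΣΦᵀt`; `γ_u = 1 − α_u Σ_uu`;
`α_u ← γ_u/μ_u²`; `β ← (N − Σγ_u)/‖t − Φμ‖²`), iterated until
max |Δ log α| < 10⁻³.  Bases whose α exceeds 10⁹ are pruned; the bias is
never pruned; if everything else is pruned the model degenerates to a
flagged bias-only predictor.  The full (non-sequential) scheme was chosen
over the fast sequential variant for transparency and determinism: given
identical inputs and config the fit is bit-reproducible.  Defaults:
α₀ = 10⁻³, β₀ = 10/Var(t), jitter 10⁻¹⁰ on the posterior system.  The
iteration cap is 10⁴: the log-α drift of surviving bases converges slowly,
but iterations become cheap (a few ms) once pruning has collapsed the basis,
so a generous cap costs little and lets sparsity patterns stabilise.

Prediction returns the posterior mean and the predictive variance
`1/β + φ(x)ᵀΣφ(x)`.  Targets are fitted in degrees without centering; the
bias absorbs the mean.  The log marginal likelihood is available as a
convergence diagnostic and is cross-checked in the tests against a dense
N×N covariance construction.

## LS-SVR baseline

Least-squares SVR with the same multi-kernel (fair-comparison default) and
regularization constant `reg_gamma` = 100 (the study reports no value; 100
is a conventional mid-range choice, config-exposed).  Training solves the
(N+1)×(N+1) saddle system `[[0, 1ᵀ], [1, K + I/γ]]·[b; a] = [0; t]` exactly;
prediction is `Σ aᵢ k(x, xᵢ) + b`.  All N coefficients are generically
nonzero — the sparsity contrast with the RVM is asserted in the tests.

## Metrics and the sample-size experiment

MAE = mean |ŷ−y|, RMSE = √(mean (y−ŷ)²), R² = 1 − SS_res/SS_tot, computed
per phase-point sample pooled over all held-out cycles ("continuous global"
scores).  RMSE ≥ MAE always.  R² requires non-constant targets and is 1 for
perfect prediction, 0 at the mean prediction, negative below it.

The sweep protocol: per random seed, hold out a fixed set of 10 cycles, then
train on nested subsets of 1, 5, 10, …, 60 cycles (13 sizes) drawn from one
shuffled order, so size effects are not confounded by resampling.  Training
sets are phase-subsampled to at most 1000 points per fit (every point up to
10 cycles, every 2nd up to 20, and so on); evaluation always uses all 100
phase points of every held-out cycle.  The cap bounds the cubic cost of the
dense Bayesian solve while keeping the small-sample fits at full resolution;
`train_phase_stride` overrides it.  The benchmark bout is simulated with 72
cycles so that 60 training plus 10 held-out cycles are available (subjects
in the motivating protocol supplied 63–82 cycles, of which 60 were used).

"Error decreases with sample size" is checked on medians across seeds as a
non-positive Spearman rank trend over the 10–60-cycle range together with
median(60 GCs) ≤ median(10 GCs); consecutive medians in the converged regime
differ by ~0.01°, so strict step-by-step monotonicity would test noise, not
the trend.

## Synthetic gait generator

Real recordings of this kind are not redistributable, so a seeded simulator
provides statistically similar data with ground truth:

* **Cycle lengths** (angle samples at 100 Hz) ~ N(126, 7²) truncated at
  ±3 SD — spanning the 122–131 per-cycle sample counts reported across
  subjects; per-subject presets S1–S5 use the reported means/SDs.
* **Activations**: smooth periodic von-Mises-style bumps, one per muscle —
  vasti in early stance (peaks at 7% and 17% of the cycle), gastrocnemii
  around push-off (40%, 52%), RF biphasic with a small loading-response
  lobe (10%) and a dominant swing-control lobe (72%) — plus a 0.02 tonic
  baseline, all within [0, 1].
* **Angle**: a fixed torque-like blend of the activations — linear weights
  (80, 0, 14.1, 6.7, 7.5)° per unit activation, intercept 0.8°, plus a
  small VM·VL co-contraction product (gain 6°) — yielding the classic
  two-peaked knee curve (~21° loading-response flexion, ~60° swing flexion,
  global minimum ≈ 5° at heel strike, range well inside 0–75°).  Tying the
  angle to the activations by construction makes the activation→angle
  regression well-posed: a model family that can represent an approximately
  linear map of the five envelopes can recover the angle, which mirrors the
  physiological premise that activations drive joint torque roughly
  proportionally.  Gaussian angle noise (default SD 1°) is added on top of
  the clean profile.
* **Raw sEMG**: the activation (evaluated at 2000 Hz) amplitude-modulates a
  unit-variance 20–450 Hz band-limited noise carrier; white sensor noise is
  added at a configurable SNR (default 20 dB).  Rectifying and low-passing
  the result recovers the driving activation (Pearson r ≥ 0.9 per channel
  at 20 dB).
* **Markers**: A, B, C form a rigid thigh/shank hinge (400 mm segments) in
  the sagittal plane; B drifts forward at walking speed, the thigh hangs
  vertically and the shank is rotated by the knee angle, so the recovered
  marker angle equals the input exactly before coordinate noise (default
  0.3 mm per axis, ≈ 0.04° of angle error).

Everything is deterministic per seed; sub-streams (EMG carrier, marker
noise) derive child seeds from the master seed.

### What the simulator does not emulate

Motor-unit physiology, electrode crosstalk and electromechanical delay;
inter-subject variability in muscle timing; non-sagittal knee motion; soft
tissue artifact on the markers; gait-speed and stride-length effects.  The
activation→angle mapping is stationary and noise is Gaussian.  Passing
tests therefore demonstrate that the pipeline and models are implemented
correctly and behave as expected on data with the stated statistical
structure, not that the accuracy figures transfer to human recordings —
on the synthetic benchmark the held-out errors (MAE ≈ 1.5°, R² ≈ 0.98) are
better than published human results, as expected for a cleaner, stationary
problem.

## Numerical choices and degenerate inputs

* Cutoffs are validated against Nyquist; constant series are rejected by
  min–max normalization; coincident markers raise a degenerate-geometry
  error; NaNs are rejected before segmentation; fewer than one complete
  cycle raises an empty-dataset error.
* The arccos argument is clamped to [−1, 1]; precisions are capped at 10¹²
  before the prune comparison; β is clipped to [10⁻¹², 10¹²]; the posterior
  Cholesky carries a 10⁻¹⁰ jitter.
* Ties in peak finding follow the deterministic behaviour of the underlying
  peak detector; segmentation is therefore reproducible.

## Known limitations

MacKay-style updates converge slowly in log-α near the pruning boundary, so
relevance-vector counts can vary by a few vectors with the iteration cap;
the fast sequential algorithm would be quicker for N ≫ 10³ but less
transparent.  The multi-kernel with the published parameters is nearly
linear over unit-interval features (γ‖x−z‖² ≤ 0.05), which limits how much
nonlinearity the regressor can express; this matches the published
configuration and is deliberately not "fixed".  The LS-SVR baseline uses a
fixed regularization constant rather than cross-validation, mirroring the
fixed-hyperparameter comparison it reproduces.
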