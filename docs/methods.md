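# Methods

This note documents the models and procedures the package implements, the
design choices behind them, and what the synthetic benchmark does and does
not demonstrate.

## Problem setting

A single animal is tracked from a hovering observer. A detector provides a
2D bounding box per video frame; a stereo camera provides per-pixel depth.
The localization geometry turns each detection into a 3D world-frame
position measurement; a temporal regularizer then fuses the noisy
per-frame measurements into a smooth trajectory estimate. The package
implements the regularizer as a learned Kalman filter and benchmarks it
against classical alternatives on synthetic trajectories.

## 3D localization from detections

For a box with center `(cx, cy)` and size `(w, h)`, an interior rectangle
scaled by `theta` about the center (default `theta = 0.5`) selects the
depth pixels averaged into the target range `S`; the interior rectangle
avoids the background pixels that contaminate box edges, and the valid
mask excludes unfilled stereo pixels. The box center back-projects through
the pinhole model, `X_C = K^-1 (S [cx, cy, 1]^T)`, and the camera-frame
point is carried to the world frame by the fixed camera-to-body transform
(optical axis to body-forward) composed with the observer's body-to-world
pose. Pixel convention: origin top-left, `u` rightward, `v` downward; the
ROI is rasterized half-open over pixel centers. Rotations are accepted as
matrices or unit quaternions (wxyz, normalized on ingest). A contracted
ROI with no valid depth raises an error at the geometry API; the tracking
layer treats that frame as a missing measurement.

## The learned filter

State-space model with identity observation map:

    y_t = f(y_{t-1}) + w_t,   w_t ~ N(0, Q_t)
    z_t = y_t + v_t,          v_t ~ N(0, R_t)

Three recurrent modules predict the filter internals each frame: `LSTM_f`
(stacked LSTM + fully connected stack, ReLU on all FC activations except
the last) emits the transition prediction y'_t; `LSTM_Q` and `LSTM_R`
(single-layer LSTMs with exponential output heads) emit strictly positive
diagonal covariances. The extended-KF recursion then runs with F the
Jacobian of f at the previous posterior:

    P'_t = F P_{t-1} F^T + Q_t
    K_t  = P'_t (P'_t + R_t)^-1
    y_t  = y'_t + K_t (z_t - y'_t),   P_t = (I - K_t) P'_t

Frames without a measurement return the prior unchanged. The loss

    L = (1/T) sum_t ( ||y_t - y^_t||_2 + lambda ||y_t - y'_t||_2 )

uses unsquared Euclidean norms (a squared variant is available by config);
the second term feeds gradient directly to the transition module
(`lambda = 1` by default). Everything — gain, covariances, Jacobian — sits
on the package's autodiff tape, so training is end-to-end backpropagation
through the filter.

Numerical choices: covariance diagonals are `exp` of the raw head outputs,
clamped to `[1e-8, 1e8]`; the posterior covariance is symmetrized as
`(P + P^T)/2` each update; `P_0 = p0 * I` with `p0` from config; the
belief initializes at the first measurement. The Jacobian is assembled
analytically from the gate values (chain rule through the cell), which
keeps it differentiable and matches central finite differences to 1e-4
relative; note the linearization is discontinuous exactly on ReLU kinks,
so gradient checks are run at generic parameter points.

### Input representation (delta features)

The plain formulation feeds the modules the raw previous posterior
ŷ_{t-1} (and z_t). With absolute coordinates a trained transition
memorizes *where* the training animals were and degrades sharply on
held-out trajectories — the package's benchmark profile therefore uses a
translation-invariant representation (`delta_features = True`):

* `LSTM_f` consumes the standardized previous displacement
  ŷ_{t-1} − ŷ_{t-2} together with exponential-moving-average displacement
  features at several timescales (alphas 0.3 / 0.1 / 0.05), and predicts
  the next displacement in the same standardized units, added onto
  ŷ_{t-1}. A learnable *direct* linear connection from the input features
  to the output (the modified-output idea — skip weights from inputs to
  outputs) is initialized to read out the slowest EMA block, so the
  untrained transition already performs smoothed constant-velocity
  extrapolation and training refines it. Velocity extrapolation thus
  reduces to a near-linear readout of the slow EMA, which gradient
  descent finds quickly; learning the equivalent slow integration from
  scratch inside the recurrence is far harder (we measured a freshly
  trained unstructured recurrence to be no better than the identity
  transition). The EMA timescale was chosen by one-step displacement-
  prediction error on the *training* split, where the alpha = 0.05 EMA of
  filtered increments extrapolates better than a constant-velocity
  filter's own velocity state.
* `LSTM_Q` consumes the standardized predicted displacement plus the same
  EMA features (they carry the motion-regime signal).
* `LSTM_R` consumes the standardized measurement innovation
  z_t − z_{last}, its absolute value, and EMA magnitude features — running
  statistics of the local noise level, the sufficient statistic that lets
  the module track a time-varying sigma.

The EMA features are differentiable state carried in the filter, so the
end-to-end gradient remains exact. The Jacobian accounts for the current-
frame dependence of the features on ŷ_{t-1} (previous EMA values held
fixed, the same convention used for the recurrent state). The covariance
heads are anchored by method-of-moments output scales estimated from
training data: `(var(dz) - var(dy))/2` for R (the excess of measurement-
increment variance over state-increment variance estimates the average
noise variance) and `var(dy)` for Q; the heads then learn multiplicative,
context-dependent corrections. With an unfitted scaler both anchors are 1
and the transform reduces to a plain exponential.

The plain input convention (absolute coordinates, simple
standardization) remains available as the default configuration
(`delta_features = False`) and is what the reduction and gradient-check
tests exercise alongside the delta mode.

## Classical baselines

Constant-velocity and constant-acceleration Kalman filters use the
standard kinematic discretization with white-noise-acceleration process
covariance and position-only observation; an exponential moving average
(`alpha = 0.3`) and the raw measurements (last value held through gaps)
complete the comparison suite, together with a plain single-layer LSTM
(16 hidden units) regressing z_t to y_t directly. Baseline constants for
the benchmark are declared, not fitted: `dt = 1/30 s`, acceleration noise
intensity `q = 1.0 m^2/s^3`, measurement variance `r = 0.2 m^2` (the
generator's nominal mid-scale noise). Filters initialize from the first
measurement with zero derived state and a large (1e4) variance on
unobserved blocks; missing measurements skip the update.

## Optimizer

Training uses the infinity-norm variant of Adam: the second-moment
accumulator generalizes from the L^2 norm to the L^p norm, and the limit
p -> infinity collapses to `v_t = max(beta2 * v_{t-1}, |g_t|)` with
`v_0 = 0` and no initialization-bias correction. The finite-p recursion
`v_t = beta2^p v_{t-1} + (1 - beta2^p) |g_t|^p` is implemented alongside
and overflow at large p is surfaced as an explicit numeric-range error.
The first moment uses the standard beta1 exponential average with bias
correction (the infinity-norm derivation constrains only the second
moment), and the step is `theta <- theta - alpha * m_hat / (v + eps)` with
`eps = 1e-8`. Defaults: `beta1 = 0.9`, `beta2 = 0.999`. Non-finite
gradients skip the affected parameter's update for that step.

## Training protocol

Truncated backpropagation through time: sequences are cut into windows
(reference protocol: 100 steps; the plain-LSTM baseline: 10 steps, batch
2, lr 5e-4, 120 epochs), the recurrent state and belief carry across
windows, the tape is cut at boundaries, and one optimizer step is taken
per window. The learning rate decays by 0.95 per epoch from the second
epoch. Gradients are clipped to global norm 10. "Period" in the reference
protocol is read as epoch. Checkpoints serialize parameters, optimizer
state and generator state for bit-exact resume.

The desk-scale profile used by the benchmark and tests (chosen for
single-CPU training): transition module 2 LSTM layers x 64 hidden + FC
64/out, noise modules 32 hidden, no dropout, lr0 5e-3, up to 25 epochs,
batch 1, TBPTT 100. Validation (the held-out split) is scored every epoch
by posterior RMSE; training stops after 8 epochs without improvement and
the best-validation weights are restored — through-the-filter training
overfits the transition module after roughly ten epochs on six sequences,
and the validation-selected model is the one the comparison table
reports.
The full-scale profile (3 x 1024 + 1024/1024/48, 256-unit noise modules,
dropout retention 0.7, lr 2e-5) is available as a named configuration;
training it is a GPU-scale exercise and is not exercised by the tests.
Teacher forcing (feeding the true previous state to the transition module
during training) is implemented behind a flag but off by default: it
creates a train/inference mismatch through the filter feedback loop that
we observed to be destabilizing.

## Synthetic benchmark

The generator replaces field footage while keeping the statistical
structure the method targets:

* **Trajectories** — smooth 2nd-order kinematics switching between
  behavioral regimes (standing: up to 0.005 m/s; walking 0.5-1.5 m/s;
  running 3-8 m/s; dwell 5-20 s). Schedules visit the regimes in shuffled
  round-robin order so every sequence exhibits all three. Within a regime
  the turn rate and speed are bounded random Fourier functions of
  continuous time; the heading integrates the turn rate (midpoint rule),
  so halving dt refines the same path. Height follows a small smooth bob.
* **Measurements** — z_t = y_t + N(0, sigma_t^2 I) with a piecewise-
  constant sigma schedule (six 10 s segments per 60 s sequence, a shuffled
  permutation of 0.05/0.1/0.2/0.4/0.6/0.8 m), 1% outlier frames with noise
  scaled 5x, and 2% dropout frames with no measurement (frame 0 always
  measured). Every sequence is a pure function of its seed.
* **Detection streams** — true positions projected into pixel boxes with
  Gaussian jitter plus constant-depth patches with invalid holes, to
  exercise the localization geometry end to end.

Defaults: 6 sequences of 60 s at 30 Hz, split 3:2:1 into
train/test/validation. Evaluation reports per-regime and overall
translation RMSE (and MAE), in meters or millimeters.

What the benchmark does *not* emulate: detector-dependent, state-dependent
measurement error (box quality varies with pose and range), multi-animal
occlusion, camera egomotion during tracking, rolling-shutter and
calibration artifacts, terrain. Passing here shows the estimator exploits
smooth motion and heteroscedastic noise as designed, not that it meets
field accuracy.

## Known limitations

* The tracked state is position-only; the filter's velocity knowledge
  lives in the recurrent modules and EMA features rather than in the
  belief covariance, so the reported P underestimates extrapolation
  uncertainty during long dropouts.
* The learned transition generalizes across trajectories only in delta
  mode; the absolute-coordinate mode is the plain
  formulation but overfits small datasets.
* Outlier robustness is learned (via the R module's innovation-magnitude
  features), not guaranteed; a gross outlier early in a sequence, before
  the EMA statistics settle, can still perturb the estimate.
* The grid-based Bayes oracle used in the tests is scalar; matrix-variate
  agreement is checked against an independently coded textbook filter
  instead.
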