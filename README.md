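# lstmkf — learned Kalman filtering for 3D wildlife trajectory tracking

Tracking an animal from a hovering observer yields one noisy 3D position
measurement per video frame: a detector's bounding box fused with stereo
depth. Classical temporal regularization — a Kalman filter with
hand-specified motion and noise models — lags behind fast gaits and
cannot react when the measurement noise changes with range, pose or
lighting. This package implements a *learned* Kalman filter (LSTM-KF) in
which three recurrent modules predict the filter's internals each frame,
trained end to end by backpropagation through the filter, together with
everything needed to evaluate it: the detection-to-3D localization
geometry, classical baselines, an infinity-norm Adam optimizer, and a
synthetic trajectory benchmark. It is aimed at researchers building
aerial wildlife-monitoring pipelines and, more generally, anyone studying
learned state estimation.

## The model

State-space model with identity observation map:

    y_t = f(y_{t-1}) + w_t,   w_t ~ N(0, Q_t)
    z_t = y_t + v_t,          v_t ~ N(0, R_t)

Per frame, `LSTM_f` predicts the transition y'_t = f(ŷ_{t-1}), and
`LSTM_Q` / `LSTM_R` emit positive diagonal covariances Q̂_t, R̂_t. The
extended-KF recursion fuses them:

    P'_t = F P_{t-1} Fᵀ + Q̂_t            (F = ∂f/∂ŷ_{t-1})
    K_t  = P'_t (P'_t + R̂_t)⁻¹
    ŷ_t  = y'_t + K_t (z_t − y'_t)        P_t = (I − K_t) P'_t

with loss `L = (1/T) Σ_t ‖y_t − ŷ_t‖₂ + λ‖y_t − y'_t‖₂`. Gradients flow
through the gain, the covariances and the Jacobian — the package carries
its own reverse-mode autodiff tape, and F is assembled analytically from
the LSTM gate values so it stays differentiable. Training uses the
infinity-norm Adam variant (`v_t = max(β₂ v_{t-1}, |g_t|)`, the stable
p→∞ limit of L^p-norm Adam) under truncated backpropagation through time.

Localization geometry: a detection box is contracted by θ about its
center, valid depths inside are averaged to a range S, the center
back-projects as `X_C = K⁻¹ (S·[u, v, 1]ᵀ)`, and the fixed
camera-to-body transform composed with the observer pose carries X_C to
world coordinates.

## A worked example

`examples/simulate_and_filter.py` generates a 30 s synthetic track
(standing/walking/running regimes, time-varying measurement noise,
dropouts) and filters it classically:

    901 frames, regimes: ['running', 'standing', 'walking'], 21 dropout frames
    raw measurements       position RMSE 0.489 m
    constant-velocity KF   position RMSE 0.182 m
    EMA smoother           position RMSE 0.242 m

The filters cut the raw measurement error by two thirds; the learned
filter's gain over them comes from adapting Q̂/R̂ to regime and noise
level. `examples/compare_table.py` runs the full protocol — train the
LSTM-KF and the plain-LSTM baseline on 3 sequences, evaluate on 2 held
out — and prints the comparison table (values in mm, seed 1):

                standing   walking   running      mean
    raw            598.3     352.5     555.5     503.0
    kalman_vel     208.1     131.8     204.1     182.7
    kalman_acc     210.0     148.2     215.0     192.9
    ema            254.4     162.0     350.2     277.7
    std_lstm     24420.8   32461.6   24350.4   27510.4
    lstm_kf        166.4     107.9     196.4     164.0

    predicted R-diagonal vs true noise variance across 12 segments:
    Spearman rho = 0.99

The learned filter beats every fixed-parameter baseline; the plain LSTM
regressor, which must memorize trajectories from scarce data, is far
worse than doing nothing — the failure mode that motivates keeping the
filter structure and learning only its internals. The Spearman line shows
the measurement-noise module has genuinely recovered the time-varying
sensor noise. Other entry points: `examples/localize_from_detections.py`
(geometry), `examples/train_lstm_kf.py` (a short training run),
`examples/adamax_on_quadratic.py` (the optimizer), and the `lstmkf` CLI
(`simulate`, `train`, `track`, `evaluate`, `compare`, `localize`).

## Layout

    src/lstmkf/
      autodiff.py    reverse-mode tape (Tensor, backward, matrix inverse, ...)
      geometry.py    box + depth -> world-frame position
      kalman.py      classical KF, CV/CA models, EMA, filter runner
      cells.py       LSTM cell, modified output connection, stacking
      model.py       the LSTM-KF (modules, filter step, loss, checkpoints)
      optim.py       infinity-norm Adam (AdaMax family)
      train.py       TBPTT loop, schedules, plain-LSTM baseline, checkpointing
      benchmark.py   trajectory/measurement/detection generators, metrics,
                     method comparison
      io.py, cli.py  CSV/YAML/NPZ formats and the command-line surface

`docs/methods.md` documents the model, the design decisions (input
representation, covariance anchoring, training protocol) and what the
synthetic benchmark does and does not demonstrate.
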