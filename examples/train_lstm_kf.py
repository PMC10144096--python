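"""Train a small LSTM-KF and watch it reduce to — then beat — a fixed filter.

Trains the learned filter for a few epochs on three synthetic sequences
and prints the loss history plus the RMSE against an untrained identity-
transition filter on a held-out sequence.  A short run for illustration;
`compare_table.py` runs the full benchmark protocol.
"""

import numpy as np

from lstmkf.benchmark import DESK_MODEL_CONFIG, rmse, simulate_sequence
from lstmkf.model import LSTMKF
from lstmkf.optim import AdaMax
from lstmkf.train import TrainConfig, tbptt_train

train_seqs = [simulate_sequence(seed, duration=20.0, rate=30.0)
              for seed in (0, 10, 20)]
test_seq = simulate_sequence(99, duration=20.0, rate=30.0)
pairs = [(s.positions, s.measurements) for s in train_seqs]

model = LSTMKF(DESK_MODEL_CONFIG, seed=0)
model.fit_input_scaler([t for t, _ in pairs], measurements=[z for _, z in pairs])

before = model.run(list(test_seq.measurements))["means"]
cfg = TrainConfig(lr0=5e-3, tbptt_window=100, epochs=5, seed=0)
history = tbptt_train(model, pairs, cfg, optimizer=AdaMax(alpha=cfg.lr0),
                      rng=np.random.default_rng(0))
after = model.run(list(test_seq.measurements))["means"]

print("epoch losses:", " ".join(f"{h:.4f}" for h in history))
print(f"held-out RMSE before training: {rmse(test_seq.positions[1:], before[1:]):.3f} m")
print(f"held-out RMSE after  training: {rmse(test_seq.positions[1:], after[1:]):.3f} m")
print("(training reshapes the transition and noise modules; the filter now"
      " smooths adaptively instead of trusting its initialization)")
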