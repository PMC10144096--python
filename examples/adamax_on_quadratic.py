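"""The infinity-norm Adam optimizer on a convex quadratic.

Minimizes 0.5 x^T A x and prints the loss trace, plus a check of the
identity between the recursive accumulator v_t = max(beta2 v_{t-1}, |g_t|)
and its closed-form decayed maximum — the property that makes the
p -> infinity limit of L^p-norm Adam cheap and stable.
"""

import numpy as np

from lstmkf.optim import AdaMax, expanded_v_inf, update_v_inf

rng = np.random.default_rng(0)
L = rng.standard_normal((6, 6))
A = L @ L.T + 0.5 * np.eye(6)
x = rng.standard_normal(6) * 3

opt = AdaMax(alpha=0.05)
for k in range(501):
    if k % 100 == 0:
        print(f"step {k:4d}  loss {0.5 * x @ A @ x:.6f}")
    x = opt.apply_update({"x": x}, {"x": A @ x})["x"]

grads = rng.standard_normal(32)
v = 0.0
for g in grads:
    v = float(update_v_inf(v, g, beta2=0.99))
closed = float(expanded_v_inf(list(grads), beta2=0.99))
print(f"recursive accumulator {v:.12f} == decayed max {closed:.12f}: "
      f"{abs(v - closed) < 1e-12}")
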