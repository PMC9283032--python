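"""The math core: a bilinear interaction node and the soft-attention gate.

Builds a small bilinear node, shows that the efficient ||Fx||^2 evaluation
equals the explicit double-sum over column inner products, and runs the
attention gate, checking that the gated vector sums to the scalar
attention-pooled feature.
"""

import numpy as np

import tissuegrid as tg

rng = np.random.default_rng(0)

# A bilinear node over a 6-dimensional feature with k=3 interaction factors.
p = tg.BilinearNodeParams.random(n=6, k=3, rng=rng)
x = rng.normal(size=6)

fast = tg.bilinear_response(x, p)           # b + w'x + ||Fx||^2, O(nk)
slow = tg.bilinear_response_bruteforce(x, p)  # double sum over <f_i, f_j>, O(n^2 k)
linear = tg.linear_response(x, p.linear_weight, p.bias)

print(f"bilinear response (efficient):  {fast:+.10f}")
print(f"bilinear response (double sum): {slow:+.10f}")
print(f"linear part only:               {linear:+.10f}")
print(f"interaction term (always >= 0): {fast - linear:+.10f}")
# The two evaluations are the same polynomial; the gap is float rounding.

# Soft attention over a feature vector f with learnable weight w.
f, w = rng.normal(size=5), rng.normal(size=5)
state = tg.attention_state(f, w)
gated = tg.attention_gate(f, w)
print(f"\nattention weights a = {np.round(state.attn, 4)} (sum {state.attn.sum():.6f})")
print(f"pooled scalar c     = {state.pooled:+.6f}")
print(f"sum of gated vector = {gated.sum():+.6f}")
# a is a softmax (positive, sums to 1); the gated vector r = a*f preserves
# dimensionality for the classifier head while conserving sum(r) = c.
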