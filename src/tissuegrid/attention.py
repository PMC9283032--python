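"""Soft attention over a feature vector.

Given a feature vector f and a learnable weight vector w of the same length,
per-element scores e_i = w_i * f_i are softmax-normalized into attention
weights a (positive, summing to 1).  Two read-outs are provided:

* ``attention_pool`` — the scalar c = sum_i a_i f_i (attention-weighted sum);
* ``attention_gate`` — the gated vector r = a ⊙ f, which preserves
  dimensionality so the result can feed a classification head.  By
  construction sum(r) == attention_pool(a, f).

The sum of the per-element scores equals the scalar score sum_i w_i f_i, so
exposing e elementwise is consistent with both the scalar and the indexed
reading of the score.
"""

from __future__ import annotations

import numpy as np

from .bilinear import _as_finite_vector

__all__ = [
    "AttentionState",
    "attention_scores",
    "attention_weights",
    "attention_pool",
    "attention_gate",
    "attention_state",
]

from dataclasses import dataclass


@dataclass
class AttentionState:
    """Full bookkeeping of one attention application: the learnable weight,
    the raw scores e, the normalized weights a, and the pooled scalar c."""

    weight: np.ndarray
    scores: np.ndarray
    attn: np.ndarray
    pooled: float


def attention_scores(f, weight) -> np.ndarray:
    """Per-element scores e_i = weight_i * f_i (their sum is the scalar score)."""
    f = _as_finite_vector(f, "f")
    weight = _as_finite_vector(weight, "weight")
    if f.shape != weight.shape:
        raise ValueError(f"length mismatch: f has {f.size}, weight has {weight.size}")
    return weight * f


def attention_weights(e) -> np.ndarray:
    """Softmax of the scores, stabilized by max-subtraction.

    Output entries are in (0, 1) and sum to 1; invariant to adding a
    constant to every score.
    """
    e = np.asarray(e, dtype=float)
    if e.ndim != 1 or e.size < 1:
        raise ValueError("scores must be a non-empty 1-D vector")
    if not np.all(np.isfinite(e)):
        raise ValueError("scores contain non-finite entries")
    z = np.exp(e - e.max())
    return z / z.sum()


def attention_pool(a, f) -> float:
    """Scalar read-out c = sum_i a_i f_i."""
    a = _as_finite_vector(a, "a")
    f = _as_finite_vector(f, "f")
    if a.shape != f.shape:
        raise ValueError(f"length mismatch: a has {a.size}, f has {f.size}")
    if abs(a.sum() - 1.0) > 1e-6 or np.any(a < 0):
        raise ValueError("a must be a valid attention vector (non-negative, sum 1)")
    return float(np.dot(a, f))


def attention_gate(f, weight) -> np.ndarray:
    """Gated vector r = a ⊙ f with a = softmax(weight ⊙ f).

    sum(r) equals attention_pool(a, f); with n = 1 the gate is the identity.
    """
    f = _as_finite_vector(f, "f")
    a = attention_weights(attention_scores(f, weight))
    return a * f


def attention_state(f, weight) -> AttentionState:
    """Run the full attention computation and return all intermediates."""
    f = _as_finite_vector(f, "f")
    weight = _as_finite_vector(weight, "weight")
    e = attention_scores(f, weight)
    a = attention_weights(e)
    return AttentionState(weight=weight, scores=e, attn=a, pooled=float(np.dot(a, f)))
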