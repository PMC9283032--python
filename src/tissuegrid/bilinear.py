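"""Bilinear interaction node: a linear response augmented with a factorized
second-order term.

A single output node computes

    y = b + w'x + x'F'F x

where ``x`` is the input feature vector of length ``n``, ``w`` a first-order
weight vector, and ``F`` a ``k x n`` factor matrix whose Gram matrix ``F'F``
encodes pairwise interactions between input features.  The double-sum
expansion

    y = b + sum_i w_i x_i + sum_i sum_j <f_i, f_j> x_i x_j

(with ``f_i`` the i-th *column* of ``F``) is mathematically identical and is
kept here as an O(n^2 k) brute-force oracle; the efficient form evaluates the
interaction as ``||F x||^2`` in O(n k).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BilinearNodeParams",
    "BilinearLayerParams",
    "linear_response",
    "bilinear_response",
    "bilinear_response_bruteforce",
    "bilinear_layer_forward",
]


def _as_finite_vector(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError(f"{name} must be a non-empty 1-D vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


@dataclass
class BilinearNodeParams:
    """Parameters (b, w, F) of one bilinear output node.

    ``factor_matrix`` has shape (k, n): k interaction factors over an
    n-dimensional input.  ``linear_weight`` must have length n.
    """

    bias: float
    linear_weight: np.ndarray
    factor_matrix: np.ndarray

    def __post_init__(self) -> None:
        self.linear_weight = _as_finite_vector(self.linear_weight, "linear_weight")
        F = np.asarray(self.factor_matrix, dtype=float)
        if F.ndim != 2:
            raise ValueError(f"factor_matrix must be 2-D (k, n), got shape {F.shape}")
        if F.shape[0] < 1:
            raise ValueError("factor_matrix needs at least one factor (k >= 1)")
        if F.shape[1] != self.linear_weight.shape[0]:
            raise ValueError(
                f"factor_matrix has {F.shape[1]} columns but linear_weight has "
                f"length {self.linear_weight.shape[0]}"
            )
        if not np.all(np.isfinite(F)):
            raise ValueError("factor_matrix contains non-finite entries")
        if not np.isfinite(self.bias):
            raise ValueError("bias is non-finite")
        self.factor_matrix = F

    @property
    def n_features(self) -> int:
        return self.linear_weight.shape[0]

    @property
    def n_factors(self) -> int:
        return self.factor_matrix.shape[0]

    @classmethod
    def random(cls, n: int, k: int, rng: np.random.Generator) -> "BilinearNodeParams":
        """Small-uniform (±1/sqrt(n)) initialization."""
        s = 1.0 / np.sqrt(n)
        return cls(
            bias=float(rng.uniform(-s, s)),
            linear_weight=rng.uniform(-s, s, size=n),
            factor_matrix=rng.uniform(-s, s, size=(k, n)),
        )


@dataclass
class BilinearLayerParams:
    """An ordered stack of bilinear nodes sharing one input dimension.

    Vectorizes the single-node form to an m-dimensional "bilinear vector".
    """

    nodes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.nodes) < 1:
            raise ValueError("a bilinear layer needs at least one node")
        n = self.nodes[0].n_features
        for node in self.nodes:
            if node.n_features != n:
                raise ValueError("all nodes must share the same input dimension")

    @property
    def n_features(self) -> int:
        return self.nodes[0].n_features

    @property
    def n_outputs(self) -> int:
        return len(self.nodes)


def linear_response(x, w, b: float) -> float:
    """First-order node response b + w'x."""
    x = _as_finite_vector(x, "x")
    w = _as_finite_vector(w, "w")
    if x.shape != w.shape:
        raise ValueError(f"length mismatch: x has {x.size}, w has {w.size}")
    return float(b + np.dot(w, x))


def bilinear_response(x, p: BilinearNodeParams) -> float:
    """Node response b + w'x + x'F'Fx, with the interaction term evaluated
    as ||Fx||^2 (O(nk)).  The interaction term is a non-negative quadratic
    form, so the output is bounded below by the linear response."""
    x = _as_finite_vector(x, "x")
    if x.shape[0] != p.n_features:
        raise ValueError(f"x has length {x.size}, parameters expect {p.n_features}")
    Fx = p.factor_matrix @ x
    return float(p.bias + np.dot(p.linear_weight, x) + np.dot(Fx, Fx))


def bilinear_response_bruteforce(x, p: BilinearNodeParams) -> float:
    """O(n^2 k) double-sum expansion over column inner products <f_i, f_j>.

    Test oracle only — numerically identical to :func:`bilinear_response`
    up to floating-point reassociation.
    """
    x = _as_finite_vector(x, "x")
    if x.shape[0] != p.n_features:
        raise ValueError(f"x has length {x.size}, parameters expect {p.n_features}")
    n = x.shape[0]
    total = p.bias
    for i in range(n):
        total += p.linear_weight[i] * x[i]
    cols = p.factor_matrix.T  # row i = column f_i of F
    for i in range(n):
        for j in range(n):
            total += np.dot(cols[i], cols[j]) * x[i] * x[j]
    return float(total)


def bilinear_layer_forward(x, layer: BilinearLayerParams) -> np.ndarray:
    """Apply every node of the layer to x, producing the bilinear vector."""
    x = _as_finite_vector(x, "x")
    if x.shape[0] != layer.n_features:
        raise ValueError(f"x has length {x.size}, layer expects {layer.n_features}")
    return np.array([bilinear_response(x, node) for node in layer.nodes])
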