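"""Graph-convolution building blocks, parameter containers and optimizers.

Every graph convolution in the model uses the renormalized propagation rule
Â = D̃^{-1/2} (A + I) D̃^{-1/2}: self-loops are added, then the adjacency is
symmetrically degree-normalized.  The rule is provided both as a plain numpy
function (for fixed, input-level adjacencies) and as a differentiable tensor
op (coarsened adjacencies depend on learnable assignment matrices, so the
normalization must be part of the tape).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator

import numpy as np

from .autodiff import Tensor

Activation = Callable[[Tensor], Tensor]

_ACTIVATIONS: dict[str, Activation] = {
    "relu": lambda t: t.relu(),
    "tanh": lambda t: t.tanh(),
    "sigmoid": lambda t: t.sigmoid(),
    "identity": lambda t: t,
    "none": lambda t: t,
}


def get_activation(name: str) -> Activation:
    try:
        return _ACTIVATIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown activation {name!r}; choose from {sorted(_ACTIVATIONS)}"
        ) from None


def normalize_adjacency(adj: np.ndarray) -> np.ndarray:
    """Renormalized GCN propagation matrix of a fixed adjacency (numpy)."""
    adj = np.asarray(adj, dtype=np.float64)
    a_tilde = adj + np.eye(adj.shape[0])
    d = a_tilde.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(d)
    return a_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def normalize_adjacency_t(adj: Tensor) -> Tensor:
    """Differentiable renormalized propagation matrix (adjacency on the tape)."""
    m = adj.shape[0]
    a_tilde = adj + Tensor(np.eye(m))
    d = a_tilde.sum(axis=1)
    d_inv_sqrt = d ** -0.5
    return a_tilde * d_inv_sqrt.reshape(m, 1) * d_inv_sqrt.reshape(1, m)


def gcn_layer(a_hat: Tensor, x: Tensor, w: Tensor, activation: Activation) -> Tensor:
    """One graph-convolution layer: activation(Â X W)."""
    return activation(a_hat @ x @ w)


@dataclass
class ModelParams:
    """All learnable parameters Φ, keyed by name.

    ``alpha`` is the globally shared encoder output-layer block that the
    per-graph gate modulates element-wise.
    """

    params: dict[str, Tensor] = field(default_factory=dict)

    def __getitem__(self, key: str) -> Tensor:
        return self.params[key]

    def __contains__(self, key: str) -> bool:
        return key in self.params

    def items(self) -> Iterator[tuple[str, Tensor]]:
        return iter(sorted(self.params.items()))

    def zero_grad(self) -> None:
        for _, p in self.items():
            p.grad = None

    # -- flat-vector views (finite-difference checks, checkpointing) ---------

    def as_vector(self) -> np.ndarray:
        return np.concatenate([p.data.ravel() for _, p in self.items()])

    def grad_vector(self) -> np.ndarray:
        out = []
        for _, p in self.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            out.append(g.ravel())
        return np.concatenate(out)

    def set_vector(self, vec: np.ndarray) -> None:
        offset = 0
        for _, p in self.items():
            n = p.data.size
            p.data = np.asarray(vec[offset : offset + n], dtype=np.float64).reshape(
                p.data.shape
            )
            offset += n
        if offset != vec.size:
            raise ValueError("parameter vector length mismatch")

    def copy(self) -> "ModelParams":
        return ModelParams(
            {k: Tensor(p.data.copy(), requires_grad=True) for k, p in self.items()}
        )

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.items():
            if k not in state:
                raise KeyError(f"missing parameter {k!r} in checkpoint")
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {k!r}: {arr.shape} vs {p.data.shape}"
                )
            p.data = arr.copy()


class SGD:
    """Plain gradient descent: Φ ← Φ − γ ∇Φ (the printed update rule)."""

    def __init__(self, params: ModelParams, lr: float):
        self.params = params
        self.lr = float(lr)

    def step(self) -> None:
        for _, p in self.params.items():
            if p.grad is not None:
                p.data -= self.lr * p.grad


class Adam:
    """Adaptive-moment estimation; the practical-convergence option."""

    def __init__(
        self,
        params: ModelParams,
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad**2
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def make_optimizer(name: str, params: ModelParams, lr: float):
    if name == "sgd":
        return SGD(params, lr)
    if name == "adam":
        return Adam(params, lr)
    raise ValueError(f"unknown optimizer {name!r}; choose 'sgd' or 'adam'")
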