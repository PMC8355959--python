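"""Extreme learning machine regression core.

A single-hidden-layer feed-forward network whose hidden weights and biases
are not trained: given input weights W (H x d) and biases c (H,), the hidden
representation of a sample x is h(x) = f(W x + c), and the output weights
alpha are the minimum-norm least-squares solution of A alpha = y, where A
stacks h(x_j) row-wise and the pseudoinverse is the Moore-Penrose one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.special import expit

ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "sigmoid": expit,
    "tanh": np.tanh,
    "linear": lambda x: x,
}


@dataclass
class ELMModel:
    """Hidden-layer parameters plus (once solved) the output weights."""

    input_weights: np.ndarray  # H x d
    hidden_biases: np.ndarray  # H
    activation: str = "sigmoid"
    output_weights: np.ndarray | None = None  # H

    def __post_init__(self) -> None:
        self.input_weights = np.atleast_2d(np.asarray(self.input_weights, float))
        self.hidden_biases = np.asarray(self.hidden_biases, float).ravel()
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}; "
                             f"registered: {sorted(ACTIVATIONS)}")
        if self.input_weights.shape[0] != self.hidden_biases.shape[0]:
            raise ValueError("input_weights rows must match hidden_biases length")
        if self.output_weights is not None:
            self.output_weights = np.asarray(self.output_weights, float).ravel()
            if self.output_weights.shape[0] != self.n_hidden:
                raise ValueError("output_weights length must equal hidden count")

    @property
    def n_hidden(self) -> int:
        return self.input_weights.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.input_weights.shape[1]

    def to_dict(self) -> dict:
        doc = {
            "activation": self.activation,
            "input_weights": self.input_weights.tolist(),
            "hidden_biases": self.hidden_biases.tolist(),
        }
        if self.output_weights is not None:
            doc["output_weights"] = self.output_weights.tolist()
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "ELMModel":
        return cls(np.array(doc["input_weights"]), np.array(doc["hidden_biases"]),
                   activation=doc["activation"],
                   output_weights=(np.array(doc["output_weights"])
                                   if "output_weights" in doc else None))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ELMModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def init_hidden(d: int, H: int, seed: int | np.random.Generator = 0
                ) -> tuple[np.ndarray, np.ndarray]:
    """Draw input weights (H x d) and biases (H,) i.i.d. uniform on [-1, 1]."""
    if d < 1 or H < 1:
        raise ValueError("d and H must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.uniform(-1.0, 1.0, size=(H, d)), rng.uniform(-1.0, 1.0, size=H)


def hidden_matrix(X: np.ndarray, model: ELMModel) -> np.ndarray:
    """Activation matrix A with A[j, i] = f(w_i . x_j + c_i)."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != model.n_inputs:
        raise ValueError(f"input width {X.shape[1]} != model width {model.n_inputs}")
    return ACTIVATIONS[model.activation](X @ model.input_weights.T + model.hidden_biases)


def solve_output_weights(A: np.ndarray, Y: np.ndarray, ridge: float = 1e-8
                         ) -> np.ndarray:
    """Solve A alpha ~= Y for the output weights.

    With ridge = 0 this is the minimum-norm least-squares (Moore-Penrose)
    solution; a tiny positive ridge solves the regularized normal equations
    instead, which keeps near-singular hidden matrices stable inside an
    optimization loop.
    """
    A = np.atleast_2d(np.asarray(A, float))
    Y = np.asarray(Y, float).ravel()
    if A.shape[0] != Y.shape[0]:
        raise ValueError("A row count must equal target length")
    if not (np.isfinite(A).all() and np.isfinite(Y).all()):
        raise ValueError("non-finite entries in the linear system")
    if ridge > 0:
        H = A.shape[1]
        gram = A.T @ A + ridge * np.eye(H)
        try:
            return np.linalg.solve(gram, A.T @ Y)
        except np.linalg.LinAlgError:
            pass  # fall through to the pseudoinverse path
    return np.linalg.lstsq(A, Y, rcond=None)[0]


def predict(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Network output e = A alpha on the scale the model was fitted on."""
    if model.output_weights is None:
        raise ValueError("model has no output weights; solve them first")
    return hidden_matrix(X, model) @ model.output_weights


def kernel_value(x_i: np.ndarray, x_j: np.ndarray, model: ELMModel) -> float:
    """Implicit ELM kernel k(x_i, x_j) = h(x_i) . h(x_j)."""
    x_i = np.asarray(x_i, float).ravel()
    x_j = np.asarray(x_j, float).ravel()
    if x_i.shape[0] != model.n_inputs or x_j.shape[0] != model.n_inputs:
        raise ValueError("kernel inputs must match the model input width")
    hi = hidden_matrix(x_i[None, :], model)[0]
    hj = hidden_matrix(x_j[None, :], model)[0]
    return float(hi @ hj)
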