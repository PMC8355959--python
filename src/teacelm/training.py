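"""PSO-tuned extreme learning machine training.

The swarm searches the ELM's random layer — input weights and hidden biases,
flattened row-major with the weights first — while the output weights stay
analytic: every fitness evaluation decodes a particle, rebuilds the hidden
matrix on the (normalized) training rows, solves the Moore-Penrose system
and scores the training residual. Test rows never enter the fitness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import elm, pso
from .datasets import Dataset
from .preprocessing import NormalizationParams, SplitIndices, normalize

FITNESS_METRICS = {
    "rmse": lambda err: float(np.sqrt(np.mean(err**2))),
    "mse": lambda err: float(np.mean(err**2)),
}


@dataclass(frozen=True)
class TrainerConfig:
    """Hyperparameters of the hybrid trainer.

    ``n_hidden`` defaults to 12 (twice the six-feature input keeps the PSO
    search space at 12 * 7 = 84 dimensions). ``cv_folds`` switches the
    fitness from plain training RMSE to k-fold cross-validated RMSE; it is
    off by default. ``ridge`` stabilizes the output-weight solve against
    near-singular hidden matrices mid-search.
    """

    n_hidden: int = 12
    activation: str = "sigmoid"
    fitness_metric: str = "rmse"
    ridge: float = 1e-8
    cv_folds: int | None = None
    pso: pso.PSOConfig = field(default_factory=pso.PSOConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be positive")
        if self.fitness_metric not in FITNESS_METRICS:
            raise ValueError(f"unknown fitness metric {self.fitness_metric!r}")
        if self.activation not in elm.ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.cv_folds is not None and self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2 when set")

    def pso_for(self, d: int) -> pso.PSOConfig:
        """The swarm config with dimension derived as H * (d + 1)."""
        cfg = self.pso.__dict__ | {
            "n_dimensions": self.n_hidden * (d + 1), "seed": self.seed}
        return pso.PSOConfig(**cfg)


@dataclass
class TrainingReport:
    """What the optimizer did: per-iteration incumbent fitness and seeds."""

    fitness_history: np.ndarray
    best_fitness: float
    n_hidden: int
    n_train: int
    seed: int


def encode(input_weights: np.ndarray, hidden_biases: np.ndarray) -> np.ndarray:
    """Flatten (W, c) to one PSO position: row-major weights, then biases."""
    W = np.atleast_2d(np.asarray(input_weights, float))
    c = np.asarray(hidden_biases, float).ravel()
    if W.shape[0] != c.shape[0]:
        raise ValueError("weight rows must match bias length")
    return np.concatenate([W.ravel(), c])


def decode(position: np.ndarray, H: int, d: int
           ) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`encode`."""
    position = np.asarray(position, float).ravel()
    if position.shape[0] != H * (d + 1):
        raise ValueError(f"position length {position.shape[0]} != H*(d+1) = {H * (d + 1)}")
    return position[:H * d].reshape(H, d), position[H * d:]


def _fold_slices(n: int, k: int) -> list[np.ndarray]:
    return [idx for idx in np.array_split(np.arange(n), k) if len(idx)]


def elm_fitness(position: np.ndarray, X_train: np.ndarray, y_train: np.ndarray,
                config: TrainerConfig) -> float:
    """Fitness of one particle: residual of the analytically-solved ELM on
    the normalized training partition (or its cross-validated analogue)."""
    d = X_train.shape[1]
    W, c = decode(position, config.n_hidden, d)
    model = elm.ELMModel(W, c, activation=config.activation)
    metric = FITNESS_METRICS[config.fitness_metric]
    try:
        if config.cv_folds is None:
            A = elm.hidden_matrix(X_train, model)
            alpha = elm.solve_output_weights(A, y_train, ridge=config.ridge)
            err = A @ alpha - y_train
        else:
            errs = []
            for held in _fold_slices(len(y_train), config.cv_folds):
                mask = np.ones(len(y_train), bool)
                mask[held] = False
                A_fit = elm.hidden_matrix(X_train[mask], model)
                alpha = elm.solve_output_weights(A_fit, y_train[mask],
                                                 ridge=config.ridge)
                A_out = elm.hidden_matrix(X_train[held], model)
                errs.append(A_out @ alpha - y_train[held])
            err = np.concatenate(errs)
        value = metric(err)
    except (np.linalg.LinAlgError, ValueError):
        return np.inf
    return value if np.isfinite(value) else np.inf


def train(dataset: Dataset, split: SplitIndices, params: NormalizationParams,
          config: TrainerConfig) -> tuple[elm.ELMModel, TrainingReport]:
    """Run the swarm over the ELM hidden layer on the training partition.

    Returns the decoded best model (output weights re-solved on the full
    training partition) and the optimizer's report.
    """
    if split.n_train == 0:
        raise ValueError("empty training partition")
    norm = normalize(dataset, params)
    X_train = norm.features[split.train_indices]
    y_train = norm.target[split.train_indices]
    d = X_train.shape[1]

    def fitness(position: np.ndarray) -> float:
        return elm_fitness(position, X_train, y_train, config)

    best, best_fitness, history = pso.optimize(fitness, config.pso_for(d))
    W, c = decode(best, config.n_hidden, d)
    model = elm.ELMModel(W, c, activation=config.activation)
    A = elm.hidden_matrix(X_train, model)
    model.output_weights = elm.solve_output_weights(A, y_train,
                                                    ridge=config.ridge)
    report = TrainingReport(history, float(best_fitness), config.n_hidden,
                            split.n_train, config.seed)
    return model, report
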