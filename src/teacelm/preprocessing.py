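"""Min-max normalization to [-1, +1] and the 75/25 train/test partition.

Both the features and the target are normalized; the pipeline denormalizes
predictions before computing metrics so errors stay on the physical TEAC
scale. Values outside the fitted range map outside [-1, 1] by design (the
transform is affine, not clipping).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import Dataset


@dataclass(frozen=True)
class NormalizationParams:
    """Per-column extrema and the scope they were fitted on."""

    feature_min: np.ndarray
    feature_max: np.ndarray
    target_min: float
    target_max: float
    scope: str  # "full" | "train"

    def __post_init__(self) -> None:
        if self.scope not in ("full", "train"):
            raise ValueError("scope must be 'full' or 'train'")


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint, exhaustive train/test row partition."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int

    @property
    def n_train(self) -> int:
        return len(self.train_indices)

    @property
    def n_test(self) -> int:
        return len(self.test_indices)


def fit_normalizer(data: Dataset, scope: str = "full",
                   split: SplitIndices | None = None) -> NormalizationParams:
    """Record column-wise min/max over the full dataset or the train rows.

    A constant column is an error: it cannot be mapped to [-1, 1] and almost
    always indicates a generator or configuration bug.
    """
    if scope == "train":
        if split is None:
            raise ValueError("train-scope normalization requires a split")
        rows = split.train_indices
    elif scope == "full":
        rows = np.arange(data.n_samples)
    else:
        raise ValueError("scope must be 'full' or 'train'")

    X = data.features[rows]
    y = data.target[rows]
    fmin, fmax = X.min(axis=0), X.max(axis=0)
    for j, name in enumerate(data.feature_names):
        if fmax[j] <= fmin[j]:
            raise ValueError(f"column {name!r} is constant over scope {scope!r}")
    tmin, tmax = float(y.min()), float(y.max())
    if tmax <= tmin:
        raise ValueError(f"column {data.target_name!r} is constant over scope {scope!r}")
    return NormalizationParams(fmin, fmax, tmin, tmax, scope)


def _scale(x: np.ndarray, lo, hi) -> np.ndarray:
    return 2.0 * (x - lo) / (hi - lo) - 1.0


def _unscale(x: np.ndarray, lo, hi) -> np.ndarray:
    return (x + 1.0) * (hi - lo) / 2.0 + lo


def normalize(data: Dataset, params: NormalizationParams) -> Dataset:
    """Map every column affinely so the fitted extrema land on -1 and +1."""
    return Dataset(
        _scale(data.features, params.feature_min, params.feature_max),
        _scale(data.target, params.target_min, params.target_max),
        feature_names=data.feature_names, target_name=data.target_name)


def denormalize(data: Dataset, params: NormalizationParams) -> Dataset:
    """Exact inverse of :func:`normalize`."""
    return Dataset(
        _unscale(data.features, params.feature_min, params.feature_max),
        _unscale(data.target, params.target_min, params.target_max),
        feature_names=data.feature_names, target_name=data.target_name)


def denormalize_target(values: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Map normalized target values (e.g. model predictions) back to the
    physical TEAC scale."""
    return _unscale(np.asarray(values, float), params.target_min, params.target_max)


def split(n: int, train_fraction: float = 0.75, seed: int = 0) -> SplitIndices:
    """Uniformly random partition into round(train_fraction * n) train rows
    and the rest. For n = 172 at 75% this is the 129/43 split."""
    if n < 4:
        raise ValueError("need at least 4 rows to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n_train = int(round(train_fraction * n))
    perm = np.random.default_rng(seed).permutation(n)
    return SplitIndices(np.sort(perm[:n_train]), np.sort(perm[n_train:]), seed)
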