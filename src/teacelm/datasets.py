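"""Synthetic composition -> TEAC datasets.

The experimental database behind the antioxidant-capacity model (172 sprouted
cruciferous seed samples, six biochemical composition variables) is not
publicly printed, so this module generates surrogate datasets with the
statistical structure that analysis assumes: a configurable feature-target
correlation vector and a configurable ceiling on the fraction of target
variance that a regression on the features can explain.

Construction
------------
Let ``rho_i`` be the requested correlation between (standardized) feature
``i`` and the (standardized) target, and ``R2max`` the requested achievable
coefficient of determination. With loadings ``lam_i = rho_i / sqrt(R2max)``
(each required to lie in (-1, 1)), one latent activity factor ``z`` and
``d - 1`` shared measurement-noise factors ``u``:

    f_i = lam_i * z + sqrt(1 - lam_i^2) * g_i . u      (standardized feature)
    y   = sqrt(R2max) * z + sqrt(1 - R2max) * eta      (standardized target)

where ``g_i`` is the i-th unit vector for the first ``d - 1`` features and
the flat unit vector ``(1,...,1)/sqrt(d-1)`` for the last. Every feature has
unit variance and ``corr(f_i, y) = rho_i`` exactly. Because the noise space
has rank ``d - 1 < d``, a linear combination of the features annihilates the
noise and recovers ``z`` exactly, so the population R^2 of the target on the
features equals ``R2max`` (for generic loadings). Features and target are
then rescaled to the configured means and spreads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

FEATURE_NAMES = ("TP", "IP6", "GLS", "PROT", "AA", "TTOT")
TARGET_NAME = "TEAC"

#: Default feature-target correlations. GLS and TTOT are the two published
#: relevancy factors; the four remaining values are only known to be negative
#: and are this package's documented choices.
DEFAULT_CORRELATIONS = {
    "TP": -0.45,
    "IP6": -0.35,
    "GLS": -0.85,
    "PROT": -0.40,
    "AA": -0.25,
    "TTOT": 0.26,
}

#: Plausible concentration scales (mg/g dry mass except PROT; arbitrary but
#: fixed). Only the target scale matters for error magnitudes.
DEFAULT_FEATURE_MEANS = {
    "TP": 12.0, "IP6": 18.0, "GLS": 25.0, "PROT": 300.0, "AA": 2.5, "TTOT": 0.6,
}
DEFAULT_FEATURE_SDS = {
    "TP": 4.0, "IP6": 5.0, "GLS": 8.0, "PROT": 60.0, "AA": 1.0, "TTOT": 0.2,
}


class GeneratorConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic composition->TEAC generator.

    Parameters
    ----------
    n_samples
        Number of rows; the emulated database holds 172.
    target_correlations
        Map feature name -> population correlation with the target, each in
        (-1, 1).
    max_r2
        Population coefficient of determination achievable by regressing the
        target on the features, in (0, 1].
    feature_means, feature_sds
        Location and spread used to rescale the standardized features.
    target_mean, target_sd
        TEAC location and spread (umol Trolox / g dry mass). The default
        spread 21.8 puts the residual scale at R^2 = 0.973 near 3.6, i.e. on
        the error scale the reference analysis reports.
    seed
        Generation seed; identical config and seed give identical data.
    """

    n_samples: int = 172
    target_correlations: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CORRELATIONS))
    max_r2: float = 0.980
    feature_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_MEANS))
    feature_sds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_SDS))
    target_mean: float = 50.0
    target_sd: float = 21.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise GeneratorConfigError("n_samples must be at least 10")
        if not 0.0 < self.max_r2 <= 1.0:
            raise GeneratorConfigError("max_r2 must lie in (0, 1]")
        if len(self.target_correlations) < 2:
            raise GeneratorConfigError("need at least two features")
        for name, rho in self.target_correlations.items():
            if not abs(rho) < 1.0:
                raise GeneratorConfigError(
                    f"correlation for {name!r} must lie strictly in (-1, 1)")
            lam = rho / np.sqrt(self.max_r2)
            if not abs(lam) < 1.0:
                raise GeneratorConfigError(
                    f"adjusted loading for {name!r} is {lam:.4f}, outside "
                    f"(-1, 1); lower |rho| or raise max_r2")
        for name in self.target_correlations:
            if name not in self.feature_means or name not in self.feature_sds:
                raise GeneratorConfigError(f"missing mean/sd for {name!r}")
            if self.feature_sds[name] <= 0:
                raise GeneratorConfigError(f"sd for {name!r} must be positive")
        if self.target_sd <= 0:
            raise GeneratorConfigError("target_sd must be positive")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.target_correlations)

    def loadings(self) -> np.ndarray:
        rho = np.array([self.target_correlations[n] for n in self.feature_names])
        return rho / np.sqrt(self.max_r2)

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneratorConfig":
        """Load a config from a YAML or JSON document mirroring the fields."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) \
            else json.loads(text)
        return cls(**data)


@dataclass
class Dataset:
    """An ordered table of composition samples with their TEAC target.

    ``features`` is n x d (row order is the linkage to ``target``);
    ``feature_names`` names the columns.
    """

    features: np.ndarray
    target: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES
    target_name: str = TARGET_NAME

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.features.shape[0] != self.target.shape[0]:
            raise ValueError("features and target row counts differ")
        if self.features.shape[1] != len(self.feature_names):
            raise ValueError("feature_names does not match feature width")
        if not (np.isfinite(self.features).all() and np.isfinite(self.target).all()):
            raise ValueError("dataset contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.features, columns=list(self.feature_names))
        frame[self.target_name] = self.target
        return frame

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path: str | Path, target_name: str = TARGET_NAME) -> "Dataset":
        frame = pd.read_csv(path)
        if target_name not in frame.columns:
            raise ValueError(f"CSV lacks target column {target_name!r}")
        names = tuple(c for c in frame.columns if c != target_name)
        return cls(frame[list(names)].to_numpy(float),
                   frame[target_name].to_numpy(float),
                   feature_names=names, target_name=target_name)


def generate_dataset(config: GeneratorConfig) -> Dataset:
    """Draw a dataset from the shared-noise factor model described above.

    Deterministic given ``(config, config.seed)``.
    """
    rng = np.random.default_rng(config.seed)
    names = config.feature_names
    d = len(names)
    lam = config.loadings()

    n = config.n_samples
    z = rng.standard_normal(n)
    u = rng.standard_normal((n, d - 1))
    eta = rng.standard_normal(n)

    # Noise mixing: feature i < d-1 owns factor i; the last feature spreads
    # its noise evenly over all factors. Rank d-1 < d, so the features pin
    # the latent z exactly and max_r2 is attainable by OLS.
    mix = np.zeros((d, d - 1))
    mix[:d - 1, :] = np.eye(d - 1)
    mix[d - 1, :] = 1.0 / np.sqrt(d - 1)

    std_features = z[:, None] * lam + u @ (mix * np.sqrt(1.0 - lam**2)[:, None]).T
    std_target = np.sqrt(config.max_r2) * z + np.sqrt(1.0 - config.max_r2) * eta

    means = np.array([config.feature_means[n_] for n_ in names])
    sds = np.array([config.feature_sds[n_] for n_ in names])
    features = means + sds * std_features
    target = config.target_mean + config.target_sd * std_target
    return Dataset(features, target, feature_names=names)
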