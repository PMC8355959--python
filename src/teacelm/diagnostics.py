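"""Model evaluation battery: fit statistics, relative deviations, the
Williams-plot applicability domain, and relevancy-factor sensitivity.

All fit statistics are computed on the physical TEAC scale. R^2 is the
coefficient of determination 1 - SSres/SStot (not a squared Pearson
correlation — the two differ for biased predictors). STD is the sample
standard deviation of the *absolute* errors, which satisfies
std(|e|)^2 = rmse^2 - mae^2 and is therefore always below the RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import Dataset

RESIDUAL_CUTOFF = 3.0  # standardized-residual outlier bound (+/-)


@dataclass(frozen=True)
class FitMetrics:
    """The five per-phase fit statistics."""

    r2: float
    mre_percent: float
    mse: float
    rmse: float
    std: float
    phase: str
    n: int

    def to_dict(self) -> dict:
        return {"phase": self.phase, "n": self.n, "r2": self.r2,
                "mre_percent": self.mre_percent, "mse": self.mse,
                "rmse": self.rmse, "std": self.std}


@dataclass
class ADResult:
    """Williams-plot applicability domain for one model fit.

    ``flags`` labels each row: ``in_domain``, ``high_leverage`` (hat value
    above the warning leverage h*), ``residual_outlier`` (standardized
    residual beyond +/-3), or ``both``.
    """

    leverages: np.ndarray
    std_residuals: np.ndarray
    warning_leverage: float
    flags: list[str]

    def counts(self) -> dict[str, int]:
        return {k: self.flags.count(k)
                for k in ("in_domain", "high_leverage", "residual_outlier", "both")}

    def suspicious_rows(self) -> list[int]:
        return [i for i, f in enumerate(self.flags) if f != "in_domain"]


@dataclass
class SensitivityResult:
    """Relevancy factor (signed correlation with the target) per feature."""

    relevancy: dict[str, float]

    def ranking_by_magnitude(self) -> list[str]:
        return sorted(self.relevancy, key=lambda k: -abs(self.relevancy[k]))

    def ranking_by_signed_effect(self) -> list[str]:
        return sorted(self.relevancy, key=lambda k: -self.relevancy[k])


def fit_metrics(actual: np.ndarray, predicted: np.ndarray,
                phase: str = "total") -> FitMetrics:
    """Compute R^2, MRE (%), MSE, RMSE and STD for one phase.

    MRE requires every actual value to be nonzero; R^2 requires a
    non-constant actual vector.
    """
    y = np.asarray(actual, float).ravel()
    yhat = np.asarray(predicted, float).ravel()
    if y.size == 0 or y.size != yhat.size:
        raise ValueError("actual and predicted must be equal-length, non-empty")
    if np.any(y == 0):
        raise ValueError("MRE undefined: an actual value is exactly zero")
    ss_tot = np.sum((y - y.mean())**2)
    if ss_tot == 0:
        raise ValueError("R^2 undefined: actual values are constant")
    err = y - yhat
    mse = float(np.mean(err**2))
    abs_err = np.abs(err)
    return FitMetrics(
        r2=float(1.0 - np.sum(err**2) / ss_tot),
        mre_percent=float(100.0 * np.mean(abs_err / np.abs(y))),
        mse=mse,
        rmse=float(np.sqrt(mse)),
        std=float(np.std(abs_err, ddof=1)) if y.size > 1 else 0.0,
        phase=phase, n=int(y.size))


def relative_deviation(actual: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """Per-sample absolute relative deviation in percent, order-preserving.

    The mean of the output equals the MRE of :func:`fit_metrics`.
    """
    y = np.asarray(actual, float).ravel()
    yhat = np.asarray(predicted, float).ravel()
    if np.any(y == 0):
        raise ValueError("relative deviation undefined at an actual value of 0")
    return 100.0 * np.abs(y - yhat) / np.abs(y)


def williams(features_norm_train: np.ndarray, features_norm_all: np.ndarray,
             residuals: np.ndarray, rmse: float) -> ADResult:
    """Leverage/standardized-residual applicability-domain analysis.

    The linear design is the normalized features plus an intercept column,
    fitted on the training rows; the leverage of any row x is
    x (X'X)^-1 x', and the warning leverage is h* = 3(p+1)/n_train with p
    the feature count. Standardized residuals are residual / rmse.
    """
    X_train = np.atleast_2d(np.asarray(features_norm_train, float))
    X_all = np.atleast_2d(np.asarray(features_norm_all, float))
    residuals = np.asarray(residuals, float).ravel()
    if X_all.shape[0] != residuals.shape[0]:
        raise ValueError("residuals must align with features_norm_all rows")
    n_train, p = X_train.shape
    design_train = np.column_stack([np.ones(n_train), X_train])
    design_all = np.column_stack([np.ones(X_all.shape[0]), X_all])
    gram = design_train.T @ design_train
    if np.linalg.matrix_rank(gram) < p + 1:
        raise np.linalg.LinAlgError(
            "training design is rank deficient; inspect the feature columns "
            "for constants or exact collinearity")
    leverages = np.einsum("ij,jk,ik->i", design_all,
                          np.linalg.inv(gram), design_all)
    h_star = 3.0 * (p + 1) / n_train
    std_res = residuals / rmse

    flags = []
    for h, r in zip(leverages, std_res):
        high = h > h_star
        out = abs(r) > RESIDUAL_CUTOFF
        flags.append("both" if high and out else
                     "high_leverage" if high else
                     "residual_outlier" if out else "in_domain")
    return ADResult(leverages, std_res, h_star, flags)


def relevancy_factors(dataset: Dataset) -> SensitivityResult:
    """Pearson correlation of each raw feature column with the raw target."""
    if dataset.n_samples < 3:
        raise ValueError("need at least 3 samples for correlations")
    y = dataset.target
    if np.std(y) == 0:
        raise ValueError("relevancy undefined: target is constant")
    relevancy = {}
    for j, name in enumerate(dataset.feature_names):
        x = dataset.features[:, j]
        if np.std(x) == 0:
            raise ValueError(f"relevancy undefined for constant column {name!r}")
        relevancy[name] = float(np.corrcoef(x, y)[0, 1])
    return SensitivityResult(relevancy)
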