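"""Functional training interface.

Thin wrappers over :class:`bloodmix.model.CompositionModel` /
:class:`~bloodmix.model.CompositionResults` for callers who prefer a
fit-function style over the model-object API. Both surfaces are
equivalent; the model objects carry the full state.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .core import CompositionMatrix, ExpressionMatrix
from .model import (
    DEFAULT_ALPHAS,
    CompositionModel,
    CompositionResults,
    LambdaPath,
    TuningResult,
)


def fit_multitask_elasticnet(
    X: ExpressionMatrix,
    Y: CompositionMatrix,
    alpha: float,
    lam: float,
    standardize: bool = True,
) -> CompositionResults:
    """Fit the multi-response Gaussian elastic net at one (alpha, lambda)."""
    return CompositionModel(X, Y, standardize=standardize).fit(alpha, lam)


def compute_lambda_path(
    X: ExpressionMatrix,
    Y: CompositionMatrix,
    alpha: float,
    n_lambda: int = 100,
    min_ratio: Optional[float] = None,
    standardize: bool = True,
) -> LambdaPath:
    """Penalty path from lambda_max (all rows zero) downwards."""
    return CompositionModel(X, Y, standardize=standardize).lambda_path(
        alpha, n_lambda=n_lambda, min_ratio=min_ratio
    )


def tune_hyperparameters(
    X: ExpressionMatrix,
    Y: CompositionMatrix,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    k: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    standardize: bool = True,
) -> TuningResult:
    """Cross-validated (alpha, lambda) selection over the grid."""
    return CompositionModel(X, Y, standardize=standardize).fit_cv(
        alphas=alphas, k=k, seed=seed, n_lambda=n_lambda
    ).tuning


def train_tuned(
    X: ExpressionMatrix,
    Y: CompositionMatrix,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    k: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    standardize: bool = True,
) -> CompositionResults:
    """Tune and refit in one call (the usual training entry point)."""
    return CompositionModel(X, Y, standardize=standardize).fit_cv(
        alphas=alphas, k=k, seed=seed, n_lambda=n_lambda
    )


def predict_composition(
    results: CompositionResults,
    X: ExpressionMatrix,
    postprocess: str = "raw",
) -> CompositionMatrix:
    """Apply a fitted model to new samples; see
    :meth:`CompositionResults.predict`."""
    return results.predict(X, postprocess=postprocess)
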