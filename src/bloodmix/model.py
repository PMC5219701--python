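"""Multi-task elastic-net prediction of cell composition from bulk expression.

:class:`CompositionModel` is the model object, built from a log2 expression
matrix (features x samples) and matching composition labels (samples x cell
types). ``fit(alpha, lam)`` solves the multi-response Gaussian elastic net
at one penalty setting; ``fit_cv`` tunes (alpha, lambda) over a grid by
k-fold cross-validated mean squared error and refits at the winner. Both
return a :class:`CompositionResults` carrying the intercepts, the
(features x cell types) coefficient matrix, the hyperparameters, tuning
diagnostics and a ``summary()`` table, and offering ``predict``.

The penalty acts on whole coefficient rows (one row = one feature's
coefficients across all cell types), so features are selected jointly for
every response — the multi-task structure that yields composition marker
genes rather than per-cell-type gene lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _solver
from .core import CompositionMatrix, ExpressionMatrix
from .errors import (
    AlignmentError,
    ConfigError,
    DegenerateDataError,
    MissingFeatureError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: alpha grid used for hyperparameter tuning, spanning lasso to ridge.
DEFAULT_ALPHAS: Tuple[float, ...] = (1.0, 0.9, 0.5, 0.1, 0.0)

#: pure ridge has no finite lambda_max; this floor stands in for alpha
#: when constructing the alpha = 0 path.
ALPHA_FLOOR: float = 1e-3


@dataclass
class LambdaPath:
    """Descending sequence of penalty strengths for one alpha.

    Starts at lambda_max, the smallest penalty that zeroes every
    coefficient row, and descends log-evenly to lambda_max * min_ratio.
    """

    alpha: float
    lambdas: np.ndarray
    n_lambda: int
    min_ratio: float

    def __post_init__(self):
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if np.any(np.diff(self.lambdas) >= 0):
            raise ValidationError("lambda path must be strictly decreasing")
        if np.any(self.lambdas <= 0):
            raise ValidationError("lambda path must be positive")


@dataclass
class TuningResult:
    """Cross-validation surface over the (alpha, lambda) grid."""

    grid: pd.DataFrame  # columns: alpha, lam, mean_mse, se_mse
    chosen_alpha: float
    chosen_lambda: float
    k: int
    seed: int

    def __post_init__(self):
        best = self.grid["mean_mse"].min()
        row = self.grid[
            (self.grid["alpha"] == self.chosen_alpha)
            & (self.grid["lam"] == self.chosen_lambda)
        ]
        if row.empty or float(row["mean_mse"].iloc[0]) > best + 1e-12:
            raise ValidationError("chosen (alpha, lambda) does not minimize CV MSE")


def _kfold_indices(n: int, k: int, rng: np.random.Generator) -> List[np.ndarray]:
    """Simple unstratified random partition into k folds of near-equal size."""
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, k)]


class CompositionModel:
    """Model object: bulk log2 expression regressed on composition labels.

    Parameters
    ----------
    X
        Log2-scale expression, features x samples (already low-expression
        filtered if desired).
    Y
        Composition labels, samples x cell types; sample ids must match
        ``X`` (any order).
    standardize
        Scale each feature to unit variance internally before penalization
        (coefficients are always reported on the original scale).
    """

    def __init__(self, X: ExpressionMatrix, Y: CompositionMatrix,
                 standardize: bool = True):
        if X.scale_tag != "log2":
            logger.warning("training on a non-log2 expression matrix")
        if set(X.sample_ids) != set(Y.sample_ids):
            raise AlignmentError(
                "expression and composition matrices carry different samples"
            )
        if X.n_samples < 2:
            raise ValidationError("need at least 2 samples to fit")
        order = [Y.sample_ids.index(s) for s in X.sample_ids]
        self.feature_ids = list(X.feature_ids)
        self.sample_ids = list(X.sample_ids)
        self.cell_types = list(Y.cell_types)
        self.design = np.ascontiguousarray(X.values.T)          # n x p
        self.responses = np.ascontiguousarray(Y.values[order])  # n x K
        self.standardize = bool(standardize)

    @classmethod
    def from_dataframes(cls, expression: pd.DataFrame, labels: pd.DataFrame,
                        standardize: bool = True) -> "CompositionModel":
        """Build from pandas frames (expression: features x samples,
        labels: samples x cell types)."""
        X = ExpressionMatrix(list(expression.index), list(expression.columns),
                             expression.to_numpy(dtype=float))
        Y = CompositionMatrix(list(labels.index), list(labels.columns),
                              labels.to_numpy(dtype=float))
        return cls(X, Y, standardize=standardize)

    # ------------------------------------------------------------------ #
    # internal linear algebra on the centered/standardized problem

    def _prepare(self, rows: Optional[np.ndarray] = None):
        X = self.design if rows is None else self.design[rows]
        Y = self.responses if rows is None else self.responses[rows]
        n = X.shape[0]
        x_mean = X.mean(axis=0)
        y_mean = Y.mean(axis=0)
        Xc = X - x_mean
        Yc = Y - y_mean
        if self.standardize:
            scale = np.sqrt(np.mean(Xc * Xc, axis=0))
            scale[scale == 0] = 1.0
        else:
            scale = np.ones(X.shape[1])
        Xs = Xc / scale
        return Xs, Yc, x_mean, y_mean, scale, n

    #: convergence tolerance (max coefficient change per sweep, on the
    #: standardized scale) for final fits
    tol: float = 1e-7
    #: looser tolerance used inside cross-validation fold fits, where only
    #: MSE-level resolution is needed
    cv_tol: float = 2e-6

    @staticmethod
    def _solve(Xs, Yc, alpha, lam, warm=None, tol=1e-7):
        n = Xs.shape[0]
        if lam == 0.0:
            B, *_ = np.linalg.lstsq(Xs, Yc, rcond=None)
            return B
        G = Xs.T @ Xs / n
        C = Xs.T @ Yc / n
        return _solver.cd_solve(G, C, lam, alpha, B0=warm, tol=tol)

    def _results(self, B_std, scale, x_mean, y_mean, alpha, lam, extra_meta=None,
                 tuning=None):
        B = B_std / scale[:, None]
        intercepts = y_mean - x_mean @ B
        meta = {
            "standardize": self.standardize,
            "n_samples": len(self.sample_ids),
            "feature_scale": [float(s) for s in scale],
        }
        if extra_meta:
            meta.update(extra_meta)
        return CompositionResults(
            feature_ids=list(self.feature_ids),
            cell_types=list(self.cell_types),
            intercepts=intercepts,
            coefficients=B,
            alpha=float(alpha),
            lam=float(lam),
            training_meta=meta,
            tuning=tuning,
            model=self,
        )

    # ------------------------------------------------------------------ #
    # public fitting API

    def fit(self, alpha: float, lam: float) -> "CompositionResults":
        """Fit at a single (alpha, lambda); intercepts are unpenalized."""
        if not 0.0 <= alpha <= 1.0:
            raise ValidationError(f"alpha must lie in [0, 1]; got {alpha}")
        if lam < 0:
            raise ValidationError(f"lambda must be non-negative; got {lam}")
        Xs, Yc, x_mean, y_mean, scale, n = self._prepare()
        B = self._solve(Xs, Yc, alpha, lam, tol=self.tol)
        return self._results(B, scale, x_mean, y_mean, alpha, lam)

    def lambda_path(self, alpha: float, n_lambda: int = 100,
                    min_ratio: Optional[float] = None) -> LambdaPath:
        """Log-spaced penalty path from lambda_max down to
        lambda_max * min_ratio (default 1e-4 when n > p, else 1e-2)."""
        Xs, Yc, *_ , n = self._prepare()
        if np.allclose(Yc, 0.0):
            raise DegenerateDataError("responses are constant; no path exists")
        if min_ratio is None:
            min_ratio = 1e-4 if n > Xs.shape[1] else 1e-2
        if not 0.0 < min_ratio < 1.0:
            raise ValidationError("min_ratio must lie in (0, 1)")
        C = Xs.T @ Yc / n
        lam_max = float(np.max(np.sqrt(np.sum(C * C, axis=1)))) / max(alpha, ALPHA_FLOOR)
        lambdas = np.geomspace(lam_max, lam_max * min_ratio, n_lambda)
        return LambdaPath(alpha=alpha, lambdas=lambdas, n_lambda=n_lambda,
                          min_ratio=min_ratio)

    def _path_coefs(self, Xs, Yc, alpha, lambdas, tol=None):
        """Fit a descending lambda path with warm starts; returns a
        (n_lambda, p, K) stack of standardized-scale coefficients."""
        n = Xs.shape[0]
        p = Xs.shape[1]
        K = Yc.shape[1]
        out = np.empty((len(lambdas), p, K))
        G = Xs.T @ Xs / n
        C = Xs.T @ Yc / n
        if alpha == 0.0:
            # ridge path via one eigendecomposition of the Gram matrix
            evals, Q = np.linalg.eigh(G)
            QtC = Q.T @ C
            for i, lam in enumerate(lambdas):
                out[i] = Q @ (QtC / (evals + lam)[:, None])
            return out
        warm = None
        for i, lam in enumerate(lambdas):
            warm = _solver.cd_solve(G, C, lam, alpha, B0=warm,
                                    tol=self.tol if tol is None else tol)
            out[i] = warm
        return out

    def fit_cv(
        self,
        alphas: Sequence[float] = DEFAULT_ALPHAS,
        k: int = 10,
        seed: int = 0,
        n_lambda: int = 100,
        min_ratio: Optional[float] = None,
    ) -> "CompositionResults":
        """Tune (alpha, lambda) by k-fold cross-validated MSE and refit.

        One random fold assignment is drawn once and shared across the
        whole alpha grid, so the comparison between alphas is paired. The
        selection criterion is the mean squared prediction error pooled
        over all cell types; ties break toward the smallest lambda, then
        the largest alpha (the sparser-path convention).
        """
        n = len(self.sample_ids)
        if k > n:
            raise ConfigError(f"k = {k} folds exceed n = {n} samples")
        if k < 2:
            raise ConfigError("need at least 2 folds")
        rng = np.random.default_rng(seed)
        folds = _kfold_indices(n, k, rng)
        rows_all = np.arange(n)

        records = []
        for alpha in alphas:
            path = self.lambda_path(alpha, n_lambda=n_lambda, min_ratio=min_ratio)
            fold_mse = np.empty((k, len(path.lambdas)))
            for f, test_idx in enumerate(folds):
                train_idx = np.setdiff1d(rows_all, test_idx)
                Xs, Yc, x_mean, y_mean, scale, _ = self._prepare(train_idx)
                coefs = self._path_coefs(Xs, Yc, alpha, path.lambdas,
                                         tol=self.cv_tol)
                X_test = self.design[test_idx]
                Y_test = self.responses[test_idx]
                Xt = (X_test - x_mean) / scale
                for i in range(len(path.lambdas)):
                    pred = y_mean + Xt @ coefs[i]
                    fold_mse[f, i] = float(np.mean((pred - Y_test) ** 2))
            mean_mse = fold_mse.mean(axis=0)
            se_mse = fold_mse.std(axis=0, ddof=1) / np.sqrt(k)
            for lam, m, s in zip(path.lambdas, mean_mse, se_mse):
                records.append({"alpha": float(alpha), "lam": float(lam),
                                "mean_mse": float(m), "se_mse": float(s)})

        grid = pd.DataFrame.from_records(records)
        best = grid["mean_mse"].min()
        cand = grid[grid["mean_mse"] <= best].copy()
        cand = cand.sort_values(["lam", "alpha"], ascending=[True, False])
        chosen = cand.iloc[0]
        tuning = TuningResult(grid=grid, chosen_alpha=float(chosen["alpha"]),
                              chosen_lambda=float(chosen["lam"]), k=k, seed=seed)
        logger.info(
            "tuned model: alpha=%.3g lambda=%.6g (CV MSE %.6g)",
            tuning.chosen_alpha, tuning.chosen_lambda, best,
        )
        Xs, Yc, x_mean, y_mean, scale, _ = self._prepare()
        B = self._solve(Xs, Yc, tuning.chosen_alpha, tuning.chosen_lambda,
                        tol=self.tol)
        return self._results(
            B, scale, x_mean, y_mean, tuning.chosen_alpha, tuning.chosen_lambda,
            extra_meta={"cv_k": k, "cv_seed": seed, "cv_mse": float(best)},
            tuning=tuning,
        )


@dataclass
class CompositionResults:
    """Fitted composition predictor.

    Holds per-cell-type intercepts, the (features x cell types)
    coefficient matrix on the original log2-expression scale, the penalty
    setting it was fit at, and free-form training provenance. Row sparsity
    of ``coefficients`` identifies the retained (composition-informative)
    features.
    """

    feature_ids: List[str]
    cell_types: List[str]
    intercepts: np.ndarray
    coefficients: np.ndarray
    alpha: float
    lam: float
    training_meta: Dict = field(default_factory=dict)
    tuning: Optional[TuningResult] = None
    model: Optional[CompositionModel] = None

    def __post_init__(self):
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError(f"alpha must lie in [0, 1]; got {self.alpha}")
        if self.lam < 0:
            raise ValidationError(f"lambda must be non-negative; got {self.lam}")
        p, K = len(self.feature_ids), len(self.cell_types)
        if self.coefficients.shape != (p, K) or self.intercepts.shape != (K,):
            raise ValidationError("coefficient/intercept shapes do not match ids")

    # ------------------------------------------------------------------ #

    @property
    def retained_mask(self) -> np.ndarray:
        return np.any(self.coefficients != 0.0, axis=1)

    @property
    def retained_features(self) -> List[str]:
        """Features with a nonzero coefficient row (selected jointly for
        all cell types by the group penalty)."""
        return [f for f, m in zip(self.feature_ids, self.retained_mask) if m]

    @property
    def n_retained(self) -> int:
        return int(self.retained_mask.sum())

    def predict(self, X: ExpressionMatrix, postprocess: str = "raw") -> CompositionMatrix:
        """Predict composition for new samples.

        ``postprocess='raw'`` returns the untouched linear predictions
        (they may exit [0, 1]); ``'clip'`` truncates to [0, 1];
        ``'clip_renorm'`` additionally renormalizes each row to sum 1.
        """
        if postprocess not in ("raw", "clip", "clip_renorm"):
            raise ValidationError(f"unknown postprocess {postprocess!r}")
        missing = [f for f in self.feature_ids if f not in set(X.feature_ids)]
        if missing:
            raise MissingFeatureError(missing)
        Xs = X.subset_features(self.feature_ids)
        pred = self.intercepts + Xs.values.T @ self.coefficients  # n x K
        closed = False
        if postprocess in ("clip", "clip_renorm"):
            pred = np.clip(pred, 0.0, 1.0)
        if postprocess == "clip_renorm":
            sums = pred.sum(axis=1, keepdims=True)
            degenerate = sums[:, 0] == 0
            if np.any(degenerate):
                logger.warning("%d all-zero prediction row(s) set to uniform",
                               int(degenerate.sum()))
                pred[degenerate] = 1.0 / len(self.cell_types)
                sums = pred.sum(axis=1, keepdims=True)
            pred = pred / sums
            closed = True
        if postprocess == "raw":
            # uncalibrated predictions may exit [0, 1]; skip range checks
            return CompositionMatrix.unchecked(list(X.sample_ids),
                                               list(self.cell_types), pred)
        return CompositionMatrix(list(X.sample_ids), list(self.cell_types),
                                 pred, closed)

    def markers(self, min_abs_coef: float = 0.0, top_k: Optional[int] = None):
        """Marker genes derived from the coefficient rows; see
        :func:`bloodmix.spv.extract_markers`."""
        from .spv import extract_markers

        return extract_markers(self, min_abs_coef=min_abs_coef, top_k=top_k)

    def save(self, path) -> None:
        from .io import write_model

        write_model(self, path)

    @classmethod
    def load(cls, path) -> "CompositionResults":
        from .io import read_model

        return read_model(path)

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = [
            "Multi-task elastic net composition model",
            "=" * 46,
            f"cell types:         {', '.join(self.cell_types)}",
            f"features (total):   {len(self.feature_ids)}",
            f"features (retained):{self.n_retained:>6}",
            f"alpha:              {self.alpha:.4g}",
            f"lambda:             {self.lam:.6g}",
        ]
        if "cv_mse" in self.training_meta:
            lines.append(f"CV mean MSE:        {self.training_meta['cv_mse']:.6g}")
        lines.append("-" * 46)
        lines.append(f"{'cell type':<10}{'intercept':>12}{'max |coef|':>14}")
        for k, ct in enumerate(self.cell_types):
            mx = float(np.max(np.abs(self.coefficients[:, k]))) if len(self.feature_ids) else 0.0
            lines.append(f"{ct:<10}{self.intercepts[k]:>12.4f}{mx:>14.4g}")
        return "\n".join(lines)
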