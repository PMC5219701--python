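"""Reference-based deconvolution: solve X = H w per sample.

Given a basis matrix H of linear-scale cell-type signatures, each bulk
sample's composition w is recovered by regression. Methods:

``nnls``
    argmin ||x - H w||_2 subject to w >= 0 (default; well-posed and the
    standard choice).
``iterative_prune``
    unconstrained least squares, repeatedly dropping the most-negative
    coefficient and refitting until all remaining coefficients are
    non-negative; pruned cell types are reported as 0. This is the classic
    signature-regression procedure used by early microarray deconvolution
    work.
``ols``
    one unconstrained least-squares fit, diagnostic only (coefficients may
    be negative).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .core import BasisMatrix, CompositionMatrix, ExpressionMatrix
from .errors import AlignmentError, InsufficientSignatureError, ValidationError

logger = logging.getLogger(__name__)

_METHODS = ("nnls", "iterative_prune", "ols")


@dataclass
class CompositionSolution:
    """Solution for one sample: proportion vector plus a degeneracy flag
    (set when the raw solution was identically zero and could not be
    normalized)."""

    proportions: np.ndarray
    degenerate: bool = False


def _ols(H: np.ndarray, x: np.ndarray) -> np.ndarray:
    w, _, rank, _ = np.linalg.lstsq(H, x, rcond=None)
    if rank < H.shape[1]:
        warnings.warn(
            f"basis matrix is rank-deficient (rank {rank} < {H.shape[1]}); "
            "unconstrained solution is not unique",
            RuntimeWarning,
            stacklevel=3,
        )
    return w


def _iterative_prune(H: np.ndarray, x: np.ndarray) -> np.ndarray:
    K = H.shape[1]
    active = list(range(K))
    w = np.zeros(K)
    while active:
        sub, *_ = np.linalg.lstsq(H[:, active], x, rcond=None)
        if np.all(sub >= 0):
            w[:] = 0.0
            w[active] = sub
            return w
        active.pop(int(np.argmin(sub)))
    return np.zeros(K)


def solve_composition(
    x: np.ndarray,
    H: BasisMatrix,
    method: str = "nnls",
    normalize: bool = True,
) -> CompositionSolution:
    """Estimate one sample's cell-type proportions from its linear-scale
    expression vector, aligned to ``H.feature_ids``.

    With ``normalize`` the solution is rescaled to sum to one (unless it
    is identically zero, in which case zeros are returned with the
    ``degenerate`` flag set).
    """
    if method not in _METHODS:
        raise ValidationError(f"unknown method {method!r}")
    x = np.asarray(x, dtype=float)
    if x.shape != (H.n_features,):
        raise AlignmentError(
            f"expression vector length {x.shape} does not match basis "
            f"features ({H.n_features})"
        )
    A = H.values
    if method == "nnls":
        w, _ = _scipy_nnls(A, x)
    elif method == "iterative_prune":
        w = _iterative_prune(A, x)
    else:
        w = _ols(A, x)
    total = float(w.sum())
    degenerate = False
    if normalize:
        if total > 0:
            w = w / total
        else:
            degenerate = True
            w = np.zeros_like(w)
    return CompositionSolution(proportions=w, degenerate=degenerate)


def deconvolve_matrix(
    X: ExpressionMatrix,
    H: BasisMatrix,
    method: str = "nnls",
    unlog: bool = True,
    normalize: bool = True,
) -> CompositionMatrix:
    """Deconvolve every sample of a bulk matrix against a basis.

    Features are intersected by exact identifier match (order taken from
    the basis); the intersection must be at least the number of cell
    types. Log2-tagged input is converted to the linear scale first when
    ``unlog`` is set, since the mixture equation is linear in expression.
    """
    shared = [f for f in H.feature_ids if f in set(X.feature_ids)]
    K = len(H.cell_types)
    if len(shared) < K:
        raise InsufficientSignatureError(
            f"only {len(shared)} shared feature(s) between expression and "
            f"basis; need at least {K}"
        )
    logger.info("deconvolving on %d shared features (%d cell types)",
                len(shared), K)
    Hs = H.subset_features(shared)
    Xs = X.subset_features(shared)
    if unlog and Xs.scale_tag == "log2":
        Xs = Xs.to_linear()
    W = np.empty((Xs.n_samples, K))
    n_degenerate = 0
    for i in range(Xs.n_samples):
        sol = solve_composition(Xs.values[:, i], Hs, method=method,
                                normalize=normalize)
        W[i] = sol.proportions
        n_degenerate += sol.degenerate
    if n_degenerate:
        logger.warning("%d sample(s) had degenerate all-zero solutions",
                       n_degenerate)
    if normalize and n_degenerate == 0 and method != "ols":
        return CompositionMatrix(list(Xs.sample_ids), list(H.cell_types), W,
                                 closed=True)
    return CompositionMatrix.unchecked(list(Xs.sample_ids), list(H.cell_types), W)
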