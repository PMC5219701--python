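"""Performance estimation for composition predictors.

Implements the metrics and resampling harness used to characterize
out-of-sample performance: per-cell-type RMSE and Pearson/Spearman
correlation, repeated k-fold cross-validation with fold-level summaries
(mean +/- sd over repeats x folds), lymphocyte-sum aggregation for
comparison against differential counts that do not resolve lymphocyte
subsets, and one-way ANOVA validation of marker genes on replicate
isolated-cell profiles with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CompositionMatrix, ExpressionMatrix, MarkerGeneSet
from .errors import ConfigError, UndefinedCorrelationError, ValidationError

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

#: lymphocyte subsets summed into the aggregate "Lymph" column
LYMPHOCYTE_TYPES = ("Bcell", "CD4T", "CD8T", "NK")


def rmse(pred: Sequence[float], truth: Sequence[float]) -> float:
    """Root-mean-square error between two equal-length vectors."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1 or pred.size == 0:
        raise ValidationError(
            f"rmse needs equal-length non-empty vectors; got {pred.shape} "
            f"and {truth.shape}"
        )
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def _check_corr_inputs(pred, truth):
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValidationError("correlation needs equal-length vectors")
    if pred.size < 3:
        raise ValidationError("correlation needs at least 3 observations")
    if np.ptp(pred) == 0 or np.ptp(truth) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined for a constant vector"
        )
    return pred, truth


def pearson(pred: Sequence[float], truth: Sequence[float]) -> float:
    """Pearson product-moment correlation; raises
    :class:`UndefinedCorrelationError` on constant input rather than
    returning NaN silently."""
    pred, truth = _check_corr_inputs(pred, truth)
    return float(stats.pearsonr(pred, truth).statistic)


def spearman(pred: Sequence[float], truth: Sequence[float]) -> float:
    """Spearman rank correlation with the same constant-input contract."""
    pred, truth = _check_corr_inputs(pred, truth)
    return float(stats.spearmanr(pred, truth).statistic)


def aggregate_lymphocytes(W: CompositionMatrix) -> CompositionMatrix:
    """Append a "Lymph" column equal to Bcell + CD4T + CD8T + NK.

    Differential counts report total lymphocytes only, so predicted
    lymphocyte subsets are summed before comparison. Original columns are
    preserved.
    """
    missing = [ct for ct in LYMPHOCYTE_TYPES if ct not in W.cell_types]
    if missing:
        raise ValidationError(
            f"cannot aggregate lymphocytes; missing column(s): {', '.join(missing)}"
        )
    if "Lymph" in W.cell_types:
        raise ValidationError("composition already has a 'Lymph' column")
    lymph = np.zeros(W.n_samples)
    for ct in LYMPHOCYTE_TYPES:
        lymph += W.column(ct)
    values = np.column_stack([W.values, lymph])
    return CompositionMatrix.unchecked(list(W.sample_ids),
                                       list(W.cell_types) + ["Lymph"], values)


@dataclass
class EvaluationReport:
    """Fold-level cross-validation metrics.

    ``entries`` has one row per (repeat, fold, cell type) with RMSE and
    Pearson r; correlations undefined on a fold (constant truth or
    prediction, or fewer than 3 test samples) are flagged and excluded
    from the r summary, with the exclusion count reported.
    """

    entries: pd.DataFrame
    k: int
    repeats: int
    seed: int
    pooled: pd.DataFrame = field(default=None)

    def summary(self) -> pd.DataFrame:
        """Mean +/- sd per cell type over the repeats x folds values."""
        g = self.entries.groupby("cell_type", sort=False)
        out = pd.DataFrame({
            "rmse_mean": g["rmse"].mean(),
            "rmse_sd": g["rmse"].std(ddof=1),
            "pearson_mean": g.apply(
                lambda d: d.loc[d["pearson_defined"], "pearson"].mean(),
                include_groups=False),
            "pearson_sd": g.apply(
                lambda d: d.loc[d["pearson_defined"], "pearson"].std(ddof=1),
                include_groups=False),
            "n_undefined_r": g["pearson_defined"].apply(lambda s: int((~s).sum())),
        })
        return out

    def to_json(self, path) -> None:
        doc = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "k": self.k,
            "repeats": self.repeats,
            "seed": self.seed,
            "entries": self.entries.to_dict(orient="records"),
            "summary": self.summary().reset_index().to_dict(orient="records"),
            "pooled": (self.pooled.reset_index().to_dict(orient="records")
                       if self.pooled is not None else None),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)


def repeated_kfold_cv(
    X: ExpressionMatrix,
    Y: CompositionMatrix,
    trainer: Callable[[ExpressionMatrix, CompositionMatrix], object],
    k: int = 10,
    repeats: int = 20,
    seed: int = 0,
) -> EvaluationReport:
    """Repeated k-fold cross-validation of a composition predictor.

    ``trainer(X_train, Y_train)`` must return an object with a
    ``predict(X_test)`` method yielding a CompositionMatrix. Each repeat
    draws a fresh seeded partition; every sample is tested exactly once
    per repeat. Metrics are computed per left-out fold and per cell type;
    summaries are mean +/- sd over the repeats x k fold-level values.
    Pooled-prediction metrics (over each sample's ``repeats`` held-out
    predictions) are also emitted for transparency.
    """
    n = X.n_samples
    if k > n:
        raise ConfigError(f"k = {k} exceeds n = {n}")
    if set(X.sample_ids) != set(Y.sample_ids):
        raise ValidationError("expression and labels carry different samples")
    Y = CompositionMatrix(list(Y.sample_ids), list(Y.cell_types), Y.values,
                          closed=False)
    y_order = [Y.sample_ids.index(s) for s in X.sample_ids]
    truth = Y.values[y_order]

    rng = np.random.default_rng(seed)
    rows = []
    pooled_pred = np.zeros((repeats, n, len(Y.cell_types)))
    for rep in range(repeats):
        perm = rng.permutation(n)
        folds = [np.sort(part) for part in np.array_split(perm, k)]
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            X_train = _subset_samples(X, train_idx)
            Y_train = CompositionMatrix(
                [X.sample_ids[i] for i in train_idx], list(Y.cell_types),
                truth[train_idx], closed=False)
            fitted = trainer(X_train, Y_train)
            X_test = _subset_samples(X, test_idx)
            pred_cm = fitted.predict(X_test)
            pred = np.asarray(pred_cm.values, dtype=float)
            pooled_pred[rep, test_idx] = pred
            for c, ct in enumerate(Y.cell_types):
                fold_rmse = rmse(pred[:, c], truth[test_idx, c])
                try:
                    fold_r = pearson(pred[:, c], truth[test_idx, c])
                    defined = True
                except (UndefinedCorrelationError, ValidationError):
                    fold_r = np.nan
                    defined = False
                rows.append({"repeat": rep, "fold": f, "cell_type": ct,
                             "rmse": fold_rmse, "pearson": fold_r,
                             "pearson_defined": defined})
    entries = pd.DataFrame(rows)
    n_undef = int((~entries["pearson_defined"]).sum())
    if n_undef:
        logger.warning("%d fold-level correlation(s) undefined and excluded "
                       "from the r summary", n_undef)
    pooled_rows = []
    flat_pred = pooled_pred.reshape(repeats * n, -1)
    flat_truth = np.tile(truth, (repeats, 1))
    for c, ct in enumerate(Y.cell_types):
        try:
            r = pearson(flat_pred[:, c], flat_truth[:, c])
        except (UndefinedCorrelationError, ValidationError):
            r = np.nan
        pooled_rows.append({"cell_type": ct,
                            "rmse": rmse(flat_pred[:, c], flat_truth[:, c]),
                            "pearson": r})
    pooled = pd.DataFrame(pooled_rows).set_index("cell_type")
    return EvaluationReport(entries=entries, k=k, repeats=repeats, seed=seed,
                            pooled=pooled)


def _subset_samples(X: ExpressionMatrix, idx: np.ndarray) -> ExpressionMatrix:
    return ExpressionMatrix(list(X.feature_ids),
                            [X.sample_ids[i] for i in idx],
                            X.values[:, idx], X.scale_tag)


@dataclass
class MarkerAnovaResult:
    """Per-marker one-way ANOVA across isolated cell-type groups."""

    table: pd.DataFrame  # feature_id, cell_type, pvalue, p_adjusted, significant, degenerate
    alpha_level: float

    @property
    def significant_fraction(self) -> float:
        if not len(self.table):
            return 0.0
        return float(self.table["significant"].mean())

    @property
    def significant_markers(self) -> List[str]:
        return list(self.table.loc[self.table["significant"], "feature_id"])


def marker_anova(
    X_ref: ExpressionMatrix,
    labels: Sequence[str],
    markers: MarkerGeneSet,
    alpha_level: float = 0.05,
    method: str = "fdr_bh",
) -> MarkerAnovaResult:
    """Validate markers on replicate isolated-cell profiles.

    Each marker gene is tested for variation across cell-type groups by
    one-way ANOVA; p-values are adjusted across all tested markers
    (Benjamini-Hochberg by default). Groups with a single replicate are
    excluded with a warning. Genes constant across all samples have an
    undefined F statistic and are reported non-significant with the
    ``degenerate`` flag.
    """
    labels = list(labels)
    if len(labels) != X_ref.n_samples:
        raise ValidationError("labels length must match number of samples")
    groups: Dict[str, List[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    usable = {g: idx for g, idx in groups.items() if len(idx) >= 2}
    dropped = set(groups) - set(usable)
    if dropped:
        warnings.warn(
            f"group(s) with a single replicate excluded from ANOVA: "
            f"{', '.join(sorted(dropped))}", UserWarning, stacklevel=2)
    if len(usable) < 2:
        raise ValidationError("ANOVA needs at least 2 groups with >= 2 replicates")

    present = set(X_ref.feature_ids)
    feat_type = [(f, ct) for ct in markers.cell_types for f in markers[ct]
                 if f in present]
    if not feat_type:
        raise ValidationError("no marker present in the reference matrix")
    row_of = {f: i for i, f in enumerate(X_ref.feature_ids)}
    pvals, degenerate = [], []
    for f, _ in feat_type:
        vals = X_ref.values[row_of[f]]
        samples = [vals[idx] for idx in usable.values()]
        if np.ptp(np.concatenate(samples)) == 0:
            pvals.append(1.0)
            degenerate.append(True)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat = stats.f_oneway(*samples)
        p = float(stat.pvalue)
        if not np.isfinite(p):
            p, deg = 1.0, True
        else:
            deg = False
        pvals.append(p)
        degenerate.append(deg)
    reject, p_adj, *_ = multipletests(pvals, alpha=alpha_level, method=method)
    table = pd.DataFrame({
        "feature_id": [f for f, _ in feat_type],
        "cell_type": [ct for _, ct in feat_type],
        "pvalue": pvals,
        "p_adjusted": p_adj,
        "significant": reject & ~np.asarray(degenerate),
        "degenerate": degenerate,
    })
    return MarkerAnovaResult(table=table, alpha_level=alpha_level)
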