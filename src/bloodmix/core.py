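"""Domain containers for bulk-blood composition estimation.

The linear mixture model underlying everything here is

    X[j, i] = sum_k W[i, k] * H[j, k] + e[j, i]

on the linear expression scale: the bulk expression of gene ``j`` in sample
``i`` is the composition-weighted sum of the cell-type signatures ``H`` plus
residual variation not attributable to composition. The containers below
hold the three matrices (bulk expression ``X``, composition ``W``, basis
``H``) together with their identifiers, and enforce the invariants the rest
of the package relies on.

All matrices are dense float64 numpy arrays; identifier bookkeeping uses
plain Python lists so that error messages can name offending ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import EmptyFeatureSetError, ValidationError

#: Canonical leukocyte panel: granulocytes, monocytes, B cells, CD4+ T
#: cells, CD8+ T cells and natural-killer cells.
DEFAULT_CELL_TYPES: Tuple[str, ...] = ("Gran", "Mono", "Bcell", "CD4T", "CD8T", "NK")

#: Default low-expression threshold in log2 units.
DEFAULT_EXPRESSION_THRESHOLD: float = 5.5


def _check_unique(ids: Sequence[str], what: str) -> List[str]:
    ids = [str(i) for i in ids]
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)
    return ids


def _as_matrix(values, n_rows: int, n_cols: int, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape != (n_rows, n_cols):
        raise ValidationError(
            f"{what} values must have shape ({n_rows}, {n_cols}); got {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{what} values must be finite")
    return arr


@dataclass
class ExpressionMatrix:
    """Bulk expression, features x samples.

    ``scale_tag`` records whether values are log2 (the working scale for
    model training) or linear (the scale on which mixing is physical).
    """

    feature_ids: List[str]
    sample_ids: List[str]
    values: np.ndarray
    scale_tag: str = "log2"

    def __post_init__(self):
        self.feature_ids = _check_unique(self.feature_ids, "feature")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.values = _as_matrix(
            self.values, len(self.feature_ids), len(self.sample_ids), "expression"
        )
        if self.scale_tag not in ("log2", "linear"):
            raise ValidationError(f"unknown scale_tag {self.scale_tag!r}")
        if self.scale_tag == "linear" and np.any(self.values < 0):
            raise ValidationError("linear-scale expression must be non-negative")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_features(self, ids: Sequence[str]) -> "ExpressionMatrix":
        index = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [index[i] for i in ids]
        return ExpressionMatrix(list(ids), list(self.sample_ids),
                                self.values[rows], self.scale_tag)

    def to_linear(self) -> "ExpressionMatrix":
        """Return a linear-scale copy (2**x if currently log2-tagged)."""
        if self.scale_tag == "linear":
            return ExpressionMatrix(list(self.feature_ids), list(self.sample_ids),
                                    self.values.copy(), "linear")
        return ExpressionMatrix(list(self.feature_ids), list(self.sample_ids),
                                np.exp2(self.values), "linear")


@dataclass
class CompositionMatrix:
    """Cell-type proportions, samples x cell types.

    Entries are unitless proportions in [0, 1]; when ``closed`` each row
    sums to one (a closed composition over the measured panel).
    """

    sample_ids: List[str]
    cell_types: List[str]
    values: np.ndarray
    closed: bool = False

    #: tolerance on the [0, 1] range check
    _RANGE_TOL = 1e-9
    #: tolerance on row closure
    _SUM_TOL = 1e-6

    def __post_init__(self):
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.cell_types = _check_unique(self.cell_types, "cell type")
        self.values = _as_matrix(
            self.values, len(self.sample_ids), len(self.cell_types), "composition"
        )
        if np.any(self.values < -self._RANGE_TOL) or np.any(self.values > 1 + self._RANGE_TOL):
            bad = self.values[(self.values < -self._RANGE_TOL) | (self.values > 1 + self._RANGE_TOL)]
            raise ValidationError(
                f"composition entries must lie in [0, 1]; found {bad.flat[0]:.6g}"
            )
        if self.closed:
            sums = self.values.sum(axis=1)
            off = np.abs(sums - 1.0) > self._SUM_TOL
            if np.any(off):
                i = int(np.flatnonzero(off)[0])
                raise ValidationError(
                    f"closed composition row {self.sample_ids[i]!r} sums to "
                    f"{sums[i]:.6g}, not 1"
                )

    @classmethod
    def unchecked(cls, sample_ids, cell_types, values) -> "CompositionMatrix":
        """Build without range validation.

        Raw (uncalibrated) model predictions may exit [0, 1]; this
        constructor lets them travel in the same container. Identifier
        uniqueness is still enforced.
        """
        obj = cls.__new__(cls)
        obj.sample_ids = _check_unique(sample_ids, "sample")
        obj.cell_types = _check_unique(cell_types, "cell type")
        obj.values = _as_matrix(values, len(obj.sample_ids), len(obj.cell_types),
                                "composition")
        obj.closed = False
        return obj

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, cell_type: str) -> np.ndarray:
        try:
            k = self.cell_types.index(cell_type)
        except ValueError:
            raise ValidationError(f"unknown cell type {cell_type!r}") from None
        return self.values[:, k]

    def reorder_types(self, cell_types: Sequence[str]) -> "CompositionMatrix":
        idx = [self.cell_types.index(c) for c in cell_types]
        return CompositionMatrix(list(self.sample_ids), list(cell_types),
                                 self.values[:, idx], self.closed)


@dataclass
class BasisMatrix:
    """Cell-type signature expression, features x cell types, linear scale."""

    feature_ids: List[str]
    cell_types: List[str]
    values: np.ndarray

    def __post_init__(self):
        self.feature_ids = _check_unique(self.feature_ids, "feature")
        self.cell_types = _check_unique(self.cell_types, "cell type")
        self.values = _as_matrix(
            self.values, len(self.feature_ids), len(self.cell_types), "basis"
        )
        if np.any(self.values < 0):
            raise ValidationError("basis values must be non-negative (linear scale)")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def subset_features(self, ids: Sequence[str]) -> "BasisMatrix":
        index = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [index[i] for i in ids]
        return BasisMatrix(list(ids), list(self.cell_types), self.values[rows])


@dataclass
class MarkerGeneSet:
    """Cell type -> ordered marker feature ids.

    A marker gene's bulk expression tracks one cell type's abundance; each
    feature belongs to at most one cell type (the sets partition the
    selected features).
    """

    markers: Dict[str, List[str]]
    provenance: str = "external"

    def __post_init__(self):
        if self.provenance not in ("model_coefficients", "external"):
            raise ValidationError(f"unknown provenance {self.provenance!r}")
        assigned = {}
        for ct, feats in self.markers.items():
            if not feats:
                raise ValidationError(f"marker list for {ct!r} is empty")
            for f in feats:
                if f in assigned:
                    raise ValidationError(
                        f"feature {f!r} assigned to both {assigned[f]!r} and {ct!r}"
                    )
                assigned[f] = ct
        self.markers = {ct: [str(f) for f in feats] for ct, feats in self.markers.items()}

    @property
    def cell_types(self) -> List[str]:
        return list(self.markers)

    def all_features(self) -> List[str]:
        return [f for feats in self.markers.values() for f in feats]

    def __getitem__(self, cell_type: str) -> List[str]:
        return self.markers[cell_type]


_AGGREGATIONS = {"min": np.min, "max": np.max, "mean": np.mean}


def filter_low_expression(
    X: ExpressionMatrix,
    threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
    aggregation: str = "min",
) -> Tuple[ExpressionMatrix, List[str]]:
    """Drop features whose aggregated log2 expression falls below a floor.

    Features with aggregated (default: minimum over samples) log2
    expression below ``threshold`` carry little reliable signal on
    microarray-like data and are excluded before model training. Returns
    the surviving matrix and the list of excluded feature ids.
    """
    if X.scale_tag != "log2":
        raise ValidationError("low-expression filter expects a log2-scale matrix")
    if aggregation not in _AGGREGATIONS:
        raise ValidationError(f"unknown aggregation {aggregation!r}")
    agg = _AGGREGATIONS[aggregation](X.values, axis=1)
    keep = agg >= threshold
    if not np.any(keep):
        raise EmptyFeatureSetError(
            f"all {X.n_features} features fall below threshold {threshold}"
        )
    excluded = [f for f, k in zip(X.feature_ids, keep) if not k]
    kept = ExpressionMatrix(
        [f for f, k in zip(X.feature_ids, keep) if k],
        list(X.sample_ids),
        X.values[keep],
        X.scale_tag,
    )
    return kept, excluded
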