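"""Reference-free composition tracking via marker-gene eigengenes.

Two steps: (1) derive per-cell-type marker genes from a fitted model's
coefficient rows — each retained feature is assigned to the cell type with
the largest absolute coefficient in its row; (2) summarize each cell
type's markers in a new bulk dataset by eigengene summarization: z-score
every marker across samples and take the first left singular vector of
the samples x markers submatrix. The resulting per-sample scores —
surrogate proportion variables (SPVs) — track the cell type's mixing
proportion without requiring a basis matrix, so they transfer across
measurement platforms where signature matrices do not.

SPV columns carry singular-vector scale (unit l2 norm), not calibrated
proportions; their sign is fixed so each correlates non-negatively with
the mean standardized marker expression.

Note: the full CellCODE-style procedure additionally residualizes markers
against global expression structure before the SVD; this implementation
deliberately keeps the plain eigengene summarization and exposes the
residualization as a possible extension point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from .core import ExpressionMatrix, MarkerGeneSet
from .errors import EmptyMarkerError, ValidationError
from .model import CompositionResults

logger = logging.getLogger(__name__)


@dataclass
class SPVMatrix:
    """Surrogate proportion variables, samples x cell types (unitless)."""

    sample_ids: List[str]
    cell_types: List[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.cell_types)):
            raise ValidationError("SPV shape does not match identifier lists")

    def column(self, cell_type: str) -> np.ndarray:
        return self.values[:, self.cell_types.index(cell_type)]


def extract_markers(
    results: CompositionResults,
    min_abs_coef: float = 0.0,
    top_k: Optional[int] = None,
) -> MarkerGeneSet:
    """Assign each retained model feature to one cell type by its largest
    absolute coefficient.

    When the model was fit with internal standardization, coefficients
    are compared on the standardized scale (coefficient x feature sd) so
    that features of different dynamic range are ranked comparably; the
    reported coefficients themselves stay on the original scale. Exact
    ties go to the earlier cell type in the model's canonical order (and
    are logged). Per cell type, features are ordered by (|coefficient|
    descending, feature id ascending); ``top_k`` keeps the strongest k.
    """
    if min_abs_coef < 0:
        raise ValidationError("min_abs_coef must be non-negative")
    coefs = results.coefficients
    scale = np.ones(len(results.feature_ids))
    if results.training_meta.get("standardize") and \
            "feature_scale" in results.training_meta:
        scale = np.asarray(results.training_meta["feature_scale"], dtype=float)
    weighted = np.abs(coefs) * scale[:, None]

    per_type: Dict[str, List] = {ct: [] for ct in results.cell_types}
    n_ties = 0
    for j, fid in enumerate(results.feature_ids):
        row = weighted[j]
        best = float(row.max())
        if best == 0.0 or best <= min_abs_coef:
            continue
        winners = np.flatnonzero(row == best)
        if len(winners) > 1:
            n_ties += 1
        k = int(winners[0])  # earlier cell type in canonical order wins
        per_type[results.cell_types[k]].append((best, fid))
    if n_ties:
        logger.info("%d tied coefficient row(s) resolved by canonical cell-type order",
                    n_ties)
    markers: Dict[str, List[str]] = {}
    for ct, entries in per_type.items():
        if not entries:
            continue
        entries.sort(key=lambda e: (-e[0], e[1]))
        if top_k is not None:
            entries = entries[:top_k]
        markers[ct] = [fid for _, fid in entries]
    if not markers:
        raise EmptyMarkerError(
            f"no feature passed min_abs_coef = {min_abs_coef}"
        )
    return MarkerGeneSet(markers, provenance="model_coefficients")


def compute_spv(X: ExpressionMatrix, markers: MarkerGeneSet) -> SPVMatrix:
    """Eigengene-summarize each cell type's markers into one SPV.

    Per cell type: subset ``X`` to the markers present (absent markers are
    dropped with a warning; fewer than 2 survivors is an error), z-score
    each marker across samples, and take the first left singular vector
    of the samples x markers submatrix, sign-fixed to correlate
    non-negatively with the mean standardized marker expression.
    """
    if X.n_samples < 3:
        raise ValidationError("SPV computation needs at least 3 samples")
    present = set(X.feature_ids)
    values = np.empty((X.n_samples, len(markers.cell_types)))
    for k, ct in enumerate(markers.cell_types):
        feats = [f for f in markers[ct] if f in present]
        dropped = len(markers[ct]) - len(feats)
        if dropped:
            logger.warning("%s: %d marker(s) absent from expression matrix, dropped",
                           ct, dropped)
        sub = X.subset_features(feats).values.T if feats else np.empty((X.n_samples, 0))
        sd = sub.std(axis=0)
        keep = sd > 0
        if int(keep.sum()) < len(feats):
            logger.warning("%s: %d constant marker(s) dropped", ct,
                           len(feats) - int(keep.sum()))
        sub = sub[:, keep]
        if sub.shape[1] < 2:
            raise ValidationError(
                f"cell type {ct!r} has {sub.shape[1]} usable marker(s) in the "
                "expression matrix; need at least 2"
            )
        Z = (sub - sub.mean(axis=0)) / sub.std(axis=0)
        U, s, _ = np.linalg.svd(Z, full_matrices=False)
        spv = U[:, 0]
        mean_marker = Z.mean(axis=1)
        if float(spv @ (mean_marker - mean_marker.mean())) < 0:
            spv = -spv
        values[:, k] = spv
    return SPVMatrix(list(X.sample_ids), list(markers.cell_types), values)


def compare_marker_sets(a: MarkerGeneSet, b: MarkerGeneSet) -> Dict[str, Dict[str, float]]:
    """Per-cell-type overlap between two marker sets.

    Returns, for every cell type present in either set, the sizes of both
    lists, the intersection count, and the Jaccard index (0 when both are
    empty for that type). Symmetric in its arguments.
    """
    out: Dict[str, Dict[str, float]] = {}
    for ct in sorted(set(a.cell_types) | set(b.cell_types)):
        sa = set(a.markers.get(ct, []))
        sb = set(b.markers.get(ct, []))
        inter = len(sa & sb)
        union = len(sa | sb)
        out[ct] = {
            "size_a": len(sa),
            "size_b": len(sb),
            "overlap": inter,
            "jaccard": inter / union if union else 0.0,
        }
    return out
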