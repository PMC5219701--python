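"""Delimited-text and JSON I/O for the domain containers.

Conventions: tab-separated values, UTF-8, one header row, one identifier
column. Expression and basis files are features-as-rows (identifier column
``feature_id``); composition files are samples-as-rows (identifier column
``sample_id``). Floats are written with 17 significant digits, which
round-trips IEEE doubles exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Tuple, Union

import numpy as np
import pandas as pd

from .core import BasisMatrix, CompositionMatrix, ExpressionMatrix, MarkerGeneSet
from .errors import FormatError, ParseError, ValidationError

PathLike = Union[str, Path]

# shortest round-trip representation (Python repr); exact under the
# numpy parser used on the way back in
def _FLOAT_FMT(v) -> str:
    return repr(float(v))


def _read_table(path: PathLike, id_name: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # malformed beyond repair
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate {id_name} identifier in {path}: {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"duplicate column identifier in {path}: {dup!r}")
    return df


def _to_numeric(df: pd.DataFrame, path: PathLike) -> np.ndarray:
    raw = df.to_numpy()
    try:
        values = raw.astype(float)  # numpy's parser is correctly rounding
    except (ValueError, TypeError):
        for (r, c), cell in np.ndenumerate(raw):
            try:
                float(cell)
            except (ValueError, TypeError):
                raise ParseError(
                    f"non-numeric value {cell!r} in {path} at row "
                    f"{df.index[r]!r}, column {df.columns[c]!r}",
                    row=df.index[r], column=df.columns[c],
                ) from None
        raise  # pragma: no cover - unreachable
    nan_mask = np.isnan(values) & ~(raw == raw)  # raw NaN = missing cell
    if nan_mask.any():
        r, c = np.argwhere(nan_mask)[0]
        raise ParseError(
            f"missing value in {path} at row {df.index[r]!r}, column "
            f"{df.columns[c]!r}", row=df.index[r], column=df.columns[c],
        )
    return values


def read_expression(
    path: PathLike,
    orientation: str = "features_as_rows",
    scale_tag: str = "log2",
) -> ExpressionMatrix:
    """Read an expression matrix, normalizing to features x samples."""
    if orientation not in ("features_as_rows", "samples_as_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    df = _read_table(path, "feature" if orientation == "features_as_rows" else "sample")
    values = _to_numeric(df, path)
    if orientation == "samples_as_rows":
        return ExpressionMatrix(list(df.columns), list(df.index), values.T, scale_tag)
    return ExpressionMatrix(list(df.index), list(df.columns), values, scale_tag)


def write_expression(X: ExpressionMatrix, path: PathLike) -> None:
    df = pd.DataFrame(X.values, index=pd.Index(X.feature_ids, name="feature_id"),
                      columns=X.sample_ids)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_composition(path: PathLike, closed: bool = False) -> CompositionMatrix:
    df = _read_table(path, "sample")
    values = _to_numeric(df, path)
    return CompositionMatrix(list(df.index), list(df.columns), values, closed)


def write_composition(W: CompositionMatrix, path: PathLike) -> None:
    df = pd.DataFrame(W.values, index=pd.Index(W.sample_ids, name="sample_id"),
                      columns=W.cell_types)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_basis(path: PathLike) -> BasisMatrix:
    df = _read_table(path, "feature")
    values = _to_numeric(df, path)
    return BasisMatrix(list(df.index), list(df.columns), values)


def write_basis(H: BasisMatrix, path: PathLike) -> None:
    df = pd.DataFrame(H.values, index=pd.Index(H.feature_ids, name="feature_id"),
                      columns=H.cell_types)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_markers(path: PathLike) -> MarkerGeneSet:
    """Read a two-column (cell_type, feature_id) marker table; row order
    within each cell type is preserved."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["cell_type", "feature_id"]:
        raise FormatError(
            f"marker file {path} must have columns cell_type, feature_id"
        )
    provenance = "external"
    if "provenance" in df.columns and len(df):
        provenance = df["provenance"].iloc[0]
    markers: dict = {}
    for ct, fid in zip(df["cell_type"], df["feature_id"]):
        markers.setdefault(ct, []).append(fid)
    return MarkerGeneSet(markers, provenance)


def write_markers(markers: MarkerGeneSet, path: PathLike) -> None:
    rows = [
        {"cell_type": ct, "feature_id": f, "provenance": markers.provenance}
        for ct in markers.cell_types for f in markers[ct]
    ]
    pd.DataFrame(rows, columns=["cell_type", "feature_id", "provenance"]).to_csv(
        path, sep="\t", index=False
    )


MODEL_SCHEMA_VERSION = 1


def write_model(results, path: PathLike) -> None:
    """Serialize a fitted composition model to a self-describing JSON
    document. Floats use Python repr (shortest round-trip), so write ->
    read reproduces coefficients bit-identically."""
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "cell_types": list(results.cell_types),
        "feature_ids": list(results.feature_ids),
        "intercepts": [float(v) for v in results.intercepts],
        "coefficients": [[float(v) for v in row] for row in results.coefficients],
        "alpha": float(results.alpha),
        "lambda": float(results.lam),
        "training_meta": results.training_meta,
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def read_model(path: PathLike):
    from .model import CompositionResults  # local import: avoids cycle

    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"model file {path} is not valid JSON: {exc}") from exc
    if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise FormatError(
            f"unsupported model schema version {doc.get('schema_version')!r}"
        )
    return CompositionResults(
        feature_ids=list(doc["feature_ids"]),
        cell_types=list(doc["cell_types"]),
        intercepts=np.asarray(doc["intercepts"], dtype=float),
        coefficients=np.asarray(doc["coefficients"], dtype=float).reshape(
            len(doc["feature_ids"]), len(doc["cell_types"])
        ),
        alpha=float(doc["alpha"]),
        lam=float(doc["lambda"]),
        training_meta=doc.get("training_meta", {}),
    )
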