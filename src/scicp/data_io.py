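"""Expression-matrix and metadata I/O, normalization, trivial filters.

The in-memory container is :class:`ExpressionMatrix`, a cells x features
log-normalized matrix with unique string ids on both axes.  On disk two
formats are supported: Matrix Market triplets with feature/barcode sidecar
files (stored features x cells by 10x convention unless told otherwise) and
dense delimited text.  Fitted models are archived as single versioned files.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "CellMetadata",
    "DataIOError",
    "read_expression",
    "write_expression",
    "read_metadata",
    "log_normalize",
    "filter_unexpressed",
    "save_model",
    "load_model",
]

ARCHIVE_FORMAT = "scicp-model"
SCHEMA_VERSION = 1


class DataIOError(ValueError):
    """Structured I/O failure naming the offending file or ids."""


def _check_unique(ids: np.ndarray, what: str, where: str) -> None:
    if len(ids) != len(set(ids)):
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        raise DataIOError(f"duplicate {what} in {where}: {dupes[:5]}")


@dataclass
class ExpressionMatrix:
    """Cells x features log-normalized expression with string ids.

    Values are kept as a dense float array; matrices at the scale this
    engine targets (thousands of cells, the HVG feature space) fit easily,
    and the downstream solvers want dense input anyway.
    """

    values: np.ndarray
    cell_ids: np.ndarray
    feature_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(
            self.values.toarray() if sp.issparse(self.values) else self.values,
            dtype=float,
        )
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        n, m = self.values.shape
        if n != len(self.cell_ids) or m != len(self.feature_ids):
            raise DataIOError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.cell_ids)} cell ids / {len(self.feature_ids)} feature ids"
            )
        _check_unique(self.cell_ids, "cell ids", "ExpressionMatrix")
        _check_unique(self.feature_ids, "feature ids", "ExpressionMatrix")
        if not np.all(np.isfinite(self.values)):
            raise DataIOError("non-finite values in expression matrix")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        """Column subset by feature id, in the requested order."""
        idx = pd.Index(self.feature_ids)
        pos = idx.get_indexer(list(feature_ids))
        if (pos < 0).any():
            missing = [f for f, p in zip(feature_ids, pos) if p < 0]
            raise DataIOError(f"features absent from matrix: {missing[:5]}")
        return ExpressionMatrix(
            self.values[:, pos], self.cell_ids, np.asarray(list(feature_ids), dtype=object)
        )

    def to_anndata(self):
        """Optional adapter to an AnnData container (thin, import-on-use)."""
        import anndata

        return anndata.AnnData(
            X=self.values.copy(),
            obs=pd.DataFrame(index=list(self.cell_ids)),
            var=pd.DataFrame(index=list(self.feature_ids)),
        )


@dataclass
class CellMetadata:
    """Per-cell batch (required) and optional cell-type label.

    Joins against an :class:`ExpressionMatrix` are by cell id string, never
    by position; order mismatches are silently aligned, missing ids raise.
    """

    cell_ids: np.ndarray
    batch: np.ndarray
    label: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.batch = np.asarray(self.batch, dtype=object)
        if self.label is not None:
            self.label = np.asarray(self.label, dtype=object)
            if len(self.label) != len(self.cell_ids):
                raise DataIOError("label length does not match cell ids")
        if len(self.batch) != len(self.cell_ids):
            raise DataIOError("batch length does not match cell ids")
        _check_unique(self.cell_ids, "cell ids", "CellMetadata")

    @property
    def batch_levels(self) -> list:
        return sorted(set(self.batch))

    def aligned_to(self, X: ExpressionMatrix) -> "CellMetadata":
        """Reorder to X's cell order; every X cell must be present."""
        idx = pd.Index(self.cell_ids)
        pos = idx.get_indexer(list(X.cell_ids))
        if (pos < 0).any():
            missing = list(np.asarray(X.cell_ids)[pos < 0])
            raise DataIOError(f"metadata missing cells: {missing[:5]}")
        return CellMetadata(
            self.cell_ids[pos],
            self.batch[pos],
            None if self.label is None else self.label[pos],
        )


def _open_maybe_gzip(path, mode="rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _read_lines(path) -> list[str]:
    with _open_maybe_gzip(path) as fh:
        return [ln.rstrip("\n").split("\t")[0] for ln in fh if ln.strip()]


def read_expression(
    path,
    fmt: str = "mtx",
    *,
    features_path=None,
    cells_path=None,
    cells_as_rows_on_disk: bool = False,
    sep: str = "\t",
) -> ExpressionMatrix:
    """Read an expression matrix as cells x features.

    Parameters
    ----------
    path
        Matrix Market triplet file (``fmt="mtx"``) or delimited text with a
        header row and a leading id column (``fmt="delimited"``).
    features_path, cells_path
        Sidecar name files for the mtx format; default to ``features.tsv``
        and ``barcodes.tsv`` next to the matrix file (``.gz`` variants are
        found automatically).
    cells_as_rows_on_disk
        The mtx default stores features x cells (10x convention); set True
        when the file is already cells x features.  For delimited files the
        flag states whether rows are cells (default False: rows = features).
    """
    if fmt == "mtx":
        if features_path is None or cells_path is None:
            base = os.path.dirname(str(path))

            def _find(stem):
                for cand in (stem + ".tsv", stem + ".tsv.gz", stem + ".txt"):
                    p = os.path.join(base, cand)
                    if os.path.exists(p):
                        return p
                raise DataIOError(f"sidecar file {stem}.tsv not found next to {path}")

            features_path = features_path or _find("features")
            cells_path = cells_path or _find("barcodes")
        try:
            with _open_maybe_gzip(path, "rb" if not str(path).endswith(".gz") else "rb") as fh:
                mat = scipy.io.mmread(fh)
        except Exception as exc:  # noqa: BLE001 - rewrap with filename
            raise DataIOError(f"cannot parse Matrix Market file {path}: {exc}") from exc
        values = np.asarray(mat.todense() if sp.issparse(mat) else mat, dtype=float)
        if not cells_as_rows_on_disk:
            values = values.T
        feature_ids = _read_lines(features_path)
        cell_ids = _read_lines(cells_path)
        if values.shape != (len(cell_ids), len(feature_ids)):
            raise DataIOError(
                f"dimension mismatch: matrix {path} is {values.shape} (cells x features) "
                f"but {cells_path} lists {len(cell_ids)} cells and "
                f"{features_path} lists {len(feature_ids)} features"
            )
        return ExpressionMatrix(values, cell_ids, feature_ids)

    if fmt == "delimited":
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # noqa: BLE001
            raise DataIOError(f"cannot parse delimited file {path}: {exc}") from exc
        bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
        if len(bad):
            raise DataIOError(f"non-numeric values in {path}, column(s) {list(bad)[:5]}")
        values = df.to_numpy(dtype=float)
        rows, cols = list(df.index.astype(str)), list(df.columns.astype(str))
        if cells_as_rows_on_disk:
            cell_ids, feature_ids = rows, cols
        else:
            values = values.T
            cell_ids, feature_ids = cols, rows
        _check_unique(np.asarray(feature_ids, dtype=object), "feature ids", str(path))
        _check_unique(np.asarray(cell_ids, dtype=object), "cell ids", str(path))
        return ExpressionMatrix(values, cell_ids, feature_ids)

    raise DataIOError(f"unknown format {fmt!r}; expected 'mtx' or 'delimited'")


def write_expression(
    X: ExpressionMatrix,
    path,
    fmt: str = "mtx",
    *,
    features_path=None,
    cells_path=None,
    cells_as_rows_on_disk: bool = False,
    sep: str = "\t",
) -> None:
    """Write an ExpressionMatrix; inverse of :func:`read_expression`."""
    if fmt == "mtx":
        base = os.path.dirname(str(path))
        features_path = features_path or os.path.join(base, "features.tsv")
        cells_path = cells_path or os.path.join(base, "barcodes.tsv")
        vals = X.values if cells_as_rows_on_disk else X.values.T
        scipy.io.mmwrite(str(path), sp.coo_matrix(vals))
        # mmwrite appends .mtx only when missing; normalize to requested name
        written = str(path) if str(path).endswith(".mtx") else str(path) + ".mtx"
        if written != str(path):
            os.replace(written, str(path))
        with open(features_path, "w") as fh:
            fh.write("\n".join(map(str, X.feature_ids)) + "\n")
        with open(cells_path, "w") as fh:
            fh.write("\n".join(map(str, X.cell_ids)) + "\n")
        return
    if fmt == "delimited":
        df = pd.DataFrame(X.values, index=list(X.cell_ids), columns=list(X.feature_ids))
        if not cells_as_rows_on_disk:
            df = df.T
        df.to_csv(path, sep=sep)
        return
    raise DataIOError(f"unknown format {fmt!r}")


def read_metadata(
    path, *, cell_col: str | None = None, batch_col: str = "batch",
    label_col: str | None = None, sep: str = "\t",
) -> CellMetadata:
    """Read a delimited metadata table into :class:`CellMetadata`."""
    df = pd.read_csv(path, sep=sep)
    if cell_col is None:
        cell_col = df.columns[0]
    for col in [cell_col, batch_col] + ([label_col] if label_col else []):
        if col not in df.columns:
            raise DataIOError(f"column {col!r} not found in {path}; has {list(df.columns)}")
    return CellMetadata(
        df[cell_col].astype(str).to_numpy(),
        df[batch_col].astype(str).to_numpy(),
        df[label_col].astype(str).to_numpy() if label_col else None,
    )


def log_normalize(
    counts: ExpressionMatrix | np.ndarray,
    scale_factor: float = 10_000.0,
    *,
    cell_ids=None,
    feature_ids=None,
) -> ExpressionMatrix:
    """Library-size normalize and natural-log transform counts.

    out[i, g] = ln(1 + counts[i, g] * scale_factor / total_i), the standard
    log-normalization with pseudocount 1.  Cells with zero total count are
    rejected (they carry no information and would divide by zero).
    """
    if scale_factor <= 0:
        raise DataIOError("scale_factor must be positive")
    if isinstance(counts, ExpressionMatrix):
        raw, cell_ids, feature_ids = counts.values, counts.cell_ids, counts.feature_ids
    else:
        raw = np.asarray(
            counts.toarray() if sp.issparse(counts) else counts, dtype=float
        )
        n, m = raw.shape
        cell_ids = cell_ids if cell_ids is not None else [f"cell{i}" for i in range(n)]
        feature_ids = (
            feature_ids if feature_ids is not None else [f"gene{g}" for g in range(m)]
        )
    if (raw < 0).any():
        raise DataIOError("counts must be non-negative")
    totals = raw.sum(axis=1)
    zero = totals == 0
    if zero.any():
        bad = list(np.asarray(cell_ids, dtype=object)[zero])
        raise DataIOError(f"cells with zero total count: {bad[:10]}")
    out = np.log1p(raw * (scale_factor / totals[:, None]))
    return ExpressionMatrix(out, cell_ids, feature_ids)


def filter_unexpressed(X: ExpressionMatrix) -> ExpressionMatrix:
    """Drop features whose column is identically zero (never expressed)."""
    keep = (X.values != 0).any(axis=0)
    if not keep.any():
        raise DataIOError("all features are unexpressed; nothing left after filtering")
    if keep.all():
        return X
    return ExpressionMatrix(X.values[:, keep], X.cell_ids, X.feature_ids[keep])


def save_model(obj, path) -> None:
    """Serialize a fitted object inside a versioned single-file envelope."""
    joblib.dump(
        {"format": ARCHIVE_FORMAT, "schema_version": SCHEMA_VERSION, "payload": obj},
        path,
    )


def load_model(path):
    """Load an archive written by :func:`save_model`, validating the envelope."""
    try:
        blob = joblib.load(path)
    except Exception as exc:  # noqa: BLE001
        raise DataIOError(f"cannot read model archive {path}: {exc}") from exc
    if not isinstance(blob, dict) or blob.get("format") != ARCHIVE_FORMAT:
        raise DataIOError(f"{path} is not a {ARCHIVE_FORMAT} archive")
    version = blob.get("schema_version")
    if version != SCHEMA_VERSION:
        raise DataIOError(
            f"archive {path} has schema version {version}; "
            f"this build reads version {SCHEMA_VERSION}"
        )
    return blob["payload"]
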