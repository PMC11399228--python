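"""Readers and writers for guide count matrices and assignment tables.

Supported inputs are the Cell Ranger triplet layout (``matrix.mtx[.gz]`` +
``features.tsv[.gz]`` + ``barcodes.tsv[.gz]``, guide features selected by
feature type) and plain CSV count tables in wide (gRNAs x cells) or long
(cell,gRNA,count) dialect.  Assignment tables round-trip through a simple
CSV with columns ``cell,guide,prob,method``.
"""

from __future__ import annotations

import gzip
import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .core import (
    AssignmentTable,
    GuideCountMatrix,
    InputError,
    ValidationError,
)

GUIDE_FEATURE_TYPE = "CRISPR Guide Capture"

__all__ = [
    "read_cellranger",
    "read_csv_counts",
    "read_batches",
    "write_cellranger",
    "write_assignments",
    "read_assignments",
    "GUIDE_FEATURE_TYPE",
]


def _find(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise InputError(f"missing file {stem}[.gz] in {directory}")


def _open_maybe_gzip(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_cellranger(
    dir_path: str | os.PathLike,
    guide_feature_type: str = GUIDE_FEATURE_TYPE,
) -> GuideCountMatrix:
    """Read a Cell Ranger count directory, keeping only guide features.

    The MTX file is features x barcodes; the result is transposed to the
    canonical cells x gRNAs orientation.  Rows whose third features column
    does not equal ``guide_feature_type`` (e.g. gene expression features of
    a combined run) are dropped.
    """
    directory = Path(dir_path)
    if not directory.is_dir():
        raise InputError(f"not a directory: {directory}")
    mtx_path = _find(directory, "matrix.mtx")
    feat_path = _find(directory, "features.tsv")
    bc_path = _find(directory, "barcodes.tsv")

    features = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    if features.shape[1] < 3:
        raise ValidationError(
            "features.tsv needs >= 3 columns (id, name, feature type)"
        )
    barcodes = pd.read_csv(bc_path, sep="\t", header=None, dtype=str)[0].to_numpy()

    with _open_maybe_gzip(mtx_path) as fh:
        mat = scipy.io.mmread(fh)
    mat = sp.csr_matrix(mat)
    if mat.shape != (len(features), len(barcodes)):
        raise ValidationError(
            f"matrix shape {mat.shape} does not match features x barcodes "
            f"({len(features)}, {len(barcodes)})"
        )
    if mat.data.size and not np.allclose(mat.data, np.round(mat.data)):
        raise ValidationError("matrix.mtx contains non-integer counts")

    keep = np.flatnonzero(features[2].to_numpy() == guide_feature_type)
    if keep.size == 0:
        raise ValidationError(
            f"no features of type {guide_feature_type!r} in {feat_path.name}"
        )
    guide_ids = features[1].to_numpy(dtype=object)[keep]
    counts = mat[keep, :].T.tocsr()
    return GuideCountMatrix(counts, cell_ids=barcodes, guide_ids=guide_ids)


def read_csv_counts(path: str | os.PathLike, orientation: str) -> GuideCountMatrix:
    """Read a CSV count table.

    ``orientation='wide'``: rows are gRNAs, the header row holds cell
    barcodes and the first column the guide ids.  ``orientation='long'``:
    header-less rows ``cell,gRNA,count``; absent pairs are zero.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"missing file {path}")
    if orientation not in ("wide", "long"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    if path.stat().st_size == 0:
        raise ValidationError(f"empty counts file {path}")

    if orientation == "wide":
        frame = pd.read_csv(path, index_col=0)
        if frame.empty:
            raise ValidationError(f"no counts in {path}")
        values = frame.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("non-numeric counts in wide CSV")
        if np.isnan(values.astype(float)).any():
            raise ValidationError("missing values in wide CSV")
        if (values < 0).any():
            raise ValidationError("negative counts in wide CSV")
        return GuideCountMatrix(
            sp.csr_matrix(values.T),
            cell_ids=frame.columns.to_numpy(dtype=object),
            guide_ids=frame.index.to_numpy(dtype=object),
        )

    frame = pd.read_csv(path, header=None, names=["cell", "guide", "count"])
    # tolerate an optional header row
    first = str(frame.iloc[0, 2])
    try:
        float(first)
    except ValueError:
        frame = frame.iloc[1:].reset_index(drop=True)
    if frame.empty:
        raise ValidationError(f"no counts in {path}")
    counts = pd.to_numeric(frame["count"], errors="coerce")
    if counts.isna().any():
        raise ValidationError("non-numeric counts in long CSV")
    if (counts < 0).any():
        raise ValidationError("negative counts in long CSV")
    if frame.duplicated(["cell", "guide"]).any():
        raise ValidationError("duplicate (cell, guide) rows in long CSV")
    cells = pd.unique(frame["cell"].astype(str))
    guides = pd.unique(frame["guide"].astype(str))
    ci = pd.Series(np.arange(len(cells)), index=cells)
    gi = pd.Series(np.arange(len(guides)), index=guides)
    mat = sp.coo_matrix(
        (
            counts.to_numpy(float),
            (ci[frame["cell"].astype(str)], gi[frame["guide"].astype(str)]),
        ),
        shape=(len(cells), len(guides)),
    ).tocsr()
    return GuideCountMatrix(
        mat, cell_ids=cells.astype(object), guide_ids=guides.astype(object)
    )


def read_batches(path: str | os.PathLike) -> pd.Series:
    """Read a two-column ``cell_id,batch`` file into a Series."""
    frame = pd.read_csv(path, header=None, names=["cell", "batch"], dtype=str)
    if frame.duplicated("cell").any():
        raise ValidationError("duplicate cell ids in batch file")
    return frame.set_index("cell")["batch"]


def with_batches(matrix: GuideCountMatrix, batches: pd.Series) -> GuideCountMatrix:
    """Return a copy of ``matrix`` with batch labels joined by cell id."""
    missing = set(matrix.cell_ids) - set(batches.index)
    if missing:
        raise ValidationError(f"batch file lacks {len(missing)} cells")
    labels = batches.reindex(matrix.cell_ids).to_numpy(dtype=object)
    return GuideCountMatrix(
        matrix.counts.copy(),
        matrix.cell_ids.copy(),
        matrix.guide_ids.copy(),
        batch=labels,
        guide_meta=matrix.guide_meta,
    )


def write_cellranger(matrix: GuideCountMatrix, dir_path: str | os.PathLike) -> None:
    """Write the Cell Ranger triplet (uncompressed) for a guide matrix."""
    directory = Path(dir_path)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(directory / "matrix.mtx"), matrix.counts.T.tocoo(), field="integer"
    )
    feats = pd.DataFrame(
        {
            0: matrix.guide_ids,
            1: matrix.guide_ids,
            2: GUIDE_FEATURE_TYPE,
        }
    )
    feats.to_csv(directory / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(matrix.cell_ids).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )


def write_assignments(table: AssignmentTable, path: str | os.PathLike) -> None:
    """Write an assignment table as ``cell,guide,prob,method`` CSV."""
    out = table.calls.copy()
    out["method"] = table.method_name
    out.to_csv(path, index=False)


def read_assignments(path: str | os.PathLike) -> AssignmentTable:
    """Read an assignment CSV written by :func:`write_assignments`."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"missing file {path}")
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    required = {"cell", "guide", "prob", "method"}
    if not required.issubset(frame.columns):
        raise ValidationError(
            f"{path}: line 1: expected header with columns {sorted(required)}"
        )
    probs = pd.to_numeric(frame["prob"], errors="coerce")
    bad = np.flatnonzero(
        frame["prob"].notna().to_numpy()
        & (probs.isna() | (probs < 0) | (probs > 1)).to_numpy()
    )
    if bad.size:
        # +2: one for the header line, one for 1-based numbering
        raise ValidationError(
            f"{path}: line {bad[0] + 2}: prob outside [0, 1]"
        )
    if frame.empty:
        return AssignmentTable("unknown", frame)
    methods = frame["method"].unique()
    if len(methods) > 1:
        raise ValidationError(f"{path}: mixed methods {methods.tolist()}")
    return AssignmentTable(
        str(methods[0]),
        frame[["cell", "guide", "prob"]].astype({"cell": str, "guide": str}),
    )
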