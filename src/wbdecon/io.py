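"""Readers and writers for the TSV / GMT formats used by the toolkit.

Matrices are tab-separated with a header row of column ids and the first
column holding row ids.  Missing values are written as the literal token
``NA``; on input both ``NA`` and empty cells are accepted as missing.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    BasisMatrix,
    CellFrequencyMatrix,
    ExpressionDataset,
    GROUPS,
    MarkerSets,
    ResidualMatrix,
    SignatureMatrix,
    ValidationError,
    _check_unique,
    validate_annotations,
)

NA_TOKEN = "NA"


class ParseError(ValueError):
    """Raised for malformed input files, naming the offending cell."""


def _read_table(path) -> pd.DataFrame:
    """Read a TSV of strings with row ids in the first column."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    _check_unique(header, "column id in header")
    raw = pd.read_csv(
        path, sep="\t", dtype=str, index_col=0, keep_default_na=False
    )
    raw.index = raw.index.astype(str)
    return raw


def _to_numeric(raw: pd.DataFrame, path) -> pd.DataFrame:
    """Convert a string table to floats; NA / empty cells become NaN."""
    is_missing = raw.isin([NA_TOKEN, ""])
    num = raw.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & ~is_missing
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        r, c = rows[0], cols[0]
        raise ParseError(
            f"{path}: malformed numeric cell at row {raw.index[r]!r}, "
            f"column {raw.columns[c]!r}: {raw.iat[r, c]!r}"
        )
    return num.astype(float)


def _collapse_duplicate_genes(values: pd.DataFrame) -> pd.DataFrame:
    """Average rows that share a gene id (mean over non-missing values).

    Output row order follows the first occurrence of each id, so the
    operation is independent of the input row order up to that rule.
    """
    if not values.index.has_duplicates:
        return values
    first_seen = values.index.drop_duplicates(keep="first")
    collapsed = values.groupby(level=0, sort=False).mean()
    return collapsed.loc[first_seen]


def read_expression_matrix(path, scale: str) -> ExpressionDataset:
    """Read a genes x samples expression TSV with declared scale.

    Duplicate gene ids are collapsed by the per-sample mean over
    non-missing values; duplicate sample ids are an error.
    """
    raw = _read_table(path)
    _check_unique(raw.columns, "sample id")
    values = _collapse_duplicate_genes(_to_numeric(raw, path))
    # deterministic row order: sort by first occurrence is already kept
    return ExpressionDataset(values, scale=scale)


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a sample sheet TSV (sample_id, dataset_id, group, disease)."""
    sheet = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "dataset_id", "group"]
    missing = [c for c in required if c not in sheet.columns]
    if missing:
        raise ParseError(f"{path}: sample sheet columns missing: {missing}")
    if "disease" not in sheet.columns:
        sheet["disease"] = ""
    sheet = sheet.set_index("sample_id")
    sheet["disease"] = sheet["disease"].replace("", None)
    bad = set(sheet["group"]) - set(GROUPS)
    if bad:
        raise ParseError(
            f"{path}: group values outside {GROUPS}: {sorted(map(str, bad))}"
        )
    validate_annotations(sheet)
    return sheet[["dataset_id", "group", "disease"]]


def annotate(
    dataset: ExpressionDataset, sheet: pd.DataFrame
) -> tuple[ExpressionDataset, list[str]]:
    """Join sample-sheet annotations onto a dataset by sample id.

    Returns the annotated dataset and the list of sheet sample ids that
    were absent from the matrix (reported, not fatal).  Matrix samples
    missing from the sheet are an error: every sample needs a group.
    """
    cols = pd.Index(dataset.sample_ids)
    unmatched = sheet.index.difference(cols).tolist()
    if unmatched:
        warnings.warn(f"sample-sheet ids absent from matrix: {unmatched}")
    absent = cols.difference(sheet.index)
    if len(absent):
        raise ValidationError(f"samples without annotation: {absent.tolist()}")
    ann = sheet.loc[cols]
    return ExpressionDataset(dataset.values, dataset.scale, ann), unmatched


def read_marker_sets(path) -> tuple[MarkerSets, list[str]]:
    """Read a GMT file of cell-type marker sets.

    Each line is ``set_name <TAB> description <TAB> gene [TAB gene ...]``.
    A gene listed under more than one cell type is dropped from every
    set; the dropped genes are returned for reporting.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: marker set {parts[0]!r} has no genes"
                )
            name = parts[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set {name!r}")
            genes = [g for g in parts[2:] if g]
            if not genes:
                raise ParseError(
                    f"{path}:{lineno}: marker set {name!r} has no genes"
                )
            sets[name] = genes
    counts: dict[str, int] = {}
    for genes in sets.values():
        for g in set(genes):
            counts[g] = counts.get(g, 0) + 1
    shared = {g for g, c in counts.items() if c > 1}
    if shared:
        warnings.warn(
            f"markers shared across cell types dropped: {sorted(shared)}"
        )
        sets = {
            name: [g for g in genes if g not in shared]
            for name, genes in sets.items()
        }
        empty = [name for name, genes in sets.items() if not genes]
        if empty:
            raise ParseError(
                f"{path}: marker sets emptied by duplicate removal: {empty}"
            )
    return MarkerSets(sets), sorted(shared)


def write_marker_sets(markers: MarkerSets, path) -> None:
    with open(path, "w") as fh:
        for name, genes in markers.sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


_FRAME_ATTR = "values"


def write_matrix(matrix, path) -> None:
    """Write any matrix container (or bare DataFrame) as TSV with NA tokens."""
    frame = matrix if isinstance(matrix, pd.DataFrame) else matrix.values
    frame.to_csv(path, sep="\t", na_rep=NA_TOKEN, index_label="id")


def _read_typed(path, cls):
    values = _to_numeric(_read_table(path), path)
    return cls(values)


def read_signature_matrix(path) -> SignatureMatrix:
    return _read_typed(path, SignatureMatrix)


def read_basis_matrix(path) -> BasisMatrix:
    return _read_typed(path, BasisMatrix)


def read_frequency_matrix(path) -> CellFrequencyMatrix:
    return _read_typed(path, CellFrequencyMatrix)


def read_residual_matrix(path) -> ResidualMatrix:
    return _read_typed(path, ResidualMatrix)


def write_sample_sheet(ann: pd.DataFrame, path) -> None:
    out = ann.copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(path, sep="\t", index=False, na_rep="")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
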