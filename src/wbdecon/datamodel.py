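"""Core in-memory containers for whole-blood deconvolution analyses.

All matrix types wrap a :class:`pandas.DataFrame` with genes (or cell types)
as rows and samples (or cell types) as columns.  Orientation is fixed and
never auto-detected.  Identifiers are case-sensitive opaque strings.

The central objects mirror the linear mixing model

    X[i, j] = sum_k B[i, k] * F[k, j] + R[i, j]

where ``X`` is observed bulk expression (:class:`ExpressionDataset`),
``B`` is per-cell-type expression under healthy conditions
(:class:`BasisMatrix`), ``F`` holds cell-type frequencies per sample
(:class:`CellFrequencyMatrix`) and ``R`` is the residual expression left
after the cell-frequency-explained component is removed
(:class:`ResidualMatrix`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("case", "control")
SCALES = ("linear", "log2")

ANNOTATION_COLUMNS = ("dataset_id", "group", "disease")


class ValidationError(ValueError):
    """Raised when a container violates one of its structural invariants."""


def _check_unique(ids, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups}")


def make_annotations(
    sample_ids,
    dataset_id,
    group,
    disease=None,
) -> pd.DataFrame:
    """Build a per-sample annotation frame.

    Parameters may be scalars (broadcast to all samples) or sequences
    aligned with ``sample_ids``.  ``disease`` may be None / NaN for
    controls and for datasets without a disease label.
    """
    n = len(sample_ids)

    def _broadcast(v):
        if v is None or np.isscalar(v) or isinstance(v, str):
            return [v] * n
        v = list(v)
        if len(v) != n:
            raise ValidationError("annotation length mismatch")
        return v

    ann = pd.DataFrame(
        {
            "dataset_id": _broadcast(dataset_id),
            "group": _broadcast(group),
            "disease": _broadcast(disease),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    validate_annotations(ann)
    return ann


def validate_annotations(ann: pd.DataFrame) -> None:
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValidationError(f"annotation columns missing: {missing}")
    _check_unique(ann.index, "sample id in annotations")
    bad = set(ann["group"]) - set(GROUPS)
    if bad:
        raise ValidationError(
            f"group values outside {GROUPS}: {sorted(map(str, bad))}"
        )


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix with scale flag and annotations.

    ``values`` rows are genes, columns are samples; missing entries are
    NaN.  ``scale`` declares whether values are on the linear or log2
    scale; linear values must be non-negative where present.
    """

    values: pd.DataFrame
    scale: str = "linear"
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"scale must be one of {SCALES}")
        _check_unique(self.values.index, "gene id")
        _check_unique(self.values.columns, "sample id")
        vals = self.values.to_numpy(dtype=float)
        if self.scale == "linear" and np.any(vals[~np.isnan(vals)] < 0):
            raise ValidationError("linear-scale expression must be >= 0")
        if self.annotations is not None:
            validate_annotations(self.annotations)
            missing = self.values.columns.difference(self.annotations.index)
            if len(missing):
                raise ValidationError(
                    f"samples without annotation: {missing.tolist()}"
                )
            # keep annotation rows aligned with the matrix columns
            self.annotations = self.annotations.loc[self.values.columns]

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def select_samples(self, sample_ids) -> "ExpressionDataset":
        """Return a new dataset restricted to ``sample_ids`` (in that order)."""
        sample_ids = list(sample_ids)
        ann = None
        if self.annotations is not None:
            ann = self.annotations.loc[sample_ids]
        return ExpressionDataset(self.values[sample_ids], self.scale, ann)

    def select_genes(self, gene_ids) -> "ExpressionDataset":
        return ExpressionDataset(
            self.values.loc[list(gene_ids)], self.scale, self.annotations
        )

    def control_ids(self) -> list[str]:
        if self.annotations is None:
            raise ValidationError("dataset has no annotations")
        return self.annotations.index[
            self.annotations["group"] == "control"
        ].tolist()

    def case_ids(self) -> list[str]:
        if self.annotations is None:
            raise ValidationError("dataset has no annotations")
        return self.annotations.index[
            self.annotations["group"] == "case"
        ].tolist()


@dataclass
class MarkerSets:
    """Cell-type -> marker gene lists; a gene belongs to at most one set."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for cell_type, genes in self.sets.items():
            if len(genes) == 0:
                raise ValidationError(f"empty marker list for {cell_type!r}")
            for g in genes:
                if g in seen:
                    raise ValidationError(
                        f"marker {g!r} appears in both {seen[g]!r} "
                        f"and {cell_type!r}"
                    )
                seen[g] = cell_type

    @property
    def cell_types(self) -> list[str]:
        return list(self.sets)

    def all_genes(self) -> list[str]:
        return [g for genes in self.sets.values() for g in genes]


def _matrix_frame(values, rows, cols) -> pd.DataFrame:
    if isinstance(values, pd.DataFrame):
        return values
    return pd.DataFrame(np.asarray(values, dtype=float), index=rows, columns=cols)


@dataclass
class SignatureMatrix:
    """Genes x cell types reference expression signatures (non-negative)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene id")
        _check_unique(self.values.columns, "cell type")
        v = self.values.to_numpy(dtype=float)
        if np.any(v[~np.isnan(v)] < 0):
            raise ValidationError("signature values must be >= 0")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def cell_types(self) -> list[str]:
        return self.values.columns.tolist()


@dataclass
class BasisMatrix:
    """Genes x cell types expression under healthy conditions (B >= 0)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene id")
        _check_unique(self.values.columns, "cell type")
        v = self.values.to_numpy(dtype=float)
        if np.any(v[~np.isnan(v)] < 0):
            raise ValidationError("basis values must be >= 0 (NNLS contract)")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def cell_types(self) -> list[str]:
        return self.values.columns.tolist()


@dataclass
class CellFrequencyMatrix:
    """Cell types x samples non-negative frequency estimates.

    Columns that could not be estimated are all-NaN ("missing").  When
    sum-to-one is enforced upstream, each non-missing column sums to 1
    within ``SUM_TOL``.
    """

    values: pd.DataFrame

    SUM_TOL = 1e-6

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "cell type")
        _check_unique(self.values.columns, "sample id")
        v = self.values.to_numpy(dtype=float)
        if np.any(v[~np.isnan(v)] < 0):
            raise ValidationError("cell frequencies must be >= 0")

    @property
    def cell_types(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    def check_sum_to_one(self) -> None:
        v = self.values.to_numpy(dtype=float)
        ok = np.isnan(v).all(axis=0)
        sums = np.nansum(v, axis=0)
        bad = ~ok & (np.abs(sums - 1.0) > self.SUM_TOL)
        if bad.any():
            cols = self.values.columns[bad].tolist()
            raise ValidationError(f"frequency columns not summing to 1: {cols}")


@dataclass
class ResidualMatrix:
    """Genes x samples residual expression R = X - B.F (sign-unrestricted)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene id")
        _check_unique(self.values.columns, "sample id")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()


def combine_datasets(datasets: list[ExpressionDataset]) -> ExpressionDataset:
    """Column-concatenate datasets on the union of genes.

    Genes absent from a dataset become missing (NaN) in its columns; the
    declared scale must agree across inputs.
    """
    if not datasets:
        raise ValidationError("no datasets to combine")
    scales = {d.scale for d in datasets}
    if len(scales) > 1:
        raise ValidationError(f"mixed scales: {sorted(scales)}")
    values = pd.concat([d.values for d in datasets], axis=1)
    _check_unique(values.columns, "sample id across datasets")
    anns = [d.annotations for d in datasets]
    ann = pd.concat(anns) if all(a is not None for a in anns) else None
    return ExpressionDataset(values, datasets[0].scale, ann)
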