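"""Cell-type frequency estimation from bulk mixtures.

Two estimators are provided.  The marker-based route (digital sorting,
``dsa_frequencies``) needs only cell-type-exclusive marker genes: the
mean marker expression of cell type k in sample j is proportional to the
true frequency, ``m_kj = c_k * f_kj``, and the unknown proportionality
constants are identified from the simplex constraint sum_k f_kj = 1.
The signature-based route (``signature_nnls_frequencies``) regresses
each bulk profile onto a genes x cell-types reference signature matrix
by non-negative least squares.

Both operate on linear-scale (un-logged) expression: the mixing model is
linear in linear-scale units, not in log units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import ttest_ind

from .datamodel import (
    CellFrequencyMatrix,
    ExpressionDataset,
    MarkerSets,
    SignatureMatrix,
    ValidationError,
)


@dataclass
class MarkerCoverage:
    """Per-cell-type report of markers found vs requested in a matrix."""

    used: dict[str, list[str]]
    missing: dict[str, list[str]] = field(default_factory=dict)


def marker_means(
    X: ExpressionDataset, markers: MarkerSets
) -> tuple[pd.DataFrame, MarkerCoverage]:
    """Mean expression of each cell type's markers per sample.

    Only markers present in the matrix contribute; per-sample means skip
    missing values.  A cell type with no usable marker is an error.
    """
    used: dict[str, list[str]] = {}
    missing: dict[str, list[str]] = {}
    rows = {}
    gene_index = X.values.index
    for cell_type, genes in markers.sets.items():
        present = [g for g in genes if g in gene_index]
        absent = [g for g in genes if g not in gene_index]
        if absent:
            missing[cell_type] = absent
        if not present:
            raise ValidationError(
                f"cell type {cell_type!r} has no usable marker in the matrix"
            )
        used[cell_type] = present
        rows[cell_type] = X.values.loc[present].mean(axis=0, skipna=True)
    means = pd.DataFrame(rows).T  # cell types x samples
    means = means[X.values.columns]
    return means, MarkerCoverage(used=used, missing=missing)


def dsa_frequencies(
    X: ExpressionDataset,
    markers: MarkerSets,
    enforce_sum_to_one: bool = True,
) -> tuple[CellFrequencyMatrix, MarkerCoverage]:
    """Marker-based (digital sorting) frequency estimation.

    Stage 1 computes marker means ``m_kj``.  Stage 2 solves for
    ``g_k = 1/c_k`` by NNLS on the system ``sum_k m_kj g_k = 1`` over all
    samples, which encodes the within-sample simplex constraint.  Stage 3
    sets ``f_kj = m_kj * g_k`` and, when ``enforce_sum_to_one``, rescales
    each column to sum exactly 1.  Samples whose marker means are all
    zero cannot be scaled and are returned as all-missing columns.
    """
    if X.scale != "linear":
        raise ValidationError("dsa_frequencies requires linear-scale expression")
    means, coverage = marker_means(X, markers)
    M = means.to_numpy(dtype=float)
    if np.isnan(M).any():
        raise ValidationError("marker means contain missing values")
    zero_cols = (M == 0).all(axis=0)
    if zero_cols.any():
        warnings.warn(
            f"samples with all-zero marker means returned as missing: "
            f"{means.columns[zero_cols].tolist()}"
        )
    usable = M[:, ~zero_cols]
    if usable.shape[1] == 0:
        raise ValidationError("no sample with non-zero marker means")
    g, _ = nnls(usable.T, np.ones(usable.shape[1]))
    F = M * g[:, None]
    if enforce_sum_to_one:
        sums = F.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            F = np.where(sums > 0, F / sums, F)
    F[:, zero_cols] = np.nan
    freq = CellFrequencyMatrix(
        pd.DataFrame(F, index=means.index, columns=means.columns)
    )
    return freq, coverage


def signature_nnls_frequencies(
    X: ExpressionDataset,
    signature: SignatureMatrix,
    rescale: bool = True,
) -> CellFrequencyMatrix:
    """Signature-based frequencies by per-sample non-negative regression.

    For each sample solve ``min_f ||x - S f||^2, f >= 0`` over the genes
    shared between the matrix and the signature.  With ``rescale`` the
    solution is divided by its sum (columns solving to all zeros are
    left as zeros, with a warning).
    """
    if X.scale != "linear":
        raise ValidationError("signature regression requires linear scale")
    shared = X.values.index.intersection(signature.values.index)
    n_cells = len(signature.cell_types)
    if len(shared) <= n_cells:
        raise ValidationError(
            f"gene overlap {len(shared)} must exceed the {n_cells} cell types"
        )
    S = signature.values.loc[shared].to_numpy(dtype=float)
    Xs = X.values.loc[shared].to_numpy(dtype=float)
    if np.isnan(Xs).any():
        raise ValidationError("expression contains missing values; impute first")
    F = np.empty((n_cells, Xs.shape[1]))
    for j in range(Xs.shape[1]):
        F[:, j], _ = nnls(S, Xs[:, j])
    if rescale:
        sums = F.sum(axis=0)
        zero = sums == 0
        if zero.any():
            warnings.warn(
                f"all-zero frequency columns left unscaled: "
                f"{[X.values.columns[j] for j in np.flatnonzero(zero)]}"
            )
        F = np.where(zero, F, F / np.where(zero, 1.0, sums))
    return CellFrequencyMatrix(
        pd.DataFrame(F, index=signature.cell_types, columns=X.values.columns)
    )


def cell_component_change(
    F: CellFrequencyMatrix, groups: pd.Series | dict
) -> pd.DataFrame:
    """Welch t-statistics of case-vs-control cell-component differences.

    Returns a frame indexed by cell type with columns ``t_statistic``,
    ``p_value`` and ``calculable``.  A cell type with zero variance in
    both groups, or estimated zero in every sample, is flagged as not
    calculable (its t and p are NaN).
    """
    groups = pd.Series(groups)
    case_ids = groups.index[groups == "case"]
    ctrl_ids = groups.index[groups == "control"]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValidationError("need >= 2 samples in each group")
    case = F.values[list(case_ids)].to_numpy(dtype=float)
    ctrl = F.values[list(ctrl_ids)].to_numpy(dtype=float)
    records = []
    for k, cell_type in enumerate(F.cell_types):
        a, b = case[k], ctrl[k]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        all_zero = (a == 0).all() and (b == 0).all()
        no_var = len(a) < 2 or len(b) < 2 or (a.var(ddof=1) == 0 and b.var(ddof=1) == 0)
        if all_zero or no_var:
            records.append((cell_type, np.nan, np.nan, False))
            continue
        t, p = ttest_ind(a, b, equal_var=False)
        records.append((cell_type, float(t), float(p), True))
    return pd.DataFrame(
        records, columns=["cell_type", "t_statistic", "p_value", "calculable"]
    ).set_index("cell_type")
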