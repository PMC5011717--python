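"""Healthy-basis estimation and per-sample residual expression profiles.

Observed bulk expression is modelled as a linear mixture over cell types
plus a residual:

    X[i, j] = sum_k B[i, k] F[k, j] + R[i, j]

``B`` is identified from control samples — their residuals are assumed
to be pure noise — by solving, for each gene independently,

    b_i = argmin_{b >= 0} sum_j (x_ij - sum_k b_k f_kj)^2

with non-negative least squares.  The residual profile ``R = X - B.F``
is then computed identically for control and case samples: for controls
it is noise, for cases it additionally carries cell-type-restricted
expression change, while deviations caused purely by cell-frequency
change cancel.  Unlike group-wise tests, R is defined per sample, which
is what makes it usable as a classification feature.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .datamodel import (
    BasisMatrix,
    CellFrequencyMatrix,
    ExpressionDataset,
    ResidualMatrix,
    ValidationError,
)

_COND_WARN = 1e8


def estimate_basis(
    X_controls: ExpressionDataset, F_controls: CellFrequencyMatrix
) -> BasisMatrix:
    """Fit the healthy cell-type basis from control samples by NNLS.

    One independent non-negative least-squares problem per gene, with
    the frequency columns as the design.  Deterministic given inputs.
    Warns when there are fewer control samples than cell types or when
    the design is numerically rank-deficient.
    """
    if X_controls.n_samples == 0:
        raise ValidationError("no control samples to estimate basis from")
    if list(X_controls.sample_ids) != list(F_controls.sample_ids):
        raise ValidationError("X and F sample columns are not aligned")
    A = F_controls.values.to_numpy(dtype=float).T  # samples x cell types
    n_cells = A.shape[1]
    if A.shape[0] < n_cells:
        warnings.warn(
            f"only {A.shape[0]} control samples for {n_cells} cell types; "
            "basis estimates may be unstable"
        )
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > _COND_WARN:
        warnings.warn(
            f"frequency design is near rank-deficient (condition number "
            f"{cond:.3g}); basis estimates may be unstable"
        )
    Xv = X_controls.values.to_numpy(dtype=float)
    if np.isnan(Xv).any():
        raise ValidationError("expression contains missing values; impute first")
    B = np.empty((Xv.shape[0], n_cells))
    for i in range(Xv.shape[0]):
        B[i], _ = nnls(A, Xv[i])
    return BasisMatrix(
        pd.DataFrame(B, index=X_controls.gene_ids, columns=F_controls.cell_types)
    )


def compute_residuals(
    X: ExpressionDataset, F: CellFrequencyMatrix, B: BasisMatrix
) -> ResidualMatrix:
    """Residual expression R = X - B.F, identically for all samples."""
    if list(X.sample_ids) != list(F.sample_ids):
        raise ValidationError("X and F sample columns are not aligned")
    if list(X.gene_ids) != list(B.gene_ids):
        raise ValidationError("X and B gene rows are not aligned")
    if list(B.cell_types) != list(F.cell_types):
        raise ValidationError("B and F cell types are not aligned")
    expected = B.values.to_numpy(dtype=float) @ F.values.to_numpy(dtype=float)
    R = X.values.to_numpy(dtype=float) - expected
    return ResidualMatrix(
        pd.DataFrame(R, index=X.gene_ids, columns=X.sample_ids)
    )
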