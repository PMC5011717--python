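"""Normalization, gene filtering, imputation and control-anchored Z-scores.

The Z-transformation here is the key cross-dataset harmonization step:
each gene is standardized by its mean and standard deviation *among the
control samples of its own dataset*, so controls follow an approximately
standard normal distribution everywhere while case deviations are kept.
Fitting (``fit_z_params``) and application (``apply_z``) are strictly
separated so that parameters can be derived from training controls only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import ExpressionDataset, ValidationError


def _frame(x) -> pd.DataFrame:
    """Accept an ExpressionDataset, matrix container, or bare DataFrame."""
    if isinstance(x, pd.DataFrame):
        return x
    return x.values


def quantile_normalize(X: ExpressionDataset) -> ExpressionDataset:
    """Quantile-normalize sample columns to a common distribution.

    The reference distribution is the across-sample mean of the sorted
    columns; each column's values are replaced by the reference values
    at their ranks.  Ties within a column receive the mean of the
    reference values over the tied rank positions.  Requires complete
    data (impute first).
    """
    values = X.values.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValidationError(
            "quantile_normalize requires complete data; run imputation first"
        )
    n_genes, n_samples = values.shape
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    reference = sorted_vals.mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_samples):
        col_sorted = sorted_vals[:, j]
        # tie groups: runs of equal values in the sorted column
        starts = np.flatnonzero(np.r_[True, col_sorted[1:] != col_sorted[:-1]])
        counts = np.diff(np.r_[starts, n_genes])
        group_means = np.add.reduceat(reference, starts) / counts
        out[order[:, j], j] = np.repeat(group_means, counts)
    return ExpressionDataset(
        pd.DataFrame(out, index=X.values.index, columns=X.values.columns),
        X.scale,
        X.annotations,
    )


def filter_and_impute(
    X: ExpressionDataset,
    mean_percentile: float = 25.0,
    max_missing_frac: float = 0.2,
    knn_k: int = 10,
) -> ExpressionDataset:
    """Low-expression filter, missingness filter, then kNN imputation.

    1. Within each dataset (by ``dataset_id`` annotation; one dataset if
       unannotated), genes whose non-missing mean is at or below the
       ``mean_percentile``-th percentile of per-gene means are dropped —
       a gene low in any dataset is dropped from the combined matrix.
    2. Genes missing in more than ``max_missing_frac`` of all samples
       are dropped.
    3. Remaining missing entries are imputed by the average of the
       ``knn_k`` nearest genes (Euclidean distance over shared
       non-missing samples, scaled to per-sample units) that have a
       value at the target sample.
    """
    if X.n_genes == 0:
        raise ValidationError("empty dataset")
    values = X.values

    if X.annotations is not None:
        dataset_groups = [
            values.columns[(X.annotations["dataset_id"] == d).to_numpy()]
            for d in X.annotations["dataset_id"].unique()
        ]
    else:
        dataset_groups = [values.columns]
    low = pd.Series(False, index=values.index)
    if mean_percentile > 0:
        for cols in dataset_groups:
            means = values[cols].mean(axis=1, skipna=True)
            cutoff = np.nanpercentile(means.to_numpy(), mean_percentile)
            low |= means <= cutoff
    kept = values.loc[~low]

    missing_frac = kept.isna().mean(axis=1)
    kept = kept.loc[missing_frac <= max_missing_frac]
    if kept.shape[0] == 0:
        raise ValidationError("all genes filtered out")

    kept = _knn_impute_genes(kept, knn_k)
    ann = X.annotations
    return ExpressionDataset(kept, X.scale, ann)


def _knn_impute_genes(values: pd.DataFrame, k: int) -> pd.DataFrame:
    """Impute missing entries from the k nearest genes (rows)."""
    arr = values.to_numpy(dtype=float).copy()
    nan_rows = np.flatnonzero(np.isnan(arr).any(axis=1))
    if nan_rows.size == 0:
        return values
    mask = ~np.isnan(arr)
    filled = np.where(mask, arr, 0.0)
    for i in nan_rows:
        if not mask[i].any():
            raise ValidationError(
                f"gene {values.index[i]!r} has no observed value at imputation"
            )
        shared = mask & mask[i]  # samples observed in both gene i and others
        n_shared = shared.sum(axis=1)
        diff = (filled - filled[i]) * shared
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.sqrt((diff**2).sum(axis=1) / n_shared)
        dist[i] = np.inf
        dist[n_shared == 0] = np.inf
        for j in np.flatnonzero(~mask[i]):
            cand = dist.copy()
            cand[~mask[:, j]] = np.inf  # neighbor must be observed at sample j
            finite = np.isfinite(cand)
            if not finite.any():
                raise ValidationError(
                    f"no neighbor available to impute gene "
                    f"{values.index[i]!r} at sample {values.columns[j]!r}"
                )
            kk = min(k, int(finite.sum()))
            nearest = np.argpartition(cand, kk - 1)[:kk]
            arr[i, j] = arr[nearest, j].mean()
    return pd.DataFrame(arr, index=values.index, columns=values.columns)


@dataclass
class ZParams:
    """Per-feature control mean/SD for the control-anchored Z-transform."""

    mean: pd.Series
    sd: pd.Series
    source: str = ""
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.mean.index.equals(self.sd.index):
            raise ValidationError("mean and sd indices differ")
        if (self.sd <= 0).any():
            raise ValidationError("retained features must have sd > 0")

    @property
    def feature_ids(self) -> list[str]:
        return self.mean.index.tolist()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd})

    def write(self, path) -> None:
        out = self.to_frame()
        out.insert(0, "feature_id", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path, source: str = "") -> "ZParams":
        frame = pd.read_csv(path, sep="\t", index_col="feature_id")
        return cls(frame["mean"], frame["sd"], source=source)


def fit_z_params(
    X_or_features,
    control_samples,
    sd_floor: float = 1e-8,
    source: str = "",
) -> ZParams:
    """Fit per-feature mean and SD on control columns only.

    SD uses the n-1 denominator.  Features whose control SD is at or
    below ``sd_floor`` are excluded from the parameters and listed in
    ``ZParams.excluded`` (applying the transform would divide by ~0).
    """
    frame = _frame(X_or_features)
    control_samples = list(control_samples)
    if len(control_samples) < 2:
        raise ValidationError("need >= 2 control samples to fit Z-params")
    ctrl = frame[control_samples]
    mean = ctrl.mean(axis=1)
    sd = ctrl.std(axis=1, ddof=1)
    degenerate = (sd <= sd_floor) | sd.isna() | mean.isna()
    excluded = frame.index[degenerate].tolist()
    if excluded:
        warnings.warn(
            f"{len(excluded)} features with control SD <= {sd_floor} excluded"
        )
    keep = frame.index[~degenerate]
    return ZParams(mean.loc[keep], sd.loc[keep], source=source, excluded=excluded)


def apply_z(X_or_features, params: ZParams) -> pd.DataFrame:
    """Standardize all samples with control-fitted parameters.

    Features present in ``params`` but absent from the matrix raise an
    error; matrix features absent from ``params`` are dropped (with a
    warning), since no valid scaling exists for them.
    """
    frame = _frame(X_or_features)
    missing = [f for f in params.feature_ids if f not in frame.index]
    if missing:
        raise ValidationError(f"matrix lacks features in params: {missing[:5]}")
    dropped = frame.index.difference(params.mean.index)
    if len(dropped):
        warnings.warn(
            f"{len(dropped)} features without Z-params dropped"
        )
    sub = frame.loc[params.mean.index]
    return sub.sub(params.mean, axis=0).div(params.sd, axis=0)
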