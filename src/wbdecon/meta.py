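"""Cross-dataset similarity and common-signature meta-analysis.

Given many independent case/control datasets, this module derives
per-dataset differential statistics and log2 fold-change profiles,
pools *disease-informative* genes (top differential genes in at least
one dataset, measured in more than half of them), measures similarity
between datasets as the Spearman correlation of their fold-change
profiles over those genes, clusters datasets by complete linkage on
``1 - correlation``, and detects genes commonly regulated in the same
direction across many datasets with a permutation-based FDR: observed
counts of genes differential in >= n datasets are compared with the
counts obtained when each dataset's differential-gene labels are
reassigned uniformly at random among its measured genes, keeping set
sizes fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import ttest_ind
from statsmodels.stats.multitest import multipletests

from .datamodel import ExpressionDataset, ValidationError


@dataclass
class FoldChangeProfile:
    """Genes x datasets log2 fold changes (case mean - control mean)."""

    values: pd.DataFrame  # NaN where gene unmeasured in a dataset

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def dataset_ids(self) -> list[str]:
        return self.values.columns.tolist()


def differential_stats(X: ExpressionDataset) -> pd.DataFrame:
    """Per-gene case-vs-control differential statistics for one dataset.

    Linear-scale input is log2(x+1)-transformed first.  Returns a frame
    indexed by gene with columns ``log2fc`` (case mean - control mean),
    ``t`` (Welch), ``p`` and ``fdr`` (Benjamini-Hochberg across genes).
    """
    if X.annotations is None:
        raise ValidationError("dataset must be annotated")
    case_ids, ctrl_ids = X.case_ids(), X.control_ids()
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValidationError("need >= 2 samples per group")
    vals = X.values
    if X.scale == "linear":
        vals = np.log2(vals + 1.0)
    a = vals[case_ids].to_numpy(dtype=float)
    b = vals[ctrl_ids].to_numpy(dtype=float)
    log2fc = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit")
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    fdr = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        fdr[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return pd.DataFrame(
        {"log2fc": log2fc, "t": t, "p": p, "fdr": fdr}, index=vals.index
    )


def fold_change_profile(stats: dict[str, pd.DataFrame]) -> FoldChangeProfile:
    """Assemble per-dataset log2 fold changes into one genes x datasets frame."""
    cols = {did: s["log2fc"] for did, s in stats.items()}
    return FoldChangeProfile(pd.DataFrame(cols))


def select_informative_genes(
    stats: dict[str, pd.DataFrame],
    top_m: int = 100,
    min_coverage_frac: float = 0.5,
) -> list[str]:
    """Pool disease-informative genes across datasets.

    A gene qualifies when it is (1) among the ``top_m`` most
    differentially expressed genes (smallest p, ties broken by larger
    |log2fc| then gene id) in at least one dataset, and (2) measured in
    more than ``min_coverage_frac`` of the datasets.  The first rule
    discards genes unchanged everywhere while giving each dataset an
    equal vote; the second removes genes with poor coverage.
    """
    if len(stats) < 2:
        raise ValidationError("need >= 2 datasets")
    union: set[str] = set()
    for s in stats.values():
        measured = s.dropna(subset=["p"])
        order = pd.DataFrame(
            {
                "p": measured["p"],
                "absfc": -measured["log2fc"].abs(),
                "gid": measured.index.astype(str),
            }
        ).sort_values(["p", "absfc", "gid"], kind="mergesort")
        union |= set(order.head(top_m).index)
    coverage: dict[str, int] = {}
    for s in stats.values():
        for g in s.index[s["log2fc"].notna()]:
            coverage[g] = coverage.get(g, 0) + 1
    n = len(stats)
    out = [
        g for g in union if coverage.get(g, 0) > min_coverage_frac * n
    ]
    return sorted(out)


def similarity_matrix(
    profiles: FoldChangeProfile,
    genes: list[str] | None = None,
    min_shared: int = 3,
) -> pd.DataFrame:
    """Pairwise Spearman correlation of fold-change profiles.

    Uses pairwise-complete genes per dataset pair; pairs sharing fewer
    than ``min_shared`` genes get a missing entry.  Symmetric with a
    unit diagonal.
    """
    vals = profiles.values
    if genes is not None:
        vals = vals.loc[[g for g in genes if g in vals.index]]
    corr = vals.corr(method="spearman", min_periods=min_shared)
    np.fill_diagonal(corr.to_numpy(), 1.0)
    return corr


def cluster_datasets(similarity: pd.DataFrame, k_or_height) -> tuple[pd.Series, np.ndarray]:
    """Complete-linkage clustering of datasets on distance 1 - correlation.

    ``k_or_height``: an ``int`` cuts the tree into that many clusters, a
    ``float`` cuts at that merge height.  Returns (labels, linkage
    matrix).  Missing similarity entries are an error — recompute with
    pairwise-complete genes first.
    """
    if similarity.isna().any().any():
        raise ValidationError(
            "similarity matrix has missing entries; recompute pairwise-complete"
        )
    dist = 1.0 - similarity.to_numpy(dtype=float)
    dist = (dist + dist.T) / 2
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="complete")
    if isinstance(k_or_height, (int, np.integer)):
        labels = fcluster(Z, t=int(k_or_height), criterion="maxclust")
    else:
        labels = fcluster(Z, t=float(k_or_height), criterion="distance")
    return pd.Series(labels, index=similarity.index, name="cluster"), Z


@dataclass
class CommonGeneResult:
    """Observed / permutation-expected counts of shared differential genes."""

    thresholds: list[int]
    observed: list[int]
    expected: list[float]
    fdr: list[float | None]  # expected/observed; None when observed == 0
    up_set: list[str] = field(default_factory=list)
    down_set: list[str] = field(default_factory=list)
    chosen_threshold: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "observed": self.observed,
                "expected": self.expected,
                "fdr": [np.nan if f is None else f for f in self.fdr],
            }
        )


def _direction_sets(
    stats: dict[str, pd.DataFrame], de_fdr_cutoff: float
) -> dict[str, tuple[set[str], set[str], list[str]]]:
    """(up set, down set, measured genes) per dataset at the FDR cutoff."""
    out = {}
    for did, s in stats.items():
        measured = s.index[s["p"].notna()].tolist()
        de = s["fdr"] < de_fdr_cutoff
        up = set(s.index[de & (s["log2fc"] > 0)])
        down = set(s.index[de & (s["log2fc"] < 0)])
        out[did] = (up, down, measured)
    return out


def _overlap_counts(
    sets: list[tuple[set[str], set[str]]], thresholds: list[int]
) -> list[int]:
    """Count genes up-regulated in >= n datasets plus those down in >= n."""
    up_counts: dict[str, int] = {}
    down_counts: dict[str, int] = {}
    for up, down in sets:
        for g in up:
            up_counts[g] = up_counts.get(g, 0) + 1
        for g in down:
            down_counts[g] = down_counts.get(g, 0) + 1
    out = []
    for n in thresholds:
        c = sum(1 for v in up_counts.values() if v >= n)
        c += sum(1 for v in down_counts.values() if v >= n)
        out.append(c)
    return out


def common_genes_fdr(
    stats: dict[str, pd.DataFrame],
    de_fdr_cutoff: float = 0.1,
    n_perm: int = 1000,
    seed: int = 0,
    chosen_threshold: int | None = None,
) -> CommonGeneResult:
    """Permutation FDR for genes shared by at least n datasets.

    Per dataset the differential sets (up / down at BH-FDR <
    ``de_fdr_cutoff``) are fixed; under the null each dataset's labels
    are reassigned uniformly at random among its measured genes with
    set sizes preserved, independently across datasets.  For each
    threshold n in 2..#datasets the direction-consistent observed count
    o_n is compared with the permutation mean p_n; FDR = p_n / o_n.
    """
    if len(stats) < 2:
        raise ValidationError("need >= 2 datasets")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    dirsets = _direction_sets(stats, de_fdr_cutoff)
    dids = list(dirsets)
    thresholds = list(range(2, len(dids) + 1))
    observed = _overlap_counts(
        [(dirsets[d][0], dirsets[d][1]) for d in dids], thresholds
    )

    rng = np.random.default_rng(seed)
    totals = np.zeros(len(thresholds))
    measured_arrays = {d: np.array(dirsets[d][2]) for d in dids}
    sizes = {d: (len(dirsets[d][0]), len(dirsets[d][1])) for d in dids}
    for _ in range(n_perm):
        perm_sets = []
        for d in dids:
            genes = measured_arrays[d]
            n_up, n_down = sizes[d]
            pick = rng.choice(len(genes), size=n_up + n_down, replace=False)
            perm_sets.append(
                (set(genes[pick[:n_up]]), set(genes[pick[n_up:]]))
            )
        totals += _overlap_counts(perm_sets, thresholds)
    expected = (totals / n_perm).tolist()
    fdr = [
        (e / o) if o > 0 else None for e, o in zip(expected, observed)
    ]

    up_set: list[str] = []
    down_set: list[str] = []
    if chosen_threshold is not None:
        up_counts: dict[str, int] = {}
        down_counts: dict[str, int] = {}
        for d in dids:
            for g in dirsets[d][0]:
                up_counts[g] = up_counts.get(g, 0) + 1
            for g in dirsets[d][1]:
                down_counts[g] = down_counts.get(g, 0) + 1
        up_set = sorted(g for g, c in up_counts.items() if c >= chosen_threshold)
        down_set = sorted(
            g for g, c in down_counts.items() if c >= chosen_threshold
        )
    return CommonGeneResult(
        thresholds=thresholds,
        observed=observed,
        expected=expected,
        fdr=fdr,
        up_set=up_set,
        down_set=down_set,
        chosen_threshold=chosen_threshold,
    )


def residual_fold_change_profile(
    collection, markers
) -> FoldChangeProfile:
    """Fold-change-like profiles computed on residual expression.

    For each dataset: estimate frequencies (marker-based), fit the basis
    on that dataset's controls, compute residuals, and take the per-gene
    case-minus-control mean residual.  Used to test whether a similarity
    cluster driven by shared cell-composition change dissolves once the
    composition-explained component is removed.
    """
    from .deconvolution import dsa_frequencies
    from .residuals import compute_residuals, estimate_basis

    cols = {}
    for ds in collection:
        if ds.annotations is None:
            raise ValidationError("datasets must be annotated")
        for did in ds.annotations["dataset_id"].unique():
            sub = ds.select_samples(
                ds.annotations.index[ds.annotations["dataset_id"] == did]
            )
            F, _ = dsa_frequencies(sub, markers)
            ctrl = sub.control_ids()
            basis = estimate_basis(
                sub.select_samples(ctrl), type(F)(F.values[ctrl])
            )
            resid = compute_residuals(sub, F, basis).values
            cols[did] = (
                resid[sub.case_ids()].mean(axis=1)
                - resid[ctrl].mean(axis=1)
            )
    return FoldChangeProfile(pd.DataFrame(cols))
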