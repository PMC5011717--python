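"""Disease-specific classification with leakage-controlled evaluation.

A disease-specific classifier treats case samples of one disease as
positives and *everything else* — healthy controls and cases of other
diseases — as negatives.  Branches are penalized (elastic-net) logistic
regressions trained on one of three Z-transformed feature spaces:

* ``original``   — the expression profile itself (log2 scale),
* ``residual``   — per-sample residuals after removing the
  cell-frequency-explained component,
* ``cell_component`` — the estimated cell-type frequencies.

The ``combined`` configuration multiplies the posterior probabilities
of the residual and cell-component branches.

Evaluation follows an independent-dataset schema: positives in a test
round come only from a held-out dataset that contributed no training
positives.  Because the held-out dataset's controls are needed to fit
feature-generation parameters (Z-params and the healthy basis), its
samples rotate through ten sub-folds: nine tenths fit parameters only,
the remaining tenth is scored.  Samples of all other diseases rotate
through a standard stratified 10-fold split between training and test
negatives.  Every round asserts that no sample is both parameter-fitting
and scored, and that no test positive shares a dataset with a training
positive.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, ttest_ind
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .datamodel import ExpressionDataset, MarkerSets, ValidationError
from .deconvolution import dsa_frequencies, signature_nnls_frequencies
from .preprocess import apply_z, fit_z_params
from .residuals import compute_residuals, estimate_basis

DEFAULT_L1_RATIOS = (0.0, 0.25, 0.5, 0.75, 1.0)
DEFAULT_CS = tuple(np.logspace(-2, 2, 5))
DEFAULT_N_TOP_GRID = (50, 100, 200, 500, 1000)


def welch_t_by_feature(Z: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Welch t-statistic per feature (row) between label groups."""
    y = labels.loc[Z.columns].astype(bool).to_numpy()
    a = Z.loc[:, y].to_numpy(dtype=float)
    b = Z.loc[:, ~y].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, _ = ttest_ind(a, b, axis=1, equal_var=False)
    return pd.Series(t, index=Z.index)


def select_top_features(Z: pd.DataFrame, labels: pd.Series, n_top: int) -> list[str]:
    """Rank features by |Welch t| descending; ties broken by feature id.

    Returns the first ``min(n_top, available)`` feature ids.  Features
    with undefined t (e.g. zero variance in both groups) rank last.
    """
    if n_top < 1:
        raise ValidationError("n_top must be >= 1")
    y = labels.loc[Z.columns].astype(bool)
    if y.all() or not y.any():
        raise ValidationError("both classes required for feature selection")
    t = welch_t_by_feature(Z, labels)
    score = t.abs().fillna(-np.inf)
    order = pd.DataFrame({"score": -score, "fid": score.index.astype(str)})
    order = order.sort_values(["score", "fid"], kind="mergesort")
    return order["fid"].head(n_top).tolist()


def auc(scores, labels) -> float:
    """Area under the ROC curve, Mann-Whitney form; ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC requires both classes")
    r = rankdata(scores)
    return float((r[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class TrainedBranch:
    """One fitted elastic-net logistic branch."""

    feature_ids: list[str]
    model: LogisticRegression
    l1_ratio: float
    C: float
    inner_auc: float
    z_source: str = ""

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(self.model.coef_.ravel(), index=self.feature_ids)


@dataclass
class DiseaseClassifier:
    """Fitted disease-specific model: up to two branches + combination rule."""

    disease: str
    branches: dict[str, TrainedBranch]
    combination: str = "single"  # or "product"


def _stratified_splits(y: np.ndarray, n_folds: int, seed: int):
    counts = np.bincount(y.astype(int), minlength=2)
    eff = min(n_folds, counts.min())
    if eff < 2:
        raise ValidationError(
            f"cannot form {n_folds} stratified folds with class counts {counts}"
        )
    skf = StratifiedKFold(n_splits=eff, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def train_branch(
    Z: pd.DataFrame,
    labels: pd.Series,
    n_top: int | None = None,
    inner_folds: int = 10,
    seed: int = 0,
    l1_ratios=DEFAULT_L1_RATIOS,
    Cs=DEFAULT_CS,
    class_weight="balanced",
    max_iter: int = 2000,
    z_source: str = "",
) -> TrainedBranch:
    """Fit an elastic-net logistic branch with inner-CV model selection.

    Features (rows of ``Z``, assumed already Z-transformed) are first
    reduced to the top ``n_top`` by |Welch t| on the training labels.
    The penalty mix (l1_ratio) and inverse regularization strength (C)
    are chosen to maximize mean AUC over a seeded stratified inner
    cross-validation; the winning pair is refit on all training data.
    Ties are resolved toward stronger regularization (smaller C), then
    smaller l1_ratio.
    """
    features = (
        select_top_features(Z, labels, n_top) if n_top is not None else list(Z.index)
    )
    Xt = Z.loc[features, :].T.to_numpy(dtype=float)
    y = labels.loc[Z.columns].astype(bool).to_numpy()
    if y.all() or not y.any():
        raise ValidationError("both classes required for training")
    splits = _stratified_splits(y, inner_folds, seed)

    def _fit(l1, C, X_fit, y_fit, tol, iters):
        clf = LogisticRegression(
            solver="saga",
            l1_ratio=l1,
            C=C,
            class_weight=class_weight,
            max_iter=iters,
            tol=tol,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X_fit, y_fit)
        return clf

    # model selection uses a loose tolerance (ranking hyperparameters only);
    # the winning pair is refit tightly on all training data below
    best = None
    for C in sorted(Cs):
        for l1 in sorted(l1_ratios):
            fold_aucs = []
            for tr, te in splits:
                if y[te].all() or not y[te].any():
                    continue
                clf = _fit(l1, C, Xt[tr], y[tr], tol=1e-2, iters=300)
                fold_aucs.append(auc(clf.predict_proba(Xt[te])[:, 1], y[te]))
            if not fold_aucs:
                continue
            mean_auc = float(np.mean(fold_aucs))
            if best is None or mean_auc > best[0] + 1e-12:
                best = (mean_auc, l1, C)
    if best is None:
        raise ValidationError("no valid inner-CV split produced both classes")
    inner_auc, l1, C = best
    model = _fit(l1, C, Xt, y, tol=1e-4, iters=max_iter)
    return TrainedBranch(
        feature_ids=features,
        model=model,
        l1_ratio=l1,
        C=C,
        inner_auc=inner_auc,
        z_source=z_source,
    )


def predict_posterior(branch: TrainedBranch, Z_new: pd.DataFrame) -> pd.Series:
    """Posterior probability of the positive class for each sample column."""
    missing = [f for f in branch.feature_ids if f not in Z_new.index]
    if missing:
        raise ValidationError(f"features missing from matrix: {missing[:10]}")
    Xt = Z_new.loc[branch.feature_ids, :].T.to_numpy(dtype=float)
    p = branch.model.predict_proba(Xt)[:, 1]
    return pd.Series(p, index=Z_new.columns)


def combine_posteriors(p_a, p_b) -> np.ndarray:
    """Element-wise product of two posterior probability vectors."""
    a = np.asarray(p_a, dtype=float)
    b = np.asarray(p_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("posterior vectors differ in length")
    if ((a < 0) | (a > 1) | (b < 0) | (b > 1)).any():
        raise ValidationError("posteriors must lie in [0, 1]")
    return a * b


def robust_gene_list(runs, branch: str = "residual") -> list[str]:
    """Genes with nonzero coefficient in a strict majority of runs.

    ``runs`` may be fitted branches or whole :class:`DiseaseClassifier`
    objects (in which case the named branch is inspected, falling back
    to the classifier's only branch).  Sorted by selection frequency
    (descending), ties by gene id.
    """
    branches = []
    for r in runs:
        if isinstance(r, DiseaseClassifier):
            branches.append(
                r.branches.get(branch) or next(iter(r.branches.values()))
            )
        else:
            branches.append(r)
    if len(branches) < 2:
        raise ValidationError("need >= 2 fitted runs")
    counts: dict[str, int] = {}
    for b in branches:
        coef = b.coefficients
        for g in coef.index[coef != 0]:
            counts[g] = counts.get(g, 0) + 1
    half = len(branches) / 2
    selected = [(g, c) for g, c in counts.items() if c > half]
    selected.sort(key=lambda gc: (-gc[1], gc[0]))
    return [g for g, _ in selected]


# ---------------------------------------------------------------------------
# Independent-dataset evaluation schema
# ---------------------------------------------------------------------------

FEATURE_CONFIGS = ("original", "residual", "cell_component", "combined")


@dataclass
class RoundAudit:
    """Sample-role record for one evaluation round."""

    held_out_dataset: str
    fold: int
    repeat: int
    param_fit: set[str]
    train: set[str]
    test: set[str]
    train_pos: set[str]
    test_pos: set[str]
    train_pos_datasets: set[str]
    test_pos_datasets: set[str]


@dataclass
class EvaluationResult:
    """Per-round AUCs and summaries of one disease-specific evaluation."""

    disease: str
    rounds: pd.DataFrame  # columns: repeat, held_out_dataset, fold, config, auc
    audits: list[RoundAudit]

    def mean_auc(self) -> pd.Series:
        return self.rounds.groupby("config")["auc"].mean()

    def per_repeat_mean(self) -> pd.DataFrame:
        return self.rounds.pivot_table(
            index="repeat", columns="config", values="auc", aggfunc="mean"
        )


def audit_leakage(result: EvaluationResult) -> list[str]:
    """Return descriptions of leakage violations (empty when clean)."""
    problems = []
    for a in result.audits:
        overlap = a.param_fit & a.test
        if overlap:
            problems.append(
                f"{a.held_out_dataset} fold {a.fold}: samples in both "
                f"param-fit and test: {sorted(overlap)[:5]}"
            )
        shared = a.train_pos_datasets & a.test_pos_datasets
        if shared:
            problems.append(
                f"{a.held_out_dataset} fold {a.fold}: positive train/test "
                f"dataset overlap: {sorted(shared)}"
            )
    return problems


def _positive_labels(ann: pd.DataFrame, disease: str) -> pd.Series:
    return ((ann["disease"] == disease) & (ann["group"] == "case")).astype(bool)


def _fold_assignments(
    ann: pd.DataFrame, n_folds: int, rng: np.random.Generator
) -> pd.Series:
    """Assign samples of one dataset to folds, stratified by group."""
    fold = pd.Series(-1, index=ann.index, dtype=int)
    for grp in ("case", "control"):
        ids = ann.index[ann["group"] == grp].to_numpy()
        ids = ids[rng.permutation(len(ids))]
        fold.loc[ids] = np.arange(len(ids)) % n_folds
    return fold


def evaluate_disease_specific(
    collection: list[ExpressionDataset],
    disease: str,
    features=FEATURE_CONFIGS,
    markers: MarkerSets | None = None,
    signature=None,
    n_top: int = 100,
    outer_repeats: int = 10,
    n_subfolds: int = 10,
    inner_folds: int = 3,
    l1_ratios=(0.0, 0.5, 1.0),
    Cs=(0.1, 1.0, 10.0),
    seed: int = 0,
    oracle=None,
) -> EvaluationResult:
    """Run the independent-dataset evaluation for one disease.

    ``collection`` is a list of annotated linear-scale datasets; the
    target disease must appear in at least two of them.  ``markers`` (or
    ``signature``) configures the deconvolution used for cell-component
    and residual features.  Returns per-round AUCs for every requested
    feature configuration, with full audit records.

    ``oracle``, when given, replaces trained models by a callable
    ``oracle(sample_ids) -> scores`` for plumbing checks.

    The inner-CV hyperparameter grid defaults here are deliberately
    compact so that a full multi-repeat evaluation remains tractable;
    ``train_branch`` retains the wider default grid for standalone use.
    """
    features = tuple(features)
    unknown = set(features) - set(FEATURE_CONFIGS)
    if unknown:
        raise ValidationError(f"unknown feature configurations: {sorted(unknown)}")
    by_id: dict[str, ExpressionDataset] = {}
    for ds in collection:
        if ds.annotations is None:
            raise ValidationError("datasets must be annotated")
        for did in ds.annotations["dataset_id"].unique():
            if did in by_id:
                raise ValidationError(f"duplicate dataset id {did}")
            by_id[did] = ds.select_samples(
                ds.annotations.index[ds.annotations["dataset_id"] == did]
            )
    disease_sets = [
        did
        for did, ds in by_id.items()
        if (_positive_labels(ds.annotations, disease)).any()
    ]
    if len(disease_sets) < 2:
        raise ValidationError(
            f"disease {disease!r} needs >= 2 independent datasets "
            f"(found {len(disease_sets)})"
        )

    need_freq = bool({"residual", "cell_component", "combined"} & set(features))
    freqs = {}
    if need_freq:
        for did, ds in by_id.items():
            if markers is not None:
                freqs[did], _ = dsa_frequencies(ds, markers)
            elif signature is not None:
                freqs[did] = signature_nnls_frequencies(ds, signature)
            else:
                raise ValidationError(
                    "markers or signature required for deconvolution features"
                )
            if freqs[did].values.isna().any().any():
                raise ValidationError(
                    f"dataset {did}: frequency estimation failed for some samples"
                )

    log_expr = {
        did: np.log2(ds.values + 1.0) if ds.scale == "linear" else ds.values
        for did, ds in by_id.items()
    }

    master = np.random.default_rng(seed)
    repeat_seeds = [int(master.integers(2**31)) for _ in range(outer_repeats)]
    records = []
    audits: list[RoundAudit] = []

    for repeat, rep_seed in enumerate(repeat_seeds):
        rng = np.random.default_rng(rep_seed)
        folds = {
            did: _fold_assignments(ds.annotations, n_subfolds, rng)
            for did, ds in by_id.items()
        }
        # caches keyed by (dataset_id, excluded_fold); excluded_fold is None
        # when every sample of the dataset is available for parameter fitting
        cache: dict[tuple[str, int | None], dict[str, pd.DataFrame]] = {}

        def round_features(did: str, excluded_fold: int | None):
            key = (did, excluded_fold)
            if key in cache:
                return cache[key]
            ds = by_id[did]
            ann = ds.annotations
            if excluded_fold is None:
                avail = ann.index
            else:
                avail = ann.index[folds[did] != excluded_fold]
            ctrl = [s for s in avail if ann.loc[s, "group"] == "control"]
            if len(ctrl) < 2:
                raise ValidationError(
                    f"dataset {did}: < 2 training controls for parameter fitting"
                )
            out: dict[str, pd.DataFrame] = {"param_fit": pd.Index(ctrl)}
            zp = fit_z_params(log_expr[did], ctrl, source=did)
            out["original"] = apply_z(log_expr[did], zp)
            if need_freq:
                F = freqs[did]
                basis = estimate_basis(
                    ds.select_samples(ctrl),
                    type(F)(F.values[ctrl]),
                )
                resid = compute_residuals(ds, F, basis).values
                zp_r = fit_z_params(resid, ctrl, source=did)
                out["residual"] = apply_z(resid, zp_r)
                zp_c = fit_z_params(F.values, ctrl, source=did)
                out["cell_component"] = apply_z(F.values, zp_c)
            cache[key] = out
            return out

        for held_out in disease_sets:
            same_disease_train = [
                d for d in disease_sets if d != held_out
            ]
            other_sets = [d for d in by_id if d not in disease_sets]
            for fold in range(n_subfolds):
                train_ids: list[str] = []
                test_ids: list[str] = []
                param_fit: set[str] = set()
                parts: dict[str, dict[str, pd.DataFrame]] = {}

                ho_ann = by_id[held_out].annotations
                ho_fold = folds[held_out]
                ho_test = ho_ann.index[ho_fold == fold].tolist()
                test_ids += ho_test
                parts[held_out] = round_features(held_out, fold)
                param_fit |= set(parts[held_out]["param_fit"])

                for did in same_disease_train:
                    ann = by_id[did].annotations
                    train_ids += ann.index.tolist()
                    parts[did] = round_features(did, None)
                    param_fit |= set(parts[did]["param_fit"])

                for did in other_sets:
                    ann = by_id[did].annotations
                    f = folds[did]
                    test_ids += ann.index[f == fold].tolist()
                    train_ids += ann.index[f != fold].tolist()
                    parts[did] = round_features(did, fold)
                    param_fit |= set(parts[did]["param_fit"])

                all_ann = pd.concat(
                    [by_id[d].annotations for d in parts]
                )
                labels = _positive_labels(all_ann, disease)
                test_pos = {s for s in test_ids if labels.get(s, False)}
                train_pos = {s for s in train_ids if labels.get(s, False)}
                audit = RoundAudit(
                    held_out_dataset=held_out,
                    fold=fold,
                    repeat=repeat,
                    param_fit=param_fit,
                    train=set(train_ids),
                    test=set(test_ids),
                    train_pos=train_pos,
                    test_pos=test_pos,
                    train_pos_datasets={
                        all_ann.loc[s, "dataset_id"] for s in train_pos
                    },
                    test_pos_datasets={
                        all_ann.loc[s, "dataset_id"] for s in test_pos
                    },
                )
                audits.append(audit)
                assert not (audit.param_fit & audit.test), (
                    "leakage: parameter-fitting sample scored as test"
                )
                assert not (
                    audit.train_pos_datasets & audit.test_pos_datasets
                ), "leakage: positive train/test dataset overlap"
                if not test_pos or len(test_ids) == len(test_pos):
                    continue  # AUC undefined this round

                y_test = labels.loc[test_ids]
                round_seed = int(
                    np.random.default_rng(
                        (rep_seed, zlib.crc32(held_out.encode()), fold)
                    ).integers(2**31)
                )

                if oracle is not None:
                    scores = np.asarray(oracle(test_ids), dtype=float)
                    for config in features:
                        records.append(
                            (repeat, held_out, fold, config,
                             auc(scores, y_test.to_numpy()))
                        )
                    continue

                def branch_matrix(space: str) -> pd.DataFrame:
                    mats = [parts[d][space] for d in parts]
                    common = mats[0].index
                    for m in mats[1:]:
                        common = common.intersection(m.index)
                    return pd.concat([m.loc[common] for m in mats], axis=1)

                posteriors: dict[str, pd.Series] = {}
                needed_spaces = set()
                for config in features:
                    if config == "combined":
                        needed_spaces |= {"residual", "cell_component"}
                    else:
                        needed_spaces.add(config)
                for space in sorted(needed_spaces):
                    Zfull = branch_matrix(space)
                    Ztrain = Zfull[train_ids]
                    top = n_top if space != "cell_component" else None
                    branch = train_branch(
                        Ztrain,
                        labels,
                        n_top=top,
                        inner_folds=inner_folds,
                        seed=round_seed,
                        l1_ratios=l1_ratios,
                        Cs=Cs,
                        z_source=f"{held_out}:{fold}",
                    )
                    posteriors[space] = predict_posterior(
                        branch, Zfull[test_ids]
                    )
                for config in features:
                    if config == "combined":
                        scores = combine_posteriors(
                            posteriors["residual"], posteriors["cell_component"]
                        )
                    else:
                        scores = posteriors[config].to_numpy()
                    records.append(
                        (repeat, held_out, fold, config,
                         auc(scores, y_test.to_numpy()))
                    )

    rounds = pd.DataFrame(
        records, columns=["repeat", "held_out_dataset", "fold", "config", "auc"]
    )
    return EvaluationResult(disease=disease, rounds=rounds, audits=audits)
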