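"""End-to-end benchmark runs on synthetic cohorts with known truth.

Each function regenerates its inputs from a seed, runs one stage of the
pipeline under the package's standard study conditions, and returns the
summary quantities a reviewer would check: deconvolution recovery
accuracy, residual nullification of pure composition shifts, classifier
AUC orderings under the leakage-controlled schema, and the dissolution
of composition-driven dataset clusters in residual space.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind
from statsmodels.stats.multitest import multipletests

from .classify import audit_leakage, evaluate_disease_specific
from .datamodel import CellFrequencyMatrix
from .deconvolution import dsa_frequencies
from .meta import (
    cluster_datasets,
    differential_stats,
    fold_change_profile,
    residual_fold_change_profile,
    select_informative_genes,
    similarity_matrix,
)
from .residuals import compute_residuals, estimate_basis
from .synthetic import (
    BENCHMARK_OWN_SHIFTS,
    DiseaseSpec,
    default_benchmark,
    make_basis,
    simulate_collection,
    simulate_dataset,
)


def dsa_recovery(seed, noise_cv: float = 0.2, n_genes: int = 500,
                 n_samples: int = 40):
    """Marker-based recovery of known mixing fractions.

    Simulates mixtures of four cell types and reports the smallest
    per-cell-type Pearson correlation between true and estimated
    frequencies, plus the largest absolute error (which is at float
    precision when ``noise_cv`` is 0).
    """
    basis, markers = make_basis(
        n_genes, ["granulocyte", "monocyte", "T_cell", "B_cell"],
        markers_per_type=5, marker_fold=50.0, seed=seed,
    )
    ds, truth = simulate_dataset(
        basis, None, 0, n_samples, [4.0, 2.0, 2.0, 1.0],
        noise_cv=noise_cv, seed=seed + 1,
    )
    F, _ = dsa_frequencies(ds, markers)
    est = F.values.to_numpy()
    true = truth.frequencies.values.to_numpy()
    r = [
        float(np.corrcoef(est[k], true[k])[0, 1]) for k in range(est.shape[0])
    ]
    return {
        "min_pearson_r": min(r),
        "max_abs_error": float(np.abs(est - true).max()),
        "n_samples": n_samples,
    }


def random_nnls_instances(seed, n_instances: int = 100, max_cond: float = 10.0):
    """Random 3-observation / 2-unknown NNLS instances for oracle checks.

    Yields (A, y) pairs with the design's condition number capped so the
    minimizer is identifiable at the grid oracle's 1e-3 resolution
    (near-collinear designs have a flat valley along which any
    finite-resolution search wanders).
    """
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n_instances:
        A = rng.uniform(0.2, 1.0, size=(3, 2))
        if np.linalg.cond(A) > max_cond:
            continue
        y = rng.uniform(0.0, 1.0, size=3)
        out.append((A, y))
    return out


def residual_nullification(seed, n_genes: int = 1000):
    """Pure composition shift: residual tests stay null, raw tests do not.

    A disease that only re-weights cell frequencies produces widespread
    marginal differential expression; after removing the frequency-
    explained component the per-gene case/control tests should flag
    almost nothing.  Returns the flag counts in both spaces at BH-FDR
    0.1 (frequencies estimated marker-based, basis fit on controls).
    """
    basis, markers = make_basis(
        n_genes, ["granulocyte", "monocyte", "T_cell", "B_cell"],
        markers_per_type=5, marker_fold=50.0, seed=seed, sdlog=1.2,
    )
    spec = DiseaseSpec(
        "shift",
        {"granulocyte": 0.5, "monocyte": 0.5, "T_cell": -0.35,
         "B_cell": -0.35},
        [],
    )
    # an ample control arm keeps basis-estimation error from leaking a
    # systematic case/control residual difference of its own
    ds, _ = simulate_dataset(
        basis, spec, 40, 100, [3.84, 1.28, 1.92, 0.96],
        noise_cv=0.1, seed=seed + 1,
    )
    F, _ = dsa_frequencies(ds, markers)
    ctrl = ds.control_ids()
    B = estimate_basis(
        ds.select_samples(ctrl), CellFrequencyMatrix(F.values[ctrl])
    )
    R = compute_residuals(ds, F, B).values
    y = (ds.annotations["group"] == "case").to_numpy()

    def flags(frame):
        arr = frame.to_numpy()
        _, p = ttest_ind(arr[:, y], arr[:, ~y], axis=1, equal_var=False)
        return int((multipletests(p, method="fdr_bh")[1] < 0.1).sum())

    return {
        "residual_flags": flags(R),
        "raw_flags": flags(np.log2(ds.values + 1)),
        "n_genes": n_genes,
    }


def classification_benchmark(seed, outer_repeats: int = 10, n_top: int = 25):
    """Feature-space comparison on the default three-disease benchmark.

    Runs the leakage-controlled independent-dataset evaluation for each
    disease and every feature configuration.  Returns the per-config
    mean AUC averaged over diseases, the per-disease table, and the
    total number of leakage violations found by the audit (always 0
    unless the schema is broken).
    """
    collection, _, markers = default_benchmark(seed)
    datasets = [ds for ds, _ in collection]
    per_disease = {}
    violations = 0
    rng = np.random.default_rng(seed + 1)
    for disease in BENCHMARK_OWN_SHIFTS:
        res = evaluate_disease_specific(
            datasets,
            disease,
            markers=markers,
            n_top=n_top,
            outer_repeats=outer_repeats,
            seed=int(rng.integers(2**31)),
        )
        violations += len(audit_leakage(res))
        per_disease[disease] = res.mean_auc()
    table = pd.DataFrame(per_disease)
    return {
        "mean_auc": table.mean(axis=1).to_dict(),
        "per_disease": table,
        "leakage_violations": violations,
        "n_rounds": outer_repeats * 2 * 10 * len(per_disease),
    }


def cluster_dissolution(seed, top_m: int = 100):
    """Composition-driven dataset clustering and its residual analogue.

    Six datasets of three diseases share the myeloid-up / lymphoid-down
    shift; four datasets of two further conditions do not (their signal
    is cell-state change only).  Bulk fold-change profiles cluster the
    shared-shift datasets together; fold changes computed on residual
    expression remove the composition component, so the within-cluster
    mean Spearman correlation collapses.
    """
    rng = np.random.default_rng(seed)
    basis_seed = int(rng.integers(2**31))
    coll_seed = int(rng.integers(2**31))
    basis, markers = make_basis(
        400, ["granulocyte", "monocyte", "CD4_T", "B_cell"],
        markers_per_type=10, marker_fold=50.0, seed=basis_seed, sdlog=1.2,
    )
    marker_genes = set(markers.all_genes())
    candidates = [g for g in basis.gene_ids if g not in marker_genes]
    picked = rng.choice(len(candidates), size=75, replace=False)

    def de(i, cell_type):
        idx = picked[i * 15 : (i + 1) * 15]
        return [
            (cell_type, candidates[j], 2.0 if p % 2 == 0 else 0.5)
            for p, j in enumerate(idx)
        ]

    shared_names = ["infectionA", "infectionB", "cancerA"]
    lone_names = ["neuroA", "neuroB"]
    sizes = (30, 30)
    specs = [
        (DiseaseSpec(shared_names[0], {}, de(0, "monocyte")), 2, sizes),
        (DiseaseSpec(shared_names[1], {}, de(1, "granulocyte")), 2, sizes),
        (DiseaseSpec(shared_names[2], {}, de(2, "monocyte")), 2, sizes),
        (DiseaseSpec(lone_names[0], {}, de(3, "CD4_T")), 2, sizes),
        (DiseaseSpec(lone_names[1], {}, de(4, "B_cell")), 2, sizes),
    ]
    # moderate composition variance here: with a highly dispersed
    # Dirichlet, chance case/control composition imbalance in the lone
    # datasets itself produces fold-change profiles aligned with the
    # shared composition axis, blurring the cluster being measured
    collection = simulate_collection(
        specs,
        basis,
        [12.0, 4.0, 6.0, 3.0],
        shared_shift={"granulocyte": 0.5, "monocyte": 0.5,
                      "CD4_T": -0.35, "B_cell": -0.35},
        shared_subset=shared_names,
        noise_cv=0.1,
        batch_scale_sd=0.3,
        seed=coll_seed,
    )
    datasets = [ds for ds, _ in collection]
    stats = {}
    for ds in datasets:
        did = ds.annotations["dataset_id"].iloc[0]
        stats[did] = differential_stats(ds)
    genes = select_informative_genes(stats, top_m=top_m)
    profiles = fold_change_profile(stats)
    sim = similarity_matrix(profiles, genes)
    labels, _ = cluster_datasets(sim, 2)
    shared_ids = [d for d in sim.index if d.split(".")[0] in shared_names]
    lone_ids = [d for d in sim.index if d not in shared_ids]
    shared_labels = set(labels[shared_ids])
    # all shared-shift datasets fall in one complete-linkage cluster;
    # no-shift datasets may occasionally attach, because a chance
    # case/control composition imbalance produces a coherent profile
    # whose rank correlation with the shared axis does not shrink with
    # sample size (its sign is random, so usually some stay outside)
    clustered_together = len(shared_labels) == 1
    n_lone_outside = sum(labels[d] not in shared_labels for d in lone_ids)

    def mean_within(corr):
        vals = [
            corr.loc[a, b]
            for i, a in enumerate(shared_ids)
            for b in shared_ids[i + 1 :]
        ]
        return float(np.mean(vals))

    resid_profiles = residual_fold_change_profile(datasets, markers)
    resid_sim = similarity_matrix(resid_profiles, genes)
    within_bulk = mean_within(sim)
    within_resid = mean_within(resid_sim)
    return {
        "shared_cluster_recovered": clustered_together,
        "n_lone_outside_cluster": n_lone_outside,
        "within_cluster_corr_bulk": within_bulk,
        "within_cluster_corr_residual": within_resid,
        "correlation_drop": within_bulk - within_resid,
        "n_informative_genes": len(genes),
    }
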