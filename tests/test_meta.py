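import numpy as np
import pandas as pd
import pytest

from wbdecon import (
    ExpressionDataset,
    ValidationError,
    cluster_datasets,
    common_genes_fdr,
    differential_stats,
    fold_change_profile,
    make_annotations,
    select_informative_genes,
    similarity_matrix,
)
from wbdecon.meta import FoldChangeProfile


def _log2_dataset(case, ctrl, genes=None):
    case = np.asarray(case, dtype=float)
    ctrl = np.asarray(ctrl, dtype=float)
    genes = genes or [f"g{i}" for i in range(case.shape[0])]
    cols = [f"p{i}" for i in range(case.shape[1])] + [
        f"n{i}" for i in range(ctrl.shape[1])
    ]
    ann = make_annotations(
        cols, "d1", ["case"] * case.shape[1] + ["control"] * ctrl.shape[1]
    )
    return ExpressionDataset(
        pd.DataFrame(np.concatenate([case, ctrl], axis=1), index=genes,
                     columns=cols),
        "log2",
        ann,
    )


class TestDifferentialStats:
    def test_welch_hand_example(self):
        # case (5,6,7) vs control (1,2,3): diff 4, se 0.8165 -> t = 4.899
        ds = _log2_dataset([[5, 6, 7]], [[1, 2, 3]])
        out = differential_stats(ds)
        assert out.loc["g0", "log2fc"] == pytest.approx(4.0)
        assert out.loc["g0", "t"] == pytest.approx(4.899, abs=1e-3)

    def test_identical_group_means_give_zero(self):
        ds = _log2_dataset([[1, 2, 3]], [[2, 1, 3]])
        out = differential_stats(ds)
        assert out.loc["g0", "log2fc"] == pytest.approx(0.0)
        assert out.loc["g0", "t"] == pytest.approx(0.0)

    def test_bh_step_up_hand_example(self):
        # p = (.01, .02, .03) -> adjusted (.03, .03, .03)
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_linear_input_logged_first(self):
        ds_lin = _log2_dataset([[3, 7, 15]], [[0, 1, 3]])
        ds_lin = ExpressionDataset(ds_lin.values, "linear",
                                   ds_lin.annotations)
        out = differential_stats(ds_lin)
        assert out.loc["g0", "log2fc"] == pytest.approx(
            np.mean(np.log2([4, 8, 16])) - np.mean(np.log2([1, 2, 4]))
        )

    def test_small_groups_rejected(self):
        ds = _log2_dataset([[5]], [[1, 2]])
        with pytest.raises(ValidationError):
            differential_stats(ds)


def _stats_frame(p_by_gene, fc_by_gene, fdr=None):
    genes = list(p_by_gene)
    p = pd.Series(p_by_gene)
    frame = pd.DataFrame(
        {
            "log2fc": pd.Series(fc_by_gene),
            "t": 1.0,
            "p": p,
            "fdr": pd.Series(fdr) if fdr is not None else p,
        },
        index=genes,
    )
    return frame


class TestInformativeGenes:
    def test_top_one_with_coverage_rule(self):
        # A tops ds1 (measured everywhere), B tops ds2 (measured once),
        # C tops ds3 (measured in 2 of 3 datasets, > 1/2 coverage)
        stats = {
            "ds1": _stats_frame(
                {"A": 0.001, "C": 0.4}, {"A": 2.0, "C": 0.3}
            ),
            "ds2": _stats_frame(
                {"A": 0.6, "B": 0.001}, {"A": 0.1, "B": 2.0}
            ),
            "ds3": _stats_frame(
                {"A": 0.5, "C": 0.001}, {"A": 0.2, "C": 2.0}
            ),
        }
        out = select_informative_genes(stats, top_m=1, min_coverage_frac=0.5)
        assert out == ["A", "C"]

    def test_large_top_m_returns_all_covered_genes(self):
        stats = {
            "ds1": _stats_frame({"A": 0.1, "B": 0.2}, {"A": 1, "B": 1}),
            "ds2": _stats_frame({"A": 0.3, "B": 0.4}, {"A": 1, "B": 1}),
        }
        assert select_informative_genes(stats, top_m=100) == ["A", "B"]

    def test_single_dataset_rejected(self):
        stats = {"ds1": _stats_frame({"A": 0.1}, {"A": 1.0})}
        with pytest.raises(ValidationError):
            select_informative_genes(stats)


class TestSimilarity:
    def test_self_correlation_is_one(self):
        prof = FoldChangeProfile(pd.DataFrame(
            {"d1": [1.0, 2, 3], "d2": [1.0, 2, 3]},
            index=["a", "b", "c"],
        ))
        sim = similarity_matrix(prof)
        assert sim.loc["d1", "d1"] == 1.0
        assert sim.loc["d1", "d2"] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        prof = FoldChangeProfile(pd.DataFrame(
            {"d1": [1.0, 2, 3], "d2": [3.0, 2, 1]}, index=["a", "b", "c"]
        ))
        assert similarity_matrix(prof).loc["d1", "d2"] == pytest.approx(-1.0)

    def test_partial_rank_agreement(self):
        prof = FoldChangeProfile(pd.DataFrame(
            {"d1": [1.0, 2, 3], "d2": [2.0, 1, 3]}, index=["a", "b", "c"]
        ))
        assert similarity_matrix(prof).loc["d1", "d2"] == pytest.approx(0.5)

    def test_insufficient_shared_genes_left_missing(self):
        prof = FoldChangeProfile(pd.DataFrame(
            {"d1": [1.0, 2, np.nan], "d2": [np.nan, 1.0, 2.0]},
            index=["a", "b", "c"],
        ))
        assert np.isnan(similarity_matrix(prof).loc["d1", "d2"])


class TestClusterDatasets:
    def test_identical_profiles_merge_first(self):
        sim = pd.DataFrame(
            [[1.0, 1.0, 0.1], [1.0, 1.0, 0.2], [0.1, 0.2, 1.0]],
            index=["a", "b", "c"], columns=["a", "b", "c"],
        )
        labels, Z = cluster_datasets(sim, 2)
        assert labels["a"] == labels["b"] != labels["c"]
        assert Z[0, 2] == pytest.approx(0.0)  # first merge at distance 0

    def test_two_pair_structure_recovered(self):
        sim = pd.DataFrame(
            [
                [1.0, 0.9, 0.1, 0.0],
                [0.9, 1.0, 0.2, 0.1],
                [0.1, 0.2, 1.0, 0.85],
                [0.0, 0.1, 0.85, 1.0],
            ],
            index=list("abcd"), columns=list("abcd"),
        )
        labels, _ = cluster_datasets(sim, 2)
        assert labels["a"] == labels["b"]
        assert labels["c"] == labels["d"]
        assert labels["a"] != labels["c"]

    def test_missing_entry_rejected(self):
        sim = pd.DataFrame(
            [[1.0, np.nan], [np.nan, 1.0]], index=["a", "b"],
            columns=["a", "b"],
        )
        with pytest.raises(ValidationError, match="pairwise-complete"):
            cluster_datasets(sim, 2)


class TestCommonGenes:
    def _de_stats(self, up_sets, measured):
        """Build per-dataset stats with chosen up-regulated DE sets."""
        stats = {}
        for did, up in up_sets.items():
            genes = measured[did]
            p = {g: (1e-6 if g in up else 0.9) for g in genes}
            fc = {g: (1.0 if g in up else 0.01) for g in genes}
            fdr = {g: (1e-4 if g in up else 0.9) for g in genes}
            stats[did] = _stats_frame(p, fc, fdr)
        return stats

    def test_gene_shared_by_all_three_counted(self):
        measured = {d: ["g1", "g2", "g3"] for d in ["d1", "d2", "d3"]}
        stats = self._de_stats(
            {"d1": {"g1"}, "d2": {"g1"}, "d3": {"g1"}}, measured
        )
        res = common_genes_fdr(stats, n_perm=10, seed=0, chosen_threshold=3)
        assert res.thresholds == [2, 3]
        assert res.observed == [1, 1]
        assert res.up_set == ["g1"]

    def test_threshold_above_any_overlap_gives_missing_fdr(self):
        measured = {d: ["g1", "g2", "g3", "g4"] for d in ["d1", "d2"]}
        stats = self._de_stats({"d1": {"g1"}, "d2": {"g2"}}, measured)
        res = common_genes_fdr(stats, n_perm=10, seed=0)
        assert res.observed == [0]
        assert res.fdr == [None]

    def test_observed_counts_non_increasing_in_threshold(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(30)]
        measured = {f"d{k}": genes for k in range(4)}
        up_sets = {
            f"d{k}": set(rng.choice(genes, size=8, replace=False))
            for k in range(4)
        }
        stats = self._de_stats(up_sets, measured)
        res = common_genes_fdr(stats, n_perm=20, seed=1)
        assert all(a >= b for a, b in zip(res.observed, res.observed[1:]))
        assert all(a >= b - 1e-9 for a, b in
                   zip(res.expected, res.expected[1:]))

    def test_permutation_mean_matches_hypergeometric_expectation(self):
        # 2 datasets, 10 genes, DE sizes 3 and 3: expected shared-by-2
        # count is 10 * (3/10) * (3/10) = 0.9
        genes = [f"g{i}" for i in range(10)]
        measured = {"d1": genes, "d2": genes}
        stats = self._de_stats(
            {"d1": {"g0", "g1", "g2"}, "d2": {"g0", "g3", "g4"}}, measured
        )
        n_perm = 1000
        res = common_genes_fdr(stats, n_perm=n_perm, seed=3)
        # per-permutation count is hypergeometric with sd ~0.7
        mc_se = 0.7 / np.sqrt(n_perm)
        assert abs(res.expected[0] - 0.9) < 3 * mc_se

    def test_direction_consistency_required(self):
        genes = ["g1", "g2"]
        up = _stats_frame({"g1": 1e-6, "g2": 0.9},
                          {"g1": 1.0, "g2": 0.0},
                          {"g1": 1e-4, "g2": 0.9})
        down = _stats_frame({"g1": 1e-6, "g2": 0.9},
                            {"g1": -1.0, "g2": 0.0},
                            {"g1": 1e-4, "g2": 0.9})
        res = common_genes_fdr({"d1": up, "d2": down}, n_perm=5, seed=0)
        assert res.observed == [0]  # opposite directions do not count

    def test_zero_permutations_rejected(self):
        genes = ["g1"]
        stats = self._de_stats({"d1": {"g1"}, "d2": {"g1"}},
                               {"d1": genes, "d2": genes})
        with pytest.raises(ValidationError):
            common_genes_fdr(stats, n_perm=0)


def test_fold_change_profile_assembles_columns():
    stats = {
        "d1": _stats_frame({"A": 0.1, "B": 0.2}, {"A": 1.5, "B": -0.5}),
        "d2": _stats_frame({"A": 0.3, "C": 0.1}, {"A": 0.5, "C": 2.0}),
    }
    prof = fold_change_profile(stats)
    assert prof.values.loc["A", "d1"] == 1.5
    assert np.isnan(prof.values.loc["C", "d1"])
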