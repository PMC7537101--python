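import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from sklearn.metrics import adjusted_rand_score

from tempoclust.containers import ValidationError
from tempoclust.timecluster import (
    ClusterParams,
    cluster_profiles,
    correlation_distance,
    cut,
    filter_by_centroid,
    filter_by_size,
    hcluster,
    recurrent_gene_report,
    standardize,
    union_profiles,
)

from _oracles import naive_cophenetic

TPS = ("E14.5", "1mo", "6mo", "12mo")


def _profiles(rows: dict[str, list[float]]) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(TPS), dtype=float)


class TestUnionProfiles:
    def test_union_is_any_age_significant_genes(self, tiny_de_table):
        prof = union_profiles(tiny_de_table)
        assert sorted(prof.index) == ["g1", "g2", "g3", "g4"]
        assert list(prof.columns) == list(TPS)

    def test_profiles_keep_nonsignificant_ages(self, tiny_de_table):
        # g1 is significant only at E14.5 yet its profile spans all four ages
        prof = union_profiles(tiny_de_table)
        assert prof.loc["g1"].tolist() == [1.0, 0.5, 0.2, 0.1]

    def test_threshold_is_strict(self, tiny_de_table):
        # significant rows have adjp == 0.01: a threshold of exactly 0.01
        # admits nothing (adjp < threshold), so the union is empty
        with pytest.raises(ValidationError, match="union is empty"):
            union_profiles(tiny_de_table, ClusterParams(adjp_threshold=0.01))

    def test_incomplete_table_rejected(self, tiny_de_table):
        broken = tiny_de_table.drop(index=tiny_de_table.index[0])
        with pytest.raises(ValidationError, match="incomplete"):
            union_profiles(broken)


class TestStandardize:
    def test_each_row_attains_unit_max(self):
        prof = _profiles({"a": [2.0, -4.0, 1.0, 0.0], "b": [-0.1, 0.05, 0.0, 0.02]})
        std = standardize(prof)
        vals = std.to_numpy()
        assert np.abs(vals).max(axis=1) == pytest.approx([1.0, 1.0])
        assert np.all(np.abs(vals) <= 1.0)

    def test_signs_and_ratios_preserved(self):
        std = standardize(_profiles({"a": [2.0, -4.0, 1.0, 0.0]}))
        assert std.loc["a"].tolist() == pytest.approx([0.5, -1.0, 0.25, 0.0])

    def test_all_zero_row_dropped_with_warning(self):
        prof = _profiles({"a": [1.0, 0.0, 0.0, 0.0], "z": [0.0, 0.0, 0.0, 0.0]})
        with pytest.warns(UserWarning, match="all-zero"):
            std = standardize(prof)
        assert list(std.index) == ["a"]


class TestCorrelationDistance:
    def test_identical_profiles_distance_zero(self):
        d = correlation_distance(_profiles({"a": [1, 0, -1, 0], "b": [2, 0, -2, 0]}))
        assert d.loc["a", "b"] == pytest.approx(0.0)

    def test_opposite_profiles_distance_two(self):
        d = correlation_distance(_profiles({"a": [1, 0, -1, 0], "b": [-1, 0, 1, 0]}))
        assert d.loc["a", "b"] == pytest.approx(2.0)

    def test_hand_computed_four_thirds(self):
        # indicator profiles at different ages: corr = -1/3, distance = 4/3
        d = correlation_distance(_profiles({"a": [1, 0, 0, 0], "b": [0, 1, 0, 0]}))
        assert d.loc["a", "b"] == pytest.approx(4.0 / 3.0)

    def test_constant_profile_conventions(self):
        d = correlation_distance(
            _profiles(
                {
                    "flat1": [2, 2, 2, 2],
                    "flat2": [5, 5, 5, 5],
                    "flatneg": [-1, -1, -1, -1],
                    "shape": [1, 0, -1, 0],
                }
            )
        )
        assert d.loc["flat1", "flat2"] == pytest.approx(0.0)  # same sign: corr 1
        assert d.loc["flat1", "flatneg"] == pytest.approx(1.0)  # opposite sign: corr 0
        assert d.loc["flat1", "shape"] == pytest.approx(1.0)  # constant vs shape: corr 0

    def test_matrix_properties(self):
        rng = np.random.default_rng(0)
        prof = pd.DataFrame(rng.normal(size=(12, 4)), columns=list(TPS))
        d = correlation_distance(prof).to_numpy()
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0.0)
        assert np.all((d >= 0.0) & (d <= 2.0))

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValidationError):
            correlation_distance(_profiles({"a": [1, 0, -1, 0]}))


class TestHcluster:
    def test_three_leaf_complete_trace(self):
        # a-b closest (0.1); complete linkage joins c at max(0.5, 0.9) = 0.9
        d = pd.DataFrame(
            [[0.0, 0.1, 0.5], [0.1, 0.0, 0.9], [0.5, 0.9, 0.0]],
            index=["a", "b", "c"],
            columns=["a", "b", "c"],
        )
        dendro = hcluster(d, linkage="complete")
        assert dendro.merges[:, 2] == pytest.approx([0.1, 0.9])
        assert sorted(dendro.merges[0, :2]) == [0, 1]
        assert dendro.merges[1, 3] == 3

    def test_three_leaf_average_trace(self):
        d = pd.DataFrame(
            [[0.0, 0.1, 0.5], [0.1, 0.0, 0.9], [0.5, 0.9, 0.0]],
            index=["a", "b", "c"],
            columns=["a", "b", "c"],
        )
        dendro = hcluster(d, linkage="average")
        assert dendro.merges[:, 2] == pytest.approx([0.1, 0.7])

    @pytest.mark.parametrize("method", ["complete", "single", "average"])
    def test_matches_naive_oracle_cophenetic(self, method):
        rng = np.random.default_rng(5)
        for _ in range(5):
            pts = rng.normal(size=(9, 3))
            D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            d = pd.DataFrame(D, index=[f"g{i}" for i in range(9)])
            d.columns = d.index
            dendro = hcluster(d, linkage=method)
            from scipy.spatial.distance import squareform

            coph = squareform(hierarchy.cophenet(dendro.merges))
            assert coph == pytest.approx(naive_cophenetic(D, method), rel=1e-10)

    def test_asymmetric_matrix_rejected(self):
        d = pd.DataFrame([[0.0, 1.0], [0.5, 0.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValidationError, match="symmetric"):
            hcluster(d)

    def test_unknown_linkage_rejected(self):
        d = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="linkage"):
            hcluster(d, linkage="centroidish")


class TestCut:
    @pytest.fixture
    def small_dendro(self):
        # heights: (a,b) at 0.2, (c,d) at 0.3, all at 1.0
        d = pd.DataFrame(
            [
                [0.0, 0.2, 1.0, 1.0],
                [0.2, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 0.3],
                [1.0, 1.0, 0.3, 0.0],
            ],
            index=["a", "b", "c", "d"],
            columns=["a", "b", "c", "d"],
        )
        return hcluster(d, linkage="complete")

    def test_zero_height_gives_singletons(self, small_dendro):
        labels = cut(small_dendro, 0.0)
        assert labels.nunique() == 4

    def test_above_max_height_gives_one_cluster(self, small_dendro):
        labels = cut(small_dendro, small_dendro.max_height + 1.0)
        assert labels.nunique() == 1

    def test_merge_at_exact_height_not_applied(self, small_dendro):
        # (c,d) merge at exactly 0.3 -> strict rule keeps them apart
        labels = cut(small_dendro, 0.3)
        assert labels["c"] != labels["d"]
        assert labels["a"] == labels["b"]
        labels2 = cut(small_dendro, 0.3 + 1e-9)
        assert labels2["c"] == labels2["d"]

    def test_cluster_count_monotone_in_height(self, small_dendro):
        ks = [cut(small_dendro, h).nunique() for h in [0.0, 0.25, 0.35, 2.0]]
        assert ks == sorted(ks, reverse=True)
        assert ks == [4, 3, 2, 1]

    def test_ids_ordered_by_size_then_first_member(self):
        d = pd.DataFrame(
            [
                [0.0, 0.1, 0.1, 1.0, 1.0],
                [0.1, 0.0, 0.1, 1.0, 1.0],
                [0.1, 0.1, 0.0, 1.0, 1.0],
                [1.0, 1.0, 1.0, 0.0, 0.1],
                [1.0, 1.0, 1.0, 0.1, 0.0],
            ],
            index=list("abcde"),
            columns=list("abcde"),
        )
        labels = cut(hcluster(d), 0.5)
        assert labels[["a", "b", "c"]].tolist() == [1, 1, 1]  # size 3 -> id 1
        assert labels[["d", "e"]].tolist() == [2, 2]

    def test_negative_height_rejected(self, small_dendro):
        with pytest.raises(ValueError):
            cut(small_dendro, -0.1)


class TestFilterByCentroid:
    def test_anticorrelated_member_removed(self):
        prof = _profiles(
            {
                "a": [1, 0, -1, 0],
                "b": [1, 0, -1, 0],
                "c": [-1, 0, 1, 0],
            }
        )
        prelim = pd.Series([1, 1, 1], index=prof.index, name="preliminary_cluster")
        asg = filter_by_centroid(prelim, prof)
        assert asg.table.loc["a", "status"] == "retained"
        assert asg.table.loc["c", "status"] == "filtered_corr"
        assert asg.table.loc["c", "corr_to_centroid"] == pytest.approx(-1.0)

    def test_centroid_is_unfiltered_member_mean(self):
        prof = _profiles({"a": [1, 0, -1, 0], "b": [1, 0, -1, 0], "c": [-1, 0, 1, 0]})
        prelim = pd.Series([1, 1, 1], index=prof.index)
        asg = filter_by_centroid(prelim, prof)
        assert asg.centroids.loc[1].tolist() == pytest.approx([1 / 3, 0.0, -1 / 3, 0.0])

    def test_singleton_cluster_gets_correlation_one(self):
        prof = _profiles({"a": [1, 0, -1, 0], "b": [0, 1, 0, -1]})
        prelim = pd.Series([1, 2], index=prof.index)
        asg = filter_by_centroid(prelim, prof)
        assert (asg.table["corr_to_centroid"] == 1.0).all()
        assert (asg.table["status"] == "retained").all()

    def test_status_consistent_with_reported_correlation(self):
        # status must implement the strict rule corr < threshold exactly,
        # judged on the correlations the function itself reports
        rng = np.random.default_rng(8)
        prof = pd.DataFrame(rng.normal(size=(20, 4)), columns=list(TPS))
        prof.index = [f"g{i}" for i in range(20)]
        prelim = pd.Series(rng.integers(1, 4, size=20), index=prof.index)
        params = ClusterParams(min_centroid_corr=0.5)
        asg = filter_by_centroid(prelim, prof, params)
        expected = np.where(
            asg.table["corr_to_centroid"] < params.min_centroid_corr,
            "filtered_corr",
            "retained",
        )
        assert (asg.table["status"].to_numpy() == expected).all()


class TestFilterBySize:
    @staticmethod
    def _assignment(size_a: int, size_b: int):
        rows = {}
        prelim = {}
        for i in range(size_a):
            rows[f"a{i:02d}"] = [1, 0, -1, 0]
            prelim[f"a{i:02d}"] = 1
        for i in range(size_b):
            rows[f"b{i:02d}"] = [0, 1, 0, -1]
            prelim[f"b{i:02d}"] = 2
        prof = _profiles(rows)
        return filter_by_centroid(pd.Series(prelim), prof)

    def test_cluster_at_minimum_size_retained(self):
        asg = filter_by_size(self._assignment(30, 30))
        assert set(asg.table["status"]) == {"retained"}
        assert asg.table["final_cluster"].nunique() == 2

    def test_cluster_one_below_minimum_dropped(self):
        asg = filter_by_size(self._assignment(30, 29))
        b_rows = asg.table.loc[[g for g in asg.table.index if g.startswith("b")]]
        assert set(b_rows["status"]) == {"filtered_size"}
        assert b_rows["final_cluster"].isna().all()
        assert list(asg.centroids.index) == [1]

    def test_renumbered_by_decreasing_size(self):
        asg = filter_by_size(self._assignment(30, 45))
        assert asg.table.loc["b00", "final_cluster"] == 1
        assert asg.table.loc["a00", "final_cluster"] == 2

    def test_all_dropped_raises(self):
        with pytest.raises(ValidationError, match="min_cluster_size"):
            filter_by_size(self._assignment(5, 5))

    def test_small_threshold_keeps_everything(self):
        asg = filter_by_size(self._assignment(5, 5), ClusterParams(min_cluster_size=1))
        assert asg.table["final_cluster"].notna().all()


class TestClusterProfiles:
    def test_row_order_invariance(self, sim_bank):
        de, _, tps = sim_bank(0)
        shuffled = de.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a1, std1, _ = cluster_profiles(de, timepoints=tps)
        a2, std2, _ = cluster_profiles(shuffled, timepoints=tps)
        pd.testing.assert_frame_equal(a1.table, a2.table)
        pd.testing.assert_frame_equal(std1, std2)

    def test_returned_profiles_are_standardized_union(self, sim_bank):
        de, _, tps = sim_bank(0)
        asg, std, dendro = cluster_profiles(de, timepoints=tps)
        assert list(std.index) == list(asg.table.index)
        assert np.abs(std.to_numpy()).max(axis=1) == pytest.approx(
            np.ones(len(std)), abs=1e-12
        )
        assert dendro.n_leaves == len(std)

    @pytest.mark.parametrize(
        "params",
        [
            ClusterParams(),  # complete linkage, cut 1.6
            ClusterParams(linkage="average", cut_height=0.8),
        ],
    )
    def test_recovers_planted_archetypes(self, sim_bank, params):
        """Final clusters of retained planted genes match their archetypes
        (ARI >= 0.9) under both supported linkage configurations."""
        de, truth, tps = sim_bank(0)
        asg, _, _ = cluster_profiles(de, params=params, timepoints=tps)
        retained = asg.table[asg.table["status"] == "retained"]
        tmpl = truth.table.loc[retained.index, "template"]
        nonnull = tmpl != "null"
        ari = adjusted_rand_score(
            tmpl[nonnull], retained.loc[nonnull.index[nonnull], "final_cluster"]
        )
        assert ari >= 0.9

    def test_five_planted_clusters_found(self, sim_bank):
        de, _, tps = sim_bank(0)
        asg, _, _ = cluster_profiles(de, timepoints=tps)
        assert asg.table["final_cluster"].nunique() == 5


class TestRecurrentGeneReport:
    def test_partition_of_tiny_table(self, tiny_de_table):
        rep = recurrent_gene_report(tiny_de_table)
        assert rep[0] == ["g5", "g6"]
        assert rep[1] == ["g1", "g2", "g3", "g4"]
        assert rep[2] == rep[3] == rep[4] == []

    def test_counts_partition_all_genes(self, sim_bank):
        de, _, _ = sim_bank(0)
        rep = recurrent_gene_report(de)
        assert sum(len(v) for v in rep.values()) == de["gene_id"].nunique()
        assert set(rep.keys()) == {0, 1, 2, 3, 4}
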