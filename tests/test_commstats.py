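"""Community statistics: Sørensen, UPGMA, SIMPROF, NMDS, richness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster import hierarchy
from skbio import DistanceMatrix

from estmeio import commstats
from estmeio.commstats import (
    METAZOAN_PHYLA,
    NormalisationError,
    nmds,
    pool_replicates,
    reads_to_percent,
    richness_by_group,
    simprof,
    sorensen_dissimilarity,
    station_richness,
    to_presence,
    upgma,
    welch_levene_ttest,
)


def presence_df(rows, samples=None, otus=None):
    rows = np.asarray(rows)
    samples = samples or [f"s{i}" for i in range(rows.shape[0])]
    otus = otus or [f"o{j}" for j in range(rows.shape[1])]
    return pd.DataFrame(rows, index=samples, columns=otus)


class TestReadsToPercent:
    def test_simple_proportions(self, tiny_table):
        pct = reads_to_percent(tiny_table)
        assert pct["st1_r1"]["otu1"] == pytest.approx(
            100 * 10 / 18
        )
        np.testing.assert_allclose(pct.sum(axis=0), 100.0, atol=1e-9)

    def test_scale_invariance(self, tiny_table):
        pct1 = reads_to_percent(tiny_table)
        scaled = tiny_table
        scaled.counts["st1_r1"] *= 10
        pct2 = reads_to_percent(scaled)
        pd.testing.assert_frame_equal(pct1, pct2)

    def test_all_zero_sample_named_in_error(self, tiny_table):
        tiny_table.counts["st1_r1"] = 0
        with pytest.raises(NormalisationError, match="st1_r1"):
            reads_to_percent(tiny_table)


class TestToPresence:
    def test_default_filter_keeps_metazoan_phyla_only(self, tiny_table):
        P = to_presence(tiny_table)
        kept_phyla = tiny_table.taxonomy.loc[P.columns, "phylum"]
        assert set(kept_phyla) <= set(METAZOAN_PHYLA)
        assert "otu5" not in P.columns  # Alveolata excluded

    def test_binarisation(self, tiny_table):
        P = to_presence(tiny_table)
        assert set(np.unique(P.values)) <= {0, 1}
        assert P.loc["st1_r1", "otu1"] == 1
        assert P.loc["st2_r1", "otu1"] == 0

    def test_filter_with_no_matches_raises(self, tiny_table):
        with pytest.raises(Exception, match="[Nn]o OTUs|empty"):
            to_presence(tiny_table, ["Rotifera"])


class TestSorensen:
    def test_identical_and_disjoint_samples(self):
        P = presence_df([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]])
        D = sorensen_dissimilarity(P)
        assert D["s0", "s1"] == 0.0
        assert D["s0", "s2"] == 1.0

    def test_hand_counted_overlap(self):
        # {A,B,C} vs {B,C,D}: a=2 shared, b=c=1 -> d = 1 - 4/6
        P = presence_df([[1, 1, 1, 0], [0, 1, 1, 1]])
        D = sorensen_dissimilarity(P)
        assert D["s0", "s1"] == pytest.approx(1 / 3)

    def test_empty_pair_defined_zero_with_warning(self):
        P = presence_df([[0, 0], [0, 0], [1, 0]])
        with pytest.warns(UserWarning, match="empty"):
            D = sorensen_dissimilarity(P)
        assert D["s0", "s1"] == 0.0
        assert D["s0", "s2"] == 1.0

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_bruteforce_set_arithmetic(self, seed):
        rng = np.random.default_rng(seed)
        M = rng.integers(0, 2, size=(5, 12))
        M[M.sum(axis=1) == 0, 0] = 1  # avoid empty samples
        D = sorensen_dissimilarity(presence_df(M))
        for i in range(5):
            for j in range(i + 1, 5):
                a = int(((M[i] == 1) & (M[j] == 1)).sum())
                b = int(((M[i] == 1) & (M[j] == 0)).sum())
                c = int(((M[i] == 0) & (M[j] == 1)).sum())
                expect = 1 - 2 * a / (2 * a + b + c)
                assert D[f"s{i}", f"s{j}"] == pytest.approx(
                    expect, abs=1e-12
                )
                assert 0.0 <= D[f"s{i}", f"s{j}"] <= 1.0


class TestUpgma:
    def test_three_leaf_hand_case(self):
        D = DistanceMatrix(
            [[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]],
            ids=["a", "b", "c"],
        )
        dend = upgma(D)
        np.testing.assert_allclose(dend.heights, [0.2, 0.6])
        assert dend.cut(0.4) == [["a", "b"], ["c"]]

    def test_equal_distances_single_height_deterministic(self):
        D = DistanceMatrix(
            0.5 * (1 - np.eye(4)), ids=list("abcd")
        )
        d1 = upgma(D)
        d2 = upgma(D)
        np.testing.assert_allclose(d1.heights, 0.5)
        np.testing.assert_array_equal(d1.linkage, d2.linkage)

    def test_heights_nondecreasing_and_ultrametric(self):
        rng = np.random.default_rng(5)
        M = rng.integers(0, 2, size=(10, 30))
        M[:, 0] = 1
        D = sorensen_dissimilarity(presence_df(M))
        dend = upgma(D)
        assert (np.diff(dend.heights) >= -1e-12).all()
        # ultrametric: cophenetic distances satisfy the strong
        # triangle inequality
        coph = hierarchy.cophenet(dend.linkage)
        from scipy.spatial.distance import squareform

        C = squareform(coph)
        n = C.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert C[i, j] <= max(C[i, k], C[k, j]) + 1e-12

    def test_cut_at_25_percent_similarity(self):
        """Cutting the dendrogram at 0.75 dissimilarity reproduces the
        '25% similarity' grouping convention."""
        blockA = np.tile([1, 1, 1, 0, 0, 0], (3, 1))
        blockB = np.tile([0, 0, 0, 1, 1, 1], (3, 1))
        P = presence_df(np.vstack([blockA, blockB]))
        dend = upgma(sorensen_dissimilarity(P))
        groups = sorted(dend.cut(0.75), key=lambda g: g[0])
        assert len(groups) == 2
        assert groups[0] == ["s0", "s1", "s2"]

    def test_newick_export_parses(self):
        D = DistanceMatrix(
            [[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]],
            ids=["a", "b", "c"],
        )
        nwk = upgma(D).to_newick()
        from skbio import TreeNode
        import io

        tree = TreeNode.read(io.StringIO(nwk))
        assert {t.name for t in tree.tips()} == {"a", "b", "c"}
        # leaf depth equals the root merge height (ultrametric tree)
        depth = tree.find("c").accumulate_to_ancestor(tree)
        assert depth == pytest.approx(0.6, abs=1e-6)


class TestSimprof:
    def test_two_disjoint_blocks_split_significantly(self):
        rng = np.random.default_rng(0)
        blockA = (rng.random((6, 40)) < 0.6).astype(int)
        blockB = (rng.random((6, 40)) < 0.6).astype(int)
        M = np.zeros((12, 80), dtype=int)
        M[:6, :40] = blockA
        M[6:, 40:] = blockB
        res = simprof(presence_df(M), n_profile_perms=200,
                      n_test_perms=199, seed=1)
        root = res.nodes[0]
        assert root.tested and root.significant
        assert root.p_value <= 0.005

    def test_minimum_attainable_p(self):
        rng = np.random.default_rng(3)
        M = (rng.random((8, 30)) < 0.5).astype(int)
        res = simprof(presence_df(M), n_profile_perms=50,
                      n_test_perms=999, seed=2)
        for node in res.nodes:
            if node.tested:
                assert node.p_value >= 1 / 1000

    def test_small_nodes_grouped_untested(self):
        rng = np.random.default_rng(4)
        M = (rng.random((2, 20)) < 0.5).astype(int)
        M[:, 0] = 1
        res = simprof(presence_df(M), n_profile_perms=20,
                      n_test_perms=19, seed=0)
        assert res.n_groups == 1
        assert not res.nodes[0].tested

    def test_groups_partition_samples(self):
        rng = np.random.default_rng(9)
        M = (rng.random((10, 40)) < 0.4).astype(int)
        M[M.sum(axis=1) == 0, 0] = 1
        P = presence_df(M)
        res = simprof(P, n_profile_perms=50, n_test_perms=99, seed=7)
        flat = [s for g in res.groups for s in g]
        assert sorted(flat) == sorted(P.index)


class TestNmds:
    def test_two_samples_exact(self):
        D = DistanceMatrix([[0.0, 0.8], [0.8, 0.0]], ids=["a", "b"])
        res = nmds(D)
        assert res.stress == 0.0
        np.testing.assert_allclose(
            np.abs(res.coords["nmds1"].values), 0.4
        )

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        M = (rng.random((8, 30)) < 0.5).astype(int)
        M[M.sum(axis=1) == 0, 0] = 1
        D = sorensen_dissimilarity(presence_df(M))
        r1 = nmds(D, seed=42)
        r2 = nmds(D, seed=42)
        pd.testing.assert_frame_equal(r1.coords, r2.coords)
        assert r1.stress == r2.stress

    def test_stress_trace_nonincreasing(self):
        rng = np.random.default_rng(8)
        M = (rng.random((12, 40)) < 0.5).astype(int)
        M[M.sum(axis=1) == 0, 0] = 1
        D = sorensen_dissimilarity(presence_df(M))
        res = nmds(D, restarts=1, seed=0)
        trace = np.asarray(res.stress_trace)
        assert (np.diff(trace) <= 1e-10).all()


class TestRichness:
    def test_fixture_counts(self, tiny_table):
        rich = richness_by_group(tiny_table, "phylum")
        assert rich.loc["st1_r1", "Nematoda"] == 2
        assert rich.loc["st1_r1", "Annelida"] == 0
        assert rich.loc["st2_r1", "Annelida"] == 1

    def test_empty_sample_all_zero(self, tiny_table):
        tiny_table.counts["st1_r1"] = 0
        rich = richness_by_group(tiny_table, "phylum")
        assert (rich.loc["st1_r1"] == 0).all()

    def test_station_richness_is_union_of_replicates(self, tiny_table):
        sample_rich = richness_by_group(tiny_table, "phylum")
        st_rich = station_richness(tiny_table, "phylum")
        # union across replicates >= per-replicate counts
        for st in ["st1", "st2"]:
            reps = tiny_table.samples.index[
                tiny_table.samples["station"] == st
            ]
            assert (
                st_rich.loc[st] >= sample_rich.loc[reps].max()
            ).all()

    def test_pooled_union_superset_property(self, small_scenario):
        from estmeio import synthio

        ds = synthio.make_dataset(small_scenario)
        P = to_presence(ds.table)
        pooled = pool_replicates(P, ds.table.samples)
        for st in pooled.index:
            reps = ds.table.samples.index[
                ds.table.samples["station"] == st
            ]
            reps = [r for r in reps if r in P.index]
            assert (
                pooled.loc[st].values
                == P.loc[reps].max(axis=0).values
            ).all()

    def test_invalid_rank_rejected(self, tiny_table):
        with pytest.raises(ValueError):
            richness_by_group(tiny_table, "genus")


class TestTTest:
    def test_identical_vectors(self):
        x = np.array([3.0, 4.0, 5.0, 6.0])
        res = welch_levene_ttest(x, x)
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_pooled_df_for_20_plus_15_stations(self):
        rng = np.random.default_rng(0)
        x = rng.normal(100, 10, 20)
        y = rng.normal(95, 10, 15)
        res = welch_levene_ttest(x, y)
        assert res.pooled
        assert res.df == 33

    def test_welch_chosen_under_unequal_variance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0, 12, 40)
        res = welch_levene_ttest(x, y)
        assert not res.pooled
        assert res.df != 78

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_levene_ttest([1.0], [2.0, 3.0])
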