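"""betaMNTD/betaNTI and the phylogenetic-signal correlogram."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel

from ecoassembly.data import CountTable, EnvironmentTable, PhyloDistances, StudyDesign
from ecoassembly.data import tree_distances_from_string
from ecoassembly.phylo import bmntd, bnti, bnti_group, mantel_correlogram, niche_values


def brute_force_bmntd(x, y, D, weighted=True):
    """Independent double-loop oracle for the nearest-taxon statistic."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ix, iy = np.flatnonzero(x), np.flatnonzero(y)
    fx = x[ix] / x[ix].sum() if weighted else np.full(ix.size, 1 / ix.size)
    fy = y[iy] / y[iy].sum() if weighted else np.full(iy.size, 1 / iy.size)
    left = sum(f * min(D[i, j] for j in iy) for f, i in zip(fx, ix))
    right = sum(f * min(D[j, i] for i in ix) for f, j in zip(fy, iy))
    return 0.5 * (left + right)


@pytest.fixture
def three_tip():
    return tree_distances_from_string("((t1:1,t2:1):1,t3:2);")


class TestBmntd:
    def test_identical_communities_give_zero(self, three_tip):
        v = [3, 1, 2]
        assert bmntd(v, v, three_tip, ["t1", "t2", "t3"]) == pytest.approx(0.0)

    def test_two_tip_forced_value(self):
        d = tree_distances_from_string("(t1:1,t2:1);")
        assert bmntd([1, 0], [0, 1], d, ["t1", "t2"]) == pytest.approx(2.0)

    def test_three_tip_hand_value(self, three_tip):
        # x = {t1:0.5, t3:0.5}, y = {t2}: 0.5*(0.5*2 + 0.5*4 + 1*2) = 2.5
        assert bmntd([1, 0, 1], [0, 1, 0], three_tip, ["t1", "t2", "t3"]) == pytest.approx(2.5)

    def test_missing_taxon_reported(self, three_tip):
        with pytest.raises(KeyError, match="t9"):
            bmntd([1, 1], [1, 1], three_tip, ["t1", "t9"])

    def test_matches_brute_force_on_random_communities(self):
        import dendropy, random

        tree = dendropy.model.birthdeath.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=15, rng=random.Random(2)
        )
        for k, lf in enumerate(tree.leaf_node_iter()):
            lf.taxon.label = f"t{k}"
        from ecoassembly.data import tree_distances

        dist = tree_distances(tree)
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 5, 15)
            y = rng.integers(0, 5, 15)
            x[rng.integers(15)] += 1
            y[rng.integers(15)] += 1
            for weighted in (True, False):
                got = bmntd(x, y, dist, dist.tips, weighted=weighted)
                want = brute_force_bmntd(x, y, dist.dist, weighted=weighted)
                assert got == pytest.approx(want)
                assert got == pytest.approx(
                    bmntd(y, x, dist, dist.tips, weighted=weighted)
                )


class TestBnti:
    def test_identical_pair_nonpositive(self, three_tip):
        res = bnti([2, 1, 1], [2, 1, 1], three_tip, ["t1", "t2", "t3"], n_shuffles=50, seed=0)
        assert res.bmntd_obs == pytest.approx(0.0)
        assert res.undefined or res.bnti <= 0

    def test_star_tree_degenerate_null_flagged(self):
        d = tree_distances_from_string("(t1:1,t2:1,t3:1,t4:1);")
        res = bnti([1, 1, 0, 0], [0, 0, 1, 1], d, d.tips, n_shuffles=50, seed=0)
        assert res.undefined and np.isnan(res.bnti)

    def test_shuffle_preserves_distance_multiset(self, three_tip):
        rng = np.random.default_rng(1)
        p = rng.permutation(3)
        permuted = three_tip.dist[np.ix_(p, p)]
        assert sorted(permuted[np.triu_indices(3, 1)]) == sorted(
            three_tip.dist[np.triu_indices(3, 1)]
        )

    def test_group_pair_count_and_determinism(self):
        d = tree_distances_from_string("((t1:1,t2:1):1,(t3:1,t4:1):1);")
        table = CountTable(
            d.tips,
            ["s1", "s2", "s3"],
            np.array([[5, 1, 0], [1, 5, 2], [0, 2, 5], [2, 0, 1]]),
        )
        design = StudyDesign(
            pd.DataFrame(
                {
                    "sample_id": ["s1", "s2", "s3"],
                    "reactor": ["R1", "R2", "R3"],
                    "level": ["L"] * 3,
                    "day": [1] * 3,
                }
            )
        )
        res1, sum1 = bnti_group(table, design, d, n_shuffles=100, seed=3)
        res2, sum2 = bnti_group(table, design, d, n_shuffles=100, seed=3)
        assert len(res1) == 3  # C(3,2)
        np.testing.assert_array_equal(
            [r.bnti for r in res1], [r.bnti for r in res2]
        )
        pd.testing.assert_frame_equal(sum1, sum2)


class TestNicheValues:
    def test_single_sample_weight(self):
        table = CountTable(["f1"], ["s1"], np.array([[4]]))
        env = EnvironmentTable(pd.DataFrame({"v": [7.0]}, index=["s1"]))
        assert niche_values(table, env).loc["f1", "v"] == pytest.approx(7.0)

    def test_weighted_mean(self):
        # relative abundances 1 and 3 (arbitrary units) at env 2 and 6
        table = CountTable(["f1"], ["s1", "s2"], np.array([[1, 3]]))
        env = EnvironmentTable(pd.DataFrame({"v": [2.0, 6.0]}, index=["s1", "s2"]))
        # both samples have a single taxon, so relative abundance is 1 in
        # each; the weighted mean over equal weights is 4
        assert niche_values(table, env).loc["f1", "v"] == pytest.approx(4.0)

    def test_unequal_weights(self):
        table = CountTable(
            ["f1", "f2"], ["s1", "s2"], np.array([[1, 3], [3, 1]])
        )
        env = EnvironmentTable(pd.DataFrame({"v": [2.0, 6.0]}, index=["s1", "s2"]))
        out = niche_values(table, env)
        # f1 rel abundance 0.25 and 0.75: (0.25*2 + 0.75*6) = 5
        assert out.loc["f1", "v"] == pytest.approx(5.0)
        assert out.loc["f2", "v"] == pytest.approx(3.0)

    def test_constant_environment_invariance(self):
        rng = np.random.default_rng(0)
        table = CountTable(
            [f"f{i}" for i in range(5)],
            ["s1", "s2", "s3"],
            rng.integers(1, 9, (5, 3)),
        )
        env = EnvironmentTable(
            pd.DataFrame({"v": [3.3] * 3}, index=["s1", "s2", "s3"])
        )
        assert np.allclose(niche_values(table, env)["v"], 3.3)


class TestMantelCorrelogram:
    @pytest.fixture
    def yule_distances(self):
        from ecoassembly.simulate import ScenarioConfig, simulate_tree_and_trait

        nwk, trait = simulate_tree_and_trait(ScenarioConfig(seed=5, S=30))
        return tree_distances_from_string(nwk), trait

    def test_identical_niches_nothing_significant(self, yule_distances):
        d, _ = yule_distances
        niche = pd.DataFrame({"v": np.ones(30)}, index=d.tips)
        out = mantel_correlogram(niche, d, n_bins=10, n_perm=99, seed=0)
        assert not out["significant"].any()
        assert not out["valid"].any()

    def test_fdr_never_adds_rejections(self, yule_distances):
        d, trait = yule_distances
        niche = pd.DataFrame({"v": trait.reindex(d.tips).to_numpy()}, index=d.tips)
        out = mantel_correlogram(niche, d, n_bins=10, n_perm=199, fdr=0.05, seed=1)
        v = out[out["valid"]]
        assert v["significant"].sum() <= (v["p"] <= 0.05).sum()
        # BH adjustment is monotone: adjusted p never below raw p
        assert (v["p_adj"] >= v["p"] - 1e-12).all()

    def test_bin_statistic_matches_skbio_mantel(self, yule_distances):
        d, trait = yule_distances
        niche = pd.DataFrame({"v": trait.reindex(d.tips).to_numpy()}, index=d.tips)
        out = mantel_correlogram(niche, d, n_bins=5, n_perm=9, seed=2)
        N = np.abs(
            niche["v"].to_numpy()[:, None] - niche["v"].to_numpy()[None, :]
        )
        iu = np.triu_indices(30, 1)
        edges = np.linspace(0, d.dist[iu].max(), 6)
        row = out[out["valid"]].iloc[1]
        b = int(row["bin"])
        member = np.zeros_like(d.dist)
        inbin = (d.dist > edges[b]) & (d.dist <= edges[b + 1])
        member[inbin] = 1.0
        np.fill_diagonal(member, 0)
        r, _, _ = skbio_mantel(
            DistanceMatrix(N, d.tips),
            DistanceMatrix(member, d.tips),
            permutations=0,
        )
        assert row["r"] == pytest.approx(-r)

    def test_requires_enough_taxa(self, yule_distances):
        d, _ = yule_distances
        niche = pd.DataFrame({"v": np.arange(5.0)}, index=d.tips[:5])
        with pytest.raises(ValueError):
            mantel_correlogram(niche, d)
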