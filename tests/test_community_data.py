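"""Count-table I/O, rarefaction, pooling, and tree distances."""

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from ecoassembly.data import (
    CountTable,
    StudyDesign,
    pool_group,
    rarefy,
    read_count_table,
    read_tree_distances,
    tree_distances_from_string,
    write_count_table,
)
from conftest import random_count_table


class TestCountTableIO:
    def test_round_trip_identity(self, tiny_table, tmp_path):
        p = tmp_path / "t.tsv"
        write_count_table(tiny_table, p)
        back = read_count_table(p)
        assert back.features == ["f1", "f2"]
        assert back.samples == ["s1", "s2"]
        assert np.array_equal(back.counts, [[3, 0], [1, 2]])

    def test_orientation_transpose(self, tiny_table, tmp_path):
        p = tmp_path / "t.tsv"
        write_count_table(tiny_table, p, orientation="samples")
        back = read_count_table(p, orientation="samples")
        assert np.array_equal(back.counts, tiny_table.counts)

    def test_non_integer_cell_names_location(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("id\ts1\ts2\nf1\t2.5\t1\nf2\t0\t3\n")
        with pytest.raises(ValueError, match=r"f1.*s1|s1.*f1"):
            read_count_table(p)

    def test_negative_cell_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("id\ts1\nf1\t-2\nf2\t1\n")
        with pytest.raises(ValueError, match="negative"):
            read_count_table(p)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            CountTable(["f1", "f1"], ["s1"], np.array([[1], [2]]))

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_round_trip_random_tables(self, tmp_path_factory, seed):
        rng = np.random.default_rng(seed)
        table = random_count_table(rng)
        p = tmp_path_factory.mktemp("io") / "t.tsv"
        write_count_table(table, p)
        back = read_count_table(p)
        assert back.features == table.features
        assert back.samples == table.samples
        assert np.array_equal(back.counts, table.counts)


class TestRarefy:
    def test_depth_equal_to_total_is_identity(self):
        t = CountTable(["a", "b"], ["s1"], np.array([[5], [5]]))
        out = rarefy(t, 10, seed=0)
        assert np.array_equal(out.counts, t.counts)

    def test_single_feature_forced_outcome(self):
        t = CountTable(["a", "b"], ["s1"], np.array([[4], [0]]))
        out = rarefy(t, 2, seed=0)
        assert np.array_equal(out.counts, [[2], [0]])

    def test_excess_depth_lists_undersized_samples(self):
        t = CountTable(["a"], ["s1", "s2"], np.array([[5, 20]]))
        with pytest.raises(ValueError, match="s1"):
            rarefy(t, 10, seed=0)

    def test_monte_carlo_matches_hypergeometric_moments(self):
        # subsampling 10 of 100 reads split 50/50: feature-1 count is
        # hypergeometric(N=100, K=50, n=10)
        t = CountTable(["a", "b"], ["s1"], np.array([[50], [50]]))
        n_draws = 10_000
        draws = np.array([rarefy(t, 10, seed=s).counts[0, 0] for s in range(n_draws)])
        mean_exp = hypergeom.mean(100, 50, 10)
        var_exp = hypergeom.var(100, 50, 10)
        se = np.sqrt(var_exp / n_draws)
        assert abs(draws.mean() - mean_exp) < 3 * se
        assert np.isclose(draws.var(), var_exp, rtol=0.1)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_never_increases_counts_or_creates_features(self, seed):
        rng = np.random.default_rng(seed)
        table = random_count_table(rng, max_count=30)
        depth = int(table.sample_totals().min())
        out = rarefy(table, depth, seed=seed)
        assert (out.counts <= table.counts).all()
        assert (out.sample_totals() == depth).all()

    def test_deterministic_given_seed(self):
        t = CountTable(["a", "b", "c"], ["s1"], np.array([[40], [30], [30]]))
        assert np.array_equal(rarefy(t, 10, 7).counts, rarefy(t, 10, 7).counts)


class TestPoolGroup:
    def test_additivity(self, two_group_design):
        t = CountTable(
            ["f1", "f2"], ["a1", "a2", "b1", "b2"],
            np.array([[1, 3, 0, 0], [2, 0, 1, 1]]),
        )
        assert np.array_equal(pool_group(t, two_group_design, "L", 1), [4, 2])

    def test_empty_group_errors(self, two_group_design, tiny_table):
        t = CountTable(["f1"], ["a1", "a2", "b1", "b2"], np.ones((1, 4), dtype=int))
        with pytest.raises(ValueError, match="no samples"):
            pool_group(t, two_group_design, "X", 99)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_pooling_conserves_total_reads(self, seed):
        rng = np.random.default_rng(seed)
        table = random_count_table(rng, n_features=20, n_samples=4)
        import pandas as pd

        design = StudyDesign(
            pd.DataFrame(
                {
                    "sample_id": table.samples,
                    "reactor": [f"R{i}" for i in range(4)],
                    "level": ["L"] * 4,
                    "day": [1] * 4,
                }
            )
        )
        pooled = pool_group(table, design, "L", 1)
        assert pooled.sum() == table.counts.sum()


class TestTreeDistances:
    def test_two_tip_path_sum(self):
        d = tree_distances_from_string("(t1:1,t2:1);")
        assert d.dist[d.tips.index("t1"), d.tips.index("t2")] == pytest.approx(2.0)

    def test_three_tip_hand_values(self):
        d = tree_distances_from_string("((t1:1,t2:1):1,t3:2);")
        i = {t: k for k, t in enumerate(d.tips)}
        assert d.dist[i["t1"], i["t3"]] == pytest.approx(4.0)
        assert d.dist[i["t1"], i["t2"]] == pytest.approx(2.0)

    def test_missing_branch_lengths_rejected(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(t1,t2);\n")
        with pytest.raises(ValueError, match="branch length"):
            read_tree_distances(p)

    def test_symmetry_zero_diagonal_and_four_point(self):
        import random

        tree = dendropy.model.birthdeath.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=12, rng=random.Random(5)
        )
        for k, lf in enumerate(tree.leaf_node_iter()):
            lf.taxon.label = f"t{k}"
        from ecoassembly.data import tree_distances

        d = tree_distances(tree)
        assert np.allclose(d.dist, d.dist.T)
        assert np.allclose(np.diag(d.dist), 0)
        # additive metric: of the three pairings of any four tips, the two
        # largest sums are equal (four-point condition)
        rng = np.random.default_rng(0)
        for _ in range(50):
            i, j, k, l = rng.choice(12, 4, replace=False)
            sums = sorted(
                [
                    d.dist[i, j] + d.dist[k, l],
                    d.dist[i, k] + d.dist[j, l],
                    d.dist[i, l] + d.dist[j, k],
                ]
            )
            assert sums[2] - sums[1] < 1e-9 * max(1.0, sums[2])
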