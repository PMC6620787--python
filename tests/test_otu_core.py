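import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from daquscope.otu_core import (
    OtuTable,
    alpha_diversity,
    css_normalize,
    filter_low_occupancy,
    prevalence_core,
    rarefy,
    read_otu_table,
    relative_abundance,
    venn_partition,
    write_otu_table,
)

from conftest import make_table


class TestIO:
    def test_round_trip(self, tiny_table, tmp_path):
        write_otu_table(tiny_table, tmp_path / "t.tsv", tmp_path / "m.tsv")
        back = read_otu_table(tmp_path / "t.tsv", tmp_path / "m.tsv")
        assert back == tiny_table

    def test_lineage_round_trip(self, tmp_path):
        t = make_table(
            {"otu1": [1, 2]},
            {"s1": "W", "s2": "W"},
            lineage={"otu1": "p_Firmicutes;g_Bacillus"},
        )
        write_otu_table(t, tmp_path / "t.tsv", tmp_path / "m.tsv")
        back = read_otu_table(tmp_path / "t.tsv", tmp_path / "m.tsv")
        assert back.lineage == t.lineage

    def test_negative_count_names_cell(self, tmp_path):
        (tmp_path / "t.tsv").write_text("#OTU ID\ts1\notuX\t-3\n")
        (tmp_path / "m.tsv").write_text("sample_id\tgroup\ns1\tW\n")
        with pytest.raises(ValueError, match="otuX.*s1"):
            read_otu_table(tmp_path / "t.tsv", tmp_path / "m.tsv")

    def test_unparseable_count_names_cell(self, tmp_path):
        (tmp_path / "t.tsv").write_text("#OTU ID\ts1\notuX\tabc\n")
        (tmp_path / "m.tsv").write_text("sample_id\tgroup\ns1\tW\n")
        with pytest.raises(ValueError, match="s1"):
            read_otu_table(tmp_path / "t.tsv", tmp_path / "m.tsv")

    def test_sample_missing_from_metadata(self, tmp_path):
        (tmp_path / "t.tsv").write_text("#OTU ID\ts1\ts2\notuX\t1\t2\n")
        (tmp_path / "m.tsv").write_text("sample_id\tgroup\ns1\tW\n")
        with pytest.raises(ValueError, match="s2"):
            read_otu_table(tmp_path / "t.tsv", tmp_path / "m.tsv")

    def test_duplicate_otu_ids_rejected(self):
        counts = pd.DataFrame([[1], [2]], index=["a", "a"], columns=["s1"])
        meta = pd.DataFrame({"group": ["W"]}, index=["s1"])
        with pytest.raises(ValueError, match="duplicate"):
            OtuTable(counts=counts, metadata=meta)


class TestFilterLowOccupancy:
    def test_single_sample_removed_despite_high_count(self):
        t = make_table(
            {"solo": [100, 0, 0], "keep": [10, 10, 10]},
            {"s1": "W", "s2": "W", "s3": "W"},
        )
        assert filter_low_occupancy(t).otu_ids == ["keep"]

    def test_total_count_boundary_strict(self):
        t = make_table(
            {"nineteen": [7, 6, 6], "twenty": [7, 6, 7]},
            {"s1": "W", "s2": "W", "s3": "W"},
        )
        assert filter_low_occupancy(t).otu_ids == ["twenty"]

    def test_empty_table_passes_through(self):
        t = make_table({}, {"s1": "W"})
        assert filter_low_occupancy(t).n_otus == 0

    def test_idempotent_and_monotone(self, community):
        table, _ = community
        once = filter_low_occupancy(table)
        assert filter_low_occupancy(once).otu_ids == once.otu_ids
        stricter = filter_low_occupancy(table, min_samples=4, min_total=100)
        assert set(stricter.otu_ids) <= set(once.otu_ids)


class TestRelativeAbundance:
    def test_fractions(self):
        t = make_table({"a": [1], "b": [3]}, {"s1": "W"})
        rel = relative_abundance(t)
        assert rel["s1"].tolist() == [0.25, 0.75]

    def test_columns_sum_to_one(self, community):
        table, _ = community
        assert np.allclose(relative_abundance(table).sum(axis=0), 1.0, atol=1e-12)

    def test_zero_total_sample_errors(self):
        t = make_table({"a": [1, 0]}, {"s1": "W", "s2": "W"})
        with pytest.raises(ValueError, match="s2"):
            relative_abundance(t)


class TestCssNormalize:
    def test_published_formula_oracle(self):
        # counts [10,5,1,1,1]: median positive = 1, s = 1+1+1 = 3
        t = make_table({f"o{i}": [c] for i, c in enumerate([10, 5, 1, 1, 1])}, {"s1": "W"})
        norm, factors = css_normalize(t, quantile=0.5)
        assert factors["s1"] == 3.0
        assert np.allclose(
            norm["s1"].to_numpy(),
            [10000 / 3, 5000 / 3, 1000 / 3, 1000 / 3, 1000 / 3],
        )

    def test_oracle_on_random_tables(self):
        # independent oracle: direct formula with numpy on each column
        rng = np.random.default_rng(0)
        for _ in range(10):
            counts = rng.integers(0, 50, size=(8, 4))
            counts[0] += 1  # keep every sample positive
            t = make_table(
                {f"o{i}": counts[i] for i in range(8)},
                {f"s{j}": "W" for j in range(4)},
            )
            q = rng.choice([0.25, 0.5, 0.75])
            norm, factors = css_normalize(t, quantile=q)
            for j, s in enumerate(t.sample_ids):
                col = counts[:, j]
                pos = np.sort(col[col > 0])
                qv = pos[int(np.ceil(q * len(pos))) - 1]
                s_j = col[col <= qv].sum()
                assert factors[s] == s_j
                assert np.allclose(norm[s].to_numpy(), col / s_j * 1000)

    def test_uniform_counts_give_equal_values(self):
        t = make_table({f"o{i}": [7] for i in range(5)}, {"s1": "W"})
        norm, _ = css_normalize(t, quantile=0.5)
        assert norm["s1"].nunique() == 1

    def test_scaling_invariance(self, tiny_table):
        norm1, f1 = css_normalize(tiny_table, quantile=0.5)
        doubled = OtuTable(
            counts=tiny_table.counts * 2, metadata=tiny_table.metadata
        )
        norm2, f2 = css_normalize(doubled, quantile=0.5)
        assert np.allclose(norm1.to_numpy(), norm2.to_numpy())
        assert all(f2[s] == 2 * f1[s] for s in f1)

    def test_bad_quantile(self, tiny_table):
        with pytest.raises(ValueError):
            css_normalize(tiny_table, quantile=1.5)

    def test_adaptive_quantile_in_range(self, community):
        table, _ = community
        norm, factors = css_normalize(table, quantile="adaptive")
        assert all(f > 0 for f in factors.values())


class TestRarefy:
    def test_exhaustive_draw_unchanged(self):
        t = make_table({"a": [3], "b": [2]}, {"s1": "W"})
        r = rarefy(t, depth=5, seed=0)
        assert r.counts["s1"].tolist() == [3, 2]

    def test_deterministic(self, community):
        table, _ = community
        a = rarefy(table, 500, seed=9)
        b = rarefy(table, 500, seed=9)
        assert a.counts.equals(b.counts)

    def test_column_sums_equal_depth(self, community):
        table, _ = community
        r = rarefy(table, 500, seed=3)
        assert (r.counts.sum(axis=0) == 500).all()

    def test_shallow_sample_dropped_with_warning(self):
        t = make_table({"a": [500, 2000]}, {"s1": "W", "s2": "W"})
        with pytest.warns(UserWarning, match="s1"):
            r = rarefy(t, depth=988, seed=0)
        assert r.sample_ids == ["s2"]

    def test_bad_depth(self, tiny_table):
        with pytest.raises(ValueError):
            rarefy(tiny_table, 0, seed=0)


class TestAlphaDiversity:
    def test_uniform_maximum(self):
        t = make_table({f"o{i}": [5] for i in range(4)}, {"s1": "W"})
        div = alpha_diversity(t, depth=20, seed=0)
        assert div.loc["s1", "shannon"] == pytest.approx(2.0)
        assert div.loc["s1", "observed_otus"] == 4

    def test_single_otu(self):
        t = make_table({"only": [9]}, {"s1": "W"})
        div = alpha_diversity(t, depth=9, seed=0)
        assert div.loc["s1", "shannon"] == 0.0
        assert div.loc["s1", "observed_otus"] == 1

    def test_hand_computed_entropy(self):
        t = make_table({"a": [1], "b": [1], "c": [2]}, {"s1": "W"})
        div = alpha_diversity(t, depth=4, seed=0)
        assert div.loc["s1", "shannon"] == pytest.approx(1.5)

    def test_entropy_bounded_by_richness(self, community):
        table, _ = community
        div = alpha_diversity(table, depth=500, seed=5)
        assert (div["shannon"] <= np.log2(div["observed_otus"]) + 1e-9).all()


class TestPrevalenceCore:
    def test_strict_095_boundary_at_131_samples(self):
        groups = {f"s{i}": "M" for i in range(131)}
        counts = {
            "in125": [1] * 125 + [0] * 6,  # 0.954 > 0.95
            "in124": [1] * 124 + [0] * 7,  # 0.947 < 0.95
        }
        t = make_table(counts, groups)
        core = prevalence_core(t, t.sample_ids, threshold=0.95)
        assert core.core_otu_ids == ["in125"]

    def test_twenty_samples_require_all(self):
        groups = {f"s{i}": "M" for i in range(20)}
        t = make_table({"in19": [1] * 19 + [0], "in20": [1] * 20}, groups)
        core = prevalence_core(t, t.sample_ids, threshold=0.95)
        assert core.core_otu_ids == ["in20"]

    def test_threshold_edges(self, community):
        table, _ = community
        everything = prevalence_core(table, table.sample_ids, threshold=0.0)
        assert set(everything.core_otu_ids) == {
            o for o, p in everything.prevalence.items() if p > 0
        }
        nothing = prevalence_core(table, table.sample_ids, threshold=1.0)
        assert nothing.core_otu_ids == []

    def test_unknown_sample(self, tiny_table):
        with pytest.raises(KeyError):
            prevalence_core(tiny_table, ["nope"])


class TestVennPartition:
    def test_exclusive_regions(self):
        t = make_table(
            {"wa": [1, 0, 0], "ya": [0, 1, 0], "ma": [0, 0, 1]},
            {"s1": "W", "s2": "Y", "s3": "M"},
        )
        v = venn_partition(t)
        assert v.region_counts == {
            frozenset({"W"}): 1,
            frozenset({"Y"}): 1,
            frozenset({"M"}): 1,
        }

    def test_triple_intersection(self):
        t = make_table({"everywhere": [2, 1, 3]}, {"s1": "W", "s2": "Y", "s3": "M"})
        v = venn_partition(t)
        assert v.region_counts == {frozenset({"W", "Y", "M"}): 1}

    def test_empty_group_errors(self, tiny_table):
        with pytest.raises(ValueError, match="zero samples"):
            venn_partition(tiny_table, groups=["W", "Y", "Z"])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**30), st.integers(2, 50))
    def test_against_brute_force_set_algebra(self, seed, n_otus):
        rng = np.random.default_rng(seed)
        presence = rng.integers(0, 2, size=(n_otus, 6))
        groups = {f"s{j}": ["A", "B", "C"][j // 2] for j in range(6)}
        t = make_table(
            {f"o{i}": presence[i] for i in range(n_otus)}, groups
        )
        v = venn_partition(t)
        # oracle: per-group OTU sets and explicit region membership
        sets = {
            g: {
                f"o{i}"
                for i in range(n_otus)
                if any(presence[i][j] for j in range(6) if groups[f"s{j}"] == g)
            }
            for g in "ABC"
        }
        for region in map(frozenset, itertools.chain.from_iterable(
            itertools.combinations("ABC", k) for k in (1, 2, 3)
        )):
            inside = set.intersection(*(sets[g] for g in region)) if region else set()
            outside = set.union(*(sets[g] for g in set("ABC") - region), set())
            expected = len(inside - outside)
            assert v.region_counts.get(region, 0) == expected
        assert v.total_otus() == len(sets["A"] | sets["B"] | sets["C"])
        for g in "ABC":
            assert v.group_totals[g] == len(sets[g])
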