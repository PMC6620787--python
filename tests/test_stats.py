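import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from daquscope.otu_core import relative_abundance
from daquscope.stats import (
    bh_fdr,
    bray_curtis,
    core_correlation_network,
    mantel,
    permanova,
    property_screen,
    spearman,
    wilcoxon_rank_sum,
)

from conftest import make_table


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40])[0] == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [9, 7, 5, 3])[0] == pytest.approx(-1.0)

    def test_midrank_oracle_with_ties(self):
        x, y = [1, 2, 2, 4], [1, 3, 2, 4]
        rho, _ = spearman(x, y)
        # brute-force mid-rank computation
        rx = np.array([1, 2.5, 2.5, 4])
        ry = np.array([1, 3, 2, 4])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected)

    def test_matches_scipy_at_large_n(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        rho, p = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_small_n_is_valid_permutation_p(self):
        rho, p = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        # oracle: enumerate all 120 rank permutations
        obs = abs(rho)
        count = sum(
            abs(np.corrcoef([1, 2, 3, 4, 5], perm)[0, 1]) >= obs - 1e-12
            for perm in itertools.permutations([1, 3, 2, 5, 4])
        )
        assert p == pytest.approx(count / 120)

    def test_constant_vector_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(rho) and math.isnan(p)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]).tolist() == [0.2]

    def test_stepup_hand_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_inflation_and_order_preservation(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=20)
        adj = bh_fdr(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        # reapplying adjustment can only inflate further
        assert (bh_fdr(adj) >= adj - 1e-12).all()

    def test_monotone_in_input(self):
        p1 = np.array([0.01, 0.2, 0.5])
        p2 = np.array([0.02, 0.3, 0.6])
        assert (bh_fdr(p1) <= bh_fdr(p2) + 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.2])


class TestWilcoxonRankSum:
    def test_exact_small_example(self):
        _, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_identical_samples(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.normal(size=int(rng.integers(3, 9)))
            b = rng.normal(size=int(rng.integers(3, 9)))
            _, p = wilcoxon_rank_sum(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approx_close_to_exact(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=10)
        b = rng.normal(loc=0.5, size=10)
        _, p_exact = wilcoxon_rank_sum(a, b, exact_max_n=10)
        _, p_approx = wilcoxon_rank_sum(a, b, exact_max_n=1)
        assert abs(p_exact - p_approx) <= 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        D = bray_curtis(np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 2.0]]))
        assert D.iloc[0, 1] == pytest.approx(0.0)
        assert D.iloc[0, 2] == pytest.approx(1.0)

    def test_direct_formula(self):
        D = bray_curtis(np.array([[1.0, 1.0], [1.0, 3.0]]))
        assert D.iloc[0, 1] == pytest.approx(1 / 3)

    def test_two_all_zero_samples_undefined(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]]))


def _brute_force_permanova_p(D, labels):
    """Independent oracle: textbook sums over explicit group partitions."""
    D = np.asarray(D, float)
    n = len(labels)

    def pseudo_f(lab):
        lab = np.asarray(lab)
        ss_t = sum(
            D[i, j] ** 2 for i in range(n) for j in range(i + 1, n)
        ) / n
        ss_w = 0.0
        for g in set(lab):
            idx = [i for i in range(n) if lab[i] == g]
            ss_w += sum(
                D[i, j] ** 2 for i in idx for j in idx if i < j
            ) / len(idx)
        g = len(set(lab))
        return ((ss_t - ss_w) / (g - 1)) / (ss_w / (n - g))

    f_obs = pseudo_f(labels)
    perms = list(itertools.permutations(labels))
    count = sum(pseudo_f(p) >= f_obs - 1e-12 for p in perms)
    return f_obs, count / len(perms)


class TestPermanova:
    def test_exhaustive_matches_brute_force(self, community):
        table, _ = community
        sub = table.select_samples(table.sample_ids[:3] + table.sample_ids[-3:])
        D = bray_curtis(sub)
        labels = sub.groups().to_numpy()
        res = permanova(D, labels, exhaustive=True)
        f_ref, p_ref = _brute_force_permanova_p(D.to_numpy(), labels)
        assert res.statistic == pytest.approx(f_ref)
        assert res.p_value == pytest.approx(p_ref)

    def test_matches_skbio_statistic(self, community):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova

        table, _ = community
        D = bray_curtis(table)
        labels = table.groups().tolist()
        res = permanova(D, labels, n_perm=99, seed=0)
        dm = skbio.DistanceMatrix(D.to_numpy(), ids=table.sample_ids)
        ref = sk_permanova(dm, grouping=labels, permutations=0)
        assert res.statistic == pytest.approx(float(ref["test statistic"]))

    def test_permutation_p_estimator(self, community):
        table, _ = community
        D = bray_curtis(table)
        res = permanova(D, table.groups().to_numpy(), n_perm=99, seed=4)
        assert 1 / 100 <= res.p_value <= 1.0
        again = permanova(D, table.groups().to_numpy(), n_perm=99, seed=4)
        assert res.p_value == again.p_value

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            permanova(np.zeros((4, 4)), ["a", "a", "b", "b"])


class TestMantel:
    def test_self_correlation(self):
        D = bray_curtis(np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]]))
        res = mantel(D, D, n_perm=9, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_constant_matrix_flagged(self):
        D = np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        D2 = D.copy()
        with pytest.warns(UserWarning, match="undefined"):
            res = mantel(D, D2, n_perm=9, seed=0)
        assert math.isnan(res.statistic)

    def test_exhaustive_matches_brute_force(self):
        rng = np.random.default_rng(11)
        X = rng.uniform(size=(5, 4))
        Y = rng.uniform(size=(5, 4))
        D1, D2 = bray_curtis(X).to_numpy(), bray_curtis(Y).to_numpy()
        res = mantel(D1, D2, exhaustive=True)
        # oracle: enumerate all 120 simultaneous row/col permutations
        iu = np.triu_indices(5, 1)
        v1 = sps.rankdata(D1[iu])
        obs = np.corrcoef(v1, sps.rankdata(D2[iu]))[0, 1]
        count = 0
        for perm in itertools.permutations(range(5)):
            p = np.array(perm)
            r = np.corrcoef(v1, sps.rankdata(D2[np.ix_(p, p)][iu]))[0, 1]
            if abs(r) >= abs(obs) - 1e-12:
                count += 1
        assert res.statistic == pytest.approx(obs)
        assert res.p_value == pytest.approx(count / 120)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            mantel(np.zeros((3, 3)), np.zeros((4, 4)))


class TestCoreCorrelationNetwork:
    def test_covarying_pair_significant(self):
        rng = np.random.default_rng(2)
        base = rng.integers(50, 150, size=20)
        counts = {
            "a": base,
            "b": base * 2,
            "c": rng.integers(50, 150, size=20),
        }
        t = make_table(counts, {f"s{i}": "M" for i in range(20)})
        net = core_correlation_network(t, ["a", "b", "c"])
        assert net.rho.loc["a", "b"] == pytest.approx(1.0)
        assert net.significant.loc["a", "b"]

    def test_symmetry_and_diagonal(self, community):
        table, _ = community
        net = core_correlation_network(table, table.otu_ids[:6])
        assert np.allclose(np.diag(net.rho), 1.0)
        assert np.allclose(net.rho, net.rho.T)
        assert np.allclose(net.p_adjusted, net.p_adjusted.T)
        assert (net.p_adjusted.to_numpy()[net.significant.to_numpy()] <= 0.05).all()

    def test_display_labels_use_lineage(self):
        t = make_table(
            {"OTU00007": [1, 2, 3], "OTU00010": [3, 2, 1]},
            {f"s{i}": "M" for i in range(3)},
            lineage={"OTU00007": "p_Actinobacteria;g_Saccharopolyspora"},
        )
        net = core_correlation_network(t, ["OTU00007", "OTU00010"])
        assert net.labels["OTU00007"] == "g_Saccharopolyspora_007"


class TestPropertyScreen:
    def test_property_equal_to_otu_abundance(self, community):
        table, _ = community
        rel = relative_abundance(table)
        props = pd.DataFrame({"SA": rel.loc[table.otu_ids[0]]})
        out = property_screen(table, props)
        assert out["SA"].loc[table.otu_ids[0], "rho"] == pytest.approx(1.0)
        assert len(out["SA"]) == table.n_otus

    def test_missing_rows_dropped_with_warning(self, community):
        table, _ = community
        rng = np.random.default_rng(0)
        props = pd.DataFrame(
            {"AC": rng.normal(size=table.n_samples)}, index=table.sample_ids
        )
        props.iloc[:3, 0] = np.nan
        with pytest.warns(UserWarning, match="AC"):
            out = property_screen(table, props)
        assert len(out["AC"]) == table.n_otus

    def test_no_overlap_errors(self, community):
        table, _ = community
        props = pd.DataFrame({"AC": [1.0]}, index=["elsewhere"])
        with pytest.raises(ValueError, match="overlap"):
            property_screen(table, props)
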