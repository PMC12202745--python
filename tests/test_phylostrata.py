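from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from devoglass import DEFAULT_STAGES
from devoglass import phylostrata as phy

from conftest import make_expr, spearman_oracle

STAGES = list(DEFAULT_STAGES)


class TestRhoEnrichment:
    def test_observed_equals_expected_gives_zero(self):
        # cluster of 50 and stratum of 40 in a universe of 100 genes with
        # observed = 20 = expected exactly
        genes = [f"g{i}" for i in range(100)]
        cluster = set(genes[:50])
        stratum = set(genes[30:70])  # overlap 20 = 50*40/100
        m = phy.rho_enrichment({"c": cluster}, {"s": stratum}, 100)
        assert m.expected.loc["c", "s"] == pytest.approx(20.0)
        assert m.rho.loc["c", "s"] == pytest.approx(0.0)

    def test_hand_evaluated_formula(self):
        genes = [f"g{i}" for i in range(100)]
        cluster = set(genes[:20])
        stratum = set(genes[10:40])  # |c|=20, |s|=30, observed=10
        m = phy.rho_enrichment({"c": cluster}, {"s": stratum}, 100)
        assert m.observed.loc["c", "s"] == 10
        assert m.expected.loc["c", "s"] == pytest.approx(6.0)
        assert m.rho.loc["c", "s"] == pytest.approx((10 - 6) ** 2 / 6)

    def test_zero_overlap_same_sizes(self):
        genes = [f"g{i}" for i in range(100)]
        m = phy.rho_enrichment({"c": set(genes[:20])}, {"s": set(genes[70:])},
                               100)
        assert m.rho.loc["c", "s"] == pytest.approx(6.0)  # (0-6)^2/6

    def test_matches_brute_force_on_random_configurations(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            total = int(rng.integers(20, 200))
            genes = [f"g{i}" for i in range(total)]
            c = set(rng.choice(genes, rng.integers(1, total), replace=False))
            s = set(rng.choice(genes, rng.integers(1, total), replace=False))
            m = phy.rho_enrichment({"c": c}, {"s": s}, total)
            obs = len(c & s)
            exp = len(c) * len(s) / total
            assert m.rho.loc["c", "s"] == pytest.approx(
                (obs - exp) ** 2 / exp, abs=1e-12)

    def test_row_sums_recover_cluster_sizes(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(300)]
        clusters = {c: set() for c in range(3)}
        strata = {s: set() for s in "xyz"}
        for g in genes:
            clusters[int(rng.integers(3))].add(g)
            strata["xyz"[int(rng.integers(3))]].add(g)
        m = phy.rho_enrichment(clusters, strata, 300)
        for c, members in clusters.items():
            assert m.observed.loc[c].sum() == len(members)
        assert m.observed.to_numpy().sum() == 300

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(100)]
        clusters = {c: set(rng.choice(genes, 30, replace=False)) for c in "ab"}
        strata = {s: set(rng.choice(genes, 40, replace=False)) for s in "uv"}
        m1 = phy.rho_enrichment(clusters, strata, 100)
        m2 = phy.rho_enrichment(dict(reversed(clusters.items())),
                                dict(reversed(strata.items())), 100)
        assert m1.rho.loc["a", "u"] == m2.rho.loc["a", "u"]

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            phy.rho_enrichment({"c": set()}, {"s": set()}, 0)


class TestStratumTrajectories:
    def test_single_stratum_equals_genome_median(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(5, 1, (50, 10)), columns=STAGES,
                          index=[f"g{i}" for i in range(50)])
        strata = pd.Series("only", index=df.index)
        med, std, skipped = phy.stratum_trajectories(df, strata)
        assert np.allclose(med.loc["only"], df.median(axis=0))
        assert skipped == []

    def test_identical_genes_zero_std(self):
        df = pd.DataFrame(np.ones((10, 10)) * 2.5, columns=STAGES,
                          index=[f"g{i}" for i in range(10)])
        strata = pd.Series("s", index=df.index)
        _, std, _ = phy.stratum_trajectories(df, strata)
        assert np.allclose(std.loc["s"], 0.0)

    def test_planted_young_stratum_peaks_at_p4(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(5, 0.3, (200, 10)), columns=STAGES,
                          index=[f"g{i}" for i in range(200)])
        young = df.index[:60]
        df.loc[young, "P4"] += 2.0
        strata = pd.Series("old", index=df.index)
        strata[young] = "young"
        med, _, _ = phy.stratum_trajectories(df, strata, ["old", "young"])
        assert med.loc["young"].idxmax() == "P4"
        assert med.loc["old"].idxmax() != "P4"

    def test_tiny_stratum_omitted(self):
        df = pd.DataFrame(np.random.default_rng(5).normal(0, 1, (10, 10)),
                          columns=STAGES, index=[f"g{i}" for i in range(10)])
        strata = pd.Series(["big"] * 9 + ["lone"], index=df.index)
        med, _, skipped = phy.stratum_trajectories(df, strata)
        assert "lone" in skipped and "lone" not in med.index


class TestStratumStageCorrelation:
    def test_identical_strata_profiles_are_one(self):
        rng = np.random.default_rng(6)
        # identical replicates within each stage and across species, so
        # every cross-species replicate pair correlates perfectly
        arr = np.repeat(rng.normal(5, 1, (60, 10)), 3, axis=1)
        ea = make_expr(arr, species="A")
        eb = make_expr(arr, species="B")
        pairs = pd.DataFrame({"gene_a": ea.gene_ids, "gene_b": eb.gene_ids})
        strata = pd.Series(["s1"] * 30 + ["s2"] * 30, index=ea.gene_ids)
        profs = phy.stratum_stage_correlation(ea, eb, pairs, strata)
        for prof in profs.values():
            assert np.allclose(prof.central, 1.0)

    def test_union_of_strata_approximates_global_profile(self):
        from devoglass.conservation import diagonal_profile
        rng = np.random.default_rng(7)
        ea = make_expr(rng.normal(5, 1, (300, 30)), species="A")
        eb = make_expr(
            ea.values.to_numpy() + rng.normal(0, 0.5, (300, 30)), species="B")
        pairs = pd.DataFrame({"gene_a": ea.gene_ids, "gene_b": eb.gene_ids})
        full = diagonal_profile(ea, eb, pairs)
        strata = pd.Series(rng.choice(["x", "y"], 300), index=ea.gene_ids)
        profs = phy.stratum_stage_correlation(ea, eb, pairs, strata)
        mixed = np.mean([profs["x"].central, profs["y"].central], axis=0)
        assert np.allclose(mixed, full.central, atol=0.1)


class TestPerGeneCorrelation:
    def test_identical_and_reversed_profiles(self):
        a = pd.DataFrame([np.arange(10.0), np.arange(10.0)], columns=STAGES,
                         index=["a0", "a1"])
        b = pd.DataFrame([np.arange(10.0), np.arange(10.0)[::-1]],
                         columns=STAGES, index=["b0", "b1"])
        pairs = pd.DataFrame({"gene_a": ["a0", "a1"], "gene_b": ["b0", "b1"]})
        rho = phy.per_gene_cross_species_correlation(a, b, pairs)
        assert rho["a0"] == pytest.approx(1.0)
        assert rho["a1"] == pytest.approx(-1.0)

    def test_matches_rank_oracle_on_random_pairs(self):
        rng = np.random.default_rng(8)
        a = pd.DataFrame(rng.normal(0, 1, (100, 10)), columns=STAGES,
                         index=[f"a{i}" for i in range(100)])
        b = pd.DataFrame(rng.normal(0, 1, (100, 10)), columns=STAGES,
                         index=[f"b{i}" for i in range(100)])
        pairs = pd.DataFrame({"gene_a": a.index, "gene_b": b.index})
        rho = phy.per_gene_cross_species_correlation(a, b, pairs)
        for i in range(0, 100, 17):
            expected = spearman_oracle(a.iloc[i], b.iloc[i])
            assert rho.iloc[i] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_profiles_excluded(self):
        a = pd.DataFrame([np.ones(10), np.arange(10.0)], columns=STAGES,
                         index=["a0", "a1"])
        b = pd.DataFrame([np.arange(10.0), np.arange(10.0)], columns=STAGES,
                         index=["b0", "b1"])
        pairs = pd.DataFrame({"gene_a": ["a0", "a1"], "gene_b": ["b0", "b1"]})
        rho = phy.per_gene_cross_species_correlation(a, b, pairs)
        assert list(rho.index) == ["a1"]
        assert rho.attrs["n_undefined"] == 1


def mannwhitney_enumeration(x, y, alternative):
    """Exact p by enumerating all group assignments of the pooled sample."""
    pooled = np.concatenate([x, y])
    n = len(x)
    idx = range(len(pooled))

    def u_stat(ix):
        xs = pooled[list(ix)]
        ys = np.delete(pooled, list(ix))
        return sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)

    observed = u_stat(range(n))
    us = [u_stat(c) for c in combinations(idx, n)]
    us = np.array(us)
    if alternative == "greater":
        return float(np.mean(us >= observed))
    if alternative == "less":
        return float(np.mean(us <= observed))
    return float(min(1.0, 2 * min(np.mean(us >= observed),
                                  np.mean(us <= observed))))


class TestRankCompare:
    def test_small_example_exact_sixth(self):
        u, p = phy.rank_compare([1, 2], [3, 4], "less")
        assert p == pytest.approx(1 / 6, abs=1e-12)

    def test_identical_groups_two_sided_near_one(self):
        _, p = phy.rank_compare(list(range(20)), list(range(20)), "two-sided")
        assert p > 0.99

    def test_large_shift_tiny_p(self):
        rng = np.random.default_rng(9)
        x = rng.normal(10, 1, 50)
        y = rng.normal(0, 1, 50)
        _, p = phy.rank_compare(x, y, "greater")
        assert p < 1e-10

    def test_matches_exact_enumeration_small_samples(self):
        rng = np.random.default_rng(10)
        for n, m in [(2, 2), (2, 4), (3, 3), (3, 5), (4, 4)]:
            vals = rng.permutation(100)[:n + m].astype(float)
            x, y = vals[:n], vals[n:]
            for alt in ("greater", "less", "two-sided"):
                _, p = phy.rank_compare(x, y, alt)
                assert p == pytest.approx(
                    mannwhitney_enumeration(x, y, alt), abs=1e-10), (n, m, alt)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            phy.rank_compare([], [1, 2])


class TestChisqDistributionTest:
    def test_proportional_rows_give_zero(self):
        idx = pd.Index(["s1", "s2"], name="stratum")
        chi2, df, p = phy.chisq_distribution_test(
            pd.Series([10, 10], index=idx), pd.Series([20, 20], index=idx))
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_diagonal_table_hand_value(self):
        idx = pd.Index(["s1", "s2"], name="stratum")
        chi2, df, p = phy.chisq_distribution_test(
            pd.Series([10, 0], index=idx), pd.Series([0, 10], index=idx))
        assert chi2 == pytest.approx(20.0)
        assert df == 1

    def test_matches_textbook_formula_on_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            s = int(rng.integers(3, 8))
            idx = pd.Index([f"s{i}" for i in range(s)])
            a = pd.Series(rng.integers(1, 50, s), index=idx).astype(float)
            b = pd.Series(rng.integers(1, 50, s), index=idx).astype(float)
            chi2, df, _ = phy.chisq_distribution_test(a, b)
            table = np.array([a, b], dtype=float)
            expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
            hand = ((table - expected) ** 2 / expected).sum()
            assert chi2 == pytest.approx(hand, abs=1e-10)
            assert df == s - 1

    def test_zero_total_strata_pooled_away(self):
        idx = pd.Index(["s1", "s2", "s3"])
        chi2, df, _ = phy.chisq_distribution_test(
            pd.Series([10, 0, 5], index=idx), pd.Series([8, 0, 9], index=idx))
        assert df == 1  # the empty stratum does not count

    def test_all_zero_row_raises(self):
        idx = pd.Index(["s1", "s2"])
        with pytest.raises(ValueError):
            phy.chisq_distribution_test(pd.Series([0, 0], index=idx),
                                        pd.Series([1, 2], index=idx))
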