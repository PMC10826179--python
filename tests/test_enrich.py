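"""Enrichment: hypergeometric and KS statistics, miRNA-permutation null."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lymphomir as lm
from lymphomir.enrich import EnrichmentConfig


def exact_hypergeom_upper_tail(N, K, n, k):
    """P[X >= k] from the combinatorial definition."""
    total = comb(N, n)
    return sum(
        comb(K, i) * comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
        if n - i <= N - K
    ) / total


def brute_force_ks(a, b):
    """Max empirical-CDF gap over all observed values."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    grid = np.unique(np.concatenate([a, b]))
    return max(
        abs((a <= t).mean() - (b <= t).mean()) for t in grid
    )


@pytest.fixture(scope="module")
def target_map():
    return lm.simulate_target_map(60, n_genes=500, targets_per_mirna=(10, 40), seed=2)


class TestTargetsOf:
    def test_union_and_empty_query(self):
        tm = lm.TargetMap(targets={"m1": frozenset({"A", "B"}), "m2": frozenset({"B", "C"})})
        assert lm.targets_of(["m1", "m2"], tm) == {"A", "B", "C"}
        assert lm.targets_of([], tm) == frozenset()
        assert lm.targets_of(["unmapped"], tm) == frozenset()


class TestHypergeometric:
    def test_exact_combinatorial_example(self):
        # N=10, K=4, n=5, full overlap: C(4,4)*C(6,1)/C(10,5) = 6/252
        universe = [f"G{i}" for i in range(10)]
        pathway = universe[:4]
        targets = universe[:4] + [universe[5]]
        k, p = lm.hypergeometric_test(targets, pathway, universe)
        assert k == 4
        assert p == pytest.approx(6 / 252, abs=1e-12)

    def test_zero_overlap_gives_p_one(self):
        universe = [f"G{i}" for i in range(10)]
        k, p = lm.hypergeometric_test(universe[5:7], universe[:3], universe)
        assert k == 0 and p == pytest.approx(1.0)

    def test_matches_enumeration_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100)[:100]:
            N = int(rng.integers(8, 40))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            universe = [f"G{i}" for i in range(N)]
            pathway = list(rng.choice(universe, size=K, replace=False))
            targets = list(rng.choice(universe, size=n, replace=False))
            k, p = lm.hypergeometric_test(targets, pathway, universe)
            assert p == pytest.approx(exact_hypergeom_upper_tail(N, K, n, k), abs=1e-10)

    def test_pmf_sums_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            N = int(rng.integers(5, 30))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            total = sum(
                comb(K, i) * comb(N - K, n - i)
                for i in range(max(0, n - (N - K)), min(K, n) + 1)
            )
            assert total == comb(N, n)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            lm.hypergeometric_test({"A"}, {"A"}, set())


class TestKsEnrichment:
    def test_identical_distributions_give_zero(self):
        scores = pd.Series([1.0, 1.0, 2.0, 2.0], index=list("abcd"))
        assert lm.ks_enrichment(scores, {"a", "c"}) == pytest.approx(0.0)

    def test_full_separation_gives_one(self):
        scores = pd.Series([1, 1, 0, 0], index=list("abcd"), dtype=float)
        assert lm.ks_enrichment(scores, {"a", "b"}) == pytest.approx(1.0)

    def test_empty_after_restriction_is_missing(self):
        scores = pd.Series([1.0], index=["a"])
        assert lm.ks_enrichment(scores, {"zzz"}) is None

    def test_matches_brute_force_ecdf_gap(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(6, 40))
            scores = pd.Series(
                rng.integers(0, 5, size=n).astype(float),
                index=[f"g{i}" for i in range(n)],
            )
            members = set(rng.choice(scores.index, size=int(rng.integers(1, n - 1)),
                                     replace=False))
            d = lm.ks_enrichment(scores, members)
            ref = brute_force_ks(scores[scores.index.isin(members)],
                                 scores[~scores.index.isin(members)])
            assert d == pytest.approx(ref, abs=1e-10)


class TestPermutationNull:
    def test_formula_floor_when_observed_exceeds_all(self, target_map):
        cfg = EnrichmentConfig(n_permutations=99, seed=1)
        universe = target_map.all_genes()
        pathway = sorted(universe)[:50]
        p = lm.permutation_null(
            observed_stat=1e9, mirna_set_size=5, panel=target_map.mirna_ids,
            target_map=target_map, pathway=pathway, universe=universe, cfg=cfg,
        )
        assert p == pytest.approx(1 / 100)

    def test_p_range_and_determinism(self, target_map):
        cfg = EnrichmentConfig(n_permutations=99, seed=5)
        universe = target_map.all_genes()
        pathway = sorted(universe)[:80]
        args = dict(observed_stat=10.0, mirna_set_size=6, panel=target_map.mirna_ids,
                    target_map=target_map, pathway=pathway, universe=universe, cfg=cfg)
        p1 = lm.permutation_null(**args)
        p2 = lm.permutation_null(**args)
        assert p1 == p2
        assert 1 / 100 <= p1 <= 1.0

    def test_set_larger_than_panel_rejected(self, target_map):
        cfg = EnrichmentConfig(n_permutations=99, seed=1)
        with pytest.raises(ValueError):
            lm.permutation_null(1.0, 1000, target_map.mirna_ids, target_map,
                                ["G0001"], target_map.all_genes(), cfg)

    def test_b_floor_validated(self):
        with pytest.raises(ValueError):
            EnrichmentConfig(n_permutations=50)


class TestEnrichAll:
    def test_empty_de_set_gives_zero_overlap_and_q_one(self, target_map):
        coll = lm.simulate_gene_sets(target_map, n_null_sets=5, seed=3)
        res = lm.enrich_all([], coll, target_map,
                            EnrichmentConfig(n_permutations=99, seed=1))
        assert (res.table["k"] == 0).all()
        assert (res.table["q"] == 1.0).all()

    def test_planted_strength_one_hits_permutation_floor(self, target_map):
        sources = target_map.mirna_ids[:8]
        coll = lm.simulate_gene_sets(
            target_map, planted=[("P", sources, 1.0)], n_null_sets=20,
            set_size=(30, 30), seed=4,
        )
        res = lm.enrich_all(sources, coll, target_map,
                            EnrichmentConfig(n_permutations=199, seed=2))
        assert res.table["perm_p"]["P"] == pytest.approx(1 / 200)
        assert res.table.index[0] == "P"  # smallest q first

    def test_gene_relabeling_leaves_permutation_p_invariant(self, target_map):
        sources = target_map.mirna_ids[:5]
        coll = lm.simulate_gene_sets(
            target_map, planted=[("P", sources, 0.8)], n_null_sets=10, seed=5
        )
        cfg = EnrichmentConfig(n_permutations=99, seed=7)
        res = lm.enrich_all(sources, coll, target_map, cfg)

        rename = {g: f"X_{g}" for g in target_map.all_genes()}
        tm2 = lm.TargetMap(targets={
            m: frozenset(rename[g] for g in target_map[m]) for m in target_map.mirna_ids
        })
        coll2 = lm.GeneSetCollection(
            sets={n: (d, frozenset(rename[g] for g in gs))
                  for n, (d, gs) in coll.sets.items()},
            universe=frozenset(rename[g] for g in coll.universe),
        )
        res2 = lm.enrich_all(sources, coll2, tm2, cfg)
        assert np.allclose(res.table["perm_p"].sort_index(),
                           res2.table["perm_p"].sort_index())

    def test_permutation_and_analytic_p_agree_in_rank_order(self):
        # high-resolution fixture: wide set sizes and a large collection so
        # the overlap count takes many values and ranks are well defined
        tm = lm.simulate_target_map(60, n_genes=800,
                                    targets_per_mirna=(10, 40), seed=2)
        rng = np.random.default_rng(8)
        de = list(rng.choice(tm.mirna_ids, size=15, replace=False))
        coll = lm.simulate_gene_sets(tm, n_null_sets=60,
                                     set_size=(50, 150), seed=9)
        res = lm.enrich_all(de, coll, tm,
                            EnrichmentConfig(n_permutations=1999, seed=3))
        rho = stats.spearmanr(res.table["perm_p"], res.table["hypergeom_p"]).statistic
        assert rho >= 0.9

    def test_type_one_error_controlled_over_null_sets(self, target_map):
        rng = np.random.default_rng(10)
        flagged = []
        for seed in range(20):
            coll = lm.simulate_gene_sets(target_map, n_null_sets=50, seed=100 + seed)
            de = list(rng.choice(target_map.mirna_ids, size=8, replace=False))
            res = lm.enrich_all(de, coll, target_map,
                                EnrichmentConfig(n_permutations=199, seed=seed))
            flagged.append(int((res.table["q"] < 0.05).sum()))
        assert np.mean(flagged) <= 2.5

    def test_stronger_planting_never_raises_permutation_p(self, target_map):
        sources = target_map.mirna_ids[:8]
        mean_p = []
        for strength in (0.2, 0.6, 1.0):
            ps = []
            for seed in range(10):
                coll = lm.simulate_gene_sets(
                    target_map, planted=[("P", sources, strength)],
                    n_null_sets=5, set_size=(30, 30), seed=seed,
                )
                res = lm.enrich_all(sources, coll, target_map,
                                    EnrichmentConfig(n_permutations=199, seed=seed))
                ps.append(float(res.table["perm_p"]["P"]))
            mean_p.append(np.mean(ps))
        assert mean_p[0] >= mean_p[1] >= mean_p[2]
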