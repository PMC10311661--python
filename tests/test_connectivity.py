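"""Weighted-KS enrichment, connectivity scoring and Tanimoto similarity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoscreen import (
    Fingerprint,
    QuerySignature,
    RankedProfile,
    generate_reference_profiles,
    preranked_gsea,
    rank_candidates,
    tanimoto,
    weighted_ks_es,
    wtcs,
)
from tests.oracles import brute_ks_es


def profile_of(n, seed=0):
    rng = np.random.default_rng(seed)
    return RankedProfile.from_scores(
        pd.Series(np.sort(rng.standard_normal(n))[::-1], index=[f"g{i:03d}" for i in range(n)])
    )


class TestWeightedKsEs:
    def test_top_block_reaches_plus_one_unweighted(self):
        p = profile_of(20)
        assert weighted_ks_es(p, {"g000", "g001", "g002"}, 0.0) == pytest.approx(1.0)

    def test_bottom_block_reaches_minus_one_unweighted(self):
        p = profile_of(20)
        assert weighted_ks_es(p, {"g017", "g018", "g019"}, 0.0) == pytest.approx(-1.0)

    @pytest.mark.parametrize("w", [0.0, 1.0, 2.0])
    @pytest.mark.parametrize("ranks", [(1, 4, 7), (0, 5, 9), (2, 3, 8), (9,)])
    def test_matches_brute_force_running_sum(self, w, ranks):
        p = profile_of(10, seed=3)
        gene_set = {p.genes[i] for i in ranks}
        expected = brute_ks_es(p.genes, gene_set, p.scores, w)
        assert weighted_ks_es(p, gene_set, w) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(7)
        p = profile_of(60, seed=8)
        for w in (0.0, 1.0):
            for _ in range(25):
                k = int(rng.integers(1, 30))
                genes = set(rng.choice(p.genes, size=k, replace=False))
                assert weighted_ks_es(p, genes, w) == pytest.approx(
                    brute_ks_es(p.genes, genes, p.scores, w), abs=1e-12
                )

    def test_rank_statistic_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        scores = pd.Series(rng.standard_normal(40), index=[f"g{i}" for i in range(40)])
        gene_set = set(scores.index[:7])
        base = weighted_ks_es(RankedProfile.from_scores(scores), gene_set, 0.0)
        for f in (lambda x: 3 * x + 2, np.exp, lambda x: x**3):
            transformed = RankedProfile.from_scores(f(scores))
            assert weighted_ks_es(transformed, gene_set, 0.0) == pytest.approx(base)

    def test_errors(self):
        p = profile_of(10)
        with pytest.raises(ValueError):
            weighted_ks_es(p, {"absent"}, 0.0)
        with pytest.raises(ValueError):
            weighted_ks_es(p, set(p.genes), 0.0)


class TestWtcs:
    def test_perfect_query_scores_one(self):
        p = profile_of(30)
        q = QuerySignature(frozenset(p.genes[:5]), frozenset(p.genes[-5:]))
        assert wtcs(p, q, 0.0) == pytest.approx(1.0)

    def test_antisymmetric_under_query_swap(self):
        p = profile_of(30, seed=2)
        up, down = frozenset(p.genes[3:8]), frozenset(p.genes[20:25])
        q = QuerySignature(up, down)
        q_swapped = QuerySignature(down, up)
        assert wtcs(p, q, 1.0) == pytest.approx(-wtcs(p, q_swapped, 1.0))

    def test_same_sign_enrichments_give_zero(self):
        p = profile_of(30)
        # both sets near the top: both ES positive
        q = QuerySignature(frozenset(p.genes[:4]), frozenset(p.genes[4:8]))
        assert wtcs(p, q, 0.0) == 0.0

    def test_bounded_by_componentwise_es(self):
        rng = np.random.default_rng(11)
        p = profile_of(50, seed=11)
        for _ in range(20):
            genes = rng.permutation(p.genes)
            q = QuerySignature(frozenset(genes[:6]), frozenset(genes[6:12]))
            es_up = weighted_ks_es(p, q.up_set, 1.0)
            es_down = weighted_ks_es(p, q.down_set, 1.0)
            assert abs(wtcs(p, q, 1.0)) <= max(abs(es_up), abs(es_down)) + 1e-12


class TestPrerankedGsea:
    def test_top_set_attains_add_one_floor(self):
        p = profile_of(200, seed=5)
        es, pval = preranked_gsea(p, set(p.genes[:10]), 0.0, n_permutations=999, seed=1)
        assert es == pytest.approx(1.0)
        assert pval == pytest.approx(1 / 1000)

    def test_es_consistent_with_weighted_ks_es(self):
        p = profile_of(100, seed=6)
        genes = set(p.genes[10:25])
        es, _ = preranked_gsea(p, genes, 1.0, n_permutations=100, seed=2)
        assert es == weighted_ks_es(p, genes, 1.0)

    def test_pvalue_floor_respected(self):
        p = profile_of(50, seed=7)
        _, pval = preranked_gsea(p, set(p.genes[:5]), 0.0, n_permutations=199, seed=3)
        assert pval >= 1 / 200

    def test_requires_enough_permutations(self):
        p = profile_of(50)
        with pytest.raises(ValueError):
            preranked_gsea(p, set(p.genes[:5]), 0.0, n_permutations=50)


class TestTanimoto:
    def test_worked_examples(self):
        a = Fingerprint("a", {1, 2, 3}, 8)
        b = Fingerprint("b", {2, 3, 4}, 8)
        assert tanimoto(a, b) == pytest.approx(0.5)
        assert tanimoto(a, a) == 1.0
        assert tanimoto(a, Fingerprint("c", {5, 6}, 8)) == 0.0

    def test_errors(self):
        a = Fingerprint("a", {1}, 8)
        with pytest.raises(ValueError):
            tanimoto(a, Fingerprint("b", {1}, 16))
        with pytest.raises(ValueError):
            tanimoto(Fingerprint("e1", set(), 8), Fingerprint("e2", set(), 8))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        bits_a=st.sets(st.integers(0, 31), min_size=1),
        bits_b=st.sets(st.integers(0, 31), min_size=1),
    )
    def test_symmetry_bounds_and_identity(self, bits_a, bits_b):
        a = Fingerprint("a", bits_a, 32)
        b = Fingerprint("b", bits_b, 32)
        t = tanimoto(a, b)
        assert t == tanimoto(b, a)
        assert 0.0 <= t <= 1.0
        assert (t == 1.0) == (bits_a == bits_b)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        bits=st.tuples(
            st.sets(st.integers(0, 15), min_size=1),
            st.sets(st.integers(0, 15), min_size=1),
            st.sets(st.integers(0, 15), min_size=1),
        )
    )
    def test_soergel_distance_triangle_inequality(self, bits):
        a, b, c = (Fingerprint(str(i), s, 16) for i, s in enumerate(bits))
        d = lambda x, y: 1.0 - tanimoto(x, y)
        assert d(a, c) <= d(a, b) + d(b, c) + 1e-12


class TestRankCandidates:
    def make_query(self, genes):
        return QuerySignature(frozenset(genes[:8]), frozenset(genes[-8:]))

    def test_self_retrieval(self):
        genes = [f"g{i:03d}" for i in range(120)]
        query = self.make_query(genes)
        profiles = generate_reference_profiles(genes, query, n_decoys=10, seed=0)
        table = rank_candidates(profiles, query)
        assert table["compound"].iloc[0] == "planted"

    def test_single_compound(self):
        genes = [f"g{i:03d}" for i in range(50)]
        query = self.make_query(genes)
        profiles = generate_reference_profiles(genes, query, n_decoys=0, seed=1)
        table = rank_candidates(profiles, query)
        assert len(table) == 1

    def test_missing_fingerprint_is_nan_not_error(self):
        genes = [f"g{i:03d}" for i in range(50)]
        query = self.make_query(genes)
        profiles = generate_reference_profiles(genes, query, n_decoys=2, seed=2)
        fp = Fingerprint("planted", {0, 1}, 16)
        table = rank_candidates(
            profiles, query, fingerprints={"planted": fp}, query_fp=fp
        )
        assert table.set_index("compound")["tanimoto"].loc["decoy000"] != table[
            "tanimoto"
        ].max()
        assert np.isnan(table.set_index("compound")["tanimoto"].loc["decoy000"])

    def test_planted_compound_tops_combined_ranking(self):
        genes = [f"g{i:03d}" for i in range(200)]
        query = self.make_query(genes)
        fam_fp = Fingerprint("query", set(range(40)), 256)
        planted_fp = Fingerprint("planted", set(range(5, 45)), 256)
        top = 0
        n_sims = 100
        for seed in range(n_sims):
            profiles = generate_reference_profiles(genes, query, n_decoys=20, seed=seed)
            rng = np.random.default_rng(1000 + seed)
            fps = {"planted": planted_fp}
            for j in range(20):
                start = int(rng.integers(100, 200))
                fps[f"decoy{j:03d}"] = Fingerprint(
                    f"decoy{j:03d}", set(range(start, start + 40)), 256
                )
            table = rank_candidates(profiles, query, fingerprints=fps, query_fp=fam_fp)
            best = table.loc[table["combined_rank"].idxmin(), "compound"]
            top += best == "planted"
        assert top >= 0.95 * n_sims
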