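"""Hypergeometric tails, reference validation, permutation null, enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from methylink import stats
from methylink.errors import ConfigurationError, DataIntegrityError


def _enumerate_tail(k, n, K, N):
    """Exhaustive oracle: enumerate all C(N, n) draws from a labelled urn."""
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for item in draw if item < K) >= k:
            hits += 1
    return hits / total


class TestHypergeomTail:
    def test_zero_overlap_gives_one(self):
        assert stats.hypergeom_tail(0, 50, 10, 100) == 1.0

    def test_full_overlap_small_urn(self):
        # all 5 annotated items drawn in a sample of 5 from 10: 1/C(10,5)
        assert stats.hypergeom_tail(5, 5, 5, 10) == pytest.approx(1 / 252)

    @pytest.mark.parametrize("N", [6, 8, 10])
    def test_matches_exhaustive_enumeration(self, N):
        for K in range(0, N + 1):
            for n in range(1, N + 1):
                for k in range(0, min(n, K) + 1):
                    assert stats.hypergeom_tail(k, n, K, N) == pytest.approx(
                        _enumerate_tail(k, n, K, N), abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            stats.hypergeom_tail(5, 3, 10, 20)


class TestValidatedRatio:
    def test_full_overlap_is_hundred_percent(self):
        pairs = {("g1", "p1"), ("g2", "p2")}
        count, ratio = stats.validated_ratio(pairs, pairs | {("g3", "p3")})
        assert (count, ratio) == (2, 1.0)

    def test_disjoint_sets_are_zero(self):
        count, ratio = stats.validated_ratio({("g1", "p1")}, {("g2", "p2")})
        assert (count, ratio) == (0, 0.0)

    def test_empty_association_set_rejected(self):
        with pytest.raises(DataIntegrityError):
            stats.validated_ratio(set(), {("g", "p")})


class TestPermutationTest:
    def test_reference_covering_universe_gives_p_one(self):
        genes, params = ["g1", "g2"], ["p1", "p2"]
        ref = {(g, p) for g in genes for p in params}
        res = stats.permutation_test(genes, params, ref, n_assoc=2,
                                     observed_count=2, n_perm=50, seed=1)
        assert (res.null_counts == 2).all()
        assert res.empirical_p == 1.0

    def test_null_matches_exhaustive_enumeration_on_tiny_universe(self):
        """3 genes x 2 params, draws of 2: overlap distribution over all
        C(6,2)=15 subsets."""
        genes, params = ["g1", "g2", "g3"], ["p1", "p2"]
        ref = {("g1", "p1"), ("g2", "p2"), ("g3", "p1")}
        universe = [(g, p) for g in genes for p in params]
        exact = np.zeros(3)
        for pair in itertools.combinations(universe, 2):
            exact[sum(p in ref for p in pair)] += 1
        exact /= exact.sum()
        res = stats.permutation_test(genes, params, ref, n_assoc=2,
                                     observed_count=0, n_perm=20000, seed=2)
        emp = np.bincount(res.null_counts, minlength=3) / res.n_perm
        np.testing.assert_allclose(emp, exact, atol=0.02)

    def test_empirical_p_never_below_add_one_floor(self):
        genes, params = [f"g{i}" for i in range(10)], [f"p{i}" for i in range(10)]
        res = stats.permutation_test(genes, params, set(), n_assoc=5,
                                     observed_count=0, n_perm=99, seed=3)
        assert res.empirical_p >= 1 / 100

    def test_determinism(self):
        genes, params = [f"g{i}" for i in range(5)], ["p1", "p2"]
        ref = {("g1", "p1")}
        a = stats.permutation_test(genes, params, ref, 3, 1, n_perm=100, seed=7)
        b = stats.permutation_test(genes, params, ref, 3, 1, n_perm=100, seed=7)
        np.testing.assert_array_equal(a.null_counts, b.null_counts)

    def test_observed_above_n_assoc_rejected(self):
        with pytest.raises(ConfigurationError):
            stats.permutation_test(["g"], ["p"], set(), 1, 2)


UNIVERSE = [f"g{i}" for i in range(20)]


class TestTermEnrichment:
    def test_query_equal_universe_gives_p_one(self):
        sets = {"t1": frozenset(UNIVERSE[:5]), "t2": frozenset(UNIVERSE[3:9])}
        out = stats.term_enrichment(UNIVERSE, UNIVERSE, sets)
        assert (out["p"] == 1.0).all()
        assert (out["k"] == out["K"]).all()

    def test_planted_term_ranks_first(self):
        query = set(UNIVERSE[:5])
        sets = {"planted": frozenset(query),
                "other": frozenset(UNIVERSE[2:12]),
                "background": frozenset(UNIVERSE[10:])}
        out = stats.term_enrichment(query, UNIVERSE, sets)
        assert out.iloc[0]["term"] == "planted"

    def test_p_matches_exhaustive_oracle(self):
        sets = {"t": frozenset(UNIVERSE[:5])}
        query = set(UNIVERSE[1:5]) | {UNIVERSE[10]}   # n=5, k=4, K=5, N=20
        out = stats.term_enrichment(query, UNIVERSE, sets)
        assert out.iloc[0]["p"] == pytest.approx(_enumerate_tail(4, 5, 5, 20),
                                                 abs=1e-12)

    def test_relabeling_invariance(self, rng):
        query = list(rng.choice(UNIVERSE, 6, replace=False))
        sets = {"t1": frozenset(rng.choice(UNIVERSE, 8, replace=False)),
                "t2": frozenset(rng.choice(UNIVERSE, 4, replace=False))}
        relabel = {g: f"x{i}" for i, g in enumerate(UNIVERSE)}
        out1 = stats.term_enrichment(query, UNIVERSE, sets)
        out2 = stats.term_enrichment(
            [relabel[g] for g in query], [relabel[g] for g in UNIVERSE],
            {t: frozenset(relabel[g] for g in s) for t, s in sets.items()})
        pd.testing.assert_frame_equal(out1.drop(columns="term"),
                                      out2.drop(columns="term"))

    def test_query_outside_universe_rejected(self):
        with pytest.raises(DataIntegrityError):
            stats.term_enrichment(["zz"], UNIVERSE, {})

    def test_fdr_column_optional(self):
        sets = {"t": frozenset(UNIVERSE[:5])}
        out = stats.term_enrichment(UNIVERSE[:5], UNIVERSE, sets, fdr=True)
        assert "q" in out.columns


class TestParameterDisease:
    def _assoc(self, rows):
        return pd.DataFrame(rows, columns=["gene", "parameter"]).assign(
            support=3, subjects="", biclusters="")

    def test_exact_gene_set_match_is_top_association(self):
        disease_sets = {"disease_A": (frozenset({"g0", "g1"}), "c", "disease"),
                        "disease_B": (frozenset(UNIVERSE[5:15]), "c", "disease")}
        assoc = self._assoc([("g0", "p1"), ("g1", "p1")])
        out = stats.parameter_disease(assoc, disease_sets, UNIVERSE)
        assert out.iloc[0]["disease"] == "disease_A"
        assert out.iloc[0]["parameter"] == "p1"

    def test_no_overlap_gives_empty_table(self):
        disease_sets = {"d": (frozenset({"g19"}), "c", "disease")}
        assoc = self._assoc([("g0", "p1")])
        out = stats.parameter_disease(assoc, disease_sets, UNIVERSE, p_max=0.01)
        assert out.empty

    def test_empty_association_table_rejected(self):
        with pytest.raises(DataIntegrityError):
            stats.parameter_disease(pd.DataFrame(columns=["gene", "parameter"]),
                                    {}, UNIVERSE)


class TestCoverageCounts:
    def _bic(self, bid, params):
        from methylink.fabia import Bicluster
        return Bicluster(bid, [], np.array([]), list(params),
                         np.zeros(len(params)), 1.0)

    def test_counts_equal_direct_tabulation(self):
        per_subject = {
            "S1": [self._bic("S1_b1", ["p1", "p2"]), self._bic("S1_b2", ["p1"])],
            "S2": [self._bic("S2_b1", ["p1"])],
        }
        out = stats.coverage_counts(per_subject)
        counts = dict(zip(out["item"], out["n_biclusters"]))
        assert counts == {"p1": 3, "p2": 1}

    def test_uncovered_parameter_absent(self):
        out = stats.coverage_counts({"S1": [self._bic("b", ["p1"])]})
        assert "p9" not in set(out["item"])

    def test_term_coverage_from_enrichment_tables(self):
        enr = pd.DataFrame({"term": ["t1", "t2"], "significant": [True, False]})
        out = stats.coverage_counts(
            {"S1": [self._bic("S1_b1", ["p1"])]},
            {"S1_b1": enr})
        terms = out[out["kind"] == "term"]
        assert list(terms["item"]) == ["t1"]
        assert terms.iloc[0]["n_biclusters"] == 1


def test_null_enrichment_fraction_calibrated(rng):
    """Random queries against random sets: significant fraction at p<=0.05
    stays at or below nominal (discrete test is conservative)."""
    genes = [f"g{i}" for i in range(200)]
    n_sig = n_tests = 0
    for rep in range(40):
        sets = {f"t{j}": frozenset(rng.choice(genes, 20, replace=False))
                for j in range(10)}
        query = set(rng.choice(genes, 25, replace=False))
        out = stats.term_enrichment(query, genes, sets)
        n_sig += int(out["significant"].sum())
        n_tests += 10
    assert n_sig / n_tests <= 0.07
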