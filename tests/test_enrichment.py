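import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import brute_bh, brute_hypergeom_tail
from netpharm.enrichment import bh_fdr, enrich, hypergeom_upper_tail
from netpharm.model import GeneSet, ValidationError


class TestHypergeomUpperTail:
    def test_zero_overlap_gives_one(self):
        assert hypergeom_upper_tail(0, 5, 3, 20) == 1.0

    def test_small_exact_value(self):
        # N=10, K=5, n=2, k=2: C(5,2)/C(10,2) = 10/45
        assert hypergeom_upper_tail(2, 5, 2, 10) == pytest.approx(10 / 45, abs=1e-12)

    def test_term_equals_background_gives_one(self):
        assert hypergeom_upper_tail(3, 12, 3, 12) == pytest.approx(1.0)

    @pytest.mark.parametrize("N", [6, 9, 12])
    def test_matches_exhaustive_enumeration(self, N):
        for K in range(1, N + 1):
            for n in range(1, N + 1):
                for k in range(0, min(n, K) + 1):
                    expected = brute_hypergeom_tail(k, K, n, N)
                    assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(
                        expected, abs=1e-12
                    )

    def test_monotone_in_overlap(self):
        ps = [hypergeom_upper_tail(k, 30, 20, 200) for k in range(0, 21)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("args", [(3, 2, 5, 10), (1, 11, 5, 10), (1, 5, 11, 10)])
    def test_inconsistent_counts_rejected(self, args):
        with pytest.raises(ValidationError):
            hypergeom_upper_tail(*args)


class TestBhFdr:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        assert np.allclose(bh_fdr([0.04, 0.01]), [0.04, 0.02])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_textbook_step_up_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 40)))
        assert np.allclose(bh_fdr(p), brute_bh(list(p)), atol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=2, max_size=30),
           st.randoms(use_true_random=False))
    def test_permutation_invariance(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        base = bh_fdr(pvals)
        shuffled = bh_fdr([pvals[i] for i in perm])
        assert np.allclose([base[i] for i in perm], shuffled, atol=1e-12)

    def test_sorted_by_p_fdr_is_non_decreasing(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.001, 1.0, size=25)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 0.0])
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.2])


def _sets():
    return [
        GeneSet("T1", "term one", "pathway", frozenset({"G1", "G2", "G3"})),
        GeneSet("T2", "term two", "pathway", frozenset({"G4", "G5", "G6", "G7"})),
        GeneSet("T3", "term three", "BP", frozenset({"G8", "G9"})),
        GeneSet("BGT", "background holder", "pathway",
                frozenset({f"B{i}" for i in range(40)})),
    ]


class TestEnrich:
    def test_query_matching_a_term_ranks_it_first(self):
        rows = enrich(["G1", "G2", "G3"], _sets(), fdr_max=1.0)
        assert rows[0].term_id == "T1"
        assert rows[0].k == 3
        assert rows[0].rich_factor == 1.0

    def test_fdr_max_one_returns_every_hit_term(self):
        rows = enrich(["G1", "G4"], _sets(), fdr_max=1.0)
        assert {r.term_id for r in rows} == {"T1", "T2"}

    def test_query_disjoint_from_all_terms_empty(self):
        rows = enrich(["B0", "B1"], _sets(), fdr_max=1.0)
        assert all(r.term_id == "BGT" for r in rows)
        rows = enrich(["Z9"], _sets(), fdr_max=1.0)
        assert rows == []

    def test_empty_query_rejected(self):
        with pytest.raises(ValidationError):
            enrich([], _sets())

    def test_empty_background_rejected(self):
        with pytest.raises(ValidationError):
            enrich(["G1"], _sets(), background=["ZZ"])

    def test_symbols_case_normalized(self):
        rows = enrich(["g1", "g2", "g3"], _sets(), fdr_max=1.0)
        assert rows[0].term_id == "T1"

    def test_effective_query_counts_only_background_genes(self):
        rows = enrich(["G1", "G2", "NOT_ANNOTATED"], _sets(), fdr_max=1.0)
        assert rows[0].n == 2

    def test_fdr_grouped_by_category(self):
        rows = enrich(["G1", "G2", "G3", "G8", "G9"], _sets(), fdr_max=1.0)
        by_id = {r.term_id: r for r in rows}
        # T3 is alone in BP: its FDR equals its p-value
        assert by_id["T3"].fdr == pytest.approx(by_id["T3"].p_value)

    def test_rich_factor_bounds_and_coverage(self):
        rows = enrich(["G4", "G5"], _sets(), fdr_max=1.0)
        row = next(r for r in rows if r.term_id == "T2")
        assert 0 < row.rich_factor < 1
        full = enrich(["G4", "G5", "G6", "G7"], _sets(), fdr_max=1.0)
        row = next(r for r in full if r.term_id == "T2")
        assert row.rich_factor == 1.0

    def test_ease_deflation_never_decreases_p(self):
        plain = enrich(["G1", "G2", "G3"], _sets(), fdr_max=1.0)
        eased = enrich(["G1", "G2", "G3"], _sets(), fdr_max=1.0, ease=True)
        p1 = {r.term_id: r.p_value for r in plain}
        p2 = {r.term_id: r.p_value for r in eased}
        assert all(p2[t] >= p1[t] for t in p1)

    def test_explicit_background_shrinks_universe(self):
        bg = ["G1", "G2", "G3", "G4", "G5", "G6", "G7"]
        rows = enrich(["G1", "G2"], _sets(), background=bg, fdr_max=1.0)
        assert all(r.N == 7 for r in rows)


class TestNullCalibration:
    def test_type_one_error_near_nominal_level(self):
        """Uniform null queries give p < 0.05 at close to a 5% rate.

        Term sizes (N=1500, K=400, n=50) are chosen so the discrete
        hypergeometric tail has an attainable level next to 0.05.
        """
        rng = np.random.default_rng(20201)
        N, K, n = 1500, 400, 50
        terms = [np.arange(i * K, (i + 1) * K) for i in range(3)]
        hits = total = 0
        for _ in range(1000):
            q = rng.choice(N, n, replace=False)
            member = np.zeros(N, dtype=bool)
            member[q] = True
            for t in terms:
                k = int(member[t].sum())
                p = hypergeom_upper_tail(k, K, n, N)
                hits += p < 0.05
                total += 1
        frac = hits / total
        half = 2.576 * np.sqrt(0.05 * 0.95 / total)
        assert 0.05 - half < frac < 0.05 + half
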