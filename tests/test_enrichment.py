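import itertools
import math
import random
from fractions import Fraction

import pytest

from condl.enrichment import (
    AnnotationDB,
    bh_adjust,
    enrich,
    hypergeom_upper_tail,
    load_gmt,
)


def exact_tail(k: int, N: int, K: int, n: int) -> Fraction:
    """P(X >= k) as an exact rational from the counting definition."""
    if k <= 0:
        return Fraction(1)
    total = Fraction(0)
    for kk in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, kk) * math.comb(N - K, n - kk), math.comb(N, n))
    return total


class TestLoadGmt:
    def test_two_terms_background_is_union(self, tmp_path):
        p = tmp_path / "a.gmt"
        p.write_text("T1\tdesc\tA\tB\nT2\tdesc\tB\tC\n")
        db = load_gmt(p)
        assert set(db.terms) == {"T1", "T2"}
        assert db.background == {"A", "B", "C"}

    def test_duplicate_genes_within_row_deduplicated(self, tmp_path):
        p = tmp_path / "a.gmt"
        p.write_text("T1\tdesc\tA\tA\tB\n")
        assert load_gmt(p).terms["T1"][1] == {"A", "B"}

    def test_short_row_rejected(self, tmp_path):
        p = tmp_path / "a.gmt"
        p.write_text("T1\tdesc-only\n")
        with pytest.raises(ValueError, match="GMT"):
            load_gmt(p)

    def test_background_missing_annotated_gene_rejected(self, tmp_path):
        p = tmp_path / "a.gmt"
        p.write_text("T1\tdesc\tA\tB\n")
        with pytest.raises(ValueError, match="background"):
            load_gmt(p, background={"A"})


class TestHypergeometricTail:
    def test_full_overlap_closed_form(self):
        # drawing all 5 annotated genes out of 20: 1 / C(20, 5)
        assert hypergeom_upper_tail(5, 20, 5, 5) == pytest.approx(1 / 15504, rel=1e-12)

    def test_matches_exact_rational_enumeration(self):
        rng = random.Random(11)
        for _ in range(300):
            N = rng.randint(2, 30)
            K = rng.randint(1, N)
            n = rng.randint(1, N)
            k = rng.randint(0, min(K, n))
            assert hypergeom_upper_tail(k, N, K, n) == pytest.approx(
                float(exact_tail(k, N, K, n)), rel=1e-9, abs=1e-12
            )

    def test_matches_literal_draw_enumeration_small(self):
        """Every C(N, n) draw enumerated explicitly for a small universe."""
        N, K, n = 9, 4, 5
        universe = list(range(N))
        annotated = set(universe[:K])
        draws = list(itertools.combinations(universe, n))
        for k in range(0, min(K, n) + 1):
            frac = sum(1 for d in draws if len(annotated & set(d)) >= k) / len(draws)
            assert hypergeom_upper_tail(k, N, K, n) == pytest.approx(frac, rel=1e-9)


DB = AnnotationDB(
    {
        "T1": ("inflammation", frozenset("ABCDE")),
        "T2": ("signaling", frozenset("FGH")),
        "T3": ("tiny", frozenset("AT")),
    },
    background=frozenset("ABCDEFGHIJKLMNOPQRSTUVWXY"),  # 25 genes
)


class TestEnrich:
    def test_fisher_full_overlap(self):
        results = enrich(set("ABCDE"), DB, method="fisher")
        r = {x.term: x for x in results}["T1"]
        assert r.k == 5 and r.K == 5 and r.n == 5 and r.N == 25
        assert r.p_raw == pytest.approx(1 / math.comb(25, 5), rel=1e-9)

    def test_low_overlap_terms_skipped(self):
        results = enrich(set("ABCDE"), DB, method="fisher")
        assert "T3" not in {r.term for r in results}  # k = 1 < 2

    def test_ease_is_more_conservative_than_fisher(self):
        rng = random.Random(12)
        for _ in range(20):
            query = set(rng.sample(sorted(DB.background), 8))
            fisher = {r.term: r.p_raw for r in enrich(query, DB, "fisher", min_overlap=2)} if any(
                len(query & genes) >= 2 for _, genes in DB.terms.values()
            ) else {}
            if not fisher:
                continue
            ease = {r.term: r.p_raw for r in enrich(query, DB, "ease", min_overlap=2)}
            for term, p in fisher.items():
                assert ease[term] >= p - 1e-12

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValueError):
            enrich({"zz_not_a_gene"}, DB)

    def test_query_equal_to_term_attains_minimal_p(self):
        base = enrich(set("ABCDE"), DB, method="fisher")
        p_full = {r.term: r.p_raw for r in base}["T1"]
        partial = enrich(set("ABCQ"), DB, method="fisher")
        p_partial = {r.term: r.p_raw for r in partial}["T1"]
        assert p_full <= p_partial


class TestBHAdjust:
    def test_hand_applied_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == [pytest.approx(0.2)]

    def test_all_equal_stay_equal(self):
        assert bh_adjust([0.04, 0.04, 0.04]) == pytest.approx([0.04, 0.04, 0.04])

    def test_general_vector_matches_hand_formula(self):
        pvals = [0.005, 0.011, 0.02, 0.04, 0.9]
        m = len(pvals)
        # step-up by hand: sort asc, p_(i) * m / i, monotone from the top
        scaled = [p * m / (i + 1) for i, p in enumerate(sorted(pvals))]
        expected = []
        running = 1.0
        for v in reversed(scaled):
            running = min(running, v)
            expected.append(running)
        expected.reverse()
        assert bh_adjust(pvals) == pytest.approx(expected)

    def test_permutation_invariant(self):
        rng = random.Random(13)
        pvals = [rng.random() for _ in range(9)]
        base = sorted(bh_adjust(pvals))
        for _ in range(5):
            perm = pvals[:]
            rng.shuffle(perm)
            assert sorted(bh_adjust(perm)) == pytest.approx(base)

    def test_adjusted_at_least_raw(self):
        rng = random.Random(14)
        pvals = [rng.random() for _ in range(12)]
        for raw, adj in zip(pvals, bh_adjust(pvals)):
            assert adj >= raw - 1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])
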