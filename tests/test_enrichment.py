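import itertools
import math

import pytest
from hypothesis import given, settings, strategies as st

from netprio import (
    TermAnnotation, enrich, go_assessment, hypergeom_p, read_gmt,
    term_overlap_eval,
)
from netprio.enrichment import significant_terms


def term(tid, genes, name="t"):
    return TermAnnotation(term_id=tid, term_name=name, genes=frozenset(genes))


class TestReadGmt:
    def test_dedup_within_line(self, tmp_path):
        p = tmp_path / "t.gmt"
        p.write_text("T1\tdesc\tA\tB\tA\n")
        terms = read_gmt(p)
        assert terms[0].genes == {"A", "B"}

    def test_three_lines(self, tmp_path):
        p = tmp_path / "t.gmt"
        p.write_text("T1\td\tA\nT2\td\tB\nT3\td\tC\tD\n")
        assert len(read_gmt(p)) == 3

    def test_duplicate_term_id_errors(self, tmp_path):
        p = tmp_path / "t.gmt"
        p.write_text("T1\td\tA\nT1\td\tB\n")
        with pytest.raises(ValueError, match="duplicate term_id"):
            read_gmt(p)

    def test_empty_line_dropped_empty_file_errors(self, tmp_path):
        p = tmp_path / "t.gmt"
        p.write_text("T1\tdesc\n")
        with pytest.raises(ValueError, match="empty GMT"):
            read_gmt(p)


class TestHypergeomP:
    def test_single_tail_term(self):
        # C(4,3)·C(6,0)/C(10,3) = 4/120
        assert hypergeom_p(3, 3, 4, 10) == pytest.approx(4 / 120)

    def test_zero_overlap_is_one(self):
        assert hypergeom_p(0, 5, 3, 20) == 1.0

    def test_forced_overlap_is_one(self):
        assert hypergeom_p(4, 10, 4, 10) == 1.0

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            hypergeom_p(5, 3, 4, 10)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(2, 12), st.data())
    def test_exhaustive_enumeration_oracle(self, bg, data):
        """P(X >= k) equals the exact fraction of all C(bg, q) draws with
        at least k term members, enumerated exhaustively."""
        q = data.draw(st.integers(1, bg))
        t = data.draw(st.integers(1, bg))
        k = data.draw(st.integers(0, min(q, t)))
        pop = range(bg)
        term_members = set(range(t))
        hits = sum(
            1 for draw in itertools.combinations(pop, q)
            if len(term_members & set(draw)) >= k
        )
        expected = hits / math.comb(bg, q)
        assert hypergeom_p(k, q, t, bg) == pytest.approx(expected)


class TestEnrich:
    TERMS = [term("T1", "ABCD"), term("T2", "EFGHIJ")]

    def test_bonferroni_doubles(self):
        res = {r.term_id: r for r in enrich(["A", "B", "C"], self.TERMS)}
        # background = 10 annotated genes; T1 overlap 3 of query 3
        assert res["T1"].p_raw == pytest.approx(4 / 120)
        assert res["T1"].p_adjusted == pytest.approx(8 / 120)
        assert not res["T1"].significant  # 0.0667 >= 0.05

    def test_single_test_significant(self):
        # explicit 10-gene background; with one tested term the raw and
        # adjusted p coincide and 4/120 clears alpha
        bg = list("ABCDEFGHIJ")
        res = enrich(["A", "B", "C"], [term("T1", "ABCD")], background=bg)
        assert res[0].p_adjusted == pytest.approx(4 / 120)
        assert res[0].significant

    def test_disjoint_query_all_p_one(self):
        res = enrich(["E"], [term("T1", "ABCD"), term("T2", "ABEF")])
        assert all(r.p_raw == 1.0 or r.overlap_count > 0 for r in res)
        t1 = next(r for r in res if r.term_id == "T1")
        assert t1.p_raw == 1.0

    def test_unannotated_query_errors(self):
        with pytest.raises(ValueError, match="not annotated"):
            enrich(["ZZZ"], self.TERMS)

    def test_unannotated_genes_ignored(self):
        base = enrich(["A", "B", "C"], self.TERMS)
        padded = enrich(["A", "B", "C", "Z1", "Z2"], self.TERMS)
        assert base == padded

    def test_adjustment_monotone_and_capped(self):
        for r in enrich(list("ABEF"), self.TERMS):
            assert r.p_raw <= r.p_adjusted <= 1.0


class TestTermOverlapEval:
    def test_set_arithmetic(self):
        res = term_overlap_eval({"T1", "T2", "T3"}, {"T2", "T3", "T4"}, 10)
        assert (res.tp, res.fp, res.fn) == (2, 1, 1)
        assert res.precision == pytest.approx(2 / 3)
        assert res.recall == pytest.approx(2 / 3)
        assert res.f_measure == pytest.approx(2 / 3)

    def test_identity(self):
        assert term_overlap_eval({"T1"}, {"T1"}, 5).f_measure == 1.0

    def test_disjoint(self):
        assert term_overlap_eval({"T1"}, {"T2"}, 5).f_measure == 0.0

    def test_empty_validation_errors(self):
        with pytest.raises(ValueError, match="no disease-related terms"):
            term_overlap_eval({"T1"}, set(), 5)

    @settings(max_examples=50, deadline=None)
    @given(st.sets(st.integers(0, 20)), st.sets(st.integers(0, 20), min_size=1))
    def test_count_identities(self, pred, val):
        res = term_overlap_eval({f"T{i}" for i in pred},
                                {f"T{i}" for i in val}, 30)
        assert res.tp + res.fp == len(pred)
        assert res.tp + res.fn == len(val)


class TestGoAssessment:
    def test_seed_list_recovers_planted_terms(self, small_bundle):
        """Each module's seed list is enriched in its own module terms,
        and a list of held-out module genes beats a random gene list."""
        terms = small_bundle.terms
        for disease, seeds in small_bundle.seed_sets.items():
            sig = significant_terms(enrich(list(seeds.genes), terms))
            planted = {t.term_id for t in terms if disease in t.term_name}
            assert sig & planted

    def test_module_list_beats_random_list(self, small_bundle):
        import numpy as np

        from netprio import RankedGeneList

        terms = small_bundle.terms
        disease = next(iter(small_bundle.seed_sets))
        seeds = small_bundle.seed_sets[disease]
        held = sorted(small_bundle.held_out[disease])
        rng = np.random.default_rng(0)
        rand = [sorted(small_bundle.network.nodes)[i]
                for i in rng.choice(small_bundle.network.n_nodes,
                                    size=len(held), replace=False)]

        def f_of(symbols):
            ranked = [RankedGeneList(disease, "AA", len(symbols),
                                     tuple((g, 1.0) for g in symbols))]
            gv = go_assessment({disease: seeds}, ranked, [], terms)
            return gv.metrics["f_measure"].iloc[0]

        assert f_of(held) > f_of(rand)

    def test_list_identical_to_seed_scores_one(self, small_bundle):
        from netprio import RankedGeneList

        disease = next(iter(small_bundle.seed_sets))
        seeds = small_bundle.seed_sets[disease]
        ranked = [RankedGeneList(disease, "AA", len(seeds),
                                 tuple((g, 1.0) for g in seeds.genes))]
        gv = go_assessment({disease: seeds}, ranked, [], small_bundle.terms)
        assert gv.metrics["f_measure"].iloc[0] == 1.0

    def test_near_one_alpha_significance_limit(self, small_bundle):
        """As alpha -> 1 significance degenerates to p_adjusted < 1; only
        terms whose adjusted p is capped at exactly 1 stay out."""
        disease = next(iter(small_bundle.seed_sets))
        seeds = small_bundle.seed_sets[disease]
        res = enrich(list(seeds.genes), small_bundle.terms, alpha=1 - 1e-12)
        assert all(r.significant == (r.p_adjusted < 1 - 1e-12) for r in res)
        assert any(r.significant for r in res)
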