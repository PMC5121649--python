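"""Annotation parsing, identifier translation, and ORA statistics."""

from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tempomics.enrichment import (
    AnnotationSet,
    TranslationDictionary,
    bh_adjust,
    compound_ora,
    hypergeometric_p,
    ora,
    read_gaf,
    read_mapping_tsv,
    translate_ids,
)
from tempomics.omics import OmicsInputError

GAF = """!gaf-version: 2.2
DB\tP1\tSYM1\t\tGO:0008150\tREF\tIEA\t\tP\t\t\tprotein\ttaxon:9606\t20240101\tDB
DB\tP2\tSYM2\t\tGO:0008150\tREF\tIEA\t\tP\t\t\tprotein\ttaxon:9606\t20240101\tDB
DB\tP3\tSYM3\tNOT\tGO:0008150\tREF\tIEA\t\tP\t\t\tprotein\ttaxon:9606\t20240101\tDB
DB\tP1\tSYM1\t\tGO:0008150\tREF\tIEA\t\tP\t\t\tprotein\ttaxon:9606\t20240101\tDB
DB\tP2\tSYM2\t\tGO:0005575\tREF\tIEA\t\tP\t\t\tprotein\ttaxon:9606\t20240101\tDB
badrow
"""


def enum_hypergeom_tail(N, K, n, m):
    """Exhaustive-enumeration oracle: draw every n-subset of an N-set with
    K marked items, count draws with >= m marked."""
    items = list(range(N))
    marked = set(items[:K])
    total = hits = 0
    for draw in combinations(items, n):
        total += 1
        if len(marked.intersection(draw)) >= m:
            hits += 1
    return Fraction(hits, total)


class TestReaders:
    def test_gaf_parse(self, tmp_path):
        f = tmp_path / "a.gaf"
        f.write_text(GAF)
        ann = read_gaf(f)
        assert ann.categories["GO:0008150"] == {"P1", "P2"}  # NOT excluded, dup once
        assert ann.categories["GO:0005575"] == {"P2"}
        assert ann.universe == {"P1", "P2", "P3"}
        assert ann.n_skipped_rows == 1

    def test_mapping_as_annotation_and_dictionary(self, tmp_path):
        f = tmp_path / "map.tsv"
        f.write_text(
            "g1\tpathA\tdesc A\ng2\tpathA\ng3\tpathB\ng4\tpathB\ng5\tpathB\n"
            "g1\tpathB\n"
        )
        ann = read_mapping_tsv(f, "annotation")
        assert set(ann.categories) == {"pathA", "pathB"}
        assert ann.descriptions["pathA"] == "desc A"
        d = read_mapping_tsv(f, "dictionary")
        assert d.mapping["g1"] == ["pathA", "pathB"]  # one-to-many preserved

    def test_empty_file_warns(self, tmp_path):
        f = tmp_path / "empty.tsv"
        f.write_text("")
        with pytest.warns(UserWarning, match="no usable rows"):
            ann = read_mapping_tsv(f, "annotation")
        assert ann.categories == {}


class TestTranslate:
    DICT = TranslationDictionary("symbol", "kegg", {"TP53": ["hsa:7157"]})

    def test_direct_lookup(self):
        mapped, unmapped = translate_ids(["TP53"], self.DICT)
        assert mapped == {"TP53": ["hsa:7157"]}
        assert unmapped == []

    def test_unknown_reported_not_dropped(self):
        mapped, unmapped = translate_ids(["NOPE"], self.DICT)
        assert mapped == {} and unmapped == ["NOPE"]

    def test_first_policy_takes_lexicographic_first(self):
        d = TranslationDictionary("s", "t", {"A": ["z9", "a1"]})
        mapped, _ = translate_ids(["A"], d, multi_policy="first")
        assert mapped == {"A": ["a1"]}


class TestHypergeometric:
    def test_worked_example_exact_third(self):
        assert hypergeometric_p(10, 3, 4, 2) == pytest.approx(1 / 3, abs=1e-12)
        assert enum_hypergeom_tail(10, 3, 4, 2) == Fraction(1, 3)

    def test_zero_overlap_is_one(self):
        assert hypergeometric_p(40, 5, 7, 0) == 1.0

    def test_maximal_overlap_single_term(self):
        # m = min(K, n): single-term tail C(K,m) C(N-K,n-m) / C(N,n)
        from math import comb

        N, K, n = 12, 4, 6
        m = min(K, n)
        expected = comb(K, m) * comb(N - K, n - m) / comb(N, n)
        assert hypergeometric_p(N, K, n, m) == pytest.approx(expected, abs=1e-12)

    def test_complete_small_sweep_against_enumeration(self):
        # all instances with N <= 9 here; the full N <= 12 sweep runs in
        # the acceptance suite
        for N in range(1, 10):
            for K in range(N + 1):
                for n in range(N + 1):
                    for m in range(min(K, n) + 1):
                        exact = float(enum_hypergeom_tail(N, K, n, m))
                        assert hypergeometric_p(N, K, n, m) == pytest.approx(
                            exact, abs=1e-12
                        )

    def test_invalid_arguments(self):
        with pytest.raises(OmicsInputError):
            hypergeometric_p(10, 11, 4, 2)
        with pytest.raises(OmicsInputError):
            hypergeometric_p(10, 3, 4, 4)


class TestBH:
    def test_all_equal_ratio(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_value_unchanged(self):
        assert bh_adjust([0.3])[0] == 0.3

    def test_hand_stepup(self):
        assert np.allclose(bh_adjust([0.005, 0.1, 0.9]), [0.015, 0.15, 0.9])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 50)
        assert np.allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])

    def test_out_of_range_rejected(self):
        with pytest.raises(OmicsInputError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone_along_sorted_p_and_bounded(self, p):
        q = bh_adjust(p)
        assert np.all(q <= 1.0) and np.all(q >= np.asarray(p) - 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)


@pytest.fixture
def small_annotations():
    genes = [f"g{i}" for i in range(10)]
    return AnnotationSet(
        {"catA": {"g0", "g1", "g2"}, "catB": {"g3", "g4", "g5", "g6"}},
        set(genes),
        {"catA": "first category"},
    )


class TestORA:
    def test_worked_overlap_example(self, small_annotations):
        res = ora(["g0", "g1", "g7", "g8"], small_annotations)
        row = next(r for r in res.all_results if r.category == "catA")
        assert (row.N, row.K, row.n, row.m) == (10, 3, 4, 2)
        assert row.p == pytest.approx(1 / 3, abs=1e-12)
        assert row.members == ["g0", "g1"]

    def test_disjoint_query_all_p_one(self, small_annotations):
        res = ora(["g7", "g8", "g9"], small_annotations)
        assert all(r.m == 0 and r.p == 1.0 for r in res.all_results)
        assert res.results == []

    def test_full_category_minimum_p(self, small_annotations):
        from math import comb

        res = ora(["g0", "g1", "g2"], small_annotations)
        row = next(r for r in res.all_results if r.category == "catA")
        assert row.p == pytest.approx(1 / comb(10, 3), abs=1e-15)

    def test_unannotated_query_ids_reported(self, small_annotations):
        res = ora(["g0", "mystery"], small_annotations)
        assert res.unannotated == ["mystery"]
        assert res.n_query_annotated == 1

    def test_empty_query_error(self, small_annotations):
        with pytest.raises(OmicsInputError, match="empty query"):
            ora([], small_annotations)

    def test_query_permutation_invariance(self, small_annotations):
        a = ora(["g0", "g1", "g4", "g9"], small_annotations)
        b = ora(["g9", "g4", "g1", "g0"], small_annotations)
        assert [(r.category, r.p, r.q) for r in a.all_results] == [
            (r.category, r.p, r.q) for r in b.all_results
        ]

    def test_bonferroni_option(self, small_annotations):
        res = ora(["g0", "g1"], small_annotations, adjustment="bonferroni")
        for r in res.all_results:
            assert r.q == pytest.approx(min(1.0, r.p * len(res.all_results)))

    def test_fdr_null_calibration(self):
        # uniform-random queries: fraction of categories called at
        # q <= 0.05 stays near or below 0.05
        rng = np.random.default_rng(42)
        genes = [f"g{i}" for i in range(60)]
        cats = {
            f"c{j}": set(rng.choice(genes, 8, replace=False)) for j in range(15)
        }
        ann = AnnotationSet(cats, set(genes))
        called = total = 0
        for _ in range(200):
            query = list(rng.choice(genes, 10, replace=False))
            res = ora(query, ann)
            called += len(res.results)
            total += len(res.all_results)
        assert called / total <= 0.05 + 0.03

    def test_compound_ora_full_map_ranks_first(self):
        compounds = [f"m{i}" for i in range(6)]
        ann = AnnotationSet(
            {"map1": {"m0", "m1", "m2"}, "map2": {"m3", "m4"}},
            set(compounds),
        )
        res = compound_ora(["m0", "m1", "m2"], ann)
        assert res.all_results[0].category == "map1"

    def test_compound_unmapped_reported(self):
        ann = AnnotationSet({"map1": {"m0"}}, {"m0", "m1"})
        res = compound_ora(["zzz"], ann)
        assert res.unannotated == ["zzz"]
        assert all(r.m == 0 for r in res.all_results)
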