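"""Tokenization, term statistics, Z-score selection, binning and vectors."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.proportion import proportions_ztest

from triagecap import (
    FeatureConfig,
    TermStats,
    bin_terms,
    compute_term_stats,
    extract_terms,
    filter_vocabulary,
    select_distinguishing,
    tokenize,
    vectorize_bins,
    vectorize_terms,
    z_score,
)
from triagecap.features import document_terms


def make_stats(df_rel, n_rel, df_irr, n_irr, terms=None) -> TermStats:
    df_rel = np.asarray(df_rel)
    df_irr = np.asarray(df_irr)
    terms = terms or [f"t{i:03d}" for i in range(len(df_rel))]
    table = pd.DataFrame(
        {
            "df_rel": df_rel,
            "df_irr": df_irr,
            "p_rel": df_rel / n_rel,
            "p_irr": df_irr / n_irr,
            "z": 0.0,
        },
        index=pd.Index(terms, name="term"),
    )
    return TermStats(table, n_rel, n_irr)


class TestTokenize:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("PRGE expression, in ANAT.", ["PRGE", "expression", "in", "ANAT"]),
            ("", []),
            ("Wnt-7a signaling", ["wnt", "7a", "signaling"]),
            ("prge lowercase", ["PRGE", "lowercase"]),
        ],
    )
    def test_cases(self, text, expected):
        assert tokenize(text) == expected


class TestExtractTerms:
    def test_unigrams_and_bigrams(self):
        assert extract_terms(["a", "b", "c"], {1, 2}) == {"a", "b", "c", "a b", "b c"}

    def test_no_bigram_from_single_token(self):
        assert extract_terms(["a"], {2}) == set()

    def test_set_semantics(self):
        assert extract_terms(["a", "b", "a", "b"], {2}) == {"a b", "b a"}

    def test_bigrams_do_not_cross_sentence_boundaries(self):
        terms = document_terms("end here. new start")
        assert "here new" not in terms
        assert "new start" in terms and "end here" in terms


class TestTermStats:
    def test_document_frequency_probability(self):
        rel = [{"t"} for _ in range(30)] + [set() for _ in range(70)]
        irr = [{"u"} for _ in range(10)]
        stats = compute_term_stats(rel, irr)
        assert stats.table.loc["t", "p_rel"] == pytest.approx(0.3)
        assert stats.table.loc["t", "p_irr"] == 0.0

    def test_duplicating_documents_preserves_probabilities(self):
        rel = [{"a", "b"}, {"a"}, {"c"}]
        irr = [{"a"}, {"b", "c"}]
        s1 = compute_term_stats(rel, irr)
        s2 = compute_term_stats(rel * 3, irr * 3)
        pd.testing.assert_series_equal(s1.table["p_rel"], s2.table["p_rel"])
        pd.testing.assert_series_equal(s1.table["p_irr"], s2.table["p_irr"])

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            compute_term_stats([], [{"a"}])


class TestFilterVocabulary:
    def _stats(self):
        # terms: stopword, single letter, rare, frequent, bigram w/ stopword, keeper
        return make_stats(
            df_rel=[40, 30, 1, 60, 30, 30],
            n_rel=50,
            df_irr=[40, 20, 0, 60, 20, 20],
            n_irr=70,
            terms=["the", "x", "rare", "ubiquitous", "the keeper", "keeper"],
        )

    def test_filters(self):
        cfg = FeatureConfig(stopwords=frozenset({"the"}), rare_min_docfreq=5,
                            frequent_max_docfrac=0.5)
        kept = set(filter_vocabulary(self._stats(), cfg).terms)
        assert kept == {"keeper"}


class TestZScore:
    def test_equal_proportions_zero(self):
        assert z_score(10, 100, 100, 1000) == pytest.approx(0.0)

    def test_antisymmetry_equal_sizes(self):
        assert z_score(12, 50, 30, 50) == pytest.approx(-z_score(30, 50, 12, 50))

    def test_hand_computed_example(self):
        # pooled p = 130/1100; z = (0.3 - 0.1)/sqrt(p(1-p)(1/100 + 1/1000))
        assert z_score(30, 100, 100, 1000) == pytest.approx(5.9071, abs=1e-3)

    def test_degenerate_pooled_proportions(self):
        assert z_score(0, 10, 0, 20) == 0.0
        assert z_score(10, 10, 20, 20) == 0.0

    def test_df_exceeding_class_size_rejected(self):
        with pytest.raises(ValueError):
            z_score(11, 10, 0, 10)

    def test_matches_independent_implementation(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n1, n2 = rng.integers(2, 500, size=2)
            a, b = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            pooled = (a + b) / (n1 + n2)
            if pooled in (0.0, 1.0):
                continue
            ref, _ = proportions_ztest([a, b], [n1, n2])
            assert z_score(int(a), int(n1), int(b), int(n2)) == pytest.approx(
                float(ref), abs=1e-9
            )


class TestSelection:
    def test_threshold_and_absolute_value(self):
        stats = make_stats([0, 0, 0], 100, [0, 0, 0], 100)
        stats.table["z"] = [0.0, -3.2, 1.5]
        kept = set(select_distinguishing(stats, 1.96).terms)
        assert kept == {"t001"}


def iterative_merge_oracle(df_rel, n_rel, df_irr, n_irr, width: Fraction):
    """Literal iterative pairwise bin merging, in exact rational arithmetic.

    Start from singleton bins; merge bins p and q whenever all member terms'
    Pr(t|rel) values share one width-w sub-interval and their Pr(t|irr)
    values share another; repeat to the fixed point.
    """

    def interval(df, n):
        return math.floor(Fraction(df, n) / width)

    bins = [[i] for i in range(len(df_rel))]
    changed = True
    while changed:
        changed = False
        for a in range(len(bins)):
            for b in range(a + 1, len(bins)):
                members = bins[a] + bins[b]
                if (
                    len({interval(df_rel[t], n_rel) for t in members}) == 1
                    and len({interval(df_irr[t], n_irr) for t in members}) == 1
                ):
                    bins[a] = members
                    del bins[b]
                    changed = True
                    break
            if changed:
                break
    return {frozenset(b) for b in bins}


def grid_partition_as_sets(stats: TermStats, width: float):
    binset = bin_terms(stats, width)
    index = {t: i for i, t in enumerate(stats.terms)}
    return {frozenset(index[t] for t in b.terms) for b in binset.bins}


class TestBinning:
    def test_identical_probabilities_share_bin(self):
        stats = make_stats([10, 10], 50, [5, 5], 50)
        assert bin_terms(stats, 0.0001).n == 1

    def test_boundary_probability_goes_to_upper_interval(self):
        # p_rel = 1/500 = 0.002 sits exactly on a bin boundary at w=1e-4
        stats = make_stats([1, 1], 500, [0, 0], 500)
        binset = bin_terms(stats, 0.0001)
        assert binset.bins[0].rel_index == 20

    def test_spec_interval_example(self):
        # p_rel = 0.50003/0.50007/0.50012 and p_irr = 0.10002/0.10009/0.10003:
        # the first two terms share both sub-intervals at w=1e-4, the third
        # differs in the rel interval
        stats = make_stats([50003, 50007, 50012], 100000,
                           [10002, 10009, 10003], 100000)
        binset = bin_terms(stats, 0.0001)
        assert binset.n == 2
        assert {len(b.terms) for b in binset.bins} == {1, 2}

    def test_degenerate_width_single_bin(self):
        with pytest.raises(ValueError):
            bin_terms(make_stats([1], 10, [1], 10), 1.0)
        stats = make_stats([3, 7, 1], 10, [2, 9, 5], 10)
        assert bin_terms(stats, 0.9999).n == 1

    def test_partition_property(self, small_corpus):
        corpus, _ = small_corpus
        rel = [document_terms(d.abstract) for d in corpus if d.label == "relevant"]
        irr = [document_terms(d.abstract) for d in corpus if d.label == "irrelevant"]
        stats = compute_term_stats(rel[:30], irr[:60])
        binset = bin_terms(stats, 0.01)
        members = [t for b in binset.bins for t in b.terms]
        assert sorted(members) == sorted(stats.terms)  # disjoint and covering
        assert binset.n <= len(stats)

    def test_grid_equals_iterative_merge_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            m = int(rng.integers(2, 50))
            n_rel = int(rng.integers(3, 40))
            n_irr = int(rng.integers(3, 40))
            df_rel = rng.integers(0, n_rel + 1, size=m)
            df_irr = rng.integers(0, n_irr + 1, size=m)
            inv = int(rng.choice([2, 3, 5, 10, 100]))
            stats = make_stats(df_rel, n_rel, df_irr, n_irr)
            got = grid_partition_as_sets(stats, 1.0 / inv)
            expected = iterative_merge_oracle(df_rel, n_rel, df_irr, n_irr,
                                              Fraction(1, inv))
            assert got == expected


class TestVectors:
    def test_term_vector_enumeration(self):
        assert vectorize_terms({"b"}, ["a", "b", "c"]).tolist() == [0, 1, 0]
        assert vectorize_terms(set(), ["a", "b"]).tolist() == [0, 0]
        assert vectorize_terms({"a", "b"}, ["a", "b"]).tolist() == [1, 1]

    def test_bin_vector_any_member_rule(self):
        stats = make_stats([10, 10, 3], 50, [5, 5, 9], 50)
        binset = bin_terms(stats, 0.0001)  # t000+t001 share a bin, t002 alone
        assert binset.n == 2
        v = vectorize_bins({"t001"}, binset)
        assert v.sum() == 1
        assert vectorize_bins(set(), binset).tolist() == [0, 0]

    def test_singleton_bins_reduce_to_term_vector(self):
        stats = make_stats([10, 20, 30], 50, [5, 15, 25], 50)
        binset = bin_terms(stats, 0.0001)
        assert binset.n == 3
        doc = {"t000", "t002"}
        order = [t for b in binset.bins for t in b.terms]
        assert vectorize_bins(doc, binset).tolist() == vectorize_terms(doc, order).tolist()
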