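"""Operon alignment: scoring, traceback, orthologous pairing."""

import itertools

import numpy as np
import pytest

from operonevo.align import (
    DEFAULT_SCORING,
    FULL,
    MISMATCH,
    PARTIAL,
    Scoring,
    align_operons,
    build_ortholog_map,
    pair_orthologous_operons,
    pair_singletons,
    score_gene_pair,
)
from operonevo.model import GENE_ALPHABET, Gene, GeneOrder

from conftest import operon, r, singleton, t


def brute_force_score(x, y, scoring=DEFAULT_SCORING):
    """Exhaustive maximum over all monotone global alignments (oracle)."""
    table = {FULL: scoring.full, PARTIAL: scoring.partial, MISMATCH: scoring.mismatch}

    def rec(i, j):
        if i == len(x) and j == len(y):
            return 0.0
        best = -np.inf
        if i < len(x) and j < len(y):
            best = max(best, table[score_gene_pair(x[i], y[j])] + rec(i + 1, j + 1))
        if i < len(x):
            best = max(best, scoring.gap + rec(i + 1, j))
        if j < len(y):
            best = max(best, scoring.gap + rec(i, j + 1))
        return best

    return rec(0, 0)


def random_operon(rng, max_len=6):
    k = int(rng.integers(1, max_len + 1))
    genes = []
    for _ in range(k):
        cls, ac = GENE_ALPHABET[rng.integers(len(GENE_ALPHABET))]
        genes.append(Gene(cls, ac, 1))
    return genes


class TestScoreGenePair:
    def test_full_match(self):
        assert score_gene_pair(t("Ala", "tgc"), t("Ala", "tgc")) == FULL

    def test_partial_match_same_class_other_anticodon(self):
        assert score_gene_pair(t("Ala", "tgc"), t("Ala", "ggc")) == PARTIAL

    def test_rrna_has_no_partial(self):
        assert score_gene_pair(r("16S"), r("23S")) == MISMATCH
        assert score_gene_pair(r("16S"), r("16S")) == FULL

    def test_signs_do_not_enter_the_score(self):
        assert score_gene_pair(t("Ala", "tgc", 1), t("Ala", "tgc", -1)) == FULL


class TestAlignOperons:
    def test_identity_scores_one_per_gene(self):
        genes = [t("Ala", "tgc"), t("Asn", "gtt")]
        al = align_operons(genes, genes)
        assert al.score == 2.0
        assert [c.label for c in al.columns] == [FULL, FULL]

    def test_partial_scores_half(self):
        al = align_operons([t("Ala", "tgc")], [t("Ala", "ggc")])
        assert al.score == 0.5

    def test_one_gap_example(self):
        x = [t("Ala", "tgc"), t("Ile", "gat"), t("Asn", "gtt")]
        y = [t("Ala", "tgc"), t("Asn", "gtt")]
        al = align_operons(x, y)
        assert al.score == 1.0  # two full matches minus one gap
        assert al.score == brute_force_score(x, y)

    def test_score_equals_column_sum(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            x, y = random_operon(rng), random_operon(rng)
            al = align_operons(x, y)
            assert al.score == pytest.approx(al.column_score())

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            x, y = random_operon(rng), random_operon(rng)
            assert align_operons(x, y).score == pytest.approx(brute_force_score(x, y))

    def test_score_symmetry(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            x, y = random_operon(rng), random_operon(rng)
            assert align_operons(x, y).score == pytest.approx(align_operons(y, x).score)

    def test_empty_operon_rejected(self):
        with pytest.raises(ValueError):
            align_operons([], [t("Ala", "tgc")])

    def test_scoring_ordering_enforced(self):
        with pytest.raises(ValueError):
            Scoring(full=1.0, partial=1.5, mismatch=-1.0, gap=-1.0)


def _order(units, terminus, gid="g"):
    return GeneOrder(gid, units, terminus)


class TestPairing:
    def test_identical_single_operon_pairs_unflipped(self):
        a = _order([operon(t("Ala", "tgc"), t("Asn", "gtt")), singleton(t("Ile", "gat"))], 1, "a")
        b = _order([operon(t("Ala", "tgc"), t("Asn", "gtt")), singleton(t("Ile", "gat"))], 1, "b")
        m = pair_orthologous_operons(a, b)
        assert len(m.operon_pairs) == 1
        assert not m.operon_pairs[0].flipped

    def test_tie_broken_by_index_distance(self):
        op = lambda: operon(t("Ala", "tgc"), t("Asn", "gtt"))
        filler = lambda: singleton(t("Met", "cat"))
        # A's operon at index 3; B has equal-scoring operons at indices 2 and 7
        a = _order([filler(), filler(), filler(), op(), filler(), filler(), filler(), filler()], 4, "a")
        b = _order([filler(), filler(), op(), filler(), filler(), filler(), filler(), op()], 4, "b")
        m = pair_orthologous_operons(a, b)
        assert len(m.operon_pairs) == 1
        assert (m.operon_pairs[0].x_index, m.operon_pairs[0].y_index) == (3, 2)

    def test_negative_scores_discarded(self):
        a = _order([operon(t("Ala", "tgc"), t("Asn", "gtt"))], 0, "a")
        b = _order([operon(r("16S"), r("23S"))], 0, "b")
        m = pair_orthologous_operons(a, b)
        assert not m.operon_pairs
        assert m.unmapped_x == [0] and m.unmapped_y == [0]

    def test_flipped_flag_from_orientation(self):
        a = _order([operon(t("Ala", "tgc"), t("Asn", "gtt")), singleton(t("Ile", "gat"))], 1, "a")
        b = _order(
            [operon(t("Asn", "gtt", -1), t("Ala", "tgc", -1)), singleton(t("Ile", "gat"))], 1, "b"
        )
        m = pair_orthologous_operons(a, b)
        assert len(m.operon_pairs) == 1 and m.operon_pairs[0].flipped

    def test_singletons_pair_by_index_proximity(self):
        filler = lambda i: operon(r("16S"), r("23S"))
        s = lambda: singleton(t("Ile", "gat"))
        pad = lambda: singleton(t("Met", "cat"))
        a_units = [pad(), s(), pad(), pad(), pad(), pad(), pad(), pad(), pad(), s()]
        b_units = [pad(), pad(), pad(), pad(), pad(), pad(), pad(), pad(), s()]
        a = _order(a_units, 5, "a")
        b = _order(b_units, 5, "b")
        m = build_ortholog_map(a, b)
        ile_pairs = [p for p in m.singleton_pairs if p.x_unit.genes[0].value() == ("Ile", "gat")]
        assert len(ile_pairs) == 1
        assert (ile_pairs[0].x_index, ile_pairs[0].y_index) == (9, 8)

    def test_different_singleton_classes_stay_unmapped(self):
        a = _order([singleton(t("Ala", "tgc")), singleton(t("Ile", "gat"))], 1, "a")
        b = _order([singleton(t("Ala", "ggc")), singleton(t("Ile", "gat"))], 1, "b")
        m = build_ortholog_map(a, b)
        # no partial singleton match: Ala(tgc) vs Ala(ggc) are not identical
        assert len(m.singleton_pairs) == 1
        assert 0 in m.unmapped_x and 0 in m.unmapped_y

    def test_pairing_is_a_matching_with_nonnegative_scores(self):
        from conftest import random_root

        for seed in range(5):
            a = random_root(seed, n=60)
            b = random_root(seed + 100, n=60)
            m = build_ortholog_map(a, b)
            xs = [p.x_index for p in m.pairs]
            ys = [p.y_index for p in m.pairs]
            assert len(xs) == len(set(xs)) and len(ys) == len(set(ys))
            assert all(p.alignment.score >= 0 for p in m.operon_pairs)
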