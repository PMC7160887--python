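"""Core model: gene orders, event application/undo, realism predicates."""

import numpy as np
import pytest

from operonevo.model import (
    AnnotationError,
    DELETION,
    DUPLICATION,
    Event,
    Gene,
    GeneOrder,
    INVERSION,
    ModelViolationError,
    REVERSED_TRANSPOSITION,
    TRANSPOSITION,
    Unit,
    apply_event,
    is_realistic,
    linearize,
    undo_event,
)
from operonevo.simulate import SimParams, simulate_branch

from conftest import operon, r, singleton, t


class TestTypes:
    def test_trna_requires_anticodon(self):
        with pytest.raises(AnnotationError):
            Gene("Ala", None, 1)

    def test_rrna_rejects_anticodon(self):
        with pytest.raises(AnnotationError):
            Gene("16S", "tgc", 1)

    def test_unit_requires_uniform_strand(self):
        with pytest.raises(AnnotationError):
            Unit("operon", [t("Ala", "tgc", 1), t("Ile", "gat", -1)])

    def test_singleton_holds_one_gene(self):
        with pytest.raises(AnnotationError):
            Unit("singleton", [t("Ala", "tgc"), t("Ile", "gat")])

    def test_provenance_excluded_from_equality(self):
        a = Gene("Ala", "tgc", 1)
        b = Gene("Ala", "tgc", 1, restored_from="X")
        assert a == b


class TestLinearize:
    def test_linear_view_reports_terminus(self, small_order):
        units, term = linearize(small_order)
        assert [u.kind for u in units] == ["operon", "singleton", "operon"]
        assert term == 2

    def test_stored_list_is_the_linearization(self, small_order):
        units, _ = linearize(small_order)
        assert units == small_order.units

    def test_invalid_terminus_rejected(self, small_order):
        small_order.terminus = 5
        with pytest.raises(AnnotationError):
            linearize(small_order)


class TestApplyEvent:
    def test_deletion_inside_operon_shrinks_it(self, small_order):
        e = Event(
            DELETION,
            None,
            1,
            {"target": ("in", 0, 1), "content": [r("23S")]},
        )
        out = apply_event(small_order, e)
        assert len(out.units[0].genes) == 3
        assert out.n_genes == small_order.n_genes - 1

    def test_inversion_next_to_origin_reverses_and_flips(self, small_order):
        e = Event(INVERSION, None, 2, {"span": (0, 2)})
        out = apply_event(small_order, e)
        # unit order reversed, genome order within units reversed, signs flipped
        assert out.units[0].genes[0] == t("Ile", "gat", -1)
        assert [g.value() for g in out.units[1].genes] == [
            ("Ala", "tgc"), ("5S", None), ("23S", None), ("16S", None)
        ]
        assert all(g.sign == -1 for g in out.units[1].genes)

    def test_transposition_across_terminus_must_be_reversed(self, small_order):
        plain = Event(TRANSPOSITION, None, 1, {"span": (1, 2), "dest": 2})
        with pytest.raises(ModelViolationError):
            apply_event(small_order, plain)
        ok = Event(REVERSED_TRANSPOSITION, None, 1, {"span": (1, 2), "dest": 2})
        out = apply_event(small_order, ok)
        assert out.units[2].genes[0] == t("Ile", "gat", -1)

    def test_duplication_changes_count_by_size(self, small_order):
        e = Event(
            DUPLICATION,
            None,
            2,
            {
                "target": ("new", 3, "operon"),
                "content": [t("Asn", "gtt", -1), t("Glu", "ttc", -1)],
                "source": (5, 2, False),
            },
        )
        out = apply_event(small_order, e)
        assert out.n_genes == small_order.n_genes + 2


class TestIsRealistic:
    def test_internal_inversion_rejected(self):
        g = GeneOrder(
            "g",
            [singleton(t("Ala", "tgc")), singleton(t("Ile", "gat")),
             singleton(t("Asn", "gtt")), singleton(t("Glu", "ttc", -1))],
            3,
        )
        ok, reason = is_realistic(Event(INVERSION, None, 1, {"span": (1, 2)}), g)
        assert not ok and "axis" in reason

    def test_partial_operon_source_rejected(self, small_order):
        # a multi-gene duplication whose source spans two units splits an operon
        e = Event(
            DUPLICATION,
            None,
            2,
            {
                "target": ("new", 3, "operon"),
                "content": [t("Ala", "tgc"), t("Ile", "gat")],
                "source": (3, 2, False),
            },
        )
        ok, reason = is_realistic(e, small_order)
        assert not ok and "operon split" in reason

    def test_whole_operon_duplication_allowed(self, small_order):
        e = Event(
            DUPLICATION,
            None,
            4,
            {
                "target": ("new", 2, "operon"),
                "content": [g.clone() for g in small_order.units[0].genes],
                "source": (0, 4, False),
            },
        )
        ok, _ = is_realistic(e, small_order)
        assert ok


class TestApplyUndoRoundTrip:
    """apply then undo is the identity for every event type (randomized)."""

    @pytest.mark.parametrize("seed", range(12))
    def test_random_event_sequences(self, seed):
        from operonevo.simulate import generate_root

        rng = np.random.default_rng(seed)
        params = SimParams(x_recipe=3, seed=seed)
        parent = generate_root(params, rng)
        child, truth = simulate_branch(
            parent, ["duplication", "deletion", "inversion", "transposition",
                     "substitution"] * 2, params.p_event, rng, "B"
        )
        g = parent.clone()
        states = [g.clone()]
        for e in truth:
            g = apply_event(g, e, strict=False)
            states.append(g.clone())
        for e, before in zip(reversed(truth), reversed(states[:-1])):
            g = undo_event(g, e)
            assert g == before

    @pytest.mark.parametrize("seed", range(6))
    def test_gene_count_conservation(self, seed):
        from operonevo.simulate import generate_root

        rng = np.random.default_rng(seed)
        params = SimParams(seed=seed)
        parent = generate_root(params, rng)
        g = parent.clone()
        child, truth = simulate_branch(
            parent, ["duplication", "deletion", "inversion", "transposition",
                     "substitution"] * 2, params.p_event, rng, "B"
        )
        for e in truth:
            before = g.n_genes
            g = apply_event(g, e, strict=False)
            delta = g.n_genes - before
            if e.event_type in ("duplication", "inversed_duplication"):
                assert delta == e.size
            elif e.event_type == "deletion":
                assert delta == -e.size
            else:
                assert delta == 0
            # realistic events keep operons contiguous and single-stranded
            for u in g.units:
                assert len({x.sign for x in u.genes}) == 1
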