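"""Step 2 decisions: gap classification, column labelling, unmapped units."""

import pytest

from operonevo.align import align_operons, build_ortholog_map, UnitPair
from operonevo.events import (
    GapDecision,
    SubDecision,
    analyze_pair,
    classify_gap,
    label_columns,
    resolve_unmapped_operon,
    resolve_unmapped_singleton,
)
from operonevo.model import (
    DELETION,
    DUPLICATION,
    INVERSED_DUPLICATION,
    GeneOrder,
    is_realistic,
)

from conftest import operon, r, singleton, t


def _order(units, terminus, gid="g"):
    return GeneOrder(gid, units, terminus)


class TestClassifyGap:
    def _host(self):
        # [Ala Ile] ... [Ala Ile] so the pair recurs; singleton Met unique
        return _order(
            [
                operon(t("Ala", "tgc"), t("Ile", "gat")),
                singleton(t("Met", "cat")),
                operon(t("Ala", "tgc"), t("Ile", "gat")),
            ],
            2,
        )

    def test_size_one_is_deletion_flagged_correctable(self):
        host = self._host()
        kind, source, correctable = classify_gap([("Ala", "tgc")], host, 0)
        assert kind == DELETION and correctable

    def test_size_two_with_source_is_duplication(self):
        host = self._host()
        kind, source, correctable = classify_gap(
            [("Ala", "tgc"), ("Ile", "gat")], host, 0
        )
        assert kind == DUPLICATION
        assert source == (3, 2, False)  # the other copy, forward

    def test_size_two_without_source_is_deletion(self):
        host = self._host()
        kind, source, correctable = classify_gap(
            [("Trp", "cca"), ("His", "gtg")], host, 0
        )
        assert kind == DELETION and not correctable

    def test_reversed_source_is_inversed_duplication(self):
        host = _order(
            [
                operon(t("Ala", "tgc"), t("Ile", "gat")),
                singleton(t("Met", "cat")),
                operon(t("Ile", "gat"), t("Ala", "tgc")),
            ],
            2,
        )
        kind, source, _ = classify_gap([("Ala", "tgc"), ("Ile", "gat")], host, 0)
        # forward search first: no forward copy here, but the reversed one exists
        assert kind == INVERSED_DUPLICATION and source == (3, 2, True)


class TestLabelColumns:
    def test_partial_column_is_one_substitution(self):
        x = _order([operon(t("Ala", "tgc"), t("Asn", "gtt")), singleton(t("Met", "cat"))], 1, "x")
        y = _order([operon(t("Ala", "ggc"), t("Asn", "gtt")), singleton(t("Met", "cat"))], 1, "y")
        m = build_ortholog_map(x, y)
        decisions = label_columns(m.operon_pairs[0], x, y, "bx", "by")
        subs = [d for d in decisions if isinstance(d, SubDecision)]
        assert len(subs) == 1
        assert subs[0].branch == "by"  # default polarity: first child ancestral

    def test_perfect_alignment_yields_no_events(self):
        x = _order([operon(t("Ala", "tgc"), t("Asn", "gtt")), singleton(t("Met", "cat"))], 1, "x")
        m = build_ortholog_map(x, x.clone())
        assert label_columns(m.operon_pairs[0], x, x, "bx", "by") == []

    def test_gap_run_with_recurring_pair_is_duplication_on_host_branch(self):
        x = _order(
            [
                operon(t("Ala", "tgc"), t("Ile", "gat"), t("Asn", "gtt"), t("Glu", "ttc")),
                operon(t("Ala", "tgc"), t("Ile", "gat")),
            ],
            1,
            "x",
        )
        y = _order(
            [operon(t("Asn", "gtt"), t("Glu", "ttc")), operon(t("Ala", "tgc"), t("Ile", "gat"))],
            1,
            "y",
        )
        m = build_ortholog_map(x, y)
        pair = next(p for p in m.operon_pairs if p.x_index == 0)
        decisions = label_columns(pair, x, y, "bx", "by")
        gaps = [d for d in decisions if isinstance(d, GapDecision)]
        assert len(gaps) == 1
        assert gaps[0].kind == DUPLICATION and gaps[0].branch == "bx"
        assert len(gaps[0].cols) == 2

    def test_neighbor_polarity_flips_substitution_branch(self):
        x = _order([operon(t("Ala", "tgc"), t("Asn", "gtt")), singleton(t("Met", "cat"))], 1, "x")
        y = _order([operon(t("Ala", "ggc"), t("Asn", "gtt")), singleton(t("Met", "cat"))], 1, "y")
        m = build_ortholog_map(x, y)
        # the neighbor carries Y's state: the ancestor had it, X substituted
        nbv = {("Ala", "ggc"), ("Asn", "gtt"), ("Met", "cat")}
        decisions = label_columns(m.operon_pairs[0], x, y, "bx", "by", neighbor_values=nbv)
        subs = [d for d in decisions if isinstance(d, SubDecision)]
        assert subs[0].branch == "bx" and subs[0].anc_value == ("Ala", "ggc")


class TestUnmappedUnits:
    def test_exact_paralog_is_whole_operon_duplication(self):
        host = _order(
            [
                operon(t("Ala", "tgc"), t("Ile", "gat")),
                singleton(t("Met", "cat")),
                operon(t("Ala", "tgc"), t("Ile", "gat")),
            ],
            2,
        )
        res = resolve_unmapped_operon(2, host, "X", "bx", "by")
        assert res.role == DUPLICATION and res.partner_index == 0
        assert not res.nested.subs and not res.nested.gaps

    def test_diverged_paralog_carries_nested_substitution(self):
        host = _order(
            [
                operon(t("Ala", "tgc"), t("Ile", "gat")),
                singleton(t("Met", "cat")),
                operon(t("Ala", "ggc"), t("Ile", "gat")),
            ],
            2,
        )
        res = resolve_unmapped_operon(2, host, "X", "bx", "by")
        assert res.role == DUPLICATION
        assert len(res.nested.subs) == 1  # an overlapping, non-visible event

    def test_orphan_operon_is_deletion_in_sibling(self):
        host = _order(
            [
                operon(t("Ala", "tgc"), t("Ile", "gat")),
                singleton(t("Met", "cat")),
                operon(r("16S"), r("23S"), r("5S")),
            ],
            2,
        )
        res = resolve_unmapped_operon(2, host, "X", "bx", "by")
        assert res.role == DELETION and res.branch == "by"

    def test_identical_singleton_elsewhere_is_duplication(self):
        host = _order(
            [singleton(t("Met", "cat")), singleton(t("Ala", "tgc")), singleton(t("Met", "cat"))],
            2,
        )
        res = resolve_unmapped_singleton(2, host, "X", "bx", "by")
        assert res.role == DUPLICATION and res.source == (0, 1, False)

    def test_unique_singleton_is_deletion_in_sibling(self):
        host = _order([singleton(t("Met", "cat")), singleton(t("Ala", "tgc"))], 1)
        res = resolve_unmapped_singleton(1, host, "X", "bx", "by")
        assert res.role == DELETION and res.branch == "by"

    def test_singleton_matching_gene_inside_operon_is_duplication(self):
        host = _order(
            [operon(t("Ala", "tgc"), t("Met", "cat")), singleton(t("Met", "cat"))], 1
        )
        res = resolve_unmapped_singleton(1, host, "X", "bx", "by")
        assert res.role == DUPLICATION  # source inside an operon is allowed


class TestInferredEventRealism:
    @pytest.mark.parametrize("seed", range(8))
    def test_content_events_replay_realistically(self, seed):
        """Every inferred content event is realistic in its application frame."""
        from operonevo.builder import infer_history
        from operonevo.model import CONTENT_EVENTS, _apply_inplace
        from operonevo.phylo import cherry_tree
        from operonevo.simulate import SimParams, simulate_tree

        ds = simulate_tree(cherry_tree(), SimParams(x_recipe=2, seed=seed))
        h = infer_history(ds.tree, ds.leaf_orders())
        for branch, events in h.events.items():
            g = h.ancestors["root"].clone()
            for e in events:
                if e.nested:
                    continue
                if e.event_type in CONTENT_EVENTS:
                    ok, reason = is_realistic(e, g)
                    assert ok, f"{e}: {reason}"
                _apply_inplace(g, e)
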