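"""Canonical descendant-frame descriptors for events.

Simulated and inferred events alike are recorded with application-frame
parameters valid in the intermediate genome they were applied to.  The
evaluation metrics, however, compare events by "length and position", which
is only meaningful in a frame shared by the truth and the inference: the
branch-end (descendant) genome.  :func:`canonicalize_events` replays a branch
and expresses every event there:

* duplications, substitutions and rearrangements are anchored to the gene
  objects they created or moved, then located in the final genome (genes
  erased by later events simply drop out of the descriptor);
* deletions leave nothing behind, so they are described by the deleted gene
  content plus the flat boundary where the genes would be re-inserted,
  resolved through the surviving flanking genes.
"""

from __future__ import annotations

from operonevo.model import (
    Event,
    GeneOrder,
    _apply_inplace,
    DELETION,
    SUBSTITUTION,
)

__all__ = ["canonicalize_events", "replay_branch"]


def replay_branch(parent: GeneOrder, events: list[Event], child_id: str | None = None) -> GeneOrder:
    """Apply a branch's events in order; nested (overlapping) events are inert."""
    g = parent.clone()
    if child_id is not None:
        g.genome_id = child_id
    for e in events:
        if not e.nested:
            _apply_inplace(g, e)
    return g


def canonicalize_events(
    parent: GeneOrder, events: list[Event]
) -> tuple[GeneOrder, list[Event]]:
    """Replay ``events`` on a copy of ``parent`` and fill ``Event.affected``.

    Returns the resulting child genome and the same event list (descriptors
    are written in place).  Events already carrying a descriptor (nested
    events receive theirs from the history builder) are left untouched.
    """
    g = parent.clone()
    records: list[tuple[Event, dict]] = []
    for e in events:
        if e.nested:
            continue
        records.append((e, _apply_inplace(g, e)))

    pos_of = {id(gene): i for i, gene in enumerate(g.flat_genes())}
    alive_units = {id(u): i for i, u in enumerate(g.units)}

    for e, rec in records:
        if e.affected is not None:
            continue
        if e.event_type == DELETION:
            prev_g, next_g = rec["prev"], rec["next"]
            if prev_g is not None and id(prev_g) in pos_of:
                locus = pos_of[id(prev_g)] + 1
            elif next_g is not None and id(next_g) in pos_of:
                locus = pos_of[id(next_g)]
            else:
                locus = 0
            e.affected = {
                "family": e.family,
                "positions": (),
                "locus": locus,
                "content": tuple(gene.value() for gene in rec["removed"]),
            }
        elif e.event_type == SUBSTITUTION:
            positions = tuple(
                pos_of[id(gene)] for gene in (rec["new"],) if id(gene) in pos_of
            )
            e.affected = {"family": e.family, "positions": positions, "locus": None, "content": ()}
        elif "inserted" in rec:  # duplications
            positions = tuple(
                sorted(pos_of[id(gene)] for gene in rec["inserted"] if id(gene) in pos_of)
            )
            e.affected = {
                "family": e.family,
                "positions": positions,
                "locus": None,
                "content": tuple(gene.value() for gene in rec["inserted"] if id(gene) in pos_of),
            }
        else:  # rearrangements: all genes of the moved/flipped units
            positions = []
            for unit in rec["units"]:
                if id(unit) in alive_units:
                    positions.extend(pos_of[id(gene)] for gene in unit.genes if id(gene) in pos_of)
            e.affected = {
                "family": e.family,
                "positions": tuple(sorted(positions)),
                "locus": None,
                "content": (),
            }
    return g, events
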