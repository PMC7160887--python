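"""Domain types for annotated circular rRNA/tRNA gene orders and evolutionary events.

A genome is a circular sequence of *units* (operons and singletons) with two
inter-unit axis markers: the origin and the terminus of replication.  Internally
a :class:`GeneOrder` stores the linearized unit list starting immediately after
the origin, so boundary 0 (== boundary ``len(units)``) is the origin and the
terminus is a boundary index strictly between them.  Units left of the terminus
form the first replichore, units right of it the second.

Evolutionary events (duplication, deletion, inversion, transposition,
substitution and their axis-crossing "inversed"/"reversed" variants) are
represented by :class:`Event` objects carrying application-frame parameters, so
that a branch history can be replayed with :func:`apply_event` and reverted
with :func:`undo_event`.

The *realistic history* constraints are:

1. genomes are organized into operons;
2. rearrangements never split an operon into separate parts;
3. moves or copies across a replication axis reverse order and flip signs;
4. segmental duplications/deletions only affect genes of a single operon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "TRNA_CLASSES",
    "RRNA_CLASSES",
    "ANTICODONS",
    "GENE_ALPHABET",
    "Gene",
    "Unit",
    "GeneOrder",
    "Event",
    "ModelViolationError",
    "AnnotationError",
    "linearize",
    "apply_event",
    "undo_event",
    "is_realistic",
]


class ModelViolationError(ValueError):
    """An event breaks the realistic-history constraints."""


class AnnotationError(ValueError):
    """A gene order violates the annotation invariants (markers, strands...)."""


# ---------------------------------------------------------------------------
# Gene alphabet
# ---------------------------------------------------------------------------

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}

_COMPL = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _revcomp(codon: str) -> str:
    return "".join(_COMPL[b] for b in reversed(codon))


def _build_anticodons() -> dict[str, tuple[str, ...]]:
    from Bio.Data.CodonTable import standard_dna_table

    table: dict[str, list[str]] = {}
    for codon, aa in sorted(standard_dna_table.forward_table.items()):
        cls = _AA3[aa]
        table.setdefault(cls, []).append(_revcomp(codon).lower())
    return {cls: tuple(sorted(set(acs))) for cls, acs in sorted(table.items())}


#: anticodon repertoire of each tRNA identity class (standard genetic code)
ANTICODONS: dict[str, tuple[str, ...]] = _build_anticodons()

TRNA_CLASSES: frozenset[str] = frozenset(ANTICODONS)
RRNA_CLASSES: frozenset[str] = frozenset({"16S", "23S", "5S"})

#: every (identity_class, anticodon) the simulator samples from
GENE_ALPHABET: tuple[tuple[str, str | None], ...] = tuple(
    [(cls, ac) for cls in sorted(ANTICODONS) for ac in ANTICODONS[cls]]
    + [(r, None) for r in sorted(RRNA_CLASSES)]
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class Gene:
    """One rRNA or tRNA gene.

    ``identity_class`` is a tRNA amino-acid class (``"Ala"``...) or an rRNA
    subunit (``"16S"``/``"23S"``/``"5S"``); tRNA genes carry a 3-letter
    lowercase ``anticodon``, rRNA genes do not.  ``sign`` is the
    transcriptional strand.  ``restored_from`` is a provenance tag set on
    genes that were placed back into an ancestor by undoing a deletion event
    on the named branch; it is ignored by value comparison.
    """

    identity_class: str
    anticodon: str | None
    sign: int
    restored_from: str | None = field(default=None)

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise AnnotationError(f"gene sign must be +1/-1, got {self.sign}")
        is_trna = self.identity_class in TRNA_CLASSES
        if is_trna and self.anticodon is None:
            raise AnnotationError(f"tRNA gene {self.identity_class} needs an anticodon")
        if not is_trna:
            if self.identity_class not in RRNA_CLASSES:
                raise AnnotationError(f"unknown identity class {self.identity_class!r}")
            if self.anticodon is not None:
                raise AnnotationError("rRNA genes are not annotated with anticodons")

    @property
    def is_trna(self) -> bool:
        return self.identity_class in TRNA_CLASSES

    def value(self) -> tuple[str, str | None]:
        """Identity content, the unit of orthology comparison (sign excluded)."""
        return (self.identity_class, self.anticodon)

    def signed_value(self) -> tuple[str, str | None, int]:
        return (self.identity_class, self.anticodon, self.sign)

    def clone(self) -> "Gene":
        return Gene(self.identity_class, self.anticodon, self.sign, self.restored_from)

    def __eq__(self, other: object) -> bool:  # value equality, provenance ignored
        if not isinstance(other, Gene):
            return NotImplemented
        return self.signed_value() == other.signed_value()

    def __hash__(self):  # identity-based: genes are tracked as objects
        return id(self)

    def __repr__(self) -> str:
        s = "-" if self.sign < 0 else ""
        if self.anticodon:
            return f"{s}tRNA-{self.identity_class}({self.anticodon})"
        return f"{s}{self.identity_class}"


OPERON = "operon"
SINGLETON = "singleton"


@dataclass(eq=False)
class Unit:
    """A singleton or an operon; ``genes`` are kept in genome (circle) order.

    All genes of a unit lie on the same strand (they share one promoter); the
    unit orientation equals that shared sign.  The promoter-first reading of a
    reverse-strand unit is the reverse of its genome-order gene list.
    """

    kind: str
    genes: list[Gene]

    def __post_init__(self) -> None:
        if self.kind not in (OPERON, SINGLETON):
            raise AnnotationError(f"unknown unit kind {self.kind!r}")
        if not self.genes:
            raise AnnotationError("empty unit")
        if self.kind == SINGLETON and len(self.genes) != 1:
            raise AnnotationError("a singleton holds exactly one gene")
        signs = {g.sign for g in self.genes}
        if len(signs) != 1:
            raise AnnotationError("all genes of a unit must share one strand")

    @property
    def orientation(self) -> int:
        return self.genes[0].sign

    def reading(self) -> list[Gene]:
        """Genes in transcription (promoter-first) order."""
        return list(self.genes) if self.orientation > 0 else list(reversed(self.genes))

    def flip(self) -> None:
        """Invert in place: reverse genome order and change all signs."""
        self.genes.reverse()
        for g in self.genes:
            g.sign = -g.sign

    def clone(self) -> "Unit":
        return Unit(self.kind, [g.clone() for g in self.genes])

    def values(self) -> tuple[tuple[str, str | None], ...]:
        return tuple(g.value() for g in self.genes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Unit):
            return NotImplemented
        return self.kind == other.kind and self.genes == other.genes

    def __hash__(self):
        return id(self)

    def __repr__(self) -> str:
        inner = " ".join(repr(g).lstrip("-") for g in self.genes)
        s = "-" if self.orientation < 0 else ""
        return f"{s}[{inner}]" if self.kind == OPERON else repr(self.genes[0])


@dataclass(eq=False)
class GeneOrder:
    """A circular annotated gene order, linearized immediately after the origin.

    ``terminus`` is an inter-unit boundary index (boundary *i* sits between
    ``units[i-1]`` and ``units[i]``); boundary 0 is the origin.
    """

    genome_id: str
    units: list[Unit]
    terminus: int

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if len(self.units) < 2:
            raise AnnotationError(
                f"{self.genome_id}: need at least 2 units to place both axis markers"
            )
        # boundaries 0 and len(units) are allowed: the terminus then sits
        # immediately next to the origin (one replichore carries no rRNA/tRNA
        # units); the two markers remain distinct loci
        if not (0 <= self.terminus <= len(self.units)):
            raise AnnotationError(
                f"{self.genome_id}: terminus boundary {self.terminus} out of range"
            )
        for u in self.units:
            u.__post_init__()
            for g in u.genes:
                g.__post_init__()

    # -- views --------------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return sum(len(u.genes) for u in self.units)

    def flat_genes(self) -> list[Gene]:
        return [g for u in self.units for g in u.genes]

    def flat_values(self) -> list[tuple[str, str | None]]:
        return [g.value() for u in self.units for g in u.genes]

    def unit_of_flat(self, pos: int) -> tuple[int, int]:
        """Map a flat gene position to a (unit_index, offset) pair."""
        acc = 0
        for i, u in enumerate(self.units):
            if pos < acc + len(u.genes):
                return i, pos - acc
            acc += len(u.genes)
        raise IndexError(pos)

    def flat_of(self, unit_index: int, offset: int = 0) -> int:
        return sum(len(u.genes) for u in self.units[:unit_index]) + offset

    def replichore(self, unit_index: int) -> int:
        return 1 if unit_index < self.terminus else 2

    def clone(self) -> "GeneOrder":
        return GeneOrder(self.genome_id, [u.clone() for u in self.units], self.terminus)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneOrder):
            return NotImplemented
        return self.units == other.units and self.terminus == other.terminus

    def __hash__(self):
        return id(self)

    def __repr__(self) -> str:
        parts = ["<o>"]
        for i, u in enumerate(self.units):
            if i == self.terminus:
                parts.append("<t>")
            parts.append(repr(u))
        return f"GeneOrder({self.genome_id}: {' '.join(parts)})"

    # -- in-place structural edits (used by event application) --------------

    def _insert_unit(self, boundary: int, unit: Unit, before_terminus: bool = False) -> None:
        self.units.insert(boundary, unit)
        if boundary < self.terminus or (boundary == self.terminus and before_terminus):
            self.terminus += 1

    def _remove_unit(self, index: int) -> Unit:
        unit = self.units.pop(index)
        if index < self.terminus:
            self.terminus -= 1
        return unit

    def _remove_block(self, s: int, e: int) -> list[Unit]:
        block = self.units[s:e]
        del self.units[s:e]
        m = e - s
        if e <= self.terminus:
            self.terminus -= m
        elif s < self.terminus:  # straddles the terminus; clamp to the gap
            self.terminus = s
        return block

    def _insert_block(self, boundary: int, block: list[Unit], before_terminus: bool = False) -> None:
        self.units[boundary:boundary] = block
        if boundary < self.terminus or (boundary == self.terminus and before_terminus):
            self.terminus += len(block)


def linearize(order: GeneOrder) -> tuple[list[Unit], int]:
    """Deterministic linear view: units after the origin plus the terminus boundary.

    The stored representation already starts right after the origin, so this
    validates and reports it; circularity is confined to this convention.
    """
    order.validate()
    return list(order.units), order.terminus


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------

DUPLICATION = "duplication"
INVERSED_DUPLICATION = "inversed_duplication"
DELETION = "deletion"
INVERSION = "inversion"
TRANSPOSITION = "transposition"
REVERSED_TRANSPOSITION = "reversed_transposition"
SUBSTITUTION = "substitution"

EVENT_TYPES = (
    DUPLICATION,
    INVERSED_DUPLICATION,
    DELETION,
    INVERSION,
    TRANSPOSITION,
    REVERSED_TRANSPOSITION,
    SUBSTITUTION,
)

CONTENT_EVENTS = {DUPLICATION, INVERSED_DUPLICATION, DELETION, SUBSTITUTION}
REARRANGEMENT_EVENTS = {INVERSION, TRANSPOSITION, REVERSED_TRANSPOSITION}


@dataclass
class Event:
    """A typed, branch-assigned evolutionary operation.

    ``params`` hold application-frame parameters understood by
    :func:`apply_event` (see below); ``affected`` is filled in later with a
    canonical descendant-frame descriptor used by the evaluation metrics.

    params by type::

        duplication / inversed_duplication:
            target: ("in", unit_idx, offset) | ("new", boundary, kind)
            content: list[Gene] as inserted (genome order)
            source:  (flat_start, length, reversed) or None   # informational
        deletion:
            target: ("in", unit_idx, offset) | ("whole", unit_idx, kind)
            content: list[Gene] removed (genome order)
        substitution:
            position: (unit_idx, offset); from_value/to_value: (class, anticodon)
        inversion:
            span: (s, e)                # unit range, axis-adjacent
        transposition / reversed_transposition:
            span: (s, e); dest: boundary index after block removal
    """

    event_type: str
    branch: str | None
    size: int
    params: dict
    nested: bool = False
    affected: dict | None = None

    @property
    def family(self) -> str:
        """Event class as reported by the evaluation metrics."""
        if self.event_type == INVERSED_DUPLICATION:
            return DUPLICATION
        if self.event_type == REVERSED_TRANSPOSITION:
            return TRANSPOSITION
        return self.event_type

    def __repr__(self) -> str:
        tag = " nested" if self.nested else ""
        return f"Event({self.event_type}@{self.branch}, size={self.size}{tag})"


def _check_content(genes: list[Gene], expected: list[Gene], what: str) -> None:
    if [g.signed_value() for g in genes] != [g.signed_value() for g in expected]:
        raise ModelViolationError(f"{what}: genome content does not match event record")


def _apply_inplace(order: GeneOrder, e: Event) -> dict:
    """Mutate ``order`` by one event; report the touched objects for tracking."""
    p = e.params
    t = e.event_type
    if t in (DUPLICATION, INVERSED_DUPLICATION):
        content = [g.clone() for g in p["content"]]
        target = p["target"]
        if target[0] == "in":
            _, u, off = target
            host = order.units[u]
            if host.kind != OPERON:
                raise ModelViolationError("can only insert inside an operon")
            host.genes[off:off] = content
        else:
            _, boundary, kind = target
            order._insert_unit(boundary, Unit(kind, content), p.get("before_terminus", False))
        return {"inserted": content}
    if t == DELETION:
        flat = order.flat_genes()
        target = p["target"]
        if target[0] == "whole":
            u = target[1]
            _check_content(order.units[u].genes, p["content"], "whole-unit deletion")
            first = order.flat_of(u)
            last = first + len(order.units[u].genes) - 1
            removed = order.units[u].genes
            p["before_terminus"] = u < order.terminus  # lets undo restore the marker
            order._remove_unit(u)
        else:
            _, u, off = target
            k = len(p["content"])
            host = order.units[u]
            if off + k > len(host.genes) or k >= len(host.genes):
                raise ModelViolationError("in-operon deletion must leave the operon non-empty")
            _check_content(host.genes[off : off + k], p["content"], "deletion")
            first = order.flat_of(u, off)
            last = first + k - 1
            removed = host.genes[off : off + k]
            del host.genes[off : off + k]
        prev_g = flat[first - 1] if first > 0 else None
        next_g = flat[last + 1] if last + 1 < len(flat) else None
        return {"removed": removed, "prev": prev_g, "next": next_g}
    if t == SUBSTITUTION:
        u, off = p["position"]
        g = order.units[u].genes[off]
        if g.value() != tuple(p["from_value"]):
            raise ModelViolationError(
                f"substitution: gene at {(u, off)} is {g.value()}, expected {p['from_value']}"
            )
        cls, ac = p["to_value"]
        new = Gene(cls, ac, g.sign)
        order.units[u].genes[off] = new
        return {"new": new, "old": g}
    if t == INVERSION:
        s, en = p["span"]
        block = order.units[s:en]
        for unit in block:
            unit.flip()
        order.units[s:en] = list(reversed(block))
        return {"units": list(block)}
    if t in (TRANSPOSITION, REVERSED_TRANSPOSITION):
        s, en = p["span"]
        d = p["dest"]
        # remember which side of the terminus the block came from, so that an
        # undo landing exactly on the terminus boundary restores the marker
        p.setdefault("src_before_terminus", en <= order.terminus)
        landing_before = p.get("dst_before_terminus", False)
        block = order._remove_block(s, en)
        if t == REVERSED_TRANSPOSITION:
            for unit in block:
                unit.flip()
            block.reverse()
        order._insert_block(d, block, landing_before)
        return {"units": list(block)}
    raise ModelViolationError(f"unknown event type {t!r}")


def _invert_event(e: Event) -> Event:
    """The event that undoes ``e`` in the child frame."""
    p = e.params
    t = e.event_type
    if t in (DUPLICATION, INVERSED_DUPLICATION):
        target = p["target"]
        if target[0] == "in":
            new_target = ("in", target[1], target[2])
        else:
            _, boundary, kind = target
            new_target = ("whole", boundary)
        return Event(DELETION, e.branch, e.size, {"target": new_target, "content": p["content"]})
    if t == DELETION:
        target = p["target"]
        if target[0] == "whole":
            kind = p.get("kind", OPERON if len(p["content"]) > 1 else SINGLETON)
            new_target = ("new", target[1], kind)
        else:
            new_target = ("in", target[1], target[2])
        return Event(
            DUPLICATION,
            e.branch,
            e.size,
            {
                "target": new_target,
                "content": p["content"],
                "source": None,
                "before_terminus": p.get("before_terminus", False),
            },
        )
    if t == SUBSTITUTION:
        return Event(
            SUBSTITUTION,
            e.branch,
            e.size,
            {"position": p["position"], "from_value": p["to_value"], "to_value": p["from_value"]},
        )
    if t == INVERSION:
        return Event(INVERSION, e.branch, e.size, {"span": p["span"]})
    # transposition: block currently at [dest, dest+m); move it back to boundary s
    s, en = p["span"]
    m = en - s
    d = p["dest"]
    return Event(
        t,
        e.branch,
        e.size,
        {"span": (d, d + m), "dest": s, "dst_before_terminus": p.get("src_before_terminus", False)},
    )


def apply_event(order: GeneOrder, e: Event, strict: bool = True) -> GeneOrder:
    """Apply one event, returning a new GeneOrder (the input is untouched).

    With ``strict`` the event must satisfy the realistic-history predicates
    (:func:`is_realistic`); replay of heuristically inferred histories relaxes
    the axis checks.
    """
    if strict:
        ok, reason = is_realistic(e, order)
        if not ok:
            raise ModelViolationError(f"{e}: {reason}")
    out = order.clone()
    _apply_inplace(out, e)
    return out


def undo_event(order: GeneOrder, e: Event) -> GeneOrder:
    """Revert one event on the genome that carries it (inverse of apply_event)."""
    out = order.clone()
    _apply_inplace(out, _invert_event(e))
    return out


# ---------------------------------------------------------------------------
# Realism predicates
# ---------------------------------------------------------------------------


def _span_ok(order: GeneOrder, s: int, e: int) -> bool:
    return 0 <= s < e <= len(order.units)


def is_realistic(e: Event, order: GeneOrder) -> tuple[bool, str]:
    """Check the realistic-history constraints of ``e`` against ``order``.

    ``order`` is the genome the event applies to (its pre-event frame).
    Returns ``(True, "")`` or ``(False, reason)``.
    """
    p = e.params
    t = e.event_type
    n_units = len(order.units)

    if t in (DUPLICATION, INVERSED_DUPLICATION):
        content = p["content"]
        if not content:
            return False, "empty duplication"
        target = p["target"]
        if target[0] == "in":
            _, u, off = target
            if not (0 <= u < n_units) or order.units[u].kind != OPERON:
                return False, "insertion target is not an operon"
            if not (0 <= off <= len(order.units[u].genes)):
                return False, "insertion offset out of range"
            host_sign = order.units[u].orientation
            if any(g.sign != host_sign for g in content):
                return False, "inserted genes must match the host operon strand"
        else:
            _, boundary, kind = target
            if not (0 <= boundary <= n_units):
                return False, "insertion boundary out of range"
            if kind == SINGLETON and len(content) != 1:
                return False, "singleton insertion must carry one gene"
        src = p.get("source")
        if src is not None:
            start, length, reversed_ = src
            flat = order.flat_values()
            if start + length > len(flat):
                return False, "duplication source out of range"
            seg = flat[start : start + length]
            copy_vals = [g.value() for g in content]
            if t == INVERSED_DUPLICATION:
                if copy_vals != list(reversed(seg)):
                    return False, "inversed duplication copy must be order-reversed vs source"
            elif copy_vals != seg:
                return False, "duplication copy must match its source"
            # a multi-gene source must be confined to one operon (proximity rule)
            if length > 1:
                u0, _ = order.unit_of_flat(start)
                u1, _ = order.unit_of_flat(start + length - 1)
                if u0 != u1:
                    return False, "operon split: segmental duplication source spans units"
        return True, ""

    if t == DELETION:
        target = p["target"]
        if target[0] == "whole":
            u = target[1]
            if not (0 <= u < n_units):
                return False, "deleted unit out of range"
            return True, ""
        _, u, off = target
        k = len(p["content"])
        if not (0 <= u < n_units):
            return False, "deletion unit out of range"
        host = order.units[u]
        if host.kind != OPERON:
            return False, "in-unit deletion requires an operon (delete the whole singleton)"
        if off + k > len(host.genes):
            return False, "deletion segment out of range"
        if k >= len(host.genes):
            return False, "deleting every gene requires a whole-unit deletion"
        return True, ""

    if t == SUBSTITUTION:
        u, off = p["position"]
        if not (0 <= u < n_units and 0 <= off < len(order.units[u].genes)):
            return False, "substitution position out of range"
        return True, ""

    if t == INVERSION:
        s, en = p["span"]
        if not _span_ok(order, s, en):
            return False, "inversion span out of range"
        tm = order.terminus
        if s < tm < en:
            return False, "axis: inversion segment may not contain the terminus"
        if not (s == 0 or en == n_units or s == tm or en == tm):
            return False, "axis: inversion segment must be immediately next to the origin or terminus"
        return True, ""

    if t in (TRANSPOSITION, REVERSED_TRANSPOSITION):
        s, en = p["span"]
        d = p["dest"]
        if not _span_ok(order, s, en):
            return False, "transposition span out of range"
        tm = order.terminus
        if s < tm < en:
            return False, "operon split: transposed block may not straddle the terminus"
        m = en - s
        if not (0 <= d <= n_units - m):
            return False, "transposition destination out of range"
        # replichore of the source, and of the destination after removal
        src_rep = 1 if en <= tm else 2
        tm_after = tm - m if en <= tm else tm
        dst_rep = src_rep if d == tm_after else (1 if d < tm_after else 2)
        crosses = src_rep != dst_rep
        if t == TRANSPOSITION and crosses:
            return False, "axis: a move across a replication axis must be a reversed transposition"
        return True, ""

    return False, f"unknown event type {t!r}"
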