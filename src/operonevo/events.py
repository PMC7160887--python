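"""Step 2: labelling duplications, deletions and substitutions.

Within each orthologous-operon alignment, mismatch and partial-match columns
become substitutions and maximal gap runs are classified by a simple rule:
a run of size >= 2 whose gene sequence occurs identically elsewhere in the
same genome (forward, or order-reversed for an inversed duplication) is a
duplication in that genome; every other run — including all runs of size
one — is a deletion in the opposite genome.  Size-one deletions whose gene
has an identical copy elsewhere are flagged *correctable*: the ambiguity the
next comparison may resolve by turning the deletion into a duplication.

Operons and singletons left unmapped by Step 1 are resolved as whole-unit
duplications when a paralog exists in the same genome — including nested
("overlapping", non-visible) events explaining the divergence from the
paralog — and otherwise as whole-unit deletions in the sibling genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from operonevo.align import (
    FULL,
    GAP_X,
    GAP_Y,
    OperonAlignment,
    Scoring,
    DEFAULT_SCORING,
    UnitPair,
    _align_both_orientations,
)
from operonevo.model import (
    DELETION,
    DUPLICATION,
    INVERSED_DUPLICATION,
    GeneOrder,
    Unit,
    OPERON,
)

__all__ = [
    "SubDecision",
    "GapDecision",
    "PairAnalysis",
    "UnmappedResolution",
    "classify_gap",
    "label_columns",
    "analyze_pair",
    "resolve_unmapped_operon",
    "resolve_unmapped_singleton",
]


@dataclass
class SubDecision:
    """A mismatch/partial column: one substitution on one branch."""

    col: int
    branch: str
    anc_value: tuple[str, str | None]
    to_value: tuple[str, str | None]


@dataclass
class GapDecision:
    """A maximal gap run: duplication in the host genome or deletion opposite."""

    side: str  # "X" | "Y": the genome that carries the genes
    cols: list[int]
    kind: str  # duplication | inversed_duplication | deletion
    branch: str
    source: tuple[int, int, bool] | None  # flat start, length, reversed
    correctable: bool
    key: tuple = ()  # stable identifier for the deletion->duplication correction


@dataclass
class PairAnalysis:
    pair: UnitPair
    subs: list[SubDecision] = field(default_factory=list)
    gaps: list[GapDecision] = field(default_factory=list)


@dataclass
class UnmappedResolution:
    side: str
    unit_index: int
    role: str  # "duplication" | "inversed_duplication" | "deletion"
    branch: str
    partner_index: int | None = None  # paralog unit for whole-operon duplications
    partner_alignment: OperonAlignment | None = None
    nested: PairAnalysis | None = None
    source: tuple[int, int, bool] | None = None
    correctable: bool = False
    key: tuple = ()


# ---------------------------------------------------------------------------
# Gap classification
# ---------------------------------------------------------------------------


def _find_elsewhere(
    flat: list[tuple], needle: list[tuple], exclude: tuple[int, int]
) -> int | None:
    """Leftmost occurrence of ``needle`` in ``flat`` outside ``exclude`` [start, end)."""
    k = len(needle)
    for s in range(len(flat) - k + 1):
        if s + k > exclude[0] and s < exclude[1]:
            continue  # overlaps the gap itself
        if flat[s : s + k] == needle:
            return s
    return None


def classify_gap(
    values: list[tuple], host: GeneOrder, flat_start: int
) -> tuple[str, tuple[int, int, bool] | None, bool]:
    """Duplication-vs-deletion rule for one gap run carried by ``host``.

    ``values`` are the gap genes (identity class, anticodon) in genome order,
    occupying flat positions ``[flat_start, flat_start+len)`` of ``host``.
    Returns (kind, source, correctable): a duplication (forward source) or an
    inversed duplication (order-reversed source) when the run has size >= 2
    and an identical gene sequence exists elsewhere in the same genome;
    otherwise a deletion, correctable when a single gap gene recurs elsewhere.
    """
    flat = host.flat_values()
    exclude = (flat_start, flat_start + len(values))
    if len(values) >= 2:
        fwd = _find_elsewhere(flat, values, exclude)
        if fwd is not None:
            return DUPLICATION, (fwd, len(values), False), False
        rev = _find_elsewhere(flat, list(reversed(values)), exclude)
        if rev is not None:
            return INVERSED_DUPLICATION, (rev, len(values), True), False
        return DELETION, None, False
    correctable = _find_elsewhere(flat, values, exclude) is not None
    return DELETION, None, correctable


# ---------------------------------------------------------------------------
# Column labelling for one orthologous pair
# ---------------------------------------------------------------------------


def _reading_to_flat(order: GeneOrder, unit_index: int, reading_pos: int) -> int:
    unit = order.units[unit_index]
    off = reading_pos if unit.orientation > 0 else len(unit.genes) - 1 - reading_pos
    return order.flat_of(unit_index, off)


def _choose_sub_branch(
    x_value: tuple,
    y_value: tuple,
    branch_x: str,
    branch_y: str,
    neighbor_values: set[tuple] | None,
) -> tuple[str, tuple, tuple]:
    """(branch, ancestral value, derived value) for one substitution column.

    The neighbor genome is the only polarity signal available: a state seen in
    the neighbor but not the other child is taken as ancestral.  Without a
    neighbor (or without a verdict) the first child's state is kept ancestral,
    so the event falls on the branch of the second.
    """
    if neighbor_values is not None:
        x_in = x_value in neighbor_values
        y_in = y_value in neighbor_values
        if y_in and not x_in:
            return branch_x, y_value, x_value
    return branch_y, x_value, y_value


def analyze_pair(
    pair: UnitPair,
    x: GeneOrder,
    y: GeneOrder,
    branch_x: str,
    branch_y: str,
    neighbor_values: set[tuple] | None = None,
    overrides: frozenset = frozenset(),
) -> PairAnalysis:
    """Substitution and gap decisions for one orthologous operon pair.

    ``overrides`` holds correction keys: size-one gap deletions listed there
    are relabelled as duplications in the genome that carries the gene (the
    Step 4 deletion->duplication correction).
    """
    out = PairAnalysis(pair)
    if pair.alignment is None:
        return out  # singletons pair only when identical
    cols = pair.alignment.columns
    xr = pair.x_unit.reading()
    i = 0
    while i < len(cols):
        c = cols[i]
        if c.label in (GAP_X, GAP_Y):
            j = i
            while j < len(cols) and cols[j].label == c.label:
                j += 1
            run = list(range(i, j))
            if c.label == GAP_Y:  # X carries the genes
                side, host, branch_dup, branch_del = "X", x, branch_x, branch_y
                unit_idx = pair.x_index
                positions = [cols[k].x_pos for k in run]
            else:
                side, host, branch_dup, branch_del = "Y", y, branch_y, branch_x
                unit_idx = pair.y_index
                positions = [cols[k].y_pos for k in run]
            unit = host.units[unit_idx]
            flats = sorted(_reading_to_flat(host, unit_idx, p) for p in positions)
            values = [host.flat_values()[f] for f in flats]
            kind, source, correctable = classify_gap(values, host, flats[0])
            key = ("gap", pair.x_index, pair.y_index, side, i)
            if kind == DELETION and correctable and key in overrides:
                src = _find_elsewhere(
                    host.flat_values(), values, (flats[0], flats[0] + len(values))
                )
                kind, source, correctable = DUPLICATION, (src, 1, False), False
            branch = branch_dup if kind != DELETION else branch_del
            out.gaps.append(
                GapDecision(side, run, kind, branch, source, correctable, key)
            )
            i = j
        else:
            if c.label != FULL:
                x_val = xr[c.x_pos].value()
                y_val = pair.y_unit.reading()[c.y_pos].value()
                branch, anc, to = _choose_sub_branch(
                    x_val, y_val, branch_x, branch_y, neighbor_values
                )
                out.subs.append(SubDecision(i, branch, anc, to))
            i += 1
    return out


def label_columns(
    al: OperonAlignment | UnitPair,
    x: GeneOrder,
    y: GeneOrder,
    branch_x: str = "X",
    branch_y: str = "Y",
    neighbor_values: set[tuple] | None = None,
) -> list[SubDecision | GapDecision]:
    """Flat decision list for one selected orthologous alignment (Step 2)."""
    pair = al if isinstance(al, UnitPair) else UnitPair(0, 0, x.units[0], y.units[0], al, False)
    res = analyze_pair(pair, x, y, branch_x, branch_y, neighbor_values)
    return sorted(res.subs + res.gaps, key=lambda d: d.col if isinstance(d, SubDecision) else d.cols[0])


# ---------------------------------------------------------------------------
# Unmapped units
# ---------------------------------------------------------------------------


def resolve_unmapped_operon(
    unit_index: int,
    host: GeneOrder,
    side: str,
    branch_host: str,
    branch_sibling: str,
    scoring: Scoring = DEFAULT_SCORING,
) -> UnmappedResolution:
    """Whole-operon duplication with nested events, or deletion in the sibling.

    The unmapped operon is globally aligned against every other operon of the
    same genome (both orientations); the strongest alignment with score >= 0
    marks it as a paralogous copy, whose gaps and mismatches become nested
    events on the same branch.  Otherwise it was deleted in the sibling.
    """
    u = host.units[unit_index]
    best: tuple | None = None
    for j, other in enumerate(host.units):
        if j == unit_index or other.kind != OPERON:
            continue
        al = _align_both_orientations(u, other, scoring)
        if al.score >= 0:
            cand = (-al.score, abs(unit_index - j), j, al, al.flipped_y)
            if best is None or cand[:3] < best[:3]:
                best = cand
    if best is None:
        return UnmappedResolution(
            side, unit_index, DELETION, branch_sibling, key=("unmapped", side, unit_index)
        )
    _, _, j, al, flipped = best
    # nested events: treat the copy as "X" and its paralog as "Y" of a local pair
    nested_pair = UnitPair(unit_index, j, u, host.units[j], al, flipped)
    nested = analyze_pair(nested_pair, host, host, branch_host, branch_host)
    start = host.flat_of(j)
    return UnmappedResolution(
        side,
        unit_index,
        DUPLICATION,
        branch_host,
        partner_index=j,
        partner_alignment=al,
        nested=nested,
        source=(start, len(host.units[j].genes), flipped),
        key=("unmapped", side, unit_index),
    )


def resolve_unmapped_singleton(
    unit_index: int,
    host: GeneOrder,
    side: str,
    branch_host: str,
    branch_sibling: str,
) -> UnmappedResolution:
    """Duplication iff an identical gene exists anywhere else in the host."""
    u = host.units[unit_index]
    value = u.genes[0].value()
    flat_pos = host.flat_of(unit_index)
    src = _find_elsewhere(host.flat_values(), [value], (flat_pos, flat_pos + 1))
    if src is not None:
        return UnmappedResolution(
            side,
            unit_index,
            DUPLICATION,
            branch_host,
            source=(src, 1, False),
            key=("unmapped", side, unit_index),
        )
    return UnmappedResolution(
        side, unit_index, DELETION, branch_sibling, key=("unmapped", side, unit_index)
    )
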