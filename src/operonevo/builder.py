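"""Step 4 and the tree driver: branch assignment, ancestor construction and
the post-order traversal.

For each cherry (X, Y) the builder:

1. pairs orthologous operons and singletons (Step 1);
2. labels duplications, deletions and substitutions (Step 2);
3. segments the dot-plot into conserved / inverted / transposed blocks
   (Step 3) and assigns each rearrangement to a branch by re-detecting the
   segment in a comparison of X against a neighboring genome N — the first
   resolved genome in the subtree that is the sibling of the cherry's parent
   (without a neighbor every rearrangement falls on the Y branch by
   convention);
4. builds the ancestral gene order by undoing the events, then re-derives,
   for each branch, an ordered replayable event list whose application to
   the ancestor reproduces the child exactly (a hard postcondition, checked).

Genes placed back into an ancestor by undoing a deletion carry a provenance
flag; when the ancestor takes part in its parent's comparison, flagged genes
of correctable size-one deletions that fall into a gap (or are unmapped
singletons) trigger the deletion->duplication correction: the cherry is
re-inferred with those gaps labelled duplications and its ancestor shrinks
accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from operonevo.align import (
    DEFAULT_SCORING,
    FULL,
    GAP_X,
    GAP_Y,
    OrthologMap,
    Scoring,
    UnitPair,
    build_ortholog_map,
)
from operonevo.coords import canonicalize_events
from operonevo.events import (
    GapDecision,
    PairAnalysis,
    SubDecision,
    UnmappedResolution,
    analyze_pair,
    resolve_unmapped_operon,
    resolve_unmapped_singleton,
)
from operonevo.model import (
    DELETION,
    DUPLICATION,
    INVERSED_DUPLICATION,
    INVERSION,
    OPERON,
    REVERSED_TRANSPOSITION,
    SINGLETON,
    TRANSPOSITION,
    SUBSTITUTION,
    Event,
    Gene,
    GeneOrder,
    Unit,
    _apply_inplace,
)
from operonevo.phylo import PhyloNode, Phylogeny
from operonevo.rearrange import CONSERVED, Segment, segment_rearrangements

__all__ = [
    "CherryRecord",
    "History",
    "InternalConsistencyError",
    "select_neighbor",
    "assign_branch",
    "infer_cherry",
    "build_ancestor",
    "infer_history",
]


class InternalConsistencyError(RuntimeError):
    """Replaying the inferred events failed to reproduce a child genome."""


# ---------------------------------------------------------------------------
# Neighbor selection and branch assignment
# ---------------------------------------------------------------------------


def select_neighbor(
    tree: Phylogeny, cherry_parent: PhyloNode, resolved: dict[str, GeneOrder]
) -> PhyloNode | None:
    """First resolved genome in the sibling subtree, depth-first left-first."""
    sib = tree.sibling(cherry_parent)
    if sib is None:
        return None
    for node in sib.preorder():
        if node.name in resolved:
            return node
    return None


def _xn_status(x: GeneOrder, n: GeneOrder, scoring: Scoring) -> dict[int, tuple[bool, bool]]:
    """For each X unit paired with the neighbor: (non-conserved?, flipped?)."""
    omap = build_ortholog_map(x, n, scoring)
    status: dict[int, tuple[bool, bool]] = {}
    for seg in segment_rearrangements(omap, x, n):
        for d in seg.dots:
            status[d.x_index] = (seg.kind != CONSERVED, d.flipped)
    return status


def assign_branch(
    seg: Segment,
    branch_x: str,
    branch_y: str,
    xn_status: dict[int, tuple[bool, bool]] | None,
) -> str:
    """Re-detection rule: a segment rearranged again in the X-vs-neighbor
    comparison happened on the branch to X; otherwise on the branch to Y.

    Without a neighbor (or without any of the segment's units paired to the
    neighbor) the event falls on the Y branch by fixed convention.
    """
    if xn_status is None:
        return branch_y
    states = [xn_status[u] for u in seg.x_units() if u in xn_status]
    if not states:
        return branch_y
    votes = sum(1 for nc, fl in states if nc and fl == seg.flipped)
    return branch_x if 2 * votes >= len(states) else branch_y


# ---------------------------------------------------------------------------
# Ancestral unit construction
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class _AncUnit:
    """One ancestral unit plus its per-branch reconstruction script."""

    unit: Unit
    pair: UnitPair | None = None  # orthologous pair it descends to (both children)
    analysis: PairAnalysis | None = None
    x_only: int | None = None  # X unit index for units deleted on the Y branch
    y_only: int | None = None  # Y unit index for units deleted on the X branch
    anc_cols: list[int] = field(default_factory=list)  # column ids forming the unit


def _ancestral_orientation(pair: UnitPair, seg_branch: str | None, branch_x: str) -> int:
    if not pair.flipped:
        return pair.x_unit.orientation
    # the covering flipped segment tells which child reoriented the unit
    if seg_branch == branch_x:
        return pair.y_unit.orientation
    return pair.x_unit.orientation


def _build_pair_unit(
    pair: UnitPair,
    analysis: PairAnalysis,
    orient: int,
    branch_x: str,
    branch_y: str,
    flags: dict[int, tuple],
) -> _AncUnit:
    """Ancestral unit of an orthologous pair, from its alignment columns."""
    if pair.alignment is None:  # identical singletons
        g = Gene(*pair.x_unit.genes[0].value(), sign=orient)
        return _AncUnit(Unit(SINGLETON, [g]), pair, analysis, anc_cols=[0])

    sub_by_col = {s.col: s for s in analysis.subs}
    gapdec_by_col: dict[int, GapDecision] = {}
    for gd in analysis.gaps:
        for c in gd.cols:
            gapdec_by_col[c] = gd

    xr = pair.x_unit.reading()
    yr = pair.y_unit.reading()
    reading: list[Gene] = []
    anc_cols: list[int] = []
    for i, col in enumerate(pair.alignment.columns):
        if col.label == GAP_Y:  # X carries the gene
            gd = gapdec_by_col[i]
            if gd.kind != DELETION:
                continue  # duplicated in X: absent from the ancestor
            g = Gene(*xr[col.x_pos].value(), sign=orient, restored_from=branch_y)
            if gd.correctable:
                flags[id(g)] = gd.key
            reading.append(g)
            anc_cols.append(i)
        elif col.label == GAP_X:
            gd = gapdec_by_col[i]
            if gd.kind != DELETION:
                continue
            g = Gene(*yr[col.y_pos].value(), sign=orient, restored_from=branch_x)
            if gd.correctable:
                flags[id(g)] = gd.key
            reading.append(g)
            anc_cols.append(i)
        elif col.label == FULL:
            reading.append(Gene(*xr[col.x_pos].value(), sign=orient))
            anc_cols.append(i)
        else:  # substitution column: ancestral state chosen in the analysis
            sub = sub_by_col[i]
            reading.append(Gene(*sub.anc_value, sign=orient))
            anc_cols.append(i)
    genes = reading if orient > 0 else list(reversed(reading))
    return _AncUnit(Unit(OPERON, list(genes)), pair, analysis, anc_cols=anc_cols)


def _restored_clone(unit: Unit, deleted_on: str) -> Unit:
    c = unit.clone()
    for g in c.genes:
        g.restored_from = deleted_on
    return c


# ---------------------------------------------------------------------------
# Branch event emission
# ---------------------------------------------------------------------------


def _weighted_lis(seq: list[int], weights: list[int]) -> set[int]:
    """Positions of a maximum-weight increasing subsequence of ``seq``."""
    n = len(seq)
    best = list(weights)
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if seq[j] < seq[i] and best[j] + weights[i] > best[i]:
                best[i] = best[j] + weights[i]
                prev[i] = j
    if not n:
        return set()
    i = max(range(n), key=lambda k: (best[k], -k))
    out = set()
    while i != -1:
        out.add(i)
        i = prev[i]
    return out


def _axis_adjacent(w: GeneOrder, s: int, e: int) -> bool:
    return s == 0 or e == len(w.units) or s == w.terminus or e == w.terminus


def _emit_rearrangements(
    w: GeneOrder, target: list[Unit], orients: dict[int, int], branch: str
) -> list[Event]:
    """Block-sort ``w`` into the target unit order/orientations, emitting
    inversion and transposition events (the inferred rearrangements)."""
    events: list[Event] = []
    tindex = {id(u): i for i, u in enumerate(target)}

    def mismatched(u: Unit) -> bool:
        return u.orientation != orients[id(u)]

    cur = w.units  # mutated through _apply_inplace
    # anchor a heaviest increasing backbone of orientation-correct units;
    # a unit on the wrong strand must take part in a flip and may not anchor
    anchored = set()
    candidates = [u for u in cur if not mismatched(u)]
    seq = [tindex[id(u)] for u in candidates]
    for pos in _weighted_lis(seq, [len(u.genes) for u in candidates]):
        anchored.add(id(candidates[pos]))

    pending = sorted((u for u in cur if id(u) not in anchored), key=lambda u: tindex[id(u)])
    for u in pending:
        ti = tindex[id(u)]
        j = next(i for i, v in enumerate(cur) if v is u)
        want = 0
        if ti > 0:
            p = target[ti - 1]
            want = next(i for i, v in enumerate(cur) if v is p) + 1
        if j == want and not mismatched(u):
            continue
        # reversed block: leftward run of descending-target, orientation-flipped units
        s, e = j, j + 1
        if mismatched(u):
            while (
                s > 0
                and id(cur[s - 1]) not in anchored
                and tindex[id(cur[s - 1])] == tindex[id(cur[s])] + 1
                and mismatched(cur[s - 1])
            ):
                s -= 1
            reversed_block = True
        else:
            reversed_block = False
        if not reversed_block:
            while (
                e < len(cur)
                and id(cur[e]) not in anchored
                and tindex[id(cur[e])] == tindex[id(cur[e - 1])] + 1
                and not mismatched(cur[e])
            ):
                e += 1
        block_ids = [id(v) for v in cur[s:e]]
        # destination boundary after removing the block
        if ti > 0:
            p = target[ti - 1]
            ppos = next(i for i, v in enumerate(cur) if v is p)
            dest = ppos + 1 - (e - s) if ppos >= e else ppos + 1
        else:
            dest = 0
        if reversed_block:
            if dest == s and _axis_adjacent(w, s, e):
                ev = Event(INVERSION, branch, e - s, {"span": (s, e)})
            else:
                ev = Event(REVERSED_TRANSPOSITION, branch, e - s, {"span": (s, e), "dest": dest})
        else:
            if dest == s:
                continue  # already in place
            ev = Event(TRANSPOSITION, branch, e - s, {"span": (s, e), "dest": dest})
        _apply_inplace(w, ev)
        events.append(ev)
        anchored.update(block_ids)

    # safety net: naive one-unit moves until the order matches
    guard = 0
    while [id(u) for u in cur] != [id(u) for u in target]:
        guard += 1
        if guard > len(target) + 2:
            raise InternalConsistencyError("block sort failed to converge")
        for i in range(len(target)):
            if cur[i] is not target[i]:
                j = next(k for k, v in enumerate(cur) if v is target[i])
                ev = Event(TRANSPOSITION, branch, 1, {"span": (j, j + 1), "dest": i})
                _apply_inplace(w, ev)
                events.append(ev)
                break

    # orientation fixes: single-unit flips (inversions when axis-adjacent)
    for i, u in enumerate(list(cur)):
        if mismatched(u):
            if _axis_adjacent(w, i, i + 1):
                ev = Event(INVERSION, branch, 1, {"span": (i, i + 1)})
            else:
                ev = Event(REVERSED_TRANSPOSITION, branch, 1, {"span": (i, i + 1), "dest": i})
            _apply_inplace(w, ev)
            events.append(ev)
    return events


def _reading_deletion_params(
    unit: Unit, a: int, b: int
) -> tuple[int, list[Gene]]:
    """Genome-order offset and content for removing reading positions [a, b)."""
    L = len(unit.genes)
    if unit.orientation > 0:
        off = a
        content = unit.genes[a:b]
    else:
        off = L - b
        content = unit.genes[L - b : L - a]
    return off, [g.clone() for g in content]


def _reading_insertion(unit_len: int, orientation: int, reading_boundary: int) -> int:
    return reading_boundary if orientation > 0 else unit_len - reading_boundary


def _emit_unit_script(
    w: GeneOrder,
    w_unit: Unit,
    anc_cols: list[int],
    pair: UnitPair,
    analysis: PairAnalysis,
    child_side: str,
    branch: str,
) -> list[Event]:
    """Content events turning one ancestral unit into its child unit."""
    if pair.alignment is None:
        return []
    events: list[Event] = []
    cols = pair.alignment.columns
    child_unit = pair.x_unit if child_side == "X" else pair.y_unit
    child_reading = child_unit.reading()
    gap_absent = GAP_X if child_side == "X" else GAP_Y  # child lacks the gene

    def child_pos(i: int) -> int | None:
        c = cols[i]
        return c.x_pos if child_side == "X" else c.y_pos

    def uidx() -> int:
        return next(k for k, v in enumerate(w.units) if v is w_unit)

    cur = list(anc_cols)

    # 1) deletions on this branch: ancestral columns absent from the child
    k = len(cur) - 1
    while k >= 0:
        if child_pos(cur[k]) is None:
            a = k
            while a > 0 and child_pos(cur[a - 1]) is None:
                a -= 1
            off, content = _reading_deletion_params(w_unit, a, k + 1)
            ev = Event(
                DELETION, branch, k + 1 - a, {"target": ("in", uidx(), off), "content": content}
            )
            _apply_inplace(w, ev)
            events.append(ev)
            del cur[a : k + 1]
            k = a - 1
        else:
            k -= 1

    # 2) duplications on this branch: child columns absent from the ancestor
    gapdec_by_col = {c: gd for gd in analysis.gaps for c in gd.cols}
    child_cols = sorted(
        (i for i in range(len(cols)) if child_pos(i) is not None), key=child_pos
    )
    i = 0
    while i < len(child_cols):
        ci = child_cols[i]
        if ci in cur:
            i += 1
            continue
        j = i
        run = []
        while j < len(child_cols) and child_cols[j] not in cur and (
            gapdec_by_col.get(child_cols[j]) is gapdec_by_col.get(ci)
        ):
            run.append(child_cols[j])
            j += 1
        boundary = i  # insert so the copies precede child_cols[i+len(run)] in reading
        orient = w_unit.orientation
        content_reading = [
            Gene(*child_reading[child_pos(c)].value(), sign=orient) for c in run
        ]
        content = content_reading if orient > 0 else list(reversed(content_reading))
        gd = gapdec_by_col.get(ci)
        etype = gd.kind if gd is not None and gd.kind != DELETION else DUPLICATION
        off = _reading_insertion(len(w_unit.genes), orient, boundary)
        ev = Event(
            etype,
            branch,
            len(run),
            {
                "target": ("in", uidx(), off),
                "content": content,
                "source": None,
                # detected in descendant coordinates; informational only
                "source_hint": gd.source if gd is not None else None,
            },
        )
        _apply_inplace(w, ev)
        events.append(ev)
        cur[boundary:boundary] = run
        i += len(run)

    # 3) substitutions on this branch
    for sub in analysis.subs:
        if sub.branch != branch:
            continue
        rpos = cur.index(sub.col)
        off = rpos if w_unit.orientation > 0 else len(w_unit.genes) - 1 - rpos
        ev = Event(
            SUBSTITUTION,
            branch,
            1,
            {"position": (uidx(), off), "from_value": sub.anc_value, "to_value": sub.to_value},
        )
        _apply_inplace(w, ev)
        events.append(ev)

    if [g.value() for g in w_unit.genes] != [g.value() for g in child_unit.genes]:
        raise InternalConsistencyError(
            f"unit script for {branch} did not reproduce the child operon"
        )
    return events


def _nested_events(
    res: UnmappedResolution, child: GeneOrder, branch: str
) -> list[Event]:
    """Overlapping (non-visible) events inside a duplicated paralogous operon.

    These are replay-inert (the whole-operon duplication inserts the final
    copy) but carry descendant-frame descriptors for the evaluation metrics.
    """
    if res.nested is None:
        return []
    out: list[Event] = []
    unit = child.units[res.unit_index]
    base = child.flat_of(res.unit_index)
    L = len(unit.genes)

    def flat_of_reading(rp: int) -> int:
        off = rp if unit.orientation > 0 else L - 1 - rp
        return base + off

    cols = res.partner_alignment.columns
    for sub in res.nested.subs:
        pos = flat_of_reading(cols[sub.col].x_pos)
        ev = Event(SUBSTITUTION, branch, 1, {}, nested=True)
        ev.affected = {"family": SUBSTITUTION, "positions": (pos,), "locus": None, "content": ()}
        out.append(ev)
    for gd in res.nested.gaps:
        if gd.side == "X":  # extra genes in the copy: a nested duplication
            positions = tuple(sorted(flat_of_reading(cols[c].x_pos) for c in gd.cols))
            etype = gd.kind if gd.kind != DELETION else DUPLICATION
            ev = Event(etype, branch, len(gd.cols), {}, nested=True)
            ev.affected = {
                "family": DUPLICATION,
                "positions": positions,
                "locus": None,
                "content": tuple(child.flat_values()[p] for p in positions),
            }
        else:  # genes of the paralog missing from the copy: a nested deletion
            partner = child.units[res.partner_index]
            pr = partner.reading()
            content = tuple(pr[cols[c].y_pos].value() for c in gd.cols)
            # locus: before the next copy gene present, in reading order
            nxt = None
            for c in range(gd.cols[-1] + 1, len(cols)):
                if cols[c].x_pos is not None:
                    nxt = flat_of_reading(cols[c].x_pos)
                    break
            locus = nxt if nxt is not None else base + (L if unit.orientation > 0 else 0)
            ev = Event(DELETION, branch, len(gd.cols), {}, nested=True)
            ev.affected = {"family": DELETION, "positions": (), "locus": locus, "content": content}
        out.append(ev)
    return out


# ---------------------------------------------------------------------------
# Cherry inference
# ---------------------------------------------------------------------------


@dataclass
class BranchRecord:
    branch: str
    events: list[Event]
    child_terminus: int


@dataclass
class CherryRecord:
    parent: str
    x_id: str
    y_id: str
    ancestor: GeneOrder
    branch_x: BranchRecord
    branch_y: BranchRecord
    flags: dict[int, tuple]  # id(ancestor gene) -> correction key
    overrides: frozenset = frozenset()

    @property
    def events(self) -> list[Event]:
        return self.branch_x.events + self.branch_y.events


def _emit_branch(
    ancestor_units: list[_AncUnit],
    anc_terminus: int,
    parent_id: str,
    child: GeneOrder,
    child_side: str,
    branch: str,
    unmapped: dict[int, UnmappedResolution],
) -> BranchRecord:
    """Derive the ordered replayable event list ancestor -> child."""
    w = GeneOrder(parent_id, [a.unit.clone() for a in ancestor_units], anc_terminus)
    wu = {id(a.unit): u for a, u in zip(ancestor_units, w.units)}
    events: list[Event] = []

    # 1) whole-unit deletions: ancestral units absent from this child
    absent_tag = "y_only" if child_side == "X" else "x_only"
    doomed = [a for a in ancestor_units if getattr(a, absent_tag) is not None]
    for a in sorted(doomed, key=lambda a: -next(i for i, v in enumerate(w.units) if v is wu[id(a.unit)])):
        u = wu[id(a.unit)]
        idx = next(i for i, v in enumerate(w.units) if v is u)
        ev = Event(
            DELETION,
            branch,
            len(u.genes),
            {"target": ("whole", idx), "content": [g.clone() for g in u.genes], "kind": u.kind},
        )
        _apply_inplace(w, ev)
        events.append(ev)

    # 2) rearrangements: sort surviving units into the child's relative order
    kept = [a for a in ancestor_units if getattr(a, absent_tag) is None]

    def child_index(a: _AncUnit) -> int:
        if a.pair is not None:
            return a.pair.x_index if child_side == "X" else a.pair.y_index
        return a.x_only if child_side == "X" else a.y_only

    kept.sort(key=child_index)
    target = [wu[id(a.unit)] for a in kept]
    orients = {}
    for a in kept:
        if a.pair is not None:
            cu = a.pair.x_unit if child_side == "X" else a.pair.y_unit
            orients[id(wu[id(a.unit)])] = cu.orientation
        else:
            orients[id(wu[id(a.unit)])] = wu[id(a.unit)].orientation
    events += _emit_rearrangements(w, target, orients, branch)

    # 3) whole-unit duplications: child units with no ancestral counterpart
    kept_child_indices = {child_index(a) for a in kept}
    inserted: list[int] = []
    for ci in sorted(unmapped):
        res = unmapped[ci]
        if res.role == DELETION:
            continue
        cu = child.units[ci]
        boundary = sum(1 for k in kept_child_indices if k < ci) + sum(
            1 for k in inserted if k < ci
        )
        etype = INVERSED_DUPLICATION if (res.source and res.source[2]) else DUPLICATION
        ev = Event(
            etype,
            branch,
            len(cu.genes),
            {
                "target": ("new", boundary, cu.kind),
                "content": [g.clone() for g in cu.genes],
                "source": None,
                "source_hint": res.source,
            },
        )
        _apply_inplace(w, ev)
        events.append(ev)
        inserted.append(ci)
        events += _nested_events(res, child, branch)

    # 4) per-unit content scripts
    for a in kept:
        if a.pair is not None:
            events += _emit_unit_script(
                w, wu[id(a.unit)], a.anc_cols, a.pair, a.analysis, child_side, branch
            )

    # 5) axis marker: the inferred events fix the unit order; the terminus is
    #    restored from the branch record on replay
    w.terminus = child.terminus
    if w != child:
        raise InternalConsistencyError(
            f"branch {branch}: replaying the inferred events does not reproduce the child"
        )
    return BranchRecord(branch, events, child.terminus)


def infer_cherry(
    x: GeneOrder,
    y: GeneOrder,
    branch_x: str,
    branch_y: str,
    parent_id: str,
    neighbor: GeneOrder | None = None,
    scoring: Scoring = DEFAULT_SCORING,
    overrides: frozenset = frozenset(),
) -> CherryRecord:
    """Solve one instance of the 2-small-phylogeny problem (Steps 1-4)."""
    omap = build_ortholog_map(x, y, scoring)
    neighbor_values = set(map(tuple, neighbor.flat_values())) if neighbor is not None else None

    analyses = {
        (p.x_index, p.y_index): analyze_pair(
            p, x, y, branch_x, branch_y, neighbor_values, overrides
        )
        for p in omap.pairs
    }

    unmapped_x: dict[int, UnmappedResolution] = {}
    for i in omap.unmapped_x:
        if x.units[i].kind == OPERON:
            unmapped_x[i] = resolve_unmapped_operon(i, x, "X", branch_x, branch_y, scoring)
        else:
            unmapped_x[i] = resolve_unmapped_singleton(i, x, "X", branch_x, branch_y)
    unmapped_y: dict[int, UnmappedResolution] = {}
    for j in omap.unmapped_y:
        if y.units[j].kind == OPERON:
            unmapped_y[j] = resolve_unmapped_operon(j, y, "Y", branch_y, branch_x, scoring)
        else:
            unmapped_y[j] = resolve_unmapped_singleton(j, y, "Y", branch_y, branch_x)

    segments = segment_rearrangements(omap, x, y)
    xn = _xn_status(x, neighbor, scoring) if neighbor is not None else None
    seg_branch: dict[int, str] = {}  # x unit index -> branch of its segment
    seg_of_x: dict[int, Segment] = {}
    for seg in segments:
        b = assign_branch(seg, branch_x, branch_y, xn) if seg.kind != CONSERVED else None
        for d in seg.dots:
            seg_of_x[d.x_index] = seg
            if b is not None:
                seg_branch[d.x_index] = b

    # ancestral units in X order
    flags: dict[int, tuple] = {}
    anc_by_x: dict[int, _AncUnit] = {}
    pair_by_x = {p.x_index: p for p in omap.pairs}
    for i, unit in enumerate(x.units):
        if i in pair_by_x:
            p = pair_by_x[i]
            orient = _ancestral_orientation(p, seg_branch.get(i), branch_x)
            anc_by_x[i] = _build_pair_unit(
                p, analyses[(p.x_index, p.y_index)], orient, branch_x, branch_y, flags
            )
        else:
            res = unmapped_x[i]
            if res.role == DELETION:  # present in the ancestor, deleted on branch Y
                anc_by_x[i] = _AncUnit(_restored_clone(unit, branch_y), x_only=i)

    # order: relocate branch-X segments to their Y positions
    tokens: list[_AncUnit] = [anc_by_x[i] for i in sorted(anc_by_x)]
    moved: list[tuple[int, list[_AncUnit]]] = []
    for seg in segments:
        if seg.kind == CONSERVED or seg_branch.get(seg.dots[0].x_index) != branch_x:
            continue
        members = [anc_by_x[d.x_index] for d in seg.dots if d.x_index in anc_by_x]
        if not members:
            continue
        members.sort(key=lambda a: a.pair.y_index)
        for mbr in members:
            tokens.remove(mbr)
        moved.append((min(a.pair.y_index for a in members), members))
    for y_anchor, members in sorted(moved, key=lambda t: t[0]):
        # insert after the pair with the largest y index below the block's
        best_pos, best_y = 0, -1
        for pos, tok in enumerate(tokens):
            if tok.pair is not None and best_y < tok.pair.y_index < y_anchor:
                best_y = tok.pair.y_index
                best_pos = pos + 1
        tokens[best_pos:best_pos] = members

    # units deleted on branch X exist only in Y; anchor them to Y neighbors
    pair_by_y = {p.y_index: p for p in omap.pairs}
    for j in sorted(unmapped_y):
        res = unmapped_y[j]
        if res.role != DELETION:
            continue
        anc = _AncUnit(_restored_clone(y.units[j], branch_x), y_only=j)
        best_pos, best_y = 0, -1
        for pos, tok in enumerate(tokens):
            ty = tok.pair.y_index if tok.pair is not None else (
                tok.y_only if tok.y_only is not None else None
            )
            if ty is not None and best_y < ty < j:
                best_y = ty
                best_pos = pos + 1
        tokens[best_pos:best_pos] = [anc]

    # terminus: anchored on X's terminus context
    anc_units = [t.unit for t in tokens]
    term = None
    for i in range(x.terminus - 1, -1, -1):
        if i in anc_by_x and anc_by_x[i] in tokens:
            term = tokens.index(anc_by_x[i]) + 1
            break
    if term is None:
        half = sum(len(u.genes) for u in anc_units) / 2
        acc, term = 0, 1
        bestd = float("inf")
        for b, u in enumerate(anc_units, start=1):
            acc += len(u.genes)
            if abs(acc - half) < bestd and b <= len(anc_units) - 1:
                bestd, term = abs(acc - half), b
    term = max(1, min(term, max(1, len(anc_units) - 1)))
    ancestor = GeneOrder(parent_id, anc_units, term)

    bx = _emit_branch(tokens, term, parent_id, x, "X", branch_x, unmapped_x)
    by = _emit_branch(tokens, term, parent_id, y, "Y", branch_y, unmapped_y)
    canonicalize_events(ancestor, bx.events)
    canonicalize_events(ancestor, by.events)
    return CherryRecord(parent_id, x.genome_id, y.genome_id, ancestor, bx, by, flags, overrides)


def build_ancestor(
    x: GeneOrder,
    y: GeneOrder,
    neighbor: GeneOrder | None = None,
    parent_id: str = "ancestor",
    scoring: Scoring = DEFAULT_SCORING,
) -> GeneOrder:
    """Ancestral gene order of a cherry (Steps 1-4 on one comparison)."""
    rec = infer_cherry(x, y, x.genome_id, y.genome_id, parent_id, neighbor, scoring)
    return rec.ancestor


# ---------------------------------------------------------------------------
# Tree driver
# ---------------------------------------------------------------------------


@dataclass
class History:
    tree: Phylogeny
    ancestors: dict[str, GeneOrder]
    events: dict[str, list[Event]]  # branch child id -> ordered events
    terminus: dict[str, int]  # branch child id -> child terminus

    def replay(self, parent_order: GeneOrder, child_id: str) -> GeneOrder:
        g = parent_order.clone()
        g.genome_id = child_id
        for e in self.events[child_id]:
            if not e.nested:
                _apply_inplace(g, e)
        g.terminus = self.terminus[child_id]
        return g

    def total_events(self, branches: list[str] | None = None) -> int:
        keys = branches if branches is not None else list(self.events)
        return sum(len(self.events[b]) for b in keys)

    def events_by_type(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for evs in self.events.values():
            for e in evs:
                out[e.family] = out.get(e.family, 0) + 1
        return out


def _triggered_flags(rec: CherryRecord, other: GeneOrder, scoring: Scoring) -> frozenset:
    """Correction keys of flagged ancestor genes that fall into a gap (or an
    unmapped singleton) when the ancestor meets its next comparison."""
    a = rec.ancestor
    omap = build_ortholog_map(a, other, scoring)
    flagged = dict(rec.flags)
    if not flagged:
        return frozenset()
    triggered: set[tuple] = set()
    paired_x = {}
    for p in omap.pairs:
        paired_x[p.x_index] = p
    for ui, unit in enumerate(a.units):
        ids = [id(g) for g in unit.genes if id(g) in flagged]
        if not ids:
            continue
        p = paired_x.get(ui)
        if p is None:
            if unit.kind == SINGLETON:
                triggered.update(flagged[i] for i in ids)
            continue
        if p.alignment is None:
            continue
        reading = unit.reading()
        gap_pos = {
            c.x_pos for c in p.alignment.columns if c.label == GAP_Y
        }
        for rp, g in enumerate(reading):
            if id(g) in flagged and rp in gap_pos:
                triggered.add(flagged[id(g)])
    return frozenset(triggered)


def infer_history(
    tree: Phylogeny,
    leaf_orders: dict[str, GeneOrder],
    use_neighbor: bool = True,
    scoring: Scoring = DEFAULT_SCORING,
) -> History:
    """Post-order traversal solving a 2-SPP per internal node.

    Before a cherry ancestor is consumed by its parent's comparison, its
    correctable restored genes are re-examined against the sibling genome and
    the deletion->duplication correction is applied (one round per cherry).
    """
    for leaf in tree.leaves():
        if leaf.name not in leaf_orders:
            raise ValueError(f"no gene order supplied for leaf {leaf.name!r}")
        leaf_orders[leaf.name].validate()

    import logging

    log = logging.getLogger("operonevo.builder")
    resolved: dict[str, GeneOrder] = {n: o for n, o in leaf_orders.items()}
    records: dict[str, CherryRecord] = {}

    def correct_child(node: PhyloNode, sibling_order: GeneOrder) -> None:
        rec = records.get(node.name)
        if rec is None or not rec.flags:
            return
        keys = _triggered_flags(rec, sibling_order, scoring)
        if not keys:
            return
        cx, cy = node.children
        nb_node = select_neighbor(tree, node, resolved) if use_neighbor else None
        nb = resolved.get(nb_node.name) if nb_node is not None else None
        new = infer_cherry(
            resolved[cx.name],
            resolved[cy.name],
            cx.name,
            cy.name,
            node.name,
            nb,
            scoring,
            overrides=rec.overrides | keys,
        )
        records[node.name] = new
        resolved[node.name] = new.ancestor

    for node in tree.postorder():
        if node.is_leaf:
            continue
        cx, cy = node.children
        # deletion->duplication correction on child ancestors, one round each
        if not cx.is_leaf:
            correct_child(cx, resolved[cy.name])
        if not cy.is_leaf:
            correct_child(cy, resolved[cx.name])
        nb_node = select_neighbor(tree, node, resolved) if use_neighbor else None
        nb = resolved.get(nb_node.name) if nb_node is not None else None
        log.info(
            "cherry (%s, %s) -> %s%s",
            cx.name,
            cy.name,
            node.name,
            f" [neighbor {nb_node.name}]" if nb_node is not None else " [no neighbor]",
        )
        rec = infer_cherry(
            resolved[cx.name],
            resolved[cy.name],
            cx.name,
            cy.name,
            node.name,
            nb,
            scoring,
        )
        records[node.name] = rec
        resolved[node.name] = rec.ancestor
        log.info(
            "  %s: %d events on the two branches",
            node.name,
            len(rec.branch_x.events) + len(rec.branch_y.events),
        )

    ancestors = {n.name: resolved[n.name] for n in tree.internals()}
    events: dict[str, list[Event]] = {}
    terminus: dict[str, int] = {}
    for rec in records.values():
        events[rec.x_id] = rec.branch_x.events
        terminus[rec.x_id] = rec.branch_x.child_terminus
        events[rec.y_id] = rec.branch_y.events
        terminus[rec.y_id] = rec.branch_y.child_terminus
    return History(tree, ancestors, events, terminus)
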