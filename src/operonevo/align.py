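"""Step 1: orthologous-operon and singleton pairing via global alignment.

Operons are aligned all-vs-all between two genomes with a simple global
dynamic program over gene identities (full match +1, partial match +0.5,
mismatch -1, gap -1).  A *full match* requires the same identity class and
anticodon, a *partial match* the same tRNA class with a different anticodon
(rRNA genes have no partial matches).  Pairs scoring >= 0 are greedily
labelled orthologous from the highest score down, ties broken by index
proximity.  Unpaired singletons are matched only when identical.

Strand is handled at the unit level: gene signs never enter the score, and a
pair whose members sit on opposite strands is flagged ``flipped`` (the signal
consumed by the rearrangement step).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from operonevo.model import Gene, GeneOrder, Unit, OPERON, SINGLETON

__all__ = [
    "FULL",
    "PARTIAL",
    "MISMATCH",
    "Scoring",
    "AlignmentColumn",
    "OperonAlignment",
    "UnitPair",
    "OrthologMap",
    "score_gene_pair",
    "align_operons",
    "pair_orthologous_operons",
    "pair_singletons",
    "build_ortholog_map",
]

FULL = "full"
PARTIAL = "partial"
MISMATCH = "mismatch"
GAP_X = "gapX"
GAP_Y = "gapY"


@dataclass(frozen=True)
class Scoring:
    """Column scores; a full match must beat a partial, which must beat both penalties."""

    full: float = 1.0
    partial: float = 0.5
    mismatch: float = -1.0
    gap: float = -1.0

    def __post_init__(self) -> None:
        if not (self.full > self.partial > max(self.mismatch, self.gap)):
            raise ValueError("scoring must satisfy full > partial > mismatch/gap")


DEFAULT_SCORING = Scoring()


def score_gene_pair(a: Gene, b: Gene) -> str:
    """Classify a gene pair as full / partial / mismatch (signs excluded)."""
    if a.identity_class != b.identity_class:
        return MISMATCH
    if not a.is_trna:  # rRNA subunits have no anticodon, hence no partial match
        return FULL
    return FULL if a.anticodon == b.anticodon else PARTIAL


@dataclass
class AlignmentColumn:
    """One aligned column; positions index the promoter-first reading of each operon."""

    label: str  # full | partial | mismatch | gapX | gapY
    x_pos: int | None
    y_pos: int | None


@dataclass
class OperonAlignment:
    columns: list[AlignmentColumn]
    score: float
    flipped_y: bool = False  # Y was aligned in reversed reading order

    def column_score(self, scoring: Scoring = DEFAULT_SCORING) -> float:
        table = {
            FULL: scoring.full,
            PARTIAL: scoring.partial,
            MISMATCH: scoring.mismatch,
            GAP_X: scoring.gap,
            GAP_Y: scoring.gap,
        }
        return sum(table[c.label] for c in self.columns)


def align_operons(
    x: list[Gene] | Unit,
    y: list[Gene] | Unit,
    scoring: Scoring = DEFAULT_SCORING,
) -> OperonAlignment:
    """Optimal global alignment of two operons read promoter-first.

    Boundary conditions M[i,0] = -i, M[0,j] = -j; the traceback is made
    deterministic by preferring, on ties, the diagonal move, then the column
    consuming X (gap in Y), then the one consuming Y (gap in X).
    """
    gx = x.reading() if isinstance(x, Unit) else list(x)
    gy = y.reading() if isinstance(y, Unit) else list(y)
    if not gx or not gy:
        raise ValueError("cannot align an empty operon")
    n, m = len(gx), len(gy)
    score_of = {FULL: scoring.full, PARTIAL: scoring.partial, MISMATCH: scoring.mismatch}

    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        M[i][0] = i * scoring.gap
    for j in range(1, m + 1):
        M[0][j] = j * scoring.gap
    labels = [[MISMATCH] * m for _ in range(n)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            lab = score_gene_pair(gx[i - 1], gy[j - 1])
            labels[i - 1][j - 1] = lab
            M[i][j] = max(
                M[i - 1][j - 1] + score_of[lab],
                M[i][j - 1] + scoring.gap,
                M[i - 1][j] + scoring.gap,
            )

    cols: list[AlignmentColumn] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and M[i][j] == M[i - 1][j - 1] + score_of[labels[i - 1][j - 1]]:
            cols.append(AlignmentColumn(labels[i - 1][j - 1], i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and M[i][j] == M[i - 1][j] + scoring.gap:
            cols.append(AlignmentColumn(GAP_Y, i - 1, None))
            i -= 1
        else:
            cols.append(AlignmentColumn(GAP_X, None, j - 1))
            j -= 1
    cols.reverse()
    return OperonAlignment(cols, M[n][m])


def _align_both_orientations(
    xu: Unit, yu: Unit, scoring: Scoring
) -> OperonAlignment:
    """Best of the canonical and the order-reversed (sign-flipped) alignment of Y."""
    fwd = align_operons(xu.reading(), yu.reading(), scoring)
    ry = list(reversed(yu.reading()))
    rev = align_operons(xu.reading(), ry, scoring)
    if rev.score > fwd.score:
        m = len(yu.genes)
        rev.flipped_y = True
        for c in rev.columns:  # re-express Y positions in canonical reading order
            if c.y_pos is not None:
                c.y_pos = m - 1 - c.y_pos
        return rev
    return fwd


@dataclass
class UnitPair:
    x_index: int
    y_index: int
    x_unit: Unit
    y_unit: Unit
    alignment: OperonAlignment | None  # None for singleton pairs
    flipped: bool  # members sit on opposite strands between the two genomes


@dataclass
class OrthologMap:
    operon_pairs: list[UnitPair] = field(default_factory=list)
    singleton_pairs: list[UnitPair] = field(default_factory=list)
    unmapped_x: list[int] = field(default_factory=list)
    unmapped_y: list[int] = field(default_factory=list)

    @property
    def pairs(self) -> list[UnitPair]:
        return self.operon_pairs + self.singleton_pairs


def pair_orthologous_operons(
    a: GeneOrder, b: GeneOrder, scoring: Scoring = DEFAULT_SCORING
) -> OrthologMap:
    """Greedy orthologous-operon pairing by descending alignment score.

    Pairs scoring below zero are discarded; ties are broken by the smallest
    index distance, then by the smaller indices.  Operons are compared in
    promoter-first reading order, which is invariant under inversions (an
    inverted operon keeps its transcription order), so one alignment covers
    both orientations and strand divergence is carried by the flipped flag.
    """
    ops_a = [(i, u) for i, u in enumerate(a.units) if u.kind == OPERON]
    ops_b = [(j, u) for j, u in enumerate(b.units) if u.kind == OPERON]
    candidates = []
    for i, xu in ops_a:
        for j, yu in ops_b:
            al = align_operons(xu.reading(), yu.reading(), scoring)
            if al.score >= 0:
                candidates.append((-al.score, abs(i - j), i, j, al))
    candidates.sort(key=lambda c: c[:4])

    out = OrthologMap()
    used_a: set[int] = set()
    used_b: set[int] = set()
    for negscore, _, i, j, al in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        flipped = a.units[i].orientation != b.units[j].orientation
        out.operon_pairs.append(UnitPair(i, j, a.units[i], b.units[j], al, flipped))
    out.unmapped_x = [i for i, _ in ops_a if i not in used_a]
    out.unmapped_y = [j for j, _ in ops_b if j not in used_b]
    return out


def pair_singletons(a: GeneOrder, b: GeneOrder, omap: OrthologMap) -> OrthologMap:
    """Pair identical singletons, closest linearized indices first.

    Identity means same class and anticodon; a sign difference is allowed and
    recorded as ``flipped``.
    """
    sing_a = [(i, u) for i, u in enumerate(a.units) if u.kind == SINGLETON]
    sing_b = [(j, u) for j, u in enumerate(b.units) if u.kind == SINGLETON]
    candidates = []
    for i, xu in sing_a:
        for j, yu in sing_b:
            if xu.genes[0].value() == yu.genes[0].value():
                candidates.append((abs(i - j), i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        flipped = a.units[i].orientation != b.units[j].orientation
        omap.singleton_pairs.append(UnitPair(i, j, a.units[i], b.units[j], None, flipped))
    omap.unmapped_x += [i for i, _ in sing_a if i not in used_a]
    omap.unmapped_y += [j for j, _ in sing_b if j not in used_b]
    omap.unmapped_x.sort()
    omap.unmapped_y.sort()
    return omap


def build_ortholog_map(
    a: GeneOrder, b: GeneOrder, scoring: Scoring = DEFAULT_SCORING
) -> OrthologMap:
    """Full Step 1: operon pairing followed by singleton pairing."""
    return pair_singletons(a, b, pair_orthologous_operons(a, b, scoring))
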