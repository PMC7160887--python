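"""Step 3: dot-plot construction and segmentation into rearrangement blocks.

Each ortholog pair from Step 1 becomes one dot (x = unit index in the first
genome, y = unit index in the second, flipped = opposite strands).  Dots are
grouped into maximal constant-slope runs over the *ranks* of the paired units
(so unpaired units in between do not break a run): slope +1 runs of unflipped
dots, slope -1 runs of flipped dots, and single dots.

The "main diagonal" is formalized as the heaviest chain of mutually collinear
forward runs — a weighted longest-increasing-subsequence over runs, weight =
dot count.  Runs on the chain are conserved; flipped runs are inversion
candidates, refined by the axis rule (an inversion must sit immediately next
to the origin or terminus in at least one genome, otherwise the segment is a
reversed transposition); the remaining runs are transpositions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from operonevo.model import GeneOrder
from operonevo.align import OrthologMap

__all__ = [
    "Dot",
    "Segment",
    "CONSERVED",
    "INVERTED",
    "TRANSPOSED_FORWARD",
    "TRANSPOSED_REVERSED",
    "build_dotplot",
    "segment_dotplot",
    "classify_inversion",
    "segment_rearrangements",
]

CONSERVED = "conserved"
INVERTED = "inverted"
TRANSPOSED_FORWARD = "transposed_forward"
TRANSPOSED_REVERSED = "transposed_reversed"


@dataclass(frozen=True)
class Dot:
    x_index: int
    y_index: int
    flipped: bool


@dataclass
class Segment:
    kind: str
    dots: list[Dot]
    axis_adjacency: dict = field(default_factory=dict)  # genome -> origin|terminus|none

    @property
    def flipped(self) -> bool:
        return self.dots[0].flipped

    def x_span(self) -> tuple[int, int]:
        xs = [d.x_index for d in self.dots]
        return min(xs), max(xs) + 1

    def y_span(self) -> tuple[int, int]:
        ys = [d.y_index for d in self.dots]
        return min(ys), max(ys) + 1

    def x_units(self) -> set[int]:
        return {d.x_index for d in self.dots}

    def y_units(self) -> set[int]:
        return {d.y_index for d in self.dots}


def build_dotplot(omap: OrthologMap, a: GeneOrder, b: GeneOrder) -> list[Dot]:
    """One dot per ortholog pair, sorted by x index."""
    dots = [Dot(p.x_index, p.y_index, p.flipped) for p in omap.pairs]
    dots.sort(key=lambda d: d.x_index)
    return dots


def _runs(dots: list[Dot]) -> list[list[Dot]]:
    """Maximal constant-slope runs in rank space, uniform flippedness per run."""
    if not dots:
        return []
    yrank = {d.y_index: r for r, d in enumerate(sorted(dots, key=lambda d: d.y_index))}
    runs: list[list[Dot]] = [[dots[0]]]
    for prev, cur in zip(dots, dots[1:]):
        dy = yrank[cur.y_index] - yrank[prev.y_index]
        same_slope = (not prev.flipped and not cur.flipped and dy == 1) or (
            prev.flipped and cur.flipped and dy == -1
        )
        if same_slope:
            runs[-1].append(cur)
        else:
            runs.append([cur])
    return runs


def _main_diagonal(runs: list[list[Dot]], yrank: dict[int, int]) -> set[int]:
    """Indices of the runs forming the heaviest increasing chain of forward runs."""
    fwd = [k for k, r in enumerate(runs) if not r[0].flipped]
    best: dict[int, tuple[float, tuple[int, ...]]] = {}
    # runs are already in x order; DP over forward runs with increasing y ranks
    chains: list[tuple[float, tuple[int, ...]]] = []
    for idx, k in enumerate(fwd):
        run = runs[k]
        w = len(run)
        lo = yrank[run[0].y_index]
        cand = (w, (k,))
        for jdx in range(idx):
            kj = fwd[jdx]
            prev_run = runs[kj]
            if yrank[prev_run[-1].y_index] < lo:
                score, chain = chains[jdx]
                # ties broken toward the chain containing the lower x index run
                if (score + w, ) > (cand[0], ) or (
                    score + w == cand[0] and chain + (k,) < cand[1]
                ):
                    cand = (score + w, chain + (k,))
        chains.append(cand)
    if not chains:
        return set()
    best_chain = max(chains, key=lambda c: (c[0], tuple(-i for i in c[1])))
    return set(best_chain[1])


def _axis_adjacency(span: tuple[int, int], order: GeneOrder) -> str:
    s, e = span
    if s == 0 or e == len(order.units):
        return "origin"
    if s == order.terminus or e == order.terminus:
        return "terminus"
    return "none"


def segment_dotplot(dots: list[Dot]) -> list[Segment]:
    """Partition the dots into conserved / inverted-candidate / transposed segments."""
    runs = _runs(dots)
    if not runs:
        return []
    yrank = {d.y_index: r for r, d in enumerate(sorted(dots, key=lambda d: d.y_index))}
    diagonal = _main_diagonal(runs, yrank)
    segments = []
    for k, run in enumerate(runs):
        if run[0].flipped:
            kind = INVERTED  # refined by classify_inversion
        elif k in diagonal:
            kind = CONSERVED
        else:
            kind = TRANSPOSED_FORWARD
        segments.append(Segment(kind, run))
    return segments


def classify_inversion(seg: Segment, a: GeneOrder, b: GeneOrder) -> str:
    """Axis rule: a flipped segment is an inversion only when it abuts an axis.

    Adjacency in either genome is accepted (the comparison cannot tell on
    which branch the event happened, and the axis constraint holds in the
    genome that carries it).
    """
    ax = _axis_adjacency(seg.x_span(), a)
    ay = _axis_adjacency(seg.y_span(), b)
    seg.axis_adjacency = {a.genome_id: ax, b.genome_id: ay}
    return INVERTED if (ax != "none" or ay != "none") else TRANSPOSED_REVERSED


def segment_rearrangements(
    omap: OrthologMap, a: GeneOrder, b: GeneOrder
) -> list[Segment]:
    """Full Step 3: dot-plot, segmentation and inversion/transposition refinement."""
    segments = segment_dotplot(build_dotplot(omap, a, b))
    for seg in segments:
        if seg.kind == INVERTED:
            seg.kind = classify_inversion(seg, a, b)
            if seg.kind == TRANSPOSED_REVERSED:
                seg.axis_adjacency = seg.axis_adjacency  # keep recorded adjacency
    return segments
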