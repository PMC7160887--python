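"""Annotation of gene orders from a genome sequence and rRNA/tRNA features.

The origin and terminus of replication are located at the extrema of the
cumulative GC skew ((G-C)/(G+C) per sliding window, cumulatively summed):
the minimum marks the origin, the maximum the terminus.  Operons are called
with a simple intergenic-distance rule: consecutive rRNA/tRNA genes on the
same strand at most 200 bp apart belong to one operon (opposite-strand genes
can never share a promoter and are kept apart, a requirement the distance
rule alone does not impose).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.SeqUtils import GC_skew

from operonevo.model import (
    AnnotationError,
    Gene,
    GeneOrder,
    OPERON,
    RRNA_CLASSES,
    SINGLETON,
    TRNA_CLASSES,
    Unit,
)

__all__ = [
    "GeneFeature",
    "gc_skew_extrema",
    "group_operons",
    "read_features_gff3",
    "annotate",
]

log = logging.getLogger("operonevo.annotation")


@dataclass(frozen=True)
class GeneFeature:
    """One rRNA/tRNA gene feature (1-based inclusive nucleotide coordinates)."""

    identity_class: str
    anticodon: str | None
    strand: int
    start: int
    end: int


def _window_skews(sequence: str, window: int) -> list[float]:
    seq = sequence.upper()
    if all(b == "N" for b in seq):
        raise AnnotationError("all-N sequence: GC skew extrema are undefined")
    n_win = len(seq) // window
    if any(
        seq.count("G", i * window, (i + 1) * window)
        + seq.count("C", i * window, (i + 1) * window)
        == 0
        for i in range(n_win)
    ):
        # zero-GC windows contribute zero skew; Biopython would divide by zero
        out = []
        for i in range(n_win):
            w = seq[i * window : (i + 1) * window]
            g, c = w.count("G"), w.count("C")
            out.append((g - c) / (g + c) if g + c else 0.0)
        return out
    return [float(s) for s in GC_skew(seq, window)]


def gc_skew_extrema(
    sequence: str, window: int | None = None
) -> tuple[int, int, bool]:
    """Origin and terminus positions from cumulative GC-skew extrema.

    Returns ``(origin, terminus, confident)`` where positions are nucleotide
    offsets of window centers.  The minimum of the cumulative skew marks the
    origin, the maximum the terminus.  ``confident`` is False when the
    cumulative-skew amplitude is indistinguishable from a random walk over
    the window skews (amplitude below twice its random-walk scale), as on a
    compositionally unpolarized sequence.
    """
    if window is None:
        window = max(1, len(sequence) // 500)
    if len(sequence) <= 2 * window:
        raise AnnotationError("sequence shorter than two GC-skew windows")
    skews = _window_skews(sequence, window)
    cum = []
    acc = 0.0
    for s in skews:
        acc += s
        cum.append(acc)
    lo = min(range(len(cum)), key=lambda i: (cum[i], i))
    hi = max(range(len(cum)), key=lambda i: (cum[i], -i))
    amplitude = cum[hi] - cum[lo]
    n = len(skews)
    sd = (sum(s * s for s in skews) / n - (sum(skews) / n) ** 2) ** 0.5
    confident = amplitude >= 2.0 * sd * math.sqrt(n) and amplitude > 0
    origin = lo * window + window // 2
    terminus = hi * window + window // 2
    return origin, terminus, confident


# ---------------------------------------------------------------------------
# Operon grouping
# ---------------------------------------------------------------------------


def _circular_gap(prev: GeneFeature, nxt: GeneFeature, seq_len: int) -> int:
    """Intergenic distance (next.start - prev.end - 1) on the circle."""
    return (nxt.start - prev.end - 1) % seq_len


def group_operons(
    features: list[GeneFeature],
    seq_len: int,
    origin: int,
    terminus: int,
    max_intergenic: int = 200,
    genome_id: str = "genome",
) -> GeneOrder:
    """Group features into operons/singletons and place the axis markers.

    Consecutive same-strand genes with an intergenic gap of at most
    ``max_intergenic`` bp merge into one operon; merging wraps around the
    circle and is therefore invariant to the rotation of the feature list.
    The origin and terminus markers are placed at the nearest inter-unit
    boundary; a marker falling inside a gene or an operon is shifted, with a
    warning.
    """
    if not features:
        raise AnnotationError("no rRNA/tRNA features to annotate")
    feats = sorted(features, key=lambda f: (f.start, f.end))
    n = len(feats)
    # merge flags between consecutive features (circular)
    merge = [
        feats[(i + 1) % n].strand == feats[i].strand
        and _circular_gap(feats[i], feats[(i + 1) % n], seq_len) <= max_intergenic
        for i in range(n)
    ]
    if all(merge) and n > 1:
        merge[-1] = False  # degenerate: everything merges around the circle

    # group start indices
    starts = [i for i in range(n) if not merge[i - 1]] or [0]
    groups: list[list[GeneFeature]] = []
    for s in starts:
        grp = [feats[s]]
        i = s
        while merge[i]:
            i = (i + 1) % n
            grp.append(feats[i])
        groups.append(grp)

    # inter-group boundary midpoints on the circle
    def boundary_pos(prev_grp, next_grp) -> float:
        e = prev_grp[-1].end
        s = next_grp[0].start
        gap = (s - e) % seq_len
        return (e + gap / 2) % seq_len

    k = len(groups)
    bounds = [boundary_pos(groups[i - 1], groups[i]) for i in range(k)]

    def circ_dist(a: float, b: float) -> float:
        d = abs(a - b) % seq_len
        return min(d, seq_len - d)

    oi = min(range(k), key=lambda i: (circ_dist(bounds[i], origin), i))
    for g in groups[oi % k]:
        if g.start <= origin <= g.end:
            log.warning(
                "%s: origin at %d falls inside a gene; marker shifted to the "
                "nearest unit boundary",
                genome_id,
                origin,
            )
    # rotate so the genome starts right after the origin boundary
    rotated = groups[oi:] + groups[:oi]
    ti = min(
        (i for i in range(1, k)),
        key=lambda i: (circ_dist(bounds[(oi + i) % k], terminus), i),
        default=1,
    )

    units = []
    for grp in rotated:
        genes = [Gene(f.identity_class, f.anticodon, f.strand) for f in grp]
        units.append(Unit(OPERON if len(genes) > 1 else SINGLETON, genes))
    order = GeneOrder(genome_id, units, ti)
    order.validate()
    if order.n_genes != len(features):
        raise AnnotationError("grouping lost or created genes")  # defensive
    return order


# ---------------------------------------------------------------------------
# GFF3 + FASTA front end
# ---------------------------------------------------------------------------


def _classify_feature(ftype: str, attrs: dict) -> tuple[str, str | None] | None:
    product = (attrs.get("product") or [""])[0]
    anticodon = (attrs.get("anticodon") or [None])[0]
    if ftype == "rRNA":
        for sub in RRNA_CLASSES:
            if product.startswith(sub) or f"{sub} " in product:
                return sub, None
        return None
    if ftype == "tRNA":
        name = product.replace("tRNA-", "")[:3]
        if name in TRNA_CLASSES:
            return name, anticodon.lower() if anticodon else None
        return None
    return None


def read_features_gff3(gff_path: str | Path) -> list[GeneFeature]:
    """rRNA/tRNA features from a GFF3 file (types rRNA and tRNA only)."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    feats = []
    for ftype in ("rRNA", "tRNA"):
        for f in db.features_of_type(ftype):
            cls = _classify_feature(ftype, dict(f.attributes))
            if cls is None:
                log.warning("skipping unrecognized %s feature at %d", ftype, f.start)
                continue
            identity, anticodon = cls
            if identity in TRNA_CLASSES and anticodon is None:
                log.warning("tRNA feature at %d lacks an anticodon; skipped", f.start)
                continue
            feats.append(
                GeneFeature(identity, anticodon, 1 if f.strand == "+" else -1, f.start, f.end)
            )
    feats.sort(key=lambda f: (f.start, f.end))
    return feats


def annotate(
    fasta_path: str | Path,
    gff_path: str | Path,
    max_intergenic: int = 200,
    window: int | None = None,
    genome_id: str | None = None,
) -> GeneOrder:
    """Annotated gene order from a genome FASTA (single record) and a GFF3."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise AnnotationError(f"{fasta_path}: expected exactly one FASTA record")
    seq = str(records[0].seq)
    origin, terminus, confident = gc_skew_extrema(seq, window)
    if not confident:
        log.warning("%s: GC-skew signal is weak; axis placement is low-confidence", fasta_path)
    features = read_features_gff3(gff_path)
    gid = genome_id or Path(fasta_path).stem
    return group_operons(features, len(seq), origin, terminus, max_intergenic, gid)
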