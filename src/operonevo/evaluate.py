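"""Accuracy metrics: ancestor match/gap comparison and event accuracy.

Ancestral gene orders are compared with a maximum-match global alignment in
which a match requires an identical gene (class and anticodon) and no
mismatch columns are allowed — a heaviest-common-subsequence.  Matches are
true positives; genes of the simulated ancestor missing from the inferred
one are false negatives, extra inferred genes are false positives; recall,
precision and their harmonic mean (F-measure) summarize the comparison.

Event accuracy is measured two ways.  *Strict* accuracy is the fraction of
simulated events recovered exactly — same event class, same branch, same
length and position in descendant coordinates — under a one-to-one matching.
*Relaxed* accuracy is the fraction of genes affected by simulated events
that are labelled with the correct event class on the correct branch,
regardless of how the inference cuts events into pieces: a two-gene deletion
recovered as two single-gene deletions scores 0 strictly but 1 relaxed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from operonevo.model import DELETION, Event, GeneOrder
from operonevo.phylo import triplet_tree
from operonevo.simulate import SimParams, simulate_tree

__all__ = [
    "AncestorComparison",
    "EventAccuracy",
    "match_gap_align",
    "strict_accuracy",
    "relaxed_accuracy",
    "BenchmarkRow",
    "run_benchmark",
]


@dataclass
class AncestorComparison:
    tp: int
    fn: int
    fp: int

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 1.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 1.0

    @property
    def f_measure(self) -> float:
        r, p = self.recall, self.precision
        if self.tp == 0:
            return 0.0 if (self.fn or self.fp) else 1.0
        return 2 * r * p / (r + p)


def match_gap_align(inferred: GeneOrder, truth: GeneOrder) -> AncestorComparison:
    """Match/gap comparison of two gene orders (no mismatch columns).

    The maximum number of matched columns is the heaviest common subsequence
    of the two flat gene sequences under gene identity (class + anticodon).
    """
    a = inferred.flat_values() if hasattr(inferred, "flat_values") else list(inferred)
    b = truth.flat_values() if hasattr(truth, "flat_values") else list(truth)
    n, m = len(a), len(b)
    dp = np.zeros((n + 1, m + 1), dtype=np.int32)
    for i in range(1, n + 1):
        ai = a[i - 1]
        row, prev = dp[i], dp[i - 1]
        for j in range(1, m + 1):
            if ai == b[j - 1]:
                row[j] = prev[j - 1] + 1
            else:
                row[j] = max(prev[j], row[j - 1])
    tp = int(dp[n][m])
    return AncestorComparison(tp=tp, fn=m - tp, fp=n - tp)


# ---------------------------------------------------------------------------
# Event accuracy
# ---------------------------------------------------------------------------


def _descriptor(e: Event) -> tuple:
    a = e.affected
    if a is None:
        raise ValueError(f"{e}: events must be canonicalized before evaluation")
    if a["family"] == DELETION:
        return (a["family"], e.branch, a["locus"], a["content"])
    return (a["family"], e.branch, a["positions"])


def strict_accuracy(truth: list[Event], inferred: list[Event]) -> float:
    """Fraction of simulated events recovered with exact extent and position.

    One-to-one greedy matching on (event class, branch, descendant-frame
    descriptor); duplication sources are not compared.
    """
    if not truth:
        return 1.0
    pool: dict[tuple, int] = {}
    for e in inferred:
        d = _descriptor(e)
        pool[d] = pool.get(d, 0) + 1
    hit = 0
    for e in truth:
        d = _descriptor(e)
        if pool.get(d, 0) > 0:
            pool[d] -= 1
            hit += 1
    return hit / len(truth)


def _deletion_cover(truth_e: Event, inferred: list[Event]) -> int:
    """Number of genes of a truth deletion covered by inferred deletions."""
    p = truth_e.affected["locus"]
    content = truth_e.affected["content"]
    k = len(content)
    covered = 0
    for value in content:
        for e in inferred:
            a = e.affected
            if a["family"] != DELETION or e.branch != truth_e.branch:
                continue
            q, h = a["locus"], len(a["content"])
            if value in a["content"] and (p - h) <= q <= (p + k):
                covered += 1
                break
    return covered


def relaxed_accuracy(truth: list[Event], inferred: list[Event]) -> float:
    """Fraction of truth-affected genes labelled with the correct event class.

    Visible events cover genes by descendant position; deletions cover their
    removed genes through content identity at an overlapping locus.
    """
    total = 0
    covered = 0
    cover_by: dict[tuple, set[int]] = {}
    for e in inferred:
        a = e.affected
        key = (a["family"], e.branch)
        cover_by.setdefault(key, set()).update(a["positions"])
    for e in truth:
        a = e.affected
        if a["family"] == DELETION:
            total += len(a["content"])
            covered += _deletion_cover(e, inferred)
        else:
            total += len(a["positions"])
            pos = cover_by.get((a["family"], e.branch), set())
            covered += sum(1 for pp in a["positions"] if pp in pos)
    return covered / total if total else 1.0


# ---------------------------------------------------------------------------
# Benchmark driver
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkRow:
    x: int
    events_per_branch: int
    replicates: int
    mean_true_events: float
    mean_inferred_events: float
    mean_f: float
    mean_strict: float
    mean_relaxed: float
    mean_strict_event_size: float
    roundtrip_rate: float


def run_benchmark(
    x_values: tuple[int, ...] = tuple(range(1, 9)),
    replicates: int = 25,
    seed: int = 0,
    use_neighbor: bool = True,
    params: SimParams | None = None,
) -> list[BenchmarkRow]:
    """Cherry-with-neighbor benchmark: triplets with x copies of each content
    event per branch plus one inversion on a cherry branch; metrics are taken
    on the two cherry branches against the simulated truth."""
    from operonevo.builder import infer_history

    base = params or SimParams()
    rows = []
    for xi, x in enumerate(x_values):
        fs, stricts, relaxeds, totals, inf_totals, sizes, rts = [], [], [], [], [], [], []
        for rep in range(replicates):
            sp = SimParams(
                n=base.n,
                p_op=base.p_op,
                prob_s=base.prob_s,
                p_event=base.p_event,
                x_recipe=x,
                cherry_inversion=base.cherry_inversion,
                seed=seed + 10_000 * xi + rep,
            )
            ds = simulate_tree(triplet_tree(), sp)
            cherry = ["X", "Y"]
            truth = [e for b in cherry for e in ds.truth[b]]
            try:
                h = infer_history(ds.tree, ds.leaf_orders(), use_neighbor=use_neighbor)
            except Exception:
                rts.append(0.0)
                stricts.append(0.0)
                relaxeds.append(0.0)
                fs.append(0.0)
                totals.append(len(truth))
                inf_totals.append(0)
                continue
            ok = all(
                h.replay(
                    h.ancestors[p.name],
                    c.name,
                )
                == (h.ancestors[c.name] if not c.is_leaf else ds.orders[c.name])
                for p, c in ds.tree.branches()
            )
            rts.append(1.0 if ok else 0.0)
            inferred = [e for b in cherry for e in h.events[b]]
            stricts.append(strict_accuracy(truth, inferred))
            relaxeds.append(relaxed_accuracy(truth, inferred))
            fs.append(match_gap_align(h.ancestors["P"], ds.orders["P"]).f_measure)
            totals.append(len(truth))
            inf_totals.append(len(inferred))
            pool = {}
            for e in inferred:
                d = _descriptor(e)
                pool.setdefault(d, []).append(e)
            for e in truth:
                d = _descriptor(e)
                if pool.get(d):
                    pool[d].pop()
                    sizes.append(e.size)
        rows.append(
            BenchmarkRow(
                x=x,
                events_per_branch=4 * x,
                replicates=replicates,
                mean_true_events=float(np.mean(totals)),
                mean_inferred_events=float(np.mean(inf_totals)),
                mean_f=float(np.mean(fs)),
                mean_strict=float(np.mean(stricts)),
                mean_relaxed=float(np.mean(relaxeds)),
                mean_strict_event_size=float(np.mean(sizes)) if sizes else 0.0,
                roundtrip_rate=float(np.mean(rts)),
            )
        )
    return rows
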