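"""Constrained gene-order evolution simulator with ground-truth event logs.

The generator builds a random annotated ancestral gene order and evolves it
along a phylogeny under the realistic-history model.  Ancestral genomes are
assembled unit by unit until a fixed gene count ``n`` is reached (the last
unit is truncated to hit ``n`` exactly): a unit is a singleton with
probability ``prob_s``, otherwise an operon whose size is geometric with
parameter ``p_op`` (support 1, 2, ...; mean ``1/p_op``).  Genes are drawn
uniformly from the rRNA/tRNA alphabet; the terminus is placed at the unit
boundary nearest ``n/2`` genes and units point away from the origin (leading
strand: +1 before the terminus, -1 after).

Event sizes are geometric with parameter ``p_event``, truncated to the legal
extent.  The generator never breaks an operon apart with a rearrangement,
only simulates inversions flanking a replication axis, and turns every
cross-axis copy or move into its inversed/reversed variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from operonevo.coords import canonicalize_events
from operonevo.model import (
    DELETION,
    DUPLICATION,
    GENE_ALPHABET,
    INVERSED_DUPLICATION,
    INVERSION,
    OPERON,
    REVERSED_TRANSPOSITION,
    SINGLETON,
    SUBSTITUTION,
    TRANSPOSITION,
    ANTICODONS,
    Event,
    Gene,
    GeneOrder,
    Unit,
    _apply_inplace,
    is_realistic,
)
from operonevo.phylo import Phylogeny

__all__ = ["SimParams", "SimulatedDataset", "generate_root", "simulate_branch", "simulate_tree"]

_TRNA = sorted(ANTICODONS)
_MAX_TRIES = 40


@dataclass
class SimParams:
    """Generator settings; the defaults are the study conditions for a
    Bacillus-like genus (ancestral genome of 120 rRNA/tRNA genes, mean operon
    size 8, singleton probability 0.35, short events)."""

    n: int = 120
    p_op: float = 0.125
    prob_s: float = 0.35
    p_event: float = 0.7
    events_per_branch: int | None = None  # plain per-branch count (types cycled)
    x_recipe: int | None = 1  # x copies each of dup/del/transposition/substitution
    cherry_inversion: bool = True  # one inversion on a random branch of each cherry
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.p_op <= 1 and 0 < self.p_event <= 1):
            raise ValueError("geometric parameters must lie in (0, 1]")
        if not (0 <= self.prob_s <= 1):
            raise ValueError("prob_s must lie in [0, 1]")
        if self.n <= 0:
            raise ValueError("ancestral gene count must be positive")


def _random_gene(rng: np.random.Generator, sign: int) -> Gene:
    cls, ac = GENE_ALPHABET[rng.integers(len(GENE_ALPHABET))]
    return Gene(cls, ac, sign)


def generate_root(params: SimParams, rng: np.random.Generator, genome_id: str = "root") -> GeneOrder:
    """Random annotated ancestral gene order of (at least) ``params.n`` genes.

    Units are appended until the gene count reaches ``n``; the final unit is
    kept whole, so the genome may slightly overshoot ``n`` (truncating it
    would depress the realized operon-size distribution below its nominal
    geometric mean).
    """
    sizes: list[tuple[str, int]] = []
    total = 0
    while total < params.n:
        if rng.random() < params.prob_s:
            kind, size = SINGLETON, 1
        else:
            kind, size = OPERON, int(rng.geometric(params.p_op))
        sizes.append((kind, size))
        total += size

    # terminus at the unit boundary nearest half the genome
    cum = 0
    best_b, best_d = 1, float("inf")
    for b, (_, size) in enumerate(sizes, start=1):
        cum += size
        d = abs(cum - total / 2)
        if d < best_d and 1 <= b <= len(sizes) - 1:
            best_b, best_d = b, d

    units = []
    for idx, (kind, size) in enumerate(sizes):
        sign = 1 if idx < best_b else -1
        units.append(Unit(kind, [_random_gene(rng, sign) for _ in range(size)]))
    order = GeneOrder(genome_id, units, best_b)
    order.validate()
    return order


# ---------------------------------------------------------------------------
# Event construction
# ---------------------------------------------------------------------------


def _geom(rng: np.random.Generator, p: float, cap: int) -> int:
    return min(int(rng.geometric(p)), cap)


def _insertion_loci(g: GeneOrder) -> list[tuple]:
    loci: list[tuple] = [("new", b) for b in range(len(g.units) + 1)]
    for u, unit in enumerate(g.units):
        if unit.kind == OPERON:
            loci += [("in", u, off) for off in range(len(unit.genes) + 1)]
    return loci


def _locus_replichore(g: GeneOrder, locus: tuple) -> int:
    if locus[0] == "in":
        return g.replichore(locus[1])
    b = locus[1]
    if b < g.terminus:
        return 1
    if b > g.terminus:
        return 2
    return 0  # exactly at the terminus: counts as either side


def _make_duplication(g: GeneOrder, p_event: float, rng: np.random.Generator) -> Event | None:
    flat = g.flat_genes()
    start = int(rng.integers(len(flat)))
    u, off = g.unit_of_flat(start)
    unit = g.units[u]
    size = _geom(rng, p_event, len(unit.genes) - off)
    whole = off == 0 and size == len(unit.genes)
    src_sign = unit.orientation
    src_rep = g.replichore(u)
    loci = _insertion_loci(g)
    for _ in range(_MAX_TRIES):
        locus = loci[rng.integers(len(loci))]
        dst_rep = _locus_replichore(g, locus)
        crossing = dst_rep != 0 and dst_rep != src_rep
        src_genes = unit.genes[off : off + size]
        if crossing:
            content = [Gene(x.identity_class, x.anticodon, -x.sign) for x in reversed(src_genes)]
            etype = INVERSED_DUPLICATION
        else:
            content = [x.clone() for x in src_genes]
            etype = DUPLICATION
        if locus[0] == "in":
            host = g.units[locus[1]]
            if content[0].sign != host.orientation:
                continue  # co-transcription: strands must agree; resample the locus
            target = ("in", locus[1], locus[2])
        else:
            kind = unit.kind if whole else (SINGLETON if size == 1 else OPERON)
            target = ("new", locus[1], kind)
        return Event(
            etype,
            None,
            size,
            {"target": target, "content": content, "source": (start, size, etype == INVERSED_DUPLICATION)},
        )
    return None


def _make_deletion(g: GeneOrder, p_event: float, rng: np.random.Generator) -> Event | None:
    for _ in range(_MAX_TRIES):
        flat_n = g.n_genes
        start = int(rng.integers(flat_n))
        u, off = g.unit_of_flat(start)
        unit = g.units[u]
        size = _geom(rng, p_event, len(unit.genes) - off)
        if off == 0 and size == len(unit.genes):
            if len(g.units) <= 2:
                continue  # keep both axis markers placeable
            return Event(
                DELETION,
                None,
                size,
                {"target": ("whole", u), "content": [x.clone() for x in unit.genes], "kind": unit.kind},
            )
        if size >= len(unit.genes):
            continue
        return Event(
            DELETION,
            None,
            size,
            {"target": ("in", u, off), "content": [x.clone() for x in unit.genes[off : off + size]]},
        )
    return None


def _make_inversion(g: GeneOrder, p_event: float, rng: np.random.Generator) -> Event | None:
    t, n = g.terminus, len(g.units)
    # the four axis-flanking anchors: (max_extent, span builder)
    anchors = [
        (t, lambda m: (0, m)),  # right of the origin
        (n - t, lambda m: (n - m, n)),  # left of the origin
        (t, lambda m: (t - m, t)),  # left of the terminus
        (n - t, lambda m: (t, t + m)),  # right of the terminus
    ]
    for _ in range(_MAX_TRIES):
        extent, builder = anchors[rng.integers(4)]
        if extent < 1:
            continue
        m = _geom(rng, p_event, extent)
        return Event(INVERSION, None, m, {"span": builder(m)})
    return None


def _make_transposition(g: GeneOrder, p_event: float, rng: np.random.Generator) -> Event | None:
    t, n = g.terminus, len(g.units)
    for _ in range(_MAX_TRIES):
        s = int(rng.integers(n))
        cap = (t - s) if s < t else (n - s)
        m = _geom(rng, p_event, cap)
        e = s + m
        dests = [d for d in range(n - m + 1) if d != s]
        if not dests:
            continue
        d = dests[rng.integers(len(dests))]
        src_rep = 1 if e <= t else 2
        t_after = t - m if e <= t else t
        dst_rep = src_rep if d == t_after else (1 if d < t_after else 2)
        etype = REVERSED_TRANSPOSITION if dst_rep != src_rep else TRANSPOSITION
        return Event(etype, None, m, {"span": (s, e), "dest": d})
    return None


def _make_substitution(g: GeneOrder, rng: np.random.Generator) -> Event | None:
    trna = [
        (u, off)
        for u, unit in enumerate(g.units)
        for off, gene in enumerate(unit.genes)
        if gene.is_trna
    ]
    if not trna:
        return None
    for _ in range(_MAX_TRIES):
        u, off = trna[rng.integers(len(trna))]
        gene = g.units[u].genes[off]
        within = rng.random() < 0.5 and len(ANTICODONS[gene.identity_class]) > 1
        if within:  # anticodon change preserving the identity class
            choices = [a for a in ANTICODONS[gene.identity_class] if a != gene.anticodon]
            to_value = (gene.identity_class, choices[rng.integers(len(choices))])
        else:  # identity class reassignment
            cls = _TRNA[rng.integers(len(_TRNA))]
            if cls == gene.identity_class:
                continue
            acs = ANTICODONS[cls]
            to_value = (cls, acs[rng.integers(len(acs))])
        return Event(
            SUBSTITUTION,
            None,
            1,
            {"position": (u, off), "from_value": gene.value(), "to_value": to_value},
        )
    return None


_MAKERS = {
    DUPLICATION: lambda g, p, rng: _make_duplication(g, p, rng),
    DELETION: lambda g, p, rng: _make_deletion(g, p, rng),
    INVERSION: lambda g, p, rng: _make_inversion(g, p, rng),
    TRANSPOSITION: lambda g, p, rng: _make_transposition(g, p, rng),
    SUBSTITUTION: lambda g, p, rng: _make_substitution(g, rng),
}


def simulate_branch(
    parent: GeneOrder,
    recipe: list[str],
    p_event: float,
    rng: np.random.Generator,
    branch_id: str,
) -> tuple[GeneOrder, list[Event]]:
    """Evolve one branch; returns the child and the truth log in descendant coordinates."""
    g = parent.clone()
    g.genome_id = branch_id
    truth: list[Event] = []
    order = list(rng.permutation(len(recipe)))
    for idx in order:
        etype = recipe[idx]
        ev = _MAKERS[etype](g, p_event, rng)
        if ev is None:
            continue  # unconstructible under the current genome; skip
        ev.branch = branch_id
        ok, reason = is_realistic(ev, g)
        if not ok:  # defensive; constructors should only emit realistic events
            raise AssertionError(f"simulator produced an unrealistic event: {reason}")
        _apply_inplace(g, ev)
        truth.append(ev)
    child, truth = canonicalize_events(parent, truth)
    child.genome_id = branch_id
    return child, truth


@dataclass
class SimulatedDataset:
    tree: Phylogeny
    orders: dict[str, GeneOrder]  # every node, ancestors included
    truth: dict[str, list[Event]]  # branch (child id) -> events
    params: SimParams = field(default_factory=SimParams)

    def leaf_orders(self) -> dict[str, GeneOrder]:
        return {n.name: self.orders[n.name] for n in self.tree.leaves()}

    def total_events(self, branches: list[str] | None = None) -> int:
        keys = branches if branches is not None else list(self.truth)
        return sum(len(self.truth[b]) for b in keys)


def simulate_tree(
    tree: Phylogeny, params: SimParams, rng: np.random.Generator | None = None
) -> SimulatedDataset:
    """Generate a root, evolve every branch, and log the ground truth.

    Each branch receives the recipe (either ``x_recipe`` copies of each of
    duplication, deletion, transposition and substitution, or a plain count
    of ``events_per_branch`` cycled over those four types), in a random
    order.  With ``cherry_inversion``, one inversion is additionally placed
    on a uniformly chosen branch of each cherry.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if params.events_per_branch is not None:
        base_types = [DUPLICATION, DELETION, TRANSPOSITION, SUBSTITUTION]
        recipe = [base_types[i % 4] for i in range(params.events_per_branch)]
    else:
        x = params.x_recipe or 0
        recipe = [DUPLICATION, DELETION, TRANSPOSITION, SUBSTITUTION] * x

    inversion_branches: set[str] = set()
    if params.cherry_inversion:
        for cherry in tree.cherries():
            pick = cherry.children[int(rng.integers(2))]
            inversion_branches.add(pick.name)

    root_order = generate_root(params, rng, genome_id=tree.root.name)
    orders = {tree.root.name: root_order}
    truth: dict[str, list[Event]] = {}
    for parent, child in tree.branches():
        branch_recipe = list(recipe)
        if child.name in inversion_branches:
            branch_recipe.insert(int(rng.integers(len(branch_recipe) + 1)), INVERSION)
        child_order, events = simulate_branch(
            orders[parent.name], branch_recipe, params.p_event, rng, child.name
        )
        orders[child.name] = child_order
        truth[child.name] = events
    return SimulatedDataset(tree, orders, truth, params)
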