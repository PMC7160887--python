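# Methods

This note records the model, the algorithmic and numerical choices, and the
limits of what the simulated validation shows. It is written for a reader
who wants to know exactly what the code computes and why the open design
points were settled the way they were.

## Representation

A `GeneOrder` stores the circular genome linearized immediately after the
origin of replication: boundary 0 (equivalently, boundary `len(units)`) is
the origin, and the terminus is another inter-unit boundary index.
Circularity is confined to this convention (`linearize` validates and
reports it); everything downstream works on the linear view. The terminus
may sit at boundary 0's circular neighbor (index 0 or `len(units)`): that is
a genome whose rRNA/tRNA units all lie on one replichore, which event
sequences can legitimately produce by deleting every unit on one side.

Units store their genes in genome (circle) order, with the unit orientation
equal to the shared strand sign. The promoter-first *reading* of a unit
(`Unit.reading()`) reverses the gene list for reverse-strand units. The
reading is invariant under inversion — reversing genome order and flipping
strand preserves transcription order — which has a useful consequence: a
single reading-order alignment covers both orientations of an operon pair,
and strand divergence is carried entirely by the unit-level `flipped` flag.
The order-reversed alignment is still computed in the within-genome paralog
search, where it detects inversed whole-operon duplications.

Genes compare by value (identity class, anticodon, strand); a provenance tag
`restored_from` marks genes placed back into an ancestor by undoing a
deletion and is excluded from equality.

## Events and replay

Events carry application-frame parameters (insertion loci, spans,
destination boundaries) that make a branch history an executable program:
applying the ordered event list to the parent genome reproduces the child
exactly, and each event is individually invertible. Two bookkeeping details
make the replay exact:

* Whole-unit deletions and transpositions record which side of the terminus
  the affected block occupied, because an insertion landing exactly on the
  terminus boundary is otherwise ambiguous.
* The child's terminus boundary is stored on the branch record and restored
  after replay. Inferred rearrangement events recover the unit order
  exactly, but the marker's position between two specific units is not
  always recoverable from the events alone (e.g. after units flanking the
  terminus were inserted or removed), so the history keeps it explicitly.

For evaluation, every event additionally receives a canonical descriptor in
descendant (branch-end) coordinates: the flat positions of the genes it
created, replaced or moved — resolved by tracking gene objects through the
replay — or, for deletions, the deleted gene content plus the flat boundary
where the genes would be re-inserted, resolved through the surviving
flanking genes. Simulated and inferred events go through the same
canonicalizer, so the two sides are compared in the same frame.

## Realism predicates

`is_realistic` enforces: operon-confined segmental duplications/deletions;
whole-unit rearrangements that never straddle the terminus; inversions
immediately flanking the origin or the terminus; and plain transpositions
that stay within their replichore (a cross-axis move must be a reversed
transposition). Two deliberate softenings:

* A reversed transposition is *not* required to cross an axis. The
  generative rule is "cross-axis moves are reversed", but detection can meet
  flipped segments in mid-replichore (stacked events moving a previously
  inverted unit), and the dot-plot classification labels these reversed
  transpositions; requiring crossing would make the inference's own output
  invalid.
* Duplications are not axis-checked against their source: after several
  events the replichore of a detected source interval in the descendant
  frame says little about the replichore at copy time. The inversed/plain
  distinction is instead driven by whether the copy matches its source
  forward or order-reversed.

Duplication-source matching compares gene content (class and anticodon) and
ignores signs: within a unit all signs equal the orientation, so the sign
pattern adds no information once orientation is handled at the unit level
(the same reason signs are excluded from alignment scoring).

## Alignment and pairing

The alignment kernel is the textbook global dynamic program with scores
full +1, partial +0.5, mismatch −1, gap −1 and boundary `M[i,0] = −i`.
These constants are exposed (`Scoring`) with the ordering constraint
full > partial > mismatch = gap enforced. The traceback is deterministic:
on ties, diagonal, then the column consuming the first operon, then the
second. Pairing is greedy from the highest score down — not an optimal
assignment — with ties broken by index distance, then by smaller indices.
Singletons pair only when identical; a same-class/different-anticodon
singleton pair is *not* accepted, because the pairing rule for singletons is
defined by identity, and the partial-match notion belongs to the operon
alignment.

## Dot-plot segmentation

The "main diagonal" is formalized as the heaviest chain of forward runs: a
weighted longest-increasing-subsequence over maximal constant-slope runs in
rank space (ranks, not raw unit indices, so unpaired units do not break a
run), weight = dot count, ties toward the chain with the lower first index.
Flipped dots form slope −1 runs; a lone flipped dot inside a forward run is
its own segment. A flipped segment is an inversion if its unit span abuts an
axis in *either* genome — one-sided adjacency is accepted because a pairwise
comparison cannot tell which branch carries the event, and the axis
constraint holds in the genome that does.

## Branch assignment and ancestor construction

Rearrangement segments are assigned by re-detection: the first resolved
genome in the subtree sibling to the cherry's parent (depth-first,
left-first; leaves are always resolved) is compared against child X, and a
segment whose units are again non-conserved with the same flip status in
that comparison (majority vote over its units) is placed on the X branch,
otherwise on the Y branch. Without a neighbor every rearrangement falls on
the Y branch and substitutions keep the first child's state ancestral — a
fixed convention that keeps the output deterministic at a known cost in
branch accuracy. With a neighbor, substitution polarity uses gene content:
a state present in the neighbor but absent from the other child is taken as
ancestral.

The ancestor is assembled per orthologous pair from the alignment columns
(match and substitution columns contribute the ancestral state; deletion
gaps contribute the surviving child's gene, flagged `restored_from`;
duplication gaps contribute nothing), ordered by placing each branch-X
segment at its neighbor-implied (Y-side) location and leaving everything
else in X order, with units deleted on one branch anchored next to their
surviving neighbors. Each branch's replayable event list is then derived
against this ancestor: whole-unit deletions, then a block-sort into the
child's unit order (each emitted move/flip is a transposition, reversed
transposition or inversion event; orientation-mismatched units are never
anchored in the sort's backbone, so inverted blocks come out as single
events), then whole-unit duplications, then per-unit content scripts
(deletions right-to-left, duplications, substitutions). The construction
ends with a hard check that replay reproduces both children exactly; a
failure raises rather than returning a silently inconsistent history.

Nested events inside a duplicated paralogous operon (the "overlapping",
non-visible events) are recorded with `nested=True`: they describe the
copy's divergence from its paralog for event counting and accuracy, while
the whole-operon duplication event already carries the final copy content,
so replay skips them.

The deletion→duplication correction runs when a cherry ancestor is about to
be consumed by its parent's comparison: restored genes from *correctable*
size-1 deletions (an identical gene exists in the witnessing child — the
precondition that made the duplication alternative viable) that fall into a
gap column or are unmapped singletons trigger a re-inference of that cherry
with those gaps labelled duplications, shrinking the ancestor. One round
per cherry; the correction never cascades into already-consumed ancestors.

## Simulator

The generator's defaults are the study conditions: ancestral genome size
n = 120 genes, operon sizes geometric with p_op = 0.125 (support 1, 2, …,
mean 8), singleton probability prob_s = 0.35, event sizes geometric with
p_event = 0.7, and gene identities uniform over the 61 standard anticodons
plus the three rRNA subunits. Units are appended until the gene count
reaches n and the final unit is kept whole: truncating it would depress the
realized operon-size mean below the geometric mean (measured ≈ 7.6 against
a realized ≈ 8.0 when the last unit is kept), whereas the slight
size-biased overshoot reproduces the intended summary statistics (mean
operon size ≈ 8, ≈ 8 singletons and ≈ 15 operons per genome). The terminus
goes to the unit boundary nearest half the realized gene count, and units
point away from the origin (leading strand: +1 before the terminus, −1
after).

Branch recipes are x copies each of duplication, deletion, transposition
and substitution (or a plain count cycled over those types), shuffled, plus
one inversion inserted at a random position on one uniformly chosen branch
of each cherry. Event construction respects every model constraint by
sampling within legal extents; an event that cannot be constructed after
bounded retries (e.g. a whole-unit deletion that would leave fewer than two
units) is skipped. Substitutions change the anticodon within the identity
class or reassign the class with probability one half each. Cross-axis
copies and moves become inversed duplications and reversed transpositions;
a copy inserted into an operon must match the host strand, otherwise the
insertion locus is resampled.

What the simulator does *not* emulate: nucleotide sequences (the method
uses none beyond anticodons), horizontal transfer, branch-length-dependent
event counts, biased gene content (real genomes favor particular tRNA
families), and correlated event placement (hot spots). Passing the
simulated benchmarks therefore shows that the inference inverts the model's
own generative process at realistic densities — not that real genomes obey
the model.

## Metrics

Ancestor accuracy is a match/gap comparison (no mismatch columns): the
heaviest common subsequence under gene identity gives the matched columns
(TP); genes of the simulated ancestor missing from the inferred one are FN,
extra inferred genes FP; recall = TP/(TP+FN), precision = TP/(TP+FP), and F
is their harmonic mean (0 when nothing matches, 1 for two empty orders).

Strict event accuracy matches events one-to-one on (event class, branch,
canonical descriptor) — positions for visible events, content plus
re-insertion locus for deletions; duplication sources are ignored, and the
inversed/reversed variants count in their base class (duplication,
transposition), matching how event classes are reported. Relaxed accuracy
asks, per gene affected by a simulated event, whether some inferred event of
the same class on the same branch covers it; deleted genes are covered by a
same-branch deletion containing the gene at an overlapping locus, so a
block deletion recovered in pieces scores fully relaxed but zero strict.

The benchmark driver simulates triplets, infers with (or without) the
neighbor, and reports per setting the mean inferred/true event counts,
ancestor F, strict and relaxed accuracies, the mean size of
strictly-recovered events, and the replay round-trip rate. The shipped
configuration uses 25 replicates per setting at x = 1..8 — enough for the
means to stabilize to a couple of percent while keeping a full run in the
tens of seconds on one CPU.

## Annotation

Axis placement uses the cumulative GC skew: per-window (G−C)/(G+C), summed;
the minimum marks the origin, the maximum the terminus; window default is
1/500 of the sequence. Cumulative rather than instantaneous skew because
the extrema of the integral are the standard, noise-robust realization of
the skew–origin correlation. A zero-GC window contributes zero skew. The
result is flagged low-confidence when the cumulative amplitude is below
twice its random-walk scale (2·sd·√windows), as on a compositionally
unpolarized sequence. Operon grouping merges consecutive same-strand genes
with an intergenic gap ≤ 200 bp (gap = next.start − prev.end − 1 on the
circle); the same-strand requirement is added to the distance rule because
opposite-strand genes cannot share a promoter. Merging wraps around the
circle, making the grouping rotation-invariant; the axis markers then go to
the nearest inter-unit boundary (midpoint of the intergenic interval), with
a warning when a computed axis falls inside a gene. Annotation never
produces single-gene operons; operons reduced to one gene *by events* keep
their kind for orthology bookkeeping.

## Known limitations

* Greedy pairing and greedy strict matching are not optimal assignments;
  both follow the stated highest-score-first rules for determinism.
* The no-neighbor convention concentrates rearrangements and substitution
  derivations on one branch; accuracy in that mode is correspondingly lower
  (quantified by the benchmark's `use_neighbor=False` arm).
* The deletion→duplication correction runs one round per cherry and cannot
  revise ancestors that have already been consumed upstream.
* Nesting of overlapping events is depth 1: events inside a duplicated
  operon are themselves plain duplications/deletions/substitutions.
* Per-cherry complexity is quadratic in gene count (alignment of all operon
  pairs dominates); genomes of a few hundred rRNA/tRNA genes process in
  seconds, and nothing in the implementation targets chromosome-scale gene
  sets.
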