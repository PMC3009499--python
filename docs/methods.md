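# Methods

## Model and decoding problem

A discrete-emission HMM with one silent start state `I`: transition
probabilities `a_ij`, per-state emission distributions `b_i(c)` over a
finite alphabet, and a label per state.  A path `π_0 = I, π_1 … π_n` emits
`x_1 … x_n` with joint probability `∏_t a_{π_{t-1}π_t} b_{π_t}(x_t)`,
optionally times a terminal weight for `π_n`.  By default every state may
end a path with weight 1; models that need explicit termination carry an
`ENDS` section whose weights are included in the row-stochasticity check.
Silent states other than `I`, parameter estimation and posterior decoding
are out of scope.

All arithmetic is in natural-log space; probability zero is `-inf`.
Sequence positions are 1..n user-facing (0 is the silent start) and
0-based half-open internally; every interval in an output file is 1-based
inclusive.

## The tie rule

Distinct paths can have exactly equal probability — not merely as a float
coincidence but systematically: in a model whose modules repeat (the same
loop or helix state visited twice), moving a self-loop residue from one
visit to another multiplies and divides the joint probability by identical
factors whenever the boundary symbols coincide.  Every decoder therefore
applies one global rule: equal-probability paths are ordered by
lexicographic comparison of their state-index sequences (lower index in the
model's state order wins).  This makes all engines bit-comparable and every
output deterministic.

## The two engines

**Naive matrix engine** (`kbest_naive`).  Each of the `(n+1)·m` cells keeps
its k best ranked scores and `(predecessor state, predecessor rank)`
backpointers; a position is processed as one vectorised candidate-matrix
update (numpy argsort per state).  Exact score ties are detected by
comparing adjacent sorted candidates and resolved with the lexicographic
rule; to make that cheap even when ties are pervasive, the engine also
carries the materialised state-index prefixes of the current frontier
(a `(m, k, n)` uint8 array), so a tie comparison is one `bytes`
comparison.  Space is Θ(k·m·n) by construction; the engine doubles as the
reference implementation.

**Compressed-tree engine** (`kbest_tree`).  Probabilities are computed
exactly as above but per state via the heap-based `merge_candidates` —
the first k steps of a |Pred|-way mergesort of the predecessors' sorted
lists, each scaled by `a_cv·b_v(x_i)`; candidates tied with the k-th score
are pulled from the heap so the tie rule sees the whole cluster.  (The
ℓ-th-best recurrence is stated here operationally, as this merge.)
Backpointers live in a two-level structure: *path nodes* (one per live
`(i, j, a)`) with a parent pointer and child counter, and *state nodes*
aggregating the ranks of one `(i, j)` into runs of states.  After every
position: prune (old-frontier path nodes with zero children are removed,
cascading to orphaned ancestors; a state node without path nodes dies),
then compress (merge child into parent when the parent is the child's only
parent and the child is the parent's only child, concatenating runs and
splicing the parent's path nodes out of the chains).  The virtual root —
the start state at position 0 — never merges.  In this design a new path
node's parent is always a frontier node at position i−1 (merging keeps the
child's path nodes), so `parent.pos == owner.start − 1` is an audited
invariant.  Recovery takes the global top-k of the `k·m` frontier scores
(terminal weights applied) and expands state runs by walking parents.

Memory is instrumented as live node counts, not bytes — byte footprints
are runtime-specific — and compared against the `k·m·(n+1)` cell count of
the matrix.  A switchable audit (`audit=True`) recounts every counter,
recomputes reachability from the frontier and verifies that no mergeable
pair remains, after every position; it changes the asymptotic cost and is
off by default.

Both engines compute each candidate score as
`predecessor_score + (log a + log b)` with identical association, so their
outputs agree bitwise, ties included; the independent correctness oracle in
the tests is brute-force enumeration of all paths.

## From k paths to an answer

Paths are grouped by *topology* — the pair (helix count, sidedness), where
sidedness is the label of position 1 and a labelling that begins mid-helix
gets the dedicated value `membrane-start`.  Helix boundary positions do not
split groups.  Group weight is the sum of members' conditional
probabilities `exp(log P(π, x) − log P(x))` with the forward total as the
denominator.

Consensus methods over a group:

* **boundary-average** — per helix ordinal, the mean member start/end on
  1-based inclusive coordinates, rounded half away from zero.  If rounding
  makes helices collide, boundaries shift right by the minimal amount (with
  a backward pass keeping everything inside the sequence); non-membrane
  segments take the labels observed in the members.  The output's topology
  provably equals the group key — this method never produces an
  inconsistent labelling, and the test suite asserts it on every group it
  ever builds.
* **position-vote** — per position, the label with the largest summed
  conditional probability (ties by label order).  May be inconsistent with
  the model; the result carries a `consistent` flag computed by a
  constrained reachability sweep (is there a positive-probability state
  path with exactly this labelling for this sequence?), and is never
  repaired.
* **helix-vote** — per helix ordinal, the modal (start, length) pair by
  summed weight (ties by the smaller pair); same flag, no repair.

The confidence report records the total conditional mass of the top k
paths, its band (`< 0.01`, `0.01 - 0.5`, `0.5 - 1` — the bands partition
[0, 1]), and whether all paths agree on the helix count.  Dual-topology
exploration returns the g heaviest groups (default 2) each with its
boundary-average consensus, flagged when fewer groups exist.

Two correctness measures compare a predicted topology against a reference,
pairing helices ordinally: the *overlap measure* requires the same topology
and ≥ 5 shared positions per helix pair; the *τ-tolerance measure* requires
every helix boundary within τ residues.  τ-correctness is monotone in τ by
construction.

## Synthetic data

The generators are the package's only data source; everything is a pure
function of its seed (one `numpy.random.default_rng` stream each).

**Random models** (`random_hmm`): reachability is guaranteed by giving each
state an incoming edge from the start or an earlier state and at least one
outgoing edge; extra edges appear with the spec's `sparsity` density;
all row weights are Dirichlet(1).  These drive the cross-engine and oracle
comparisons.

**Membrane fixture** (`toy_membrane_hmm`, 12 states): inside loop (2 dwell
states, mean length 11, charged-biased emissions), in→out helix (entry +
2 dwell + exit, minimum 4, mean 22, hydrophobic), outside loop (2 dwell
states, mean 14, polar-biased), out→in helix (mean 22), cycling.  Design
choices that matter:

* Helix and loop lengths come from short chains of self-looping states
  rather than single geometric states: real membrane-spanning helices are
  ~15–30 residues and loops of 1 residue do not occur, and a decoder cannot
  be expected to recover features the length model itself calls freak
  events.
* All eight dwell self-loop probabilities are pairwise distinct, so moving
  a dwell residue between states always changes the path probability —
  without this, dwell allocations tie exactly and the top-k collapses onto
  combinatorial rearrangements of one labelling.
* Emission distributions on the 4-class alphabet are strongly separated
  (helix h=0.80 vs loop h≤0.07; inside charged-rich, outside polar-rich),
  so helix count and sidedness are both recoverable from sequence alone.

What the fixture does *not* emulate: real amino-acid composition (20
letters, position-specific helix profiles), signal peptides, re-entrant
loops, and length distributions learned from data.  Passing tests on this
fixture demonstrate the decoding and consensus machinery under a
well-specified generative model, not predictive performance on real
proteins.

**Mirror fixture** (`mirror_hmm`, 24 states): two copies of the membrane
model, entered with probability ½ each, the second with inside/outside
labels exchanged; emissions and internal transitions are copied, so the
copy swap is a model automorphism and every path has an equal-probability
mirror twin of opposite sidedness — the dual-topology situation in
miniature.  The dual-topology runs use n=40 and k=32: the exact pairing of
the top-k requires the rank-k boundary to sit where paths traverse at most
one membrane cycle, because deeper-ranked paths revisit states and their
within-copy relocation ties form 4-way tie clusters that any deterministic
tie rule must cut asymmetrically if the boundary lands inside one.

## Problem sizes and numerics

The shipped study conditions: 500 random instances (m ≤ 8, n ≤ 50,
k ≤ 64) for engine equivalence, with every fifth instance enumeration-sized
(m ≤ 4, n ≤ 8) for the brute-force oracle; compression measured on one
n=2000, k=100 membrane-model decode with audits at every position; 200
replicates of n=300, k=100 for topology recovery; 200 decodes of n=150,
k=50 for consensus consistency; 50 mirror sequences for dual-topology
symmetry.  Tolerances: probability comparisons at 1e-9 absolute in log
space; recomputed path scores at 1e-12; normalisation checks at 1e-9.
Degenerate inputs: an empty sequence is an error; a sequence no path can
emit yields an empty result (k'=0), not an exception; `viterbi` returns
`None` in that case.

`viterbi` is the k=1 case of the naive engine rather than a third DP:
a backward-argmax implementation cannot reproduce the front-lexicographic
tie rule under exact ties, and the rule must be identical across decoders.
Its independent check is the enumeration oracle, like the k-best engines.

## Known limitations

* The naive engine supports at most 255 states (uint8 prefix rows); the
  tree engine has no such limit.
* `merge_candidates` reconstructs tied paths through parent walks in the
  tree engine; adversarial models consisting almost entirely of exact ties
  degrade it toward O(n) per comparison (the naive engine's byte-prefix
  representation does not suffer from this).
* Group weights use conditional probabilities, which requires one forward
  pass per sequence; for very long sequences this doubles decode cost.
* The boundary-average repair guarantees topological consistency but can,
  in principle, place averaged boundaries up to a few residues away from
  any member's boundary when members disagree wildly.
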