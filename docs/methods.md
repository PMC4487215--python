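# Methods

## Problem and model

Two species' PPI networks are undirected simple graphs over opaque
protein identifiers. A *conserved protein complex* is modelled as a
solution: a pair of protein sets (ModuleOne ⊆ network one,
ModuleTwo ⊆ network two) joined by sequence-supported homologous
mappings, such that the whole unit is connected through within-network
paths and cross-network links. The method assumes protein complexes are
the conserved unit of interactome evolution, that homology seeds
(bidirectional BLAST hits) are sparse and noisy, and that interaction
data is incomplete — hence indirect paths must be allowed when deciding
whether two candidate members are "connected".

## Homology seeding

A cross-network pair is a *real* mapping when both directional E-values
are strictly below the cutoff (default 10⁻⁹) and both proteins occur in
their networks; these pairs form the binary seed matrix **A**. The mean
E-value (E_ab + E_ba)/2 is retained as a diagnostic similarity only —
no downstream stage weights by it, because admission decisions are
binary in the detection procedure. A record missing the reverse
direction fails the cutoff (the mean needs both directions). The cutoff
is strict (<), applied independently to both directions.

## Unbalanced bi-random walk

With **P** the row-normalized adjacency of network one and **H** the
column-normalized adjacency of network two (isolated nodes give zero
rows/columns), the mapping matrix is iterated for t = 1..max(l, r):

    R_t = α · (λ_p(t)·P·R_{t−1} + λ_h(t)·R_{t−1}·H) / (λ_p(t)+λ_h(t))
          + (1−α) · A,      R_0 = A

with λ_p(t) = 1 iff t ≤ l and λ_h(t) = 1 iff t ≤ r. The update
equations of the walk are stated here explicitly as this package's
fixed reconstruction of the two-sided propagation-with-regularization
scheme; the convex form guarantees 0 ≤ R ≤ 1 for binary A and keeps
seeded pairs anchored at every step. Two deliberate properties:

- **No convergence test.** The iteration count is exactly max(l, r):
  the walk is short-range by design, in contrast to global aligners
  that iterate to an eigenvector fixed point. No re-normalization is
  applied between steps.
- **Support locality.** R(i,j) > 0 only if some seed (i₀,j₀) lies
  within graph distance l of i in network one and r of j in network
  two. This is asserted against a brute-force distance oracle in tests.
- The indicator semantics are t ≤ l (so l = 2 means two propagation
  steps), which makes l = r = 2 reproduce the common two-step leniency.

Positive R entries without an A entry are *artificial* mappings; any
positive mass qualifies by default (`artificial_mapping_min = 0`,
configurable).

## Partitioning

Network one is divided either by a complex catalogue (memberships
intersected with the network; empty intersections dropped; order
preserved) or by the bundled minimal Markov clustering: column-stochastic
adjacency with unit self-loops, expansion by squaring, inflation 2.0
with column renormalization, iterated to a 10⁻⁶ max-norm fixed point,
clusters read from attractor supports (merged when attractor systems
overlap). Any external clustering plugs in through the catalogue file
format. Singleton clusters are retained.

## Detection steps

**Step 1 (grow).** For subnetwork members u, v joined by a path of
length ≤ l in network one (paths may leave the subnetwork), the pair is
admissible when they share a mapped partner under R and either

(a) some shared partner is really matched (per A) to u or v, or
(b) two distinct shared partners are each really matched to subnetwork
    members outside u, v and u's bounded neighborhood (the "other"
    proteins are required to be subnetwork members — the natural reading
    that keeps the rule decidable within the division).

Growth is connected and deterministic: it starts from the
lexicographically smallest member participating in any admissible pair
and absorbs members reachable through admissible pairs. Only really
matched partners enter ModuleTwo (artificial mappings may *witness*
sharing but never contribute members). A singleton subnetwork
degenerates to the node plus its real homologs. Pair admissibility
depends only on R, A and the subnetwork, so the result does not depend
on traversal order.

**Step 2 (refine).** Each ModuleTwo node is weighted by its summed R
score to ModuleOne. ModuleTwo splits into components under depth-r
bounded connectivity, where connecting paths may traverse intermediate
nodes anywhere in network two (consistent with the leniency that
admitted them). Components of size ≥ 2 survive and mark their ModuleOne
counterparts covered. A singleton whose counterparts are all covered is
dropped; singletons competing for an uncovered counterpart keep only
the highest weight, ties broken to the smallest identifier.

**Step 3 (attach).** A subnetwork member outside ModuleOne re-enters
when its true homolog is already in ModuleTwo, or reaches ModuleTwo by
a path of length ≤ r (then the homolog joins ModuleTwo). Finally,
members of either module with no A-link into the other module are
discarded, iterated to a fixed point, and the surviving links are
recorded with the solution. Note the attached member need not touch
ModuleOne in network one: the emitted solution is connected as a
*combined* unit (within-network bounded paths plus homology links), and
that is the connectivity invariant the tests assert.

**Role reversal.** The procedure repeats with the networks swapped
(l ↔ r, R and A transposed) over network two's subnetworks; those
solutions are side-swapped back so ModuleOne always holds network-one
proteins.

**Step 4 (filter).** A solution is removed iff some retained solution
has a *strictly larger* network-one complex with OS > t (default 0.8).
Candidates are processed in descending |ModuleOne| (ties: descending
|ModuleTwo|, then smallest member) so dominators are settled before
their victims; equal-size duplicates are both retained by the strict
rule and collapse later in the distinct-complex accounting, which drops
exact duplicates and complexes of fewer than two proteins.

## Evaluation

A prediction matches a known complex iff OS ≥ 0.2. Precision =
MPC/PC, recall = MKC/known_total, F their harmonic mean (0 when PC = 0),
CR = Σᵢ maxⱼ |KCᵢ ∩ Pⱼ| / Σᵢ |KCᵢ|. One prediction may match several
known complexes; a known complex counts once regardless of how many
predictions hit it. The recall denominator is an explicit, logged
parameter (default: catalogue size) because published catalogues are
routinely filtered before use and the filtering is rarely stated.

Functional relevance uses Resnik similarity on the biological-process
DAG: p(term) is the descendant-closed annotation count over annotated
proteins in the corpus, IC = −ln p (natural log, the standard choice),
term similarity is the IC of the most informative common ancestor
(is_a/part_of ancestors), protein similarity the max over annotation
term pairs, with unannotated proteins scoring 0 (flagged). Solution
averages (mixed / within each module / cross-network only) are
unweighted means over solutions; single-protein modules contribute no
within-average. Cross-species term pairs take IC from the first
annotation set's corpus; for strict comparability build one pooled
annotation set over both species' GAF files and pass it as both
arguments.

## Synthetic benchmark

The generator emulates what the method needs to see: modular networks,
noisy mirroring, many-to-many maps. Each planted module is connected by
construction (random spanning path) plus pair edges at
`intra_edge_prob = 0.9`; the mirror keeps each edge with probability
1 − `edge_rewire_rate` and replaces the rest with random in-module
pairs; true pairs get E-values of 10⁻⁵⁰ both ways minus an exact
`homolog_dropout` fraction; `duplicate_rate` of network-two module
members are copied with identical edges and homology links; both sides
receive `background_nodes = 40` extra proteins with Erdős–Rényi edges
at 0.01. Defaults are the benchmark conditions exercised throughout:
10 complexes, sizes 4–8, dropout 0.1, rewire 0.1.

What the generator does **not** emulate: scale-free degree
distributions, realistic sequence evolution (E-values are labels, not
alignments), correlated false-positive interactions, or overlapping
complexes. Passing the benchmark therefore demonstrates the machinery
is correct under the model's own assumptions, not performance on real
interactomes.

## Numerical and degenerate-input choices

- Sparse (CSR) matrices throughout the walk; the dense recurrence is
  allowed only as the test oracle. Agreement is asserted to 10⁻¹².
- Walk entries below machine-zero are eliminated after iteration; MCL
  prunes below 10⁻¹² and reads attractors above 10⁻⁹.
- Empty networks, empty seed tables, empty subnetwork lists and empty
  solutions all flow through as empty results, not errors; domain
  errors are reserved for genuinely invalid parameters (α ∉ (0,1),
  t ∉ (0,1], inflation ≤ 1, negative E-values, empty sets in OS).
- All traversal orders, tie-breaks and output orders are deterministic
  (lexicographic), so identical configurations produce byte-identical
  outputs.

## Problem sizes

The test suite and the acceptance script run on instances chosen to
exercise every code path at interactive speed: walk-oracle agreement on
100 random ≤10-node network pairs across all (l, r) ∈ {0..3}²,
connectivity against an all-pairs oracle on 50 random 12-node graphs,
and the full pipeline on the 10-complex benchmark (~100 proteins per
network). The pipeline is sparse end to end and scales to real
interactome sizes, but the published-scale datasets (DIP/HIPPIE-sized
networks with CYC2008/CORUM catalogues) are deliberately out of scope
here.

## Known limitations

- The growth step admits pairs, so a subnetwork whose admissible pairs
  split into several components yields only the component containing
  the smallest participating member; the others are reachable by
  re-running on a refined division.
- Recall against published tables depends on an unknowable catalogue
  filtering; the denominator is exposed rather than guessed.
- MCL here is minimal (dense arrays, no sparse pruning schedule); it is
  intended for moderate networks and as the built-in default, not as a
  replacement for a tuned MCL implementation on very large graphs.
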