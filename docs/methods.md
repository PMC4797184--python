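# Methods

## Graphs and conventions

All analyses operate on undirected simple graphs with string node labels.
Input edge lists are deduplicated and self-loops dropped (interaction
exports routinely contain self-interactions, but every statistic here
assumes a simple graph).  Node order is lexicographic by label wherever a
matrix is built — shortest-path, weight, correlation and contingency
matrices are therefore bit-reproducible across runs and platforms.
Analyses that need connectivity (shortest paths, deletion perturbations)
run on the giant connected component (GCC), mirroring how interaction
networks are pre-processed; GCC size ties break toward the component
containing the lexicographically smallest label.

Shortest paths are unweighted hop counts (the networks carry no edge
weights), computed with `scipy.sparse.csgraph`.

## Modularity and NMI

Newman modularity is computed through its decomposition: e is the K×K
matrix of edge-end fractions between communities, a its row sums, and
Q = Σᵢ (eᵢᵢ − aᵢ²).  Isolated nodes are legal (k_v = 0 contributes
nothing); an edgeless graph has no defined Q and is rejected.

Partition agreement uses normalized mutual information computed from the
contingency table of shared-node counts.  Entropies and mutual information
use natural logarithms (NMI is base-invariant); 0·log 0 terms are 0.  The
default normalization is I/max(H(U), H(V)), which scores identical
partitions 1.0; the sum-normalized variant I/(H(U)+H(V)) — which scores
identical partitions 0.5 — is available as `variant="sum"`.  Conventions
for degenerate cases: if both partitions are single blocks NMI(max) = 1.0,
if exactly one is, 0.0.  One practical consequence: an algorithm that
collapses to a single community before *and* after a perturbation scores
NMI = 1 against itself, i.e. "perfectly stable by vacuity"; robustness
results for label propagation must be read with this in mind.

## Correlation-distance detection

The working hypothesis is that same-module nodes have positively
correlated distance profiles.  Two profile matrices are used: S, the
all-pairs shortest-path matrix, and M = A·S (true matrix product), whose
row i is the sum of the S-rows of i's neighbors.  A and S are symmetric
but M is generally not — the matrix product is the only reading under
which an asymmetric weight matrix arises, and rows (not columns) of M are
correlated.  Diagonal entries (self-distances of 0) stay in the profiles;
no masking is applied.

Row correlations (Pearson, or Spearman with average-rank ties) become
distances D = 1 − ρ ∈ [0, 2].  A zero-variance profile row has undefined
correlation; every pair involving one is assigned the neutral distance 1
(ρ = 0 on the D = 1 − ρ scale).  Ward linkage clusters D — by default the
`ward.D2` dialect (Lance–Williams recurrence on squared distances, the
textbook Ward objective and scipy's native behavior); the historical
`ward.D` dialect (recurrence on raw distances) is available and is
realized by feeding √D to the D2 machinery and squaring the merge heights
back.  Every cut level k = 1..n of the dendrogram is scored with Q and the
argmax is returned, ties toward fewer communities.  The scan is O(n·m)
overall and is not the bottleneck at the network sizes this package
targets (n ≤ ~10⁴).  Graphs with fewer than 3 nodes skip the correlation
machinery (row correlations need ≥ 3 columns) and return the single-block
partition, which maximizes Q there.

## Reference algorithms

**Greedy agglomeration (fast-greedy).**  Starts from singletons with the
pair score dQ_ij = 1/(2m) − k_i·k_j/(2m)² for adjacent pairs.  The pair
score equals e_ij − a_i·a_j, half the symmetric modularity gain
e_ij + e_ji − 2·a_i·a_j of the merge; since a uniform factor cannot change
the argmax, scores are kept in this convention and the recorded Q advances
by twice the score of each merge.  After merging i and j, third-community
scores update as S_(ij)k = S_ik + S_jk when k touches both, else
S_ik − a_j·a_k (resp. S_jk − a_i·a_k).  Bookkeeping is sparse rows plus a
lazy max-heap; ties break toward the smallest community-id pair.
Agglomeration runs to a single community, recording Q at every step, and
the maximum-Q cut is reported (with the full merge trace available).  If
the remaining communities become disconnected from each other, the two
smallest-id communities merge with score −a_i·a_j.

**Label propagation.**  Unique initial labels; in each sweep the nodes are
visited in a fresh seeded random order and each adopts the label held by
the maximum number of its neighbors, ties resolved uniformly at random
(seeded).  Updates are asynchronous (the original formulation's default).
A node whose current label is among the tied-maximal labels counts as
converged; the algorithm stops when a sweep changes nothing.

**External backends.**  Walktrap, spinglass and multilevel are exposed via
python-igraph behind the same dispatch surface, with seeds forwarded to
igraph's RNG.  They are adapters only — if igraph is missing the call
raises a capability error, never a silent fallback.

## Benchmark generator

The generator plants a non-overlapping community structure:

1. **Degrees** are drawn from a truncated discrete power law
   p(d) ∝ d^(−γ) on [d_min, d_max].  Defaults: γ = 1, d_max = 20, mean
   degree 10; d_min is the integer truncation point whose distribution
   mean is closest to the target (γ = 1, d_max = 20 gives d_min = 4, mean
   ≈ 9.6).  The degree sum is made even by a single ±1 adjustment.
2. **Community sizes** come from a truncated power law (exponent 1 by
   default) on [k_min, k_max], drawn until the running sum reaches n; the
   remainder is appended if it is ≥ k_min, else topped up by borrowing
   single nodes from communities above k_min, else dissolved into
   communities below k_max.  Defaults k_min = 20, k_max = 50: the bound
   k_max > d_max is required so every node can place its internal degree,
   which rules out a (10, 20) pair when d_max = 20.
3. **Mixing.**  Each node's degree splits into round((1−μ)·d) internal
   stubs (banker's rounding — an unbiased split) and the rest external.
4. **Assignment.**  Nodes are assigned to random communities that can hold
   them (community size must exceed the node's internal degree); a full
   community displaces a random member back into the pool.
5. **Wiring.**  Within each community the internal degree sequence is made
   graphical (Erdős–Gallai check; if necessary, stub pairs are demoted —
   at μ = 0 they are dropped outright so that no external edge can ever
   appear) and realized by Havel–Hakimi construction followed by 10·m
   seeded double-edge swaps.  Community subgraphs can be dense, where
   naive configuration-model repair stalls; this construction cannot.
   External stubs are paired by a configuration-model shuffle with
   rewiring sweeps that eliminate self-loops, duplicates and
   within-community pairs.

The realized mixing (fraction of edge ends running between communities) is
reported; for μ ≤ 0.5 it lands within ~0.02 of the target, the residual
coming from stub rounding.

**Perturbations.**  `add_random_edges` inserts ⌊fraction·m⌋ uniformly
sampled non-edges (rejection sampling — m ≪ n² in every target regime).
`delete_random_edges` removes ⌊fraction·m⌋ edges, each drawn uniformly
from the current candidates whose endpoints both keep degree ≥ 1 and whose
removal cannot disconnect the graph; bridges are excluded explicitly
(degree guards alone do not imply connectedness) and the candidate set is
refreshed after every removal.

## Enrichment

For every (module, term) pair with a nonzero term∩background, the
one-sided over-representation significance is the hypergeometric tail
P(X ≥ k) of the 2×2 table [[k, K−k], [t−k, N−K−t+k]].  The background
defaults to all nodes of the analyzed (GCC) network, and terms are
intersected with it before counting; restricting to annotated-only nodes
is exposed as an alternative by passing that background.  Bonferroni
divides α (default 0.001) by the number of tests actually performed in
the analysis — all (module, term) pairs — with the boundary inclusive
(p ≤ α/n).  A term counts as "enriched in k modules" only through
Bonferroni-significant results.

The synthetic-annotation generator emits, per planted community, terms
containing a coverage-fraction sample of its nodes plus a noise-fraction
of outside nodes, and a handful of unaligned random terms as negatives.
It emulates the *alignment* between gene sets and modules, not the
hierarchical, size-skewed structure of a real ontology: passing tests show
the testing machinery is calibrated (clean aligned terms are found in
exactly one module; shuffled nulls produce essentially no hits at
α = 0.001), not that any particular ontology snapshot would behave alike.

## Experiments and study conditions

All sweep functions derive per-task seeds from one top-level seed via
`numpy.random.SeedSequence.spawn`, so any configuration reruns
bit-identically.  Results are long-format tables (network, method,
replicate, metric, value) that round-trip through CSV; summary rows use
truncation (not rounding) at 4 decimals, matching the convention of the
bundled reference tables, whose printed edge densities are likewise
truncated.

Benchmark sweeps in the test-suite and acceptance script run at a reduced
size chosen to keep full parameter grids practical on a single CPU:
n = 300 with communities of 30–60 nodes (≈ 7 communities), 20 replicates
per mixing value over μ ∈ {0.05, …, 0.5}, six native methods.  At this
scale the correlation methods saturate near NMI = 1 for μ ≤ 0.3, so
monotonicity of mean NMI in μ is asserted with a 0.01 Monte-Carlo
allowance, and "label propagation is weakest in the hard regime" is
evaluated as the mean over μ ∈ {0.3, 0.4, 0.5} (pointwise at μ = 0.3,
label propagation still benefits from the large planted communities and
fast-greedy dips lower; the collapse sets in at μ ≥ 0.4).

The deletion-robustness experiment uses a base benchmark at μ = 0.35.
The choice is deliberate: at μ = 0.05 every method's detection is
perfectly stable under 5 % deletions (NMI ≡ 1 — nothing to measure), and
at μ ≥ 0.4 label propagation collapses to one block on both sides of the
perturbation and scores a vacuous NMI = 1.  At μ = 0.35 the detected
modularity (≈ 0.4–0.5) matches the range reported for real interaction
networks, and deletions measurably change every method's output.

The bundled reference tables carry published per-network summaries for ten
BioGRID PINs.  The regression of Q on the number of detected modules
(ordinary least squares with intercept, order 1 or 2; per-term two-sided
t-tests from statsmodels) reproduces the published significances —
fast-greedy quadratic p ≈ 0.0194/0.0211, multilevel linear p ≈ 3·10⁻⁵,
spinglass linear p ≈ 0.004.

## Known limitations

- Non-overlapping partitions only; overlapping-module extensions of Q and
  NMI are out of scope.
- Unweighted, undirected graphs; no streaming representation — an n×n
  distance matrix must fit in memory, which bounds the correlation methods
  at roughly 10⁴ nodes.
- The benchmark's γ = 1 degree exponent follows the reference study
  conditions; the wider benchmark literature favors 2–3, and both are
  configurable.
- Ward merge ties inherit scipy's deterministic nearest-neighbor-chain
  ordering rather than an explicit smallest-index rule; runs are
  reproducible, but tie-heavy toy matrices may merge in a different (still
  valid) order than a hand simulation.
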