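# Methods

## Similarity diffusion

The node-pair similarity model treats correspondence between two undirected
networks as a recursive property: a pair `(i, j)` with `i ∈ V_A`, `j ∈ V_B`
is similar when the neighbours of `i` are similar to the neighbours of `j`,
blended with topology-free prior evidence (elemental similarity, e.g. a BLAST
score matrix `H`).  With `Ã` and `B̃` the column-stochastic adjacency matrices
(`column j of A` divided by `degree(j)`; all-zero columns for isolated
nodes), one iteration is

    X ← α Ã X B̃ᵀ + (1 − α) H',

where `H'` is `H` scaled to unit 1-norm.  On the stacked vector
`x = vec(X)` (column stacking) this is `x ← α (B̃ ⊗ Ã) x + (1 − α) h`, the
PageRank-style linear system the model descends from.  Both formulations are
implemented; the Kronecker form is a test oracle guarded at
`n_A·n_B ≤ 10⁴` since its operator is dense and quadratic in the number of
pairs, while the production kernel is a sparse–dense–sparse triple matrix
product per iteration.

Conventions and numerical choices:

* **Orientation.** `X` is `n_A × n_B` with rows indexing the first network.
  The choice is locked by an equivalence test between the two formulations
  and by the hand-computed fixed point of two identical single-edge graphs
  with a uniform prior (uniform `X = 1/4` at `α = 1`).
* **Normalisation.** The norm on `x` and `h` is the 1-norm, applied to `h`
  once at setup and to `x` after every iteration, so entries remain a
  probability mass over node pairs.  For networks without isolated nodes the
  update is already mass-preserving; the explicit renormalisation only acts
  when isolated nodes leak mass.
* **Initialisation.** `X₀ = H'`.  Any start converges for `α < 1`; this one
  makes `α = 0` exactly stationary from the first iterate.
* **Iteration count.** Fixed at 20 by default rather than a convergence
  tolerance, so runs are exactly reproducible; an optional early-stop
  (1-norm delta `< tol`) is available but off by default.
* **Degenerate mass.** If `α = 1` and the diffusion annihilates all mass
  (possible only when the prior is supported on isolated nodes), the previous
  iterate is kept instead of dividing by zero; a single isolated node pair
  therefore yields `X = [[1]]` for every `α`.
* **Parameters.** `alpha = 0.8` and `iterations = 20` are the defaults used
  throughout; `alpha` trades topological context (high) against prior
  fidelity (low).

## Matching

`X` encodes a weighted bipartite graph; the matchers return an injective set
of pairs.  Internally the smaller side always plays the buyers/rows role
(the matrix is transposed and results mapped back when `n_A > n_B`).

* **Greedy ½-approximation** (matrix form): select the maximum entry, zero
  its row and column, repeat until a dimension is exhausted.  Ties break to
  the smallest row then column index, making the output deterministic.  Only
  strictly positive entries produce pairs.  Weight ≥ ½ of optimal.
* **Auction.** Buyers bid `u_i − v_i + ε` (best minus second-best profit plus
  an increment) for their most profitable object; the object switches to the
  highest bidder at the raised price.  Prices are non-decreasing; a buyer
  whose best profit is no longer positive drops out permanently, which is
  sound because prices never fall.  Fractional scores are integerized as
  `round(x·scale)` (default `scale = 10⁶`) because the optimality guarantee
  is stated for integer weights: with integer weights and
  `ε < 1/min(n)` the final weight equals the exact optimum (verified against
  the enumeration oracle on hundreds of random instances).  With a single
  object the second-best profit is defined as 0.
* **Adaptive ε-scaling.** `ε₀ = 1/(min(n)+1)` on the scaled problem,
  multiplied by `growth = 4` after every bidding round that assigns fewer
  than `δ = max(1, ⌈0.01·min(n)⌉)` net new buyers; prices are retained across
  ε phases (resetting them would discard the work done in earlier phases).
  The auction result is padded to maximum cardinality by pairing unmatched
  rows, in order, with the first free columns (greedy completion), so on an
  entrywise-positive matrix cardinality is always `min(n)`.  This variant
  deliberately trades assignment quality for bounded runtime; on
  heavily-tied instances it can trail the greedy matcher in weight while
  still clearing the ½-optimal floor, and no optimality is claimed for it.
* **Exact oracle.** `brute_force_optimal` enumerates every injection of the
  smaller side (guard: min dimension ≤ 9) and is itself cross-checked against
  an independent assignment solver in the test suite.  It is the reference
  for all approximation-ratio and exactness tests and is never used in the
  pipeline.

## Alignment graph and assessment

Nodes are matched pairs; `{(i₁,j₁),(i₂,j₂)}` is an edge iff `(i₁,i₂) ∈ E_A`
and `(j₁,j₂) ∈ E_B`.  Conserved-edge counting is vectorised as an elementwise
AND of the two induced adjacency submatrices and verified against a pairwise
double loop.  Components are maximal connected sets, singletons included.

Enrichment treats each component as a predicted functionally-coherent group.
Per species independently, the component is projected to that species' nodes,
intersected with the annotation background (the population a hypergeometric
draw must come from), and each term annotating a projected node receives the
exact upper-tail p-value `P(X ≥ k)` for `X ~ Hypergeom(N, K, n)` with `N` the
background size, `K` the term's carriers and `n` the projection size.  A term
is enriched at `p ≤ 0.05` (default; an optional per-component Bonferroni
correction is available but off by default, since the raw-threshold
behaviour is the reference).  Summaries: TNR = percentage of components with
at least one enriched term (singletons count in the denominator — a
fragmented alignment *should* score low); TPR = number of distinct enriched
terms over all components (union, not sum, so a term found twice counts
once).  Flat term labels only; no ontology-graph ancestry propagation is
performed, so TPR/TNR values are not comparable to tools that propagate
annotations up an ontology.

## Synthetic data

`generate_pair` draws network A as Erdős–Rényi `G(n, p)` (defaults `n = 50`,
`p = 0.1`, mean degree ≈ 5 — sparse, PPI-like for correctness testing),
relabels a copy as network B, deletes `⌈rewire_frac·|E|⌉` edges and inserts
the same number uniformly among non-edges, and optionally appends extra
B-nodes (attached to one random node with probability ½, isolated
otherwise).  `generate_elemental` scores truth pairs at `true_score = 1` and
sprinkles `noise_pairs` uniform off-truth scores.  `generate_annotations`
plants each term on a breadth-first connected module of A and its truth image
in B; backgrounds contain every node.

What the generator does *not* emulate: heavy-tailed PPI degree
distributions, correlated BLAST score structure, study bias in annotations,
or ontology term hierarchies.  Passing recovery tests therefore demonstrate
algorithmic correctness and noise response, not biological performance on
real interactomes.

A practical note on enrichment fixtures: above the percolation threshold
(`p > 1/n`) an ER alignment graph has one giant component, so component-level
enrichment is uninformative by construction.  Assessment demonstrations and
the reproduction script use a sub-percolation fixture (`n = 60`,
`p = 0.018`) whose alignment graph fragments into components commensurate
with the planted modules.

## Problem sizes and determinism

Tests and the reproduction script run at deliberately small scale — networks
of 2–12 nodes for oracle comparisons (where enumeration and Kronecker
operators are exact and cheap), 50–60 nodes for pipeline recovery, 20 seeds
per condition — sizes at which every stochastic claim is paired with either
an exact oracle or a Monte-Carlo average.  Every random draw flows from an
explicit integer seed; identical configuration and inputs produce
byte-identical matching files (outputs are sorted by descending score with
lexicographic tie-breaks before writing).

## Known limitations

* The adaptive auction's quality degrades on instances with many near-tied
  scores (see above); use the fixed-increment auction when weight optimality
  matters more than speed.
* Hypergeometric enrichment on overlapping components is tested per
  component with no cross-component correction.
* Elemental scores are taken as given non-negative weights; no BLAST-specific
  normalisation is applied.
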