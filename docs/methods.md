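# Methods

## Model

A rooted phylogenetic network `N` is a DAG with a single root of
outdegree 2, leaves of indegree 1, internal tree vertices of signature
(1,2) and reticulate vertices of signature (2,1).  Leaves carry the taxon
labels `1..n`; `r` denotes the number of reticulate vertices, so a valid
network has `2(n + r) − 1` vertices.  Two further conditions are part of
the definition: every edge has at least one tree-vertex endpoint (the
*edge condition*), and the two parents of every reticulate vertex must be
able to *coexist in time*.  Vertices `u`, `v` cannot coexist when a chain
of directed paths, each containing a tree edge and consecutive paths
linked through co-parents of a reticulation, leads from `u` to `v`; we
evaluate this declarative relation as a boolean fixed point
`S · (L · S)*`, where `S` is the "directed path with ≥ 1 tree edge"
relation and `L` links co-parents.  A path must contain at least one edge
(so a vertex never fails to coexist with itself); the worst case is
exponential in principle but trivial at the supported scale.

Validation is tiered — `dag` (acyclic, single root, reachability),
`degrees` (signatures, leaf-label bijection, the vertex-count identity),
`edge_condition`, `time_consistency` — and scoring requires only the
`dag` tier: the recursions are well defined on any rooted DAG, and users
may legitimately hold networks that fail the stricter tiers.  A strict
CLI flag enforces all tiers.  Parallel edges are rejected at
construction: they would breach the edge condition and break the
uniqueness of the traversal tree.

Given a `k×k` nonnegative cost matrix over an alphabet and a leaf state
assignment λ, the parsimony score of an extension λ̂ (a state for every
vertex, agreeing with λ on the leaves) is the cost summed over **all**
edges, `P2(λ̂) = Σ_e c_{λ̂(tail), λ̂(head)}`; the object of interest is its
minimum over extensions.

## Traversals and the traversal tree

Depth-first pre- and post-order walks from the root visit each vertex
once (a reticulate vertex is not re-entered from its second parent), so
both walks trace the same spanning tree — the traversal tree.  Children
are expanded in increasing integer label, which fixes both orders
deterministically and yields order-consistency: vertices with no directed
path between them appear in the same relative order in both walks.  A
network may carry an explicit per-vertex child order overriding the
ascending default; the single-reticulation reference network uses one
(root children visited 5 then 4) because its published traversal
sequences follow the order in which the network is drawn rather than the
ascending rule, and the test suite pins those sequences character for
character.

An edge `(v, w)` *satisfies the traversal condition* when `w` is
reticulate and `v` precedes `w`'s other parent in post-order.  Exactly
one parent of each reticulation satisfies it; on time-consistent networks
it is the traversal-tree parent.

## Network Sankoff bounds

Post-order phase.  Leaves get `S_v(i) = 0` at the observed state and ∞
elsewhere.  For an edge `(v, w)` the contribution at parent state `i` is

* `min_j [c_ij + S_w(j)]` when `w` is not reticulate, or when `w` is
  reticulate and the edge satisfies the traversal condition — that parent
  accounts for the entire subnetwork below `w`;
* `min_j c_ij` for the other parent of a reticulate `w`: the state later
  assigned at `w` is unknown, so only the cheapest substitution along the
  edge itself is priced.

`S_v(i)` sums the contributions over `v`'s children; `S = min_i
S_root(i)` is a lower bound on the optimum, because it is the exact
minimum over the relaxation in which each reticulate vertex may take two
states (one per parent).  Argmins are recorded for backtracking, ties
always resolved toward the smallest state index, making extensions
reproducible across platforms.

Pre-order phase.  The root takes an argmin state; every other vertex is
assigned by backtracking from its *accounting parent* — the
traversal-condition parent for a reticulate vertex, the unique parent
otherwise — in top-down order of the spanning tree those parents form.
On time-consistent networks this accounting tree is exactly the traversal
tree; on structurally valid but time-inconsistent DAGs (one reticulation
parent an ancestor of the other) the traversal-tree parent can differ
from the traversal-condition parent, and assigning along the accounting
tree is the choice that remains well defined and keeps the bookkeeping
identity below.  At each reticulate vertex `w`, if the other parent `v'`
(state `i'`) preferred `j' ≠ j` (the assigned state), a *conflict* is
recorded; in all cases the upper bound is updated as
`S' ← S' − c_{i'j'} + c_{i'j}`.  The result satisfies, by construction,

* `S' = P2(extension)` exactly (checked edge-by-edge in tests), and
* `lower = upper` whenever no conflict occurred.

Complexity is `O((n + r) k²)` per site.  Per-edge nonnegative weight
multipliers are accepted (the recursion is unchanged with `w_e · c_ij`),
covering linearly scaled edge-specific costs; the default weight is 1.

Missing leaf data (`?`) initializes a leaf's column to all zeros — the
standard Sankoff convention — and is an extension beyond the strict
model; Fitch-style routines require fully observed leaves.

Multi-site matrices are scored per site and summed; the score is
site-separable, so sums of per-site lower/upper bounds are valid
aggregate bounds.

## Exact optimum and the oracle

Pinning every reticulate vertex to a fixed state makes the dynamic
programme exact: the unpinned vertices interact along the traversal tree
only, and the non-traversal reticulate edges price against known states.
Pinning is implemented by masking the vertex's state column (and both
branch minimizations) rather than by graph surgery, so the `k^r`
enumeration reuses the post-order routine unchanged; with all
reticulations pinned the pre-order phase can produce no conflicts, and
the code asserts this.  Ties across pinnings resolve to the
lexicographically smallest combination.  Complexity `O(n k^{r+2})`,
guarded at `r ≤ 12`.

The independent test oracle enumerates *all* extensions (vectorized over
the `k^m` assignments of the `m` non-leaf vertices, guarded at `10^7`
combinations) and never touches the dynamic programme; agreement between
the two on every corpus instance is the project's central correctness
check.

The majority heuristic pins each reticulate vertex to the state occurring
most often among the leaves reachable from it (smallest index on ties)
and reruns the pinned programme; the result is the score of a concrete
conflict-free extension, hence an upper bound, at cost `O(n k²)`.

## Network Fitch

Under unit costs the post-order sweep assigns each vertex a state set:
intersection of the children's sets when nonempty, union otherwise with
the counter `UB` incremented; a single-child vertex (a reticulation)
copies its child's set without increment.  The pre-order sweep assigns
the smallest root state and propagates states down the traversal tree,
keeping the parent's state when possible; at each reticulation the
published fixing step increments `UB` when the other parent's state lies
in the set but differs from the assigned state.  That step is silent when
the other parent's state is *outside* the set even though the edge then
carries a substitution, so `UB` can undercount the extension it returns.
The module therefore always also reports `direct_score`, the unit-cost
edge-sum of the concrete extension, and treats it as the authoritative
upper bound — it is provably the score of a valid extension.

For no-sister networks the displayed-tree bounds take the tree retaining
each reticulation's traversal-tree edge, run classic Fitch on it (lower
bound: the network optimum pays at least a displayed subtree), then lift
the tree assignment to the suppressed vertices — each copies the state of
the surviving vertex at the bottom of its contracted chain, which is
cost-neutral along the chain — and price all network edges (upper bound).

## Displayed trees and P1

A no-sister network displays `2^r` trees: delete one incoming edge per
reticulation and suppress degree-two vertices.  Suppression is iterated
to a fixed point because deletions cascade; if the root drops to
outdegree one its edge is contracted and the child becomes the root.
Trees are enumerated as a binary counter over reticulations in post-order
with in-edges sorted by parent id.  `P1` is the minimum classic Sankoff
score over the displayed trees; the classic tree Sankoff and Fitch
routines are implemented separately from the network code and double as
the `r = 0` specialization oracle in tests.  No displayed-tree semantics
are defined (or invented) for networks with sister reticulations.

## Synthetic instances

The generator emulates the regime the heuristics target: it grows a
random rooted binary tree by uniform joins, adds each reticulation by
subdividing two random distinct edges and connecting the new vertices,
and rejection-samples until the candidate passes structural validation,
acyclicity, time-consistency (required by default, since it is part of
the network definition) and optionally the no-sister predicate.  Leaves
keep labels `1..n`; internal vertices are renumbered deterministically in
topological order.  Characters are uniform i.i.d. leaf states; cost
matrices come in three regimes — unit, random-integer (off-diagonal in
0..5) and random metric (symmetric positive integers closed under
shortest paths).  Everything is reproducible from the seed.

What the generator does not emulate: biologically calibrated processes
(no coalescent-with-hybridization, no branch lengths, no site rate
heterogeneity, no character correlation).  Passing tests certify the
combinatorial algorithms on valid networks of the stated sizes, not
statistical performance on real alignments.  One feasibility note: three
leaves cannot host two non-sister, time-consistent reticulations under
edge-pair subdivision, so no-sister corpora skip that corner.

## Problem sizes used by the test suite and acceptance script

Corpora span `n = 3..7` leaves, `r = 0..2` reticulations and alphabets
`k = 2..4` (several seeds per cell; ≥ 200 instances for the oracle
check), 100 random trees for the specialization checks, and `n = 4..10`,
`r ≤ 2` for the small-network experiment rerun, where the reported
statistic is the fraction of instances on which a Sankoff bound equals
the exact optimum (typically 92–97%, instances with neither bound tight
are flagged).  These sizes keep the exhaustive oracle exact and the full
run in seconds while covering every degree signature and both conflict
and conflict-free behaviour.

## Known limitations

* The bounds can be loose on adversarial instances; only the `k^r`
  enumeration is exact, and it is exponential in `r`.
* General nonlinear per-edge cost functions are out of scope (only linear
  per-edge weight multipliers are supported).
* The coexistence fixed point and the brute-force oracle are exponential
  in the worst case and guarded accordingly.
* eNewick support covers the `#H` hybrid-tag dialect with integer labels;
  NEXUS and sequence-alignment inputs are out of scope.
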