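# Methods

## Model

An admixture graph is a pair `(N, Θ)`. `N` is a rooted binary
leaf-labeled DAG: the root has in-degree 0 / out-degree 2, leaves have
in-degree 1 / out-degree 0 and carry population labels bijectively, and
every other vertex has in-degree + out-degree = 3. Vertices of in-degree 2
are admixture nodes. `Θ` assigns every edge a drift length `c_e ≥ 0` and
every admixture node a proportion `γ ∈ [0, 1]` attached to a designated
incoming edge (the other incoming edge carries `1 − γ`).

Allele frequencies are treated as Brownian motion along edges with
per-edge variance `c_e`; an admixed population's frequency is the
γ-weighted *average* of the frequencies arriving along its two parent
edges. Writing `p_i(e)` for the probability that leaf *i*'s inheritance
path traverses `e` (computed in one reverse-topological pass, with the
weight entering an admixture node split γ / 1−γ across its in-edges), the
expected f2-statistic is `Y(i,j) = Σ_e (p_i(e) − p_j(e))² c_e`. On a tree
this is the path-length distance between the leaves; the test suite checks
the general case against a Monte-Carlo simulation of the Brownian model.
Note the weighting is quadratic in the path probabilities because
frequencies mix linearly — resolving each admixture by a random choice of
one parent per replicate would instead give weights linear in γ and is
*not* the f2 model.

The data are the observed vector `X` over all unordered population pairs
with per-entry scales `Z` (standard errors). The composite log-likelihood
is `−(1/2) Σ_i [(X_i−Y_i)²/Z_i² + 2 ln Z_i + ln 2π]`, natural logarithms
throughout. At a perfect fit with constant `Z = z` over `n` pairs it equals
`−(n/2)(2 ln z + ln 2π)`; at `z = 10⁻⁴` this is 82.914 (n = 10), 124.37
(n = 15) and 373.11 (n = 45). The root position is not identifiable (any
relocation ancestral to all admixture nodes preserves `Y`), and the two
root-incident edge lengths enter only through their sum.

## Parameter fitting

The three branch lengths incident to an admixture node cannot be estimated
jointly, so a *convention* pins some to zero:

* `admixturegraph` — both incoming edges of every admixture node are fixed
  to 0; the outgoing edge is free.
* `treemix` — requires a tree-based labeling ψ (a 0/1 edge labeling in
  which every non-root vertex has exactly one incoming 0-edge, every
  internal vertex at least one outgoing 0-edge, and both root edges are
  0); the free edges are the ψ=0 edges whose tail is not an admixture
  node.

Because the contribution of an admixture node's incoming edges is exactly
proportional to its outgoing edge's, the `admixturegraph` convention can
always represent the exact expected vector of any parameterization, so
true topologies refit on their own exact data always reach the perfect-fit
likelihood under it. Under `treemix` the same holds for the graphs
considered here; chained admixture nodes can in principle make the bound
unattainable, which is why the fixed-topology acceptance fits use
`admixturegraph`.

For fixed proportions, `Y` is linear in the free lengths, so the profile
problem is a nonnegative least-squares fit (scipy NNLS on the
`1/Z`-weighted system) solved exactly; fixed-to-0 edges are excluded from
the design matrix rather than penalized, guaranteeing exact zeros. The
proportions are optimized by multi-start coordinate descent: a coarse grid
(0.05, 0.15, …, 0.95 per node; the full product for h ≤ 2, axis-wise scans
around 0.5 otherwise) is evaluated, the best three starts are refined by
cycling bounded scalar minimization (tolerance 1e-10, at most 200 rounds),
and the best refined optimum wins, ties going to the earlier start. The
profile in γ can be multimodal, which is why the grid multi-start is used
instead of a joint gradient method; at these problem sizes it is cheap.
Repeated design-matrix evaluations go through a precomputed traversal
structure (`drift.F2Model`) so a fit costs milliseconds.

Tree-based labelings are found in linear time by reduction to 2-SAT (each
admixture node chooses its gene-flow in-edge; every "some out-edge must be
0" constraint involves at most two choices because out-degrees are ≤ 2)
and enumerated exhaustively over the `2^h` choices when all labelings are
scored (guard: h ≤ 12).

## Search

The driver follows the STB-ML scheme. Step 1 builds a starting tree rooted
at the outgroup: neighbor joining on the f2 matrix (default; f2 distances
are additive on trees, and NJ is consistent), exhaustive ML over all
topologies (guarded to ≤ 8 populations), or seeded random stepwise
addition followed by tail-move climbing. Then for each requested admixture
event: (2a) exhaustive search of the gene-flow edge-addition neighborhood
— ordered pairs of base-tree edges whose linking arc is legal, legality
decided by a precomputed reachability closure (the arc s→t creates a cycle
iff head(f) already reaches tail(e)) and cross-checked against
apply-and-validate; (2b) steepest-ascent tail-move hill climbing with
improvement tolerance 1e-6 log-units (exact ties are common at perfect
fit; anything smaller is optimizer noise); (2c) optionally, exhaustive
maximum-likelihood network orientation.

The orientation step enumerates every valid orientation of the current
network's undirected version with the root on the outgroup's pendant edge
and any h internal vertices admixed (`C(|V∖L|, h)` candidates; a flag
unlocks all root edges, and an `h ≤ 6` cap guards the exhaustive search).
Orientation given a root edge and admixture set is unique when it exists
and is computed by constraint propagation on required in-degrees; the
implementation is verified against an exhaustive direction-assignment
oracle. Each candidate is scored over all its tree-based labelings, and
the argmax (ties to enumeration order) replaces the network only if it
improves the likelihood, so the step is monotone. A heuristic
edge-addition mode (candidates restricted to edges on the root paths of
the top-k scaled-residual pairs, k = 5) is provided for larger problems;
the exhaustive mode is the default for the problem sizes used here.

Networks are compared *modulo the root position* as marked derooted
graphs: the undirected root-suppressed graph with admixture nodes marked,
which characterizes the equivalence class by the orientation-uniqueness
property. The tail-move BFS distance deduplicates classes via a
Weisfeiler–Lehman hash bucket followed by exact isomorphism (networkx
VF2 with leaf-label matching).

## Fixtures and the f2 simulator

`make_m1` builds the five-population case study: caterpillar on A–E rooted
at E, with a gene-flow arc from D's pendant edge onto A's pendant edge
(A admixed, h = 1, 11 edges). The drift lengths (0.09–0.2) and γ = 0.671
are fixture constants chosen so that the documented phenomenology holds,
and `validate_m1` asserts it: the NJ/ML starting tree is *not* a base tree
of the truth; the best gene-flow edge addition from that tree yields a
network with E admixed (triplet distance 9 from the truth); and — by brute
force over all 525 one-event networks on five populations, generated by
edge additions on every rooted tree topology and deduplicated modulo the
root — the truth is the unique global optimum of its own exact data. The
minimal tail-move distance from the E-admixed local optimum to the truth
is 3, and every length-3 path passes through a network scoring below the
local optimum, so hill climbing cannot escape it.

`random_graph(n, h, seed)` draws a random rooted binary tree (first
population attached below the root as the outgroup), applies h random
legal gene-flow edge additions (avoiding the outgroup pendant edge),
lengths ~ U(0.01, 0.5) and γ ~ U(0.1, 0.9). Exact datasets set every
standard error to 10⁻⁴, small enough to sharpen the likelihood surface
without numerical trouble. `simulate_f2` adds independent Gaussian noise
`se·ε` to the exact vector — it emulates sampling error of the summary
statistics only, not linkage between SNP blocks, jackknife covariance of
the estimates, or ascertainment; passing tests therefore demonstrate
correctness of the search and fitting machinery under the model's own
assumptions, not robustness to misspecified real data.

A configuration hook exists for shifting standard errors by a small
constant (default 0: the exact-data experiments set the SE directly).

## Problem sizes and numerics

The test suite and the acceptance script run at the scale the analysis is
designed for: 5–10 populations, h ≤ 2, where exhaustive neighborhoods,
brute-force enumerations (525 one-event networks, 2^|E| direction
assignments, 10⁵-replicate Monte Carlo) and BFS over tail-move space all
complete in seconds to a couple of minutes. Likelihood comparisons use a
1e-6 improvement threshold; NNLS is exact; γ refinement uses bounded
Brent with xatol 1e-10. Equidistant NJ ties resolve by the first
minimal pair, making every run deterministic given the seed.

## Known limitations

* Estimating f2 and standard errors from allele counts (SNP-block
  jackknife) is out of scope; the package starts from f-statistics.
* The exhaustive orientation search is exponential in h (capped at 6);
  the constrained incremental variant around the latest edge addition is
  not implemented.
* Non-binary networks and labeled internal vertices are not supported.
* Confidence intervals on fitted lengths and proportions are not
  computed.
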