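# admixorient

Maximum-likelihood admixture graph estimation from f2-statistics, with a
network-orientation search step that rescues hill climbing from the local
optima induced by a bad starting tree.

## The problem

The history of a set of populations with gene flow is modeled as an
*admixture graph* `(N, Θ)`: a rooted binary phylogenetic network `N` whose
in-degree-2 vertices ("admixture nodes") represent admixture events, plus
numeric parameters `Θ` — branch lengths `c_e` in units of genetic drift and
an inheritance proportion `γ` per admixture node. The data are f2-statistics:
for populations *i*, *j*, the expected squared allele-frequency difference.
Under the Gaussian drift approximation the model-implied value is

    Y(i,j) = Σ_e (p_i(e) − p_j(e))² · c_e

where `p_i(e)` is the admixture-weighted probability that the lineage of
leaf *i* traverses edge *e*; on a tree this is the plain path-length
distance. Observed statistics `X` with scales `Z` are modeled as independent
Gaussians around `Y`, giving the composite log-likelihood

    log ℓ(N) = −(1/2) Σ_i [ (X_i − Y_i)²/Z_i² + 2 log Z_i + log 2π ].

Starting-tree-based (STB-ML) searches — build an ML/NJ starting tree, then
add gene-flow edges and hill-climb with tail moves — are the standard
automated approach (TreeMix-style). This package implements that pipeline
*and* an exhaustive **maximum-likelihood network orientation (MLNO)** step:
after each edge addition, every valid re-orientation of the current
network's undirected version (every choice of admixed nodes, rooted at the
outgroup) is scored, and the best one replaces the current network. There
are simple five-population models with a single admixed leaf on which the
plain pipeline is *guaranteed* to return the wrong topology; the
orientation step recovers the truth.

Intended users: population geneticists and method developers working with
f-statistics (TreeMix / qpGraph-style workflows) who want a transparent,
fully scriptable Python implementation with exact brute-force baselines at
small scale.

## Worked example: the five-population case study

The built-in case-study fixture is a caterpillar tree on populations
A–E rooted at the outgroup E, with a gene-flow edge added from the D
lineage onto A's pendant edge, so that A is admixed. Its exact
f2-statistics (standard error 10⁻⁴ on all 10 pairs) are the input.

```sh
admixorient fixture m1 --out m1
admixorient infer --input m1.f2.tsv --outgroup E -m 1 --mlno off --out baseline
admixorient infer --input m1.f2.tsv --outgroup E -m 1 --mlno on  --out oriented
admixorient distance --graph-a baseline.edges.tsv --graph-b m1.edges.tsv
admixorient distance --graph-a oriented.edges.tsv --graph-b m1.edges.tsv
```

The baseline run (no orientation step) prints

```
[starting_tree] loglik=-575773.393065
[edge_addition_1] loglik=-195292.090982
[tail_climb_1] loglik=-195292.090982
final loglik: -195292.090982
```

and its returned network has **E** admixed — a wrong topology at triplet
distance **9** from the truth, and a local optimum: no tail or head move
improves it (at least three tail moves are needed to reach the truth, and
every such path passes through a network with a lower score). The
orientation-augmented run continues

```
[mlno_1] loglik=82.914018
final loglik: 82.914018
```

recovering the true topology (triplet distance **0**) at the perfect-fit
likelihood −(10/2)(2 ln 10⁻⁴ + ln 2π) = 82.914, which rounds to 83.

The same computation through the library:

```python
import admixorient as ao

fx = ao.make_m1()
config = ao.SearchConfig(num_admixture=1, outgroup="E", mlno=True)
trace, network, fit = ao.run_search(fx.data, config)
print(round(fit.loglik))                              # 83
print(ao.triplet_distance(network, fx.network))       # 0
```

## Layout

| module | contents |
| --- | --- |
| `admixorient.network` | directed/undirected binary networks, validation, isomorphism, tree-based labelings, displayed trees |
| `admixorient.drift` | path weights, expected f2, composite likelihood, residuals |
| `admixorient.fitting` | NNLS + coordinate-descent parameter fitting under the treemix / admixturegraph conventions |
| `admixorient.moves` | edge additions, tail/head moves, reachability, BFS move distance |
| `admixorient.orientation` | constraint-propagation orientation, orientation neighborhoods, MLNO |
| `admixorient.search` | NJ / exact-ML / random-addition starting trees, hill climbing, full pipeline |
| `admixorient.metrics`, `admixorient.fixtures` | triplet distance, case-study and random fixtures, f2 noise simulator |
| `admixorient.io`, `admixorient.cli` | TSV formats, extended Newick, `admixorient` command |

See `docs/methods.md` for the model, fitting conventions, and design
choices in detail.
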