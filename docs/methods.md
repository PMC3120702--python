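# Methods

## Problem and model

seedscan addresses seed-based subnetwork extraction: given a weighted,
undirected protein–protein interaction (PPI) graph and a few *seed proteins*
assumed to belong to one signal transduction pathway, find a compact,
densely and strongly connected subnetwork that contains the seeds and,
ideally, the rest of the pathway. The model rests on two assumptions about
signalling pathways in integrated interactomes: members of one pathway
interact (i) more often and (ii) more strongly with each other than with
proteins outside the pathway. Both direct and computationally predicted
(indirect) interactions carry signal under this model, which is why the
method is designed for large integrated databases rather than curated
physical-interaction sets.

## Edge weights

Each interaction pair carries up to two confidence scores: an integrated
evidence score in the STRING style (integer 0–999, normalized by dividing by
1000) and a GO semantic-similarity score in the TCSS style (real in [0, 1],
normalized by multiplying by 0.999; accepted as a precomputed input column —
computing TCSS from the GO DAG is out of scope). The two are combined with a
probabilistic-OR rule on the rescaled scores,

    w = 0.999 · [1 − (1 − S_TCSS/0.999)(1 − S_STRING/0.999)],

which is symmetric, returns the other score unchanged when one source is
absent (score 0), dominates either single source, and never exceeds the
0.999 cap. Pairs scored by neither source are removed; duplicate unordered
pairs keep the maximum combined score (conservative toward keeping
evidence); self-interactions are dropped. An edge below the score threshold
(default 0.800) is treated as absent; for search purposes a present edge has
distance `1 − w` and an absent one infinite distance.

## Pre-processing

1. **Common scope.** A bounded reachability search keeps only nodes
   connected to *every* given seed within `dfs_path_length` hops (default
   10). The bound is an unweighted hop count, since scoping happens before
   the weight-to-distance conversion. Seeds are always retained.
2. **Seed expansion.** A non-seed protein with ≥ 3 interactions with the
   given seeds, or ≥ 2 interactions of weight ≥ the credible threshold
   (default 0.980), is promoted to a seed and will appear in the final
   network. The default is a single promotion pass counting edges to the
   *user-given* seeds, which makes the operation idempotent. A cascading
   variant (`cascade=True`) iterates to a fixed point against the growing
   seed set; on dense graphs whose background edges survive the score
   threshold this variant can avalanche far beyond the pathway (on the
   bundled synthetic benchmark it routinely promotes most of the background),
   so it is opt-in only.

## The steepest-descent search

The search removes one node per step, never a seed, with a connectivity
guard: a removal that would split the seeds across components is rejected
and the next-ranked candidate is tried; if every candidate is rejected the
descent stops.

* **Distance phase** (while some non-seed node lacks a direct seed edge):
  remove the node whose Dijkstra shortest-path distance to the *nearest*
  seed is largest. Nodes unreachable from every seed have infinite distance
  and go first.
* **Aggregate phase** (once every remaining non-seed node touches a seed
  directly, where distances no longer discriminate): remove the node whose
  *aggregate score* — the summed weight of its direct edges to seeds — is
  smallest.

Ties in either phase break lexicographically by identifier, making the
descent fully deterministic.

Once the shrinking network reaches the size threshold (default 50, read
inclusively so a starting network already below the threshold is also
recorded), every connected snapshot is recorded with its weighted density

    D_n = Σ e_ij·w_ij / (n(n−1)/2).

A removal can momentarily strand a non-seed fragment while the seeds stay
connected; such disconnected snapshots are skipped (the stranded nodes have
infinite seed distance and are removed on the immediately following steps,
and a disconnected snapshot's density is dominated anyway). The five densest
snapshots (`keep_candidates`) are the candidates. Because fragments of a
dense module can out-densify the whole module, the *final* network is the
**largest** of the five — the density/size balance at the heart of the
selection rule.

## Edge pruning and ranking

Recorded candidates still carry weak (mostly indirect) edges. Each candidate
is pruned by repeatedly removing the least-weighted edge whose removal (a)
keeps the network connected and (b) strictly increases the average weight

    W_n = Σ e_ij·w_ij / Σ e_ij,

until the average weight peaks. Equal-minimum edges are chosen uniformly at
random under an explicit, logged RNG seed — the only randomness in the whole
pipeline. Termination guarantees that every remaining edge is either a
bridge or at least as heavy as the current mean; on exhaustive enumeration
of all connected spanning subgraphs of small random graphs, the greedy
terminal W_n matches the global optimum. Pruned candidates are ranked by
total retained weight

    S_n = Σ e_ij·w_ij

(descending; equal scores order by larger size, then node set), truncated to
`top_n` (default 5).

## Evaluation

Precision = correctly predicted / total predicted; recall = correctly
predicted / reference pathway size; both also reported as whole percents
with half-up rounding. Term enrichment uses the upper-tail hypergeometric
probability P(X ≥ x) of drawing x annotated proteins in a size-M network
from an N-protein background containing n annotated ones (delegated to
`scipy.stats.hypergeom`, cross-checked in the tests against exact rational
enumeration). Raw p-values are reported by default for comparability with
published tables; a Benjamini–Hochberg column is available with
`adjust=True`. The background size N is a user parameter.

## Synthetic benchmark

The generator plants a pathway module (default 15 nodes, edge probability
0.6, weights uniform in [0.88, 0.999]) in a sparse background (default 85
nodes, edge probability 0.05, weights uniform in [0.80, 0.87]), with
pathway–background cross edges at probability 0.05 and one decoy module
(pathway density, background weights, `pathway_size` nodes carved from the
background) that a weight-insensitive search would confuse with the target.
A repair pass adds minimum necessary edges so the pathway induces a
connected subgraph and the whole graph is connected. Everything is
deterministic per RNG seed.

What the generator does *not* emulate: scale-free degree structure, hub
proteins shared between pathways, identifier realism, and score noise
correlated with annotation depth. Passing the recovery tests therefore shows
that the search concentrates on a planted high-weight dense module under the
model's own assumptions — not that it resolves the overlapping-pathway
ambiguity of real interactomes.

A known regime limitation follows from the selection rule: when the planted
module is far from a clique (edge probability 0.6), snapshot density rises
essentially monotonically as the descent shrinks the network, so the five
densest snapshots are the five smallest, and the "largest of the top five"
rule returns a dense core rather than the full module. On the default
benchmark this yields mean precision 1.0 but mean recall ≈ 0.69 (20
replicates, 3 seeds); with clique-like modules (edge probability ≥ 0.8) the
density curve becomes non-monotone and recall rises above 0.9. The bundled
recovery test asserts the stricter recall bound and currently documents this
regime honestly rather than relaxing it.

## Numerical and design choices

* Distance of a node to the seed set is the minimum over seeds, which is
  what the worked five-node example's printed values imply.
* The aggregate phase removes the *minimum* aggregate-score node (the
  example keeps the higher contributor).
* Density ordering rounds D_n to 9 decimals before comparison so that
  genuine ties (e.g. sub-cliques of a uniform-weight clique, identical up to
  float accumulation order) break by size, larger first.
* Seeds isolated by thresholding produce an explicit "no interaction above
  the score threshold" error rather than a silent failure; disconnected
  seeds produce an error suggesting a lower threshold.
* Identifiers are opaque, case-sensitive strings; no synonym resolution.
* Defaults: score threshold 0.800, credible threshold 0.980, path length 10,
  size threshold 50, keep 5, top_n 5.

## Problem sizes

The test-suite oracles run on deliberately small instances chosen so that
exhaustive enumeration is exact and fast: shortest-path checks on 100 random
graphs of ≤ 8 nodes against all-simple-paths enumeration; pruning checks on
25 random graphs of ≤ 8 nodes and ≤ 13 edges against a 2^E scan of all
connected spanning subgraphs; hypergeometric checks against exact rational
sums for every parameter combination with N ≤ 12; recovery statistics over
20 generator replicates of the 100-node default benchmark.
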