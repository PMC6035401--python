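# Methods

## Model

`gcas` scores pairwise associations on a weighted undirected
heterogeneous network by iterated first-order spectral graph
convolution. With adjacency *A*, the convolution operator is
*Â = D̃*^{−1/2}(*A*+*I*)*D̃*^{−1/2}, where *D̃* is the degree matrix of
*Ã = A + I*; adding the identity gives every node a self-connection so
signal is retained locally, and the symmetric normalization keeps the
spectral radius at most 1. Information propagated to the t-th order
neighbourhood of a seed node is *C_t = θ' Â^t* with a per-step filter
parameter; the package fixes the first two steps at 1 and every later
step at a damping factor θ, so the cumulative score matrix is

    S = Σ_{t=1}^{K} θ^{max(t−2,0)} Â^t,     off-diagonal entries only.

A score *S_ij* therefore aggregates every path of length ≤ K between
*i* and *j*, with paths of three or more links damped geometrically.
Diagonal entries are self-associations and are discarded. Since Â is
symmetric, *S* is symmetric; since every term is non-negative with
spectral norm ≤ 1, every score is non-negative, bounded by K, and
non-decreasing in K.

Assumptions: the network is static during scoring; edge weights are
non-negative association strengths on comparable scales; undirected
edges (no causal orientation); no node features beyond connectivity.

## Parameters

| parameter | default | meaning |
|-----------|---------|---------|
| K         | 9       | convolution depth bound; pairs more than K links apart score 0 |
| θ         | 0.25    | damping per extra link beyond two; θ=0 truncates at 2 links, θ=1 disables damping |
| top_m     | 100     | inferred edges retained per node (best-scoring new partners) |
| τ         | 1e−4    | score floor below which an inferred association is discarded |

K and θ defaults are the optimum of a grid search over link-removal
sub-networks (K 2–12, θ 0.05–0.9; objective mean AUC_50 — the grid and
objective are exposed in `grid_search`). θ^0 is defined as 1 so θ=0 is
well-formed. The retention policy (top_m, τ) decides which of the O(n²)
scores become stored inferred edges; it exists because materializing all
pairs is neither useful nor scalable, and it is configuration-exposed
because any cutoff is a pragmatic choice. Ranking reads the stored
(retained) edges; a `live_propagation` flag re-runs the convolution per
query phenotype instead, bypassing retention truncation at higher query
cost.

## Network construction

Edge weights: phenotype–phenotype edges carry the Lin similarity
2·IC(mica)/(IC(p₁)+IC(p₂)) of each direct is-a pair, where
IC(p) = −ln(f(p)/N) with f the descendant-inclusive annotation count
(set-union semantics: a term below a diamond counts once per ancestor).
The annotation corpus defaults to the disease-resource's
disease→phenotype annotations and is injectable. Zero-count terms get
add-one smoothing so IC is finite and every ontology edge has a defined
weight; the 0/0 Lin case (two zero-IC terms) is defined as 0. Lin edges
are restricted to direct is-a pairs — all-pairs similarity would
densify the graph quadratically. Multi-rooted ontologies get a
synthetic zero-IC super-root.

Phenotype–disease edges map the frequency qualifier of the annotation
to the midpoint of its published frequency range (obligate 1.0,
very frequent 0.9, frequent 0.55, occasional 0.17, very rare 0.02);
excluded annotations (weight 0) are dropped because they cannot carry
propagation mass. Disease–gene, curated gene–gene interaction, and
gene–pathway membership edges all have weight 1. A concept appearing as
both a phenotype and a disease node (same normalized label) is kept as
two nodes bridged by a weight-1 edge rather than merged.

Edges are stored once per unordered pair per provenance
(ontological / curated / inferred); re-adding the same pair+provenance
keeps the maximum weight (idempotent ingestion), while the exported
adjacency sums across provenances — both evidence channels contribute
propagation mass. Node order for matrices is the lexicographic sort of
ids, so matrices are bit-reproducible.

The phenotype–gene projection ("trunc" network) used by the
cross-validation removes disease and pathway intermediaries; every
phenotype–disease–gene 2-hop path becomes a direct edge with weight
Σ_d w(p,d)·w(d,g). The product preserves both association strengths and
the sum aggregates multiple disease mediators; this rule is isolated in
one operation (`collapse_to_trunc`) since other aggregations are
defensible.

## Evaluation protocols

**AUC_N.** For a ranked candidate list with known targets, every
non-target ahead of a target is a false positive and
AUC_N = Σ_targets max(N − fp_before, 0)/(N·#targets) — the ROC area
with false positives truncated at N, normalized to [0, 1]; the full AUC
is the N = #negatives case. Targets receiving zero propagation score
are absent from the candidate list; they stay in the denominator with
zero contribution.

**Link-removal cross-validation.** Each of 10 folds removes a seeded
random 10% of the phenotype–gene links of the projection, re-runs the
convolution from every affected phenotype on the remaining network, and
ranks that phenotype's candidates (all genes with nonzero score, ties
broken by gene id). AUC_N (N ∈ {50, 100, 300, 500, 1000}) and full AUC
are averaged over test phenotypes within a fold. The analytic null
reported alongside is the exact expectation under a uniformly random
ranking of the same candidate sets: each target's false-positive count
is uniform on {0, …, #negatives}, so
E[AUC_N] = Σ_{j=0}^{neg} max(N−j, 0)/(N·(neg+1)), scaled by the
fraction of targets present.

**Top-k recall.** A case is captured at k when the best (minimum) rank
over its causal genes is ≤ k (inclusive); the curve reports the
percentage of cases captured per cutoff. The pairwise variant scores
each (phenotype, causal gene) pair against the phenotype's own ranked
list and can exclude pairs already linked in the pre-augmentation
network, removing the overlap bias between inputs and inferred edges.

## Synthetic benchmark

The generator emulates the structure of the real sources at desk scale:
a random rooted is-a DAG of 200 phenotype terms (random-parent tree
plus 10% extra is-a links), 40 diseases each annotated to 2–Poisson(4)
phenotypes of a random clade with sampled frequency qualifiers and to
1–3 of 150 genes, an Erdős–Rényi interaction layer (p = 0.02) and 10
Poisson(12)-sized pathway gene sets over the genes, and 50 planted
cases. A case is a distinct (disease, causal gene) pair with a 3–5-term
phenotype query drawn from the disease's annotations, so multiple cases
may share a disease. Planted (phenotype, gene) pairs are connected only
through a disease intermediary, never directly — recovering them
genuinely requires multi-hop propagation. An option withholds the
mediating disease–gene link entirely to create strict inference
targets. All randomness flows from one seeded generator; a fixture
bundle written to disk and re-ingested through the parsers reproduces
the generated network exactly.

What the generator does *not* emulate: the scale-free degree
distributions, annotation depth biases and synonym ambiguity of real
ontologies and disease resources, literature-biased interaction
coverage, or noisy/partial clinical phenotyping. Passing benchmarks
here demonstrate correctness and discriminative behaviour of the
machinery, not clinical-grade accuracy on real cases.

## Numerical choices

Double precision throughout; terms accumulated in ascending t so sums
are reproducible. Â is built sparsely and powers are applied as sparse
mat-vec (per seed) or sparse×dense products (full matrix); Â^t is never
formed per seed. The full-matrix path is guarded at 20 000 nodes
(overridable) since it allocates n² doubles. Ranking ties break by gene
id ascending; the most-informative-common-ancestor ties break by
lexicographically smallest term id. Degenerate inputs are defined
explicitly: isolated nodes normalize to a unit self-entry, empty
networks refuse matrix export, queries whose phenotypes are all unknown
are errors while partially-unknown queries skip with a warning.

The acceptance runner uses the default benchmark sizes above
(400 nodes, ~800 curated edges, 50 cases, 10 CV folds) — small enough
to re-run end to end in seconds while leaving clear separation between
the method and its random null.

## Known limitations

- Absolute scores depend on the frequency-qualifier map and the IC
  corpus, neither of which has a canonical published value; rankings are
  far more stable than raw scores across these choices.
- The retention policy truncates stored inferred edges; ranked lists for
  very high-degree queries can differ from live propagation beyond the
  top_m-th partner.
- Evaluation CLI output is TSV only; plotting is left to downstream
  tools.
- No directed edges, no temporal versioning, no entity disambiguation
  beyond exact id matching and exact-label phenotype/disease bridging.
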