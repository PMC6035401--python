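# gcas

Phenotype-driven causal-gene prioritization for rare diseases on a
heterogeneous association network, powered by **G**raph
**C**onvolution-based **A**ssociation **S**coring (GCAS).

Clinicians working up a rare-disease case typically have a handful of
phenotype terms (HPO IDs) and a long list of candidate genes from exome
or genome sequencing. `gcas` builds a weighted undirected network whose
nodes are phenotypes, diseases, genes and pathways, infers new pairwise
associations by spectral graph convolution, and ranks candidate genes by
their cumulative association score with the query phenotypes.

## The model

Let *A* be the adjacency matrix of the network and
*Â = D̃*<sup>−1/2</sup>(*A* + *I*)*D̃*<sup>−1/2</sup> the self-loop
normalized adjacency (the first-order approximation of a spectral graph
convolution). The pairwise association score matrix is

&nbsp;&nbsp;&nbsp;&nbsp;*S* = Σ<sub>t=1..K</sub> θ<sup>max(t−2, 0)</sup> *Â*<sup>t</sup>

with only the off-diagonal entries of *S* taken as scores. *K* bounds
the convolution depth (pairs more than *K* links apart score zero) and
θ ∈ [0, 1] damps information flowing along paths of three or more links.
Defaults are *K* = 9, θ = 0.25.

The initial network combines:

| edge class            | weight                                    |
|-----------------------|-------------------------------------------|
| phenotype–phenotype   | Lin similarity 2·IC(mica)/(IC(p₁)+IC(p₂)) over is-a pairs |
| phenotype–disease     | frequency qualifier (obligate 1.0 … very rare 0.02) |
| disease–gene          | 1                                          |
| gene–gene (curated interactions) | 1                               |
| gene–pathway          | 1                                          |

with IC(p) = −ln(f(p)/N) from a descendant-inclusive annotation corpus.
GCAS scores between unlinked pairs are added back as *inferred* edges,
giving the integrated association network used for ranking.

## Worked example

Everything below runs on a self-generated synthetic benchmark — no
downloads needed:

```bash
gcas simulate --seed 1 --out fx/
gcas build --ontology fx/ontology.obo --diseases fx/diseases.tsv \
           --genes fx/genes.tsv --pathways fx/pathways.gmt \
           --ppi fx/ppi.tsv --out netdir/
gcas infer --net netdir/ --K 9 --theta 0.25 --out hanrd/
gcas rank-cases --hanrd hanrd/ --cases fx/cases.tsv --out ranks.tsv
head -4 ranks.tsv
```

```
case_id	causal_gene	rank	case_rank
CASE0001	SGN0055	1	1
CASE0002	SGN0109	2	2
CASE0003	SGN0121	1	1
```

Each row gives the 1-based rank of a case's known causal gene in the
ranked gene list produced from that case's phenotype query; `case_rank`
is the best rank over the case's causal genes. The link-removal
cross-validation of the inference step:

```bash
gcas trunc --net netdir/ --out truncdir/
gcas evaluate cv --net truncdir/ --folds 10 --seed 17 --out cv.tsv
```

reports, per fold, the mean AUC_N (ROC area truncated at N false
positives, N ∈ {50, 100, 300, 500, 1000}) over test phenotypes whose
gene links were withheld, plus the full AUC.

The same operations are available as a library
(`gcas.generate`, `gcas.build_network`, `gcas.infer_associations`,
`gcas.rank_genes`, `gcas.cross_validate`, …); see `docs/methods.md` for
the modelling details.

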