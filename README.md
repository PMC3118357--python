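# wdcm — Weibull distribution-based clustering of gene expression data

`wdcm` clusters genes by the *distributions* of their expression values
rather than by distances between expression profiles. Each gene's observed
values are modelled as i.i.d. draws from a gene-specific two-parameter
Weibull distribution with density

    f(x; a, b) = (b/a) (x/a)^(b-1) exp(-(x/a)^b),   x ≥ 0,

with scale *a* > 0 and shape *b* > 0. Genes whose empirical distribution is
consistent with the fitted Weibull (Kolmogorov–Smirnov test, p > 0.05) are
kept; the retained genes are then clustered in the 2-D (a, b) parameter
plane by a hub-node algorithm that determines the number of clusters
automatically from the inter-point distances. Because each gene's
distribution is fitted from its own observed values, matrices with
scattered missing entries are clustered **without imputation** — the
package also ships the machinery to quantify that robustness (mask cells
at random, re-cluster, score the overlap).

It is aimed at transcriptomics analysts who want a distribution-based
alternative to k-means/SOM-style profile clustering, and at methodologists
who need a clean reference implementation of the pipeline with all its
evaluation measures: Adjusted Rand Index, GO annotation ratios, and the
Cluster Overlap Ratio stability index.

## Worked example

Simulate the four-blob reference condition — 300 genes whose (a, b)
parameters concentrate around (1,1), (1,6), (6,1), (6,6), observed over 50
samples — then screen and cluster (`examples/02_cluster_parameters.py`):

```python
from wdcm import HubConfig, SimConfig, adjusted_rand_index, run_pipeline, simulate_matrix

sim = simulate_matrix(SimConfig(seed=1))
screen, partition = run_pipeline(sim.matrix, hub_cfg=HubConfig(threshold_factor=0.5))
```

prints

```
screened: 300/300 genes accepted
auto-determined cluster count: k = 4
  cluster 0:  75 genes, hub g0065 at (a=0.99, b=0.97)
  cluster 1:  75 genes, hub g0121 at (a=0.93, b=6.13)
  cluster 2:  75 genes, hub g0163 at (a=5.98, b=1.00)
  cluster 3:  75 genes, hub g0299 at (a=5.96, b=5.91)
ARI against the planted partition: 1.0000
```

All 300 genes pass the goodness-of-fit screen (they really are Weibull),
the hub algorithm finds k = 4 without being told, each hub sits at a
planted center, and the Adjusted Rand Index of 1.0 says the recovered
clusters coincide exactly with the planted ones. The other scripts in
`examples/` walk through screening contaminated data, the evaluation
measures on hand-checkable inputs, and the missing-data experiment.

The same pipeline is available from the shell:

```sh
wdcm simulate --preset four-blobs --seed 1 --out sim/
wdcm run --matrix sim/matrix.tsv --out results/
wdcm evaluate --metric ari --clusters results/clusters.tsv --reference sim/truth.tsv
wdcm robustness --matrix sim/matrix.tsv --fractions 0.05,0.25 --runs 20 --seed 1 --out cor.tsv
```

Every command writes a `manifest.json` (version, resolved configuration,
input digests, seeds) so any run can be replayed exactly.

## Input formats

Expression matrices are delimited text (TSV, or CSV by extension): header
row of sample ids, first column gene ids, empty/`NA`/`NaN`/`null` cells
treated as missing (configurable). Partitions are two-column TSV
(gene, cluster). Annotations are three-column TSV (gene, term, ontology
∈ {BP, CC, MF}) or GAF 2.x. Fit tables are TSV with columns
(gene, a, b, n_obs, D, p_value, accepted, offset).

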