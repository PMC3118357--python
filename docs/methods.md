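# Methods

## Model

Each gene *i* of an m × n expression matrix is treated as a random variable:
its observed expression values x_i1, …, x_in are modelled as i.i.d. draws
from a gene-specific two-parameter Weibull distribution with density

    f(x; a, b) = (b/a) (x/a)^(b-1) exp(-(x/a)^b),   x ≥ 0,

where a > 0 is the scale (spread, in expression units) and b > 0 the shape
(dimensionless; b = 1 is the exponential, b ≈ 3.6 is near-Gaussian). The
working hypothesis is that genes with similar expression behaviour have
similar (a, b), so clustering the genes reduces to clustering the fitted
parameter pairs in the 2-D (a, b) plane. Because each gene's distribution
is estimated from its own observed values only, rows with scattered missing
entries participate without imputation — the missing cells are simply
excluded from that gene's sample.

The pipeline is: (1) fit (a_i, b_i) per gene; (2) screen each gene by a
Kolmogorov–Smirnov goodness-of-fit test against its fitted distribution,
keeping genes with p > α; (3) cluster the retained (a, b) points with a
hub-node algorithm that determines the cluster count automatically;
(4) evaluate with the Adjusted Rand Index (external agreement), GO
annotation ratios (functional consistency), and the Cluster Overlap Ratio
(stability under missingness).

## Parameter estimation

Maximum likelihood. The shape solves the one-dimensional profile-likelihood
equation

    Σ x_i^b log x_i / Σ x_i^b − 1/b − mean(log x_i) = 0,

which is monotone in b; we bracket the root by doubling and solve with
Brent's method to 1e-12 relative tolerance, evaluating the weighted mean
through a softmax in log-space so large b never overflows. The scale then
has the closed form a = (mean x_i^b)^(1/b). Near-constant samples have no
finite root: the shape is capped at 1e4, the fit flagged `degenerate`, and
the scale reported as the sample value — a spike is not Weibull-like and
such genes are subsequently rejected by the screen rather than crashing it.

An alternative estimator `minimize_ks` chooses (a, b) minimizing the KS
distance itself (Nelder–Mead started at the MLE, never returning a worse
distance than the MLE). It mirrors the reading of the screening rule in
which parameters are *selected* so the null is accepted; MLE is the default
because it is the standard, reproducible choice.

### Positivity

Weibull support is x ≥ 0, but expression matrices may contain negative
values (log-ratios). The default `global_shift` mode adds a single
matrix-wide constant ε − min(matrix) when any value is ≤ 0, with
ε = 0.01 × (global range), recording the offset in every fit so the (a, b)
of different genes remain comparable. `per_gene_shift` and
`drop_nonpositive_genes` are available when a global shift is inappropriate.
The applied offset is stored in the fit table; no transform is silently
forgotten.

## Goodness-of-fit screen

D = sup_x |F_n(x) − F(x)| is computed exactly over the order statistics as
max_i max(i/n − F(x_(i)), F(x_(i)) − (i−1)/n); ties in the sample pass
through this formula unchanged. The p-value uses the asymptotic Kolmogorov
series Q(λ) = 2 Σ_{k≥1} (−1)^{k−1} exp(−2k²λ²) at λ = √n·D, truncated once
terms fall below 1e-12 and clamped to [0, 1]. A gene is retained when
p > α, with α = 0.05.

Two deliberate simplifications are documented rather than corrected:

* **Lilliefors effect.** D is computed against the *fitted* distribution,
  which makes the nominal p-values conservative — the realized rejection
  rate on truly-Weibull genes sits well below α (the test bench verifies
  ≤ 0.05 over 500 replicates at n = 100). No Lilliefors-style correction is
  applied; the screen errs toward keeping genes.
* **Asymptotics.** The series p-value is an n → ∞ approximation; genes with
  fewer than `min_n = 8` observed values are skipped (reported, not fitted)
  because the approximation is unreliable there.

## Hub clustering

Distances are Euclidean in raw (a, b) by default; optional z-scoring of
each coordinate (`standardize`) is provided because scale and shape can
differ by orders of magnitude on real data. The join threshold is
T = `threshold_factor` × (mean pairwise distance), default factor 0.5.

1. **Leader pass** (input order): the first point founds hub 0; each later
   point joins the nearest existing hub if that distance is ≤ T, else
   founds a new hub.
2. **Re-election loop** (up to `max_iter` − 1 times): each cluster's hub
   becomes its medoid; any two hubs within T of each other are merged
   (transitively, keeping the lowest label and re-electing the merged
   medoid); every point then moves to its nearest hub, ties breaking to the
   lowest hub index; emptied clusters are dropped. The loop stops when
   assignments stabilize.
3. Clusters smaller than `min_cluster_size` (default 1, i.e. disabled) are
   absorbed into the nearest other hub's cluster.

The hub-merge step in (2) is a design choice this package makes
deliberately: a bare leader pass is order-dependent and seeds several hubs
inside any point cloud wider than T, and medoid reassignment alone can
never reunite them, which fragments elongated clusters (shape estimates
have heavier sampling noise than scale estimates, so clusters stretch along
the b axis). Under the threshold semantics — points within T of a hub
belong with it — two hubs within T of *each other* describe one cluster,
so merging them is the consistent completion of the rule. With
`max_iter = 1` the algorithm degrades to the pure single leader pass.

Everything is deterministic given the input order and configuration; no
randomness is used anywhere in the clustering. Shrinking `threshold_factor`
never decreases the number of clusters (verified over a factor grid).

## Evaluation measures

**ARI** is computed in the Hubert–Arabie pair-count form: with a, b, c, d
the counts of gene pairs co-clustered in both / only the reference / only
the candidate / neither partition,

    ARI = 2(ad − bc) / [(a+b)(b+d) + (a+c)(c+d)].

Pair counts come from contingency-table algebra and are cross-checked in
the test bench against brute-force pair enumeration and against
scikit-learn's contingency implementation. The adjusted index can be
negative (agreement below chance); it is reported as-is. A degenerate
denominator (both partitions all-singletons or all-one-cluster) returns 1
for identical partitions and 0 otherwise.

**Annotation ratio.** For one cluster and one GO namespace (BP/CC/MF), scan
every term annotating at least one member; the term covering the most
members wins (ties to the lexicographically smallest term id) and the
cluster's ratio is that coverage over the cluster size, unannotated genes
counting in the denominator only. The final ratio is the unweighted mean
over clusters. Annotations come from a locally supplied table (3-column TSV
or GAF 2.x); the statistic makes no use of the GO graph structure.

**COR.** For incomplete-data clusters I_1..I_m against complete-data
clusters C_1..C_n: x_i = max_k |I_i ∩ C_k| / |I_i| and p_i = |I_i| / Σ|I_j|;
COR = Σ p_i x_i ∈ [0, 1], equal to 1 exactly when every incomplete cluster
nests inside one complete cluster. The verbal definition of the weighting
is ambiguous in isolation; the size-weighted mean is the only reading
consistent with p_i being "the proportion of genes in cluster I_i".

## Robustness experiment

Masking operates on individual cells (not whole genes or arrays): exactly
round(fraction × #observed) observed cells are set missing, uniformly
without replacement, reproducibly from a seed. The experiment clusters the
complete matrix once, then for each missing fraction (default 5–25% in 5%
steps) and each of `n_runs` repetitions (default 100, matching the
convention for a full experiment) masks, re-screens, re-clusters, and
computes COR over the genes accepted in that masked run, restricted to
genes the complete run also clustered. Genes falling below `min_n` in a
masked run drop out of that run. Per-run seeds derive from
SeedSequence(base_seed, round(fraction·1e6), run), so any run is exactly
replayable in isolation. Runs accepting zero genes record COR as undefined
(NaN) and are excluded from the per-fraction mean, with a warning.

## Synthetic data

The generator produces the setting the model assumes, with ground truth:

* k planted clusters of `genes_per_cluster` genes; gene i in cluster c gets
  (a_i, b_i) = center_c + truncated-Gaussian jitter (redrawn until both
  coordinates are positive; ≥ 100 failures is an error), then `n_samples`
  i.i.d. Weibull(a_i, b_i) values.
* The default condition is four well-separated centers (1,1), (1,6),
  (6,1), (6,6) with jitter sd 0.15, 75 genes each, 50 samples — enough
  samples for the screen's asymptotics while keeping parameter-estimation
  noise visibly nonzero.
* Contaminants (a configurable fraction of genes, chosen uniformly) draw
  from a two-component Gaussian mixture with modes at μ ± 0.95σ and
  component sd ≈ 0.31σ, moment-matched to a randomly chosen Weibull center
  so the screen must reject them on *shape*, not on range; negatives are
  resampled (truncation). A mean/variance-matched uniform family is also
  available. The 0.95σ mode offset was fixed a priori as "clearly bimodal
  yet moment-matched".
* MCAR masking is applied last; everything reproduces bit-for-bit from the
  seed.

What the generator does **not** emulate: platform physics (dye bias, array
or batch effects, heteroscedastic technical noise), correlated missingness,
gene–gene correlation within a cluster beyond shared parameters, and
cluster-size imbalance. Passing tests therefore demonstrate correctness of
the machinery and the method's behaviour under its own assumptions — not
performance on any real cancer data set.

## Test-bench problem sizes

The reference end-to-end condition is 300 genes × 50 samples; screening
operating characteristics use 250 genes × 100 samples with 20%
contamination; MLE recovery uses 200 replicates at n ∈ {50, 200, 1000} and
a point check at n = 2000; the robustness trend uses 20 runs per fraction
over the 5–25% grid. These sizes make every property statistically sharp
while keeping a full run of the suite fast on one CPU.

## Known limitations

* Per-gene α with no multiple-testing correction, as the screening rule
  prescribes; the screen's conservativeness partially offsets this.
* No mixture distributions: genes failing the Weibull screen are discarded
  rather than modelled.
* The asymptotic p-value is anti-conservative for very small n; `min_n`
  guards the worst of it but n ≈ 10–20 p-values remain approximate.
* Clustering is specifically 2-D (a, b) clustering; the module is not a
  general n-dimensional clustering API.
* External reference partitions for ARI must be hard partitions; mapping
  genes that belong to several functional groups is left to the user.
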