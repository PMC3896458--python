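# Methods

## Model and procedure

The pipeline analyses a genes × samples matrix of positive, linear-scale
intensities with a two-group design (≥ 2 samples per group; the motivating
setting is 5 cases vs 5 controls). All test statistics are computed on log2
intensities; fold changes are ratios of group geometric means on the linear
scale, so `fold_change = 2^(mean log2 case − mean log2 control)` exactly.

### Random variance model t-test

Assumptions: per-gene log2 intensities are Normal with gene-specific
variance σ²; across genes the precisions are exchangeable,
1/σ² ~ Gamma(shape a, scale b) (equivalently σ² is inverse-gamma). Under
this prior the residual variance s² with m degrees of freedom satisfies
s²·a·b ~ F(m, 2a) marginally, which is the likelihood used to fit (a, b):
the negative log-likelihood Σ −[log f_F(a·b·s²ᵢ; m, 2a) + log(a·b)] is
minimised over (log a, log b) with Nelder–Mead from four moment-matched
starts (a₀ ∈ {1.2, 2, 4, 8}, b₀ = 1/((a₀−1)·mean s²)), taking the best.
Exactly-zero variances are dropped with a warning before fitting (the F
density is zero there); fewer than 50 usable variances is an error, as is
(near-)zero dispersion of the variances, where the MLE degenerates.

The moderated variance is the posterior point s̃² = (m·s² + 2/b)/(m + 2a),
a convex combination of s² and the prior point 1/(a·b); the statistic
t = Δx̄ / √(s̃²(1/n₁+1/n₂)) is referred to Student t with m + 2a degrees of
freedom. As a → 0⁺ with 1/b → 0⁺ this reduces to the ordinary pooled
t-test (verified to 1e-9 in the tests). A gene with zero variance and zero
mean difference gets t = 0, p = 1.

Selection defaults to raw p < α (α = 0.05), the convention of the analyses
this package reproduces; Benjamini–Hochberg q-values are always reported
alongside (via statsmodels) and can be used as an optional gate by the
caller. Direction is up/down by fold change vs 1, falling back to the sign
of the mean log2 difference when the fold change is exactly 1; a fully
degenerate record (fold change 1, t = 0) is excluded with a warning.
Output ordering is p ascending, ties by |t| descending then gene id, which
makes runs deterministic.

### Over-representation

Terms are restricted to the measured universe (N = genes on the array)
before testing, and tested separately against the up- and down-regulated
lists. The two-sided Fisher exact p is the total probability of tables
with the observed margins whose probability does not exceed the observed
table's. It is computed in exact integer arithmetic: all probabilities for
fixed margins share the denominator C(N, Nf), so integer hypergeometric
weights C(n,k)·C(N−n, Nf−k) decide ties exactly. This avoids the
floating-point tie-tolerance heuristics of asymptotic implementations and
is what makes exact agreement with full enumeration possible; it matches
`scipy.stats.fisher_exact` to ~1e-16 on random tables.

The χ² companion test is Pearson's statistic without Yates correction
(a continuity correction would systematically inflate χ² p-values and bias
the Nk count below); a zero margin yields p = 1 with a warning. The
empirical FDR of a batch is 1 − Nk/T, where T is the number of terms tested
for that gene list and Nk counts terms with Fisher p < χ² p. T is
interpreted as the per-batch term count, recorded once per batch, because
the quantity is a property of the Fisher-vs-χ² comparison over the batch,
not of a single term. Significance is gated on the Fisher p alone; the FDR
is reported alongside. The signed enrichment score is +Re for the up batch
and −Re for the down batch (magnitude Re = (nf/n)/(Nf/N)); up batches sort
by score descending, down batches ascending, so the most enriched terms
lead both.

### Networks and centralities

GO-map / Path-Net: nodes are the significant terms (class up, down, or
both when a term is significant in both batches); edges are
caller-supplied term–term relations restricted to those nodes — curated
pathway cross-links in real use, synthetic pairs in testing. Relations
naming terms absent from the tested collection are skipped with a warning.

Signal-Net: the directed interaction graph induced on the DE genes (both
endpoints DE, isolated genes dropped). Edges carry KEGG-style relation
codes {a, ex, b, c, ind, inh, u, s} as labels only — paths are unit-length
and unweighted because no weighting is defined for these annotations.
Binding (`b`) edges are treated as undirected and contribute both
orientations.

Betweenness uses the relative form C′B(v) = 2/((n−1)(n−2)) ·
Σ σ_st(v)/σ_st, pairs without a path contributing zero. The default mode
runs shortest paths on the directed graph — consistent with source/sink
nodes having betweenness exactly zero in the reference tables — while the
2/((n−1)(n−2)) normalization (the undirected two-per-pair convention) is
kept verbatim; its documented consequence is that directed-mode values are
bounded by 2 rather than 1. Undirected mode counts each unordered pair
once and is bounded by 1. Computation delegates to networkx's Brandes
accumulation (unnormalised) and is rescaled; the contract is equality with
an explicit all-pairs shortest-path enumeration oracle, asserted to 1e-9
in the tests. With n < 3 the normalization is undefined and all values are
reported as 0 with a warning.

Degree Ki is the distinct-neighbor count of the undirected projection
(reciprocal partners count once — the only reading consistent with
published tables where degree < indegree + outdegree); indegree/outdegree
count distinct source/target genes. Clustering is the local
Watts–Strogatz coefficient on the undirected projection,
2·(edges among neighbors)/(Ki(Ki−1)), 0 when Ki < 2. Core genes sort by
betweenness descending, ties by degree then gene id.

## Synthetic data

The generator emulates the study conditions end to end: 5 vs 5 samples,
2,000 genes, precisions Gamma(a = 2, scale b = 1), per-gene baseline log2
level Normal(7, 1.5²) to mimic microarray dynamic range, 100 planted DE
genes with a mean log2 shift of 2 split evenly up/down, 50 gene sets of
size 10–40 (alternating GO / pathway categories) of which 10 are planted
enriched — drawing 60% of their members from one direction's DE genes —
and ~600 directed interactions whose endpoints are drawn with a 10×
attachment weight for designated hub genes (heavy-tailed degree, as in
real signalling tables). The bundle draws interaction edges over the
planted DE genes plus 100 background genes, mirroring a pathway-derived
interaction source that concentrates on genes of interest. All defaults
are `SimConfig` fields; one integer seed drives every draw and identical
configs are byte-identical on disk.

What the generator does **not** emulate: probe-level noise and
summarisation, intensity-dependent variance trends, batch effects,
correlated genes, and annotation bias (term overlap structure, gene
multi-functionality). Passing planted-truth tests therefore demonstrates
the statistical machinery is correct under the stated model, not that the
pipeline is robust to those real-data violations.

## Numerical choices

- Prior fit: optimisation in log-parameters, multiple starts; degenerate
  and insufficient inputs raise typed errors rather than returning NaNs.
- Fisher: exact integer weights; p clipped at 1. χ²: closed-form Pearson
  statistic, p from χ²₁.
- Problem sizes in tests and the acceptance script (10,000 genes for null
  calibration, 5,000 variances for prior recovery, 100 random graphs with
  n ≤ 12 for the betweenness oracle, all 2×2 tables with N ≤ 60 for the
  Fisher oracle) were chosen so Monte-Carlo bands are tight — e.g. the
  null rejection rate at α = 0.05 has standard error ≈ 0.0022 at 10,000
  genes against a ±0.01 acceptance band — while the whole suite stays
  fast on one CPU.
- Determinism: every stochastic routine takes its generator from an
  integer seed; tie-breaks in all orderings are total (stable sorts with
  explicit final keys).

## Known limitations

- Two groups only; no paired designs or covariates.
- Raw-p selection is the default by design; with 2,000 genes and a true
  null it admits ~100 false positives — the q-value column is there for
  stricter control.
- The empirical FDR = 1 − Nk/T is a batch-level diagnostic of the
  Fisher-vs-χ² comparison, not a per-term error rate; it is reported, not
  used as a gate.
- The directed-mode betweenness keeps the undirected normalization
  constant, so values are comparable within a run but not to the [0,1]
  undirected scale.
- GO-style ancestor propagation, gene-length/abundance bias correction and
  rank-based (GSEA-style) enrichment are out of scope.
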