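# Methods

## The mutation model and burden test

All tests rest on the standard de novo mutation model for trio studies:
each gene g has a per-haploid-copy, per-generation mutation probability
μ<sub>g,c</sub> for each variant class c (synonymous, missense, deleterious
missense, protein-truncating). In a cohort of N probands the class count for
a gene set S is Poisson with mean λ = 2·N·Σ<sub>g∈S</sub> μ<sub>g,c</sub>
(the factor 2 counts the two haploid genomes). Rate tables are consumed, not
estimated: deriving μ from sequence context is out of scope.

The burden p-value is the exact upper tail P(X ≥ observed) for
X ~ Poisson(λ), computed with the Poisson survival function at
observed − 1. The ≥ convention (rather than >) is deliberate: it is the
convention under which the published worked values the acceptance tests pin
down are reproduced exactly. Degenerate inputs: λ = 0 with no observations
gives O/E = NaN and p = 1; λ = 0 with observations gives p = 0 with a
warning. O/E is observed/λ whenever λ > 0.

Missense counts are reported *inclusive* of the deleterious-missense (Dmis)
subset — a Dmis record increments both counters — because published burden
tables report missense and Dmis side by side with rates that are only
consistent under the inclusive convention.

The Dmis criterion is a single configurable deleteriousness score column
with a threshold (default 0.7, inclusive). This is a deliberate stand-in
for whatever ensemble predictor an annotation pipeline used upstream; the
package consumes pre-annotated tables and is agnostic about the predictor.

## Case–control comparisons under size imbalance

Cohorts of tens of thousands of probands are compared against a few
thousand controls, so two complements to the expectation test are provided:

* **Fisher exact test** on the 2×2 table of per-sample event counts vs
  cohort sizes. The reported odds ratio is the sample (cross-product) OR;
  when a margin is zero the Haldane (+0.5) OR is reported alongside a
  NaN/∞ sentinel.
* **Downsampled permutation test**: each of n_iter iterations draws,
  without replacement, a case subset equal in size to the control arm,
  pools it with the controls, permutes labels, and records the difference
  in mean per-sample count. The statistic choice (rate difference, one
  label permutation per downsample) is an interpretation — published
  descriptions of this procedure do not pin down the statistic — and the
  empirical p uses the add-one estimator (1 + hits)/(n_iter + 1), which is
  conservative and never zero. The calibration tests assert
  super-uniformity (P(p ≤ α) ≤ α under the null), which is the guarantee
  this estimator actually provides.

## Ascertainment differentials

The contribution of a variant class is summarized by the difference in
per-sample event frequency between cases and controls. With case rate r₁
and control rate r₀:

* percentage of cases affected = 100·(r₁ − r₀);
* percentage of proband events attributable =
  100·[((r₁ − r₀)/r₁)·|S|]/G, where |S| is the gene-set size and G = 20 154
  the protein-coding genome denominator.

A negative differential is reported as zero contribution with a warning:
under the model a risk class cannot be protective, so a negative estimate
is sampling noise.

## TADA-denovo

For gene g and class c the count is x ~ Poisson(2Nμγ), with γ = 1 under the
null. Under the alternative, γ ~ Gamma(shape = γ̄β, rate = β), giving the
marginal as a negative binomial with size γ̄β and success probability
β/(β + λ). The class Bayes factor is the marginal-likelihood ratio,
evaluated in closed form in log space; no quadrature is used in the
implementation (quadrature is the *test oracle*). Evidence that exceeds the
float range degrades gracefully: BF = ∞ yields posterior null 0 and q = 0.

Hyperparameter defaults: π = 0.05 (prior fraction of risk genes),
γ̄ = 20 for PTV, γ̄ = 8 for Dmis, β = 1 for both. These are the generic
magnitudes used for neurodevelopmental-disorder gene discovery; they are
configurable, and a method-of-moments helper estimates γ̄ from a gene-set
O/E ratio via E[O/E] = (1 − π) + π·γ̄, floored at 1.

When a rate table lacks a Dmis column, μ_dmis defaults to 0.25·μ_mis
(configurable), logged prominently.

**Meta-analysis across cohorts.** Two modes are exposed. The default pools
counts and sample sizes before a single TADA pass (one shared γ per gene
across cohorts); the alternative multiplies per-cohort Bayes factors
(independent γ per cohort). These are different models and do not coincide
numerically — the product of two negative-binomial/Poisson ratios is not
the pooled ratio — so the test suite asserts the property that actually
holds: the pooled-mode result depends only on the summed counts, i.e. it is
invariant to how counts split across cohorts. Pooling is the default
because a risk gene's effect size is plausibly shared across closely
related phenotypes.

**Bayesian FDR.** posterior null = (1 − π)/((1 − π) + π·BF); genes are
sorted BF-descending and the q at rank i is the running mean of the top-i
posterior nulls, with tie blocks sharing the block's worst q. Tiers:
strong q ≤ 0.05, possible q ≤ 0.1, suggestive q ≤ 0.2 (boundaries
inclusive). Genes with zero counts are retained in the ranking so the FDR
denominator is the analyzed universe, not the mutated subset.

## Network analysis

Edges with STRING combined score strictly greater than 600 are retained
(duplicates keep the maximal score; self-loops are dropped and counted).
The connectivity statistic between a prioritized set A and a comparison
set B counts edges with one endpoint in each, after removing shared genes
from B. The permutation null redraws A uniformly without replacement from
the graph's node universe (degree matching is not applied — the published
procedure does not state matching, and uniform redraw is the simplest
exchangeable null; a custom universe can be passed). p uses the same
add-one estimator as above, so p ≥ 1/(n_perm + 1) and results are
bit-reproducible given (seed, n_perm).

Six of CytoHubba's twelve hub-ranking algorithms are implemented: degree,
closeness (within-component), betweenness (unnormalized), stress, raw
eccentricity (smaller = more central; the ranking helper inverts it) and
maximal clique centrality, MCC(v) = Σ over maximal cliques C ∋ v with
|C| ≥ 2 of (|C| − 1)!, so an isolated node scores 0. Stress is computed
from all-pairs BFS distances and path counts (O(n³)); it is intended for
the few-hundred-node graphs hub analysis is run on. The remaining six
CytoHubba metrics are out of scope. Consensus hubs are ordered by mean
rank across methods, ties broken lexicographically.

## Expression enrichment

The 2×2 construction is explicit: x1 = |set ∩ category|,
x2 = |set \ category|, x3 = |category| − x1, x4 = |universe| − x1 − x2 − x3,
with the sample OR and a two-sided Fisher exact p. "Expressed in the
module/cluster" means membership in the supplied table; a threshold-based
membership builder (mean expression within cluster > cutoff) is provided
for synthetic data. No multiple-testing correction is applied across
categories by default (matching the nominal-p reporting convention of
module-enrichment analyses); Benjamini–Hochberg is available via a flag.

Prenatal bias: per gene, the paired values are the mean log2(x + 1) over
prenatal and over postnatal samples; a two-sided Wilcoxon signed-rank test
runs across genes. The log2(x + 1) transform is this package's choice (the
summarization upstream of published versions of this test is not stated);
it stabilizes the heavy right tail of RPKM-like values. All-tied input
returns p = 1 with a warning; at least 5 genes are required.

## Synthetic data: what it emulates and what it does not

The generators invert the analysis model: log-normal per-gene missense
rates (log μ ~ Normal(−11, 1), i.e. μ around 1.7×10⁻⁵) with fixed class
ratios μ_ptv = 0.1·μ_mis, μ_syn = 0.4·μ_mis, μ_dmis = 0.25·μ_mis — ratios
chosen so expected class proportions echo large published trio-cohort
burden tables; Bernoulli(π) risk flags with Gamma(γ̄β, β) relative risks;
Poisson counts at 2Nμγ expanded to one variant record per event (a sample
may carry several events, matching events/N rate arithmetic);
preferential-attachment PPI backbones with extra risk–risk edges added
with probability `risk_boost` and sub-threshold decoy edges; log-normal
expression with a +`effect` prenatal shift on log2 means for the biased
set. All generators are pure functions of (parameters, seed).

What passing tests on these data do **not** show: real cohorts have
sequence-context-dependent rates correlated with gene length, ascertainment
and annotation artifacts, relatedness between risk genes and network
degree, and batch structure in expression data. The synthetic null is
exactly the model's null, so calibration results here demonstrate
implementation correctness, not robustness to model misspecification.

## Problem sizes and numerical choices

The shipped demo scenario uses 400 genes, 6000 + 2000 probands, 1500
controls, 2000 permutation iterations per engine — sizes chosen so a full
run completes in seconds while every stage still has detectable signal.
Calibration suites in the tests use 200 replicates (1000 genes, N = 5000
for FDR calibration), which bounds the Monte-Carlo error of an empirical
FDR near 0.1 at roughly ±0.01 and keeps binomial 95% bounds meaningful for
super-uniformity checks. Per-stage seeds are derived from the single
top-level seed by hashing the stage name, keeping all seeds below 2³¹ and
reruns byte-identical.

## Known limitations

* Published per-gene FDR tables cannot be reproduced without the original
  cohort DNVs, rate tables and hyperparameters; the TADA acceptance surface
  is therefore property-based (oracle agreement and calibration), not
  value-based.
* Only the de novo arm of TADA is implemented; the transmission/case-control
  arms and estimation of π from data are out of scope.
* Variant annotation, liftover, transcript models and mtDNA-encoded genes
  are out of scope (mtDNA gene lists are handled by set exclusion during
  curation).
* The permutation statistic for the downsampling test and the permutation
  universe for the connectivity test are interpretations where published
  descriptions are ambiguous; both are documented above and configurable
  where it matters.
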