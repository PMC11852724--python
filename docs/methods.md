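# Methods

This note documents the statistical models, the design decisions taken
where the analysis left them open, and what the synthetic-data tests do
and do not establish.

## Differential expression

The two-group comparison assumes gene-level read counts are negative
binomial with Var = μ + α·μ² and a common per-sample library scale.

* **Normalization.** Median-of-ratios size factors: per sample, the
  median over genes (nonzero in every sample) of the ratio of the
  count to the gene's geometric mean, rescaled to geometric mean 1.
* **Low-count screen.** Genes with row sum < 10 (configurable) are not
  tested and carry status `filtered`; the screen's survivors define the
  background for enrichment and the universe for overlap testing.
* **Fold change.** log2FC = log2((m_case + c)/(m_ctrl + c)) on
  normalized group means with pseudocount c = 0.5 normalized counts,
  keeping estimates finite when one group is all zeros.
* **Dispersion.** Gene-wise method-of-moments α pooled within groups,
  averaged 50/50 with a fitted mean–dispersion trend α(μ) = a₀ + a₁/μ
  (least squares over informative genes). The trend borrows strength
  across genes the way RNA-seq dispersion estimation conventionally
  does; the 50/50 weight keeps genuine gene-level signal.
* **Test.** Wald z = log2FC/se with the delta-method standard error
  from the NB group-mean variances. The statistic is referred to a
  Student t with effective df = (n₁+n₂−2)/w², where w = 0.5 is the
  moment-estimate weight: averaging the noisy gene-wise estimate with
  the (nearly noise-free) trend scales its sampling variance by w²,
  Satterthwaite-style. w = 1 recovers the naive within-group df; w → 0
  the normal reference. Null simulations (8v8, 2000 genes, dispersion
  0.1) put the raw p < 0.05 rate at 0.048–0.052 across independent seed
  batches; the naive t(n₁+n₂−2) was conservative (≈ 0.037) and the
  plain normal slightly anticonservative (≈ 0.055).
* **Gates.** `up`/`down` require |log2FC| > 2 and BH-adjusted p < 0.05,
  strict inequalities; the inclusive ≥/≤ reading is available because
  the two are genuinely interchangeable at continuous data and both
  appear in practice.

Not implemented (out of scope): shrunken fold-change estimators,
covariate designs beyond two groups, and outlier replacement. On real
data with batch structure or uneven library quality, the calibration
measured here does not automatically transfer.

## Sample structure and exclusion

PCA runs on log2(normalized + 1), a variance-stabilizing surrogate that
preserves the rank/variance structure the plot needs while being fully
specified; genes are ranked by variance and the top 500 retained
(configurable), columns centered, and components signed so the
largest-|loading| gene is positive (determinism across BLAS builds).

Tumor samples indistinguishable from normals are excluded before DE by
a quantitative rule standing in for what is otherwise a visual call: in
the first k = 2 components, a tumor sample is excluded when it lies
closer to the normal-group centroid than to its own leave-one-out tumor
centroid. Reports label the rule explicitly (`pc_centroid_distance`).
A singleton tumor group leaves leave-one-out undefined; nothing is
excluded and a warning is issued.

## Overlap permutation test

The null model redraws k subsets of the observed sizes uniformly
without replacement from the tested-gene universe and intersects them —
equivalent to permuting gene labels once. The one-sided p is the
fraction of random intersections ≥ the observed overlap, floored at
1/n_permutations (never reported as 0, matching "< 1/n" reporting).

The default implementation samples the intersection size directly by
hypergeometric thinning: intersecting a uniform subset of size kᵢ with
a fixed set of size x leaves a Hypergeometric(N, x, kᵢ) count, so
chaining one draw per set yields the exact k-way distribution. This is
provably identical in distribution to materializing the label subsets
(the `labels` route, kept and cross-checked by a chi-square test on the
two distributions) and makes 10⁵–10⁶ draws effectively free. Analytic
anchors: E[overlap] = N·Π(kᵢ/N); for k = 2 the tail is hypergeometric
in closed form.

The tested-gene universe is never printed alongside published set
sizes; 20,000 is used for standalone invocations (roughly the
protein-coding transcriptome passing a count filter). The downregulated
three-way overlap conclusion is insensitive to this choice — it holds
for any universe ≥ 15,000.

## Pathway activation level

PAL_p = 100·Σ ARR·lg(CNR)/Σ|ARR| over pathway members, with CNR the
case (or case-group mean) expression over the control-group mean.
Decisions the formula's verbal definition leaves open:

* expression is size-factor-normalized counts, with pseudocount 1 on
  both numerator and denominator guarding zeros (the alternative —
  dropping zero-expression genes — changes nothing at the planted
  effect sizes tested here);
* members with ARR = 0, and members missing from the matrix, contribute
  to neither sum; a pathway with no contributing members is reported as
  absent, not zero;
* group-level PAL averages the case samples first, then forms CNR and
  PAL ("averaged biosample" convention).

Pathway topology (edges) never enters the statistic; only the
gene → ARR map does.

## Fusion screen

Removal rules: junction reads ≤ 2 AND spanning fragments ≤ 2 (the
plain reading of "neither exceeds 2"; an OR variant is a flag since the
intended Boolean is ambiguous), and any mitochondrial partner
(chromosome MT/chrM/chrMT or symbol prefix "MT-"). When both rules hit
one record the low-support fate is reported; each filter assigns fates
through that fixed priority, making the filters commute.

Classification of retained candidates is a reproducible
operationalization of by-inspection calls: overlapping same-strand loci
→ transcript variant; same chromosome, same strand, 5′ partner upstream
in transcription orientation, inter-locus gap ≤ 100 kb (configurable)
→ read-through; everything else → likely chromosomal rearrangement.
Paralog-family grouping (several named pairs likely representing one
event) needs homology data and stays a manual-annotation column, as
does browser-level exon-junction review (`manually_reviewed`
pass-through flag).

## Therapy scoring

BES = w_g·mean(log2 CNR over target genes) + w_p·mean(PAL/100 over
target pathways), weights 1/1 by default. The externally published
coefficients behind the original score are not reproduced here; the
form above is this package's documented operationalization of "target
gene expression plus targeted pathway activation", with weights and
thresholds config-exposed so published coefficients can be substituted.
Positive BES ⇔ net target upregulation. "Upregulated target" for the
k/n bookkeeping means CNR > 1 (strict) against the tissue-matched
control mean. Sample clustering of the BES matrix is agglomerative,
Euclidean, average linkage, cut at 2 clusters. The GD2 signature is the
mean log2 CNR of ST8SIA1 and B4GALNT1, called positive above 0 — the
threshold is a neutral default, not a clinically validated cut-point.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:
log-normal baseline means (meanlog 4, sdlog 1.5 — a realistic bulk
dynamic range with low-count genes present), NB counts with
Var = μ + αμ² (α = 0.1 default; 0.05 in the high-power planted
scenarios), log-normal library size factors (sdlog 0.15), per-tissue
log-normal effects (sdlog 0.7 default) that separate tissues in PCA but
cancel within tumor-vs-matched-normal contrasts, planted per-(gene,
group) fold changes, optional "normal-like" tumor samples drawn from
the matched control distribution, pathways whose activators/repressors
are drawn from planted-up/-down genes so the expected PAL sign is known
by construction, and fusion tables planting every filter fate and
class with the intended outcome recorded.

Default group sizes mirror the analyzed study (16 pituitary tumors
after exclusion vs 7 normals; 6 lung tumors vs 8 normals; pancreatic
tumors vs 8 normals) with one deviation: the pancreatic group gets 2
samples because the two-group NB test requires at least 2 per
condition, whereas the original comparison used a single sample — a
design this package deliberately refuses to test.

What the generator does **not** emulate: batch effects, GC/length
biases, isoform structure, correlated gene modules beyond the planted
pathways, cell-type composition differences, and FFPE degradation.
Passing the planted-truth suites therefore demonstrates correctness of
the estimators and bookkeeping under the assumed model, not robustness
to real-data artifacts.

## Problem sizes and numerical choices

Simulation suites use 2000-gene cohorts at the study's sample sizes
(8v8 for calibration scenarios), 10 replicates for null calibration,
and 2·10⁵ draws for the standalone overlap tests — sizes chosen so the
whole suite runs in seconds while keeping Monte-Carlo error well below
every asserted margin. Ties in BH are handled by stable sorting;
PCA sign ties resolve to the first maximal loading; cluster ties follow
the matrix's sample order. All randomness flows from a single integer
seed through `numpy.random.Generator`; derived stage seeds stay below
2³¹.
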