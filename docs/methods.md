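# Methods

This note documents the statistical models behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that matter for reproducibility.

## Synthetic study design

The generator emulates a population transcriptomic study of a continuous
socioeconomic exposure at desk scale: 500 samples, 2000 genes, 100
transcription factors (the defaults used by the analysis scripts and the
acceptance script).

**Cohort.** The SES composite is simulated directly as a standardized
continuous score (downstream models consume only the composite, so the four
underlying indicators — education, income, occupation, subjective status —
are not simulated separately). Mediators and covariates derive from the
SES score through a Gaussian copula: latent value ρ·SES + √(1−ρ²)·ε, then
thresholded (binary/ordinal variables) or rescaled (BMI ~ N(28, 6²) kg/m²,
waist in cm correlated 0.85 with BMI, perceived stress on a 0–40 scale).
Default correlations with SES: BMI −0.3, stress −0.2, smoking −0.25,
alcohol +0.05, financial stress −0.3, insurance +0.25 — magnitudes typical
of US young-adult cohorts. Ordered alcohol categories (0, 1–2, 3–5, >5
drinks) enter mediation models as numeric scores 0–3.

**Counts.** Negative binomial per gene with gene-specific dispersion
(mean 0.1, the standard bulk RNA-seq noise model; it is also what makes TMM
and the DE t-test meaningfully testable). The log2 mean for gene g, sample
i is

    baseline_g + effect_g · [(1−f_g)·SES_i + f_g·bmi_path_i]
      + module factor + batch/sex offsets + log2 library factor

with baseline ~ N(6, 1.5²) log2 units, library factors lognormal (sd 0.25
in log2), a batch shift of 0.2 log2 units, and 5 planted co-expression
modules of 100 genes each driven by latent per-sample factors (loading sd
0.4). Five percent of genes carry SES effects, half up, half down, with
|effect| ~ U(0.3, 1) log2 per SD of SES — the planted analogue of a
study-scale DEG list.

**Mediation path.** `bmi_path` is standardized BMI divided by the SES–BMI
copula correlation ρ. With mediator model slope a = ρ and outcome-model
mediator slope b = f·effect/ρ, the linear-mediation closed form gives
ACME/total = ab/(c′+ab) = f exactly, so the planted `mediated_fraction` *is*
the estimand. Half of the DE genes get f = 0.5 by default; if ρ were set to
0 while fractions are planted, generation refuses rather than silently
producing an unmediatable truth.

**Networks.** Transcription factors are genes (the last 100 gene ids), so a
TF can itself be differentially expressed (Set B is reachable). Five true
TFs are each wired to 10 DE targets at confidence 0.9. Decoy GRN edges onto
DE targets are drawn below the 0.4 medium-confidence threshold — this is
the planted-recoverability condition: a medium-confidence filter then
recovers exactly the true regulators. Decoy edges onto non-DE targets span
[0, 1] so the network as a whole has realistic score mass on both sides of
the threshold. PPI edges: 8 true neighbors per true TF at score 0.9, 3000
decoy edges with scores spanning [0, 1]. The writers emit the [0,1] float
dialect; the reader also accepts 0–1000 integer scores (divided by 1000).

**Ontology.** A forest of 3 roots, branching 3, depth exactly 3 below the
roots (120 nodes). Leaves are annotated with 10–40 genes drawn from the
measured genes plus PPI partner proteins; parents annotate the union of
their children. Six leaves are enriched for planted DE genes (60% of their
annotation) so over-representation analysis has signal to find.

**What the generator does not emulate:** allele/eQTL structure, survey
design weights, missing data, gene-length or GC biases, the mRNA
degradation structure of real blood draws, and real pathway-size
distributions. Passing tests therefore demonstrate that the inference chain
recovers the structure it targets under its stated noise model — not that
it is robust to every artifact of real cohort data.

## Normalization and differential expression

TMM follows the weighted-trimmed-mean-of-M-values algorithm: M/A values on
genes positive in both sample and reference, double rank trimming (30% on
M, 5% on A, keeping ranks in (⌊n·t⌋, n−⌊n·t⌋]), inverse asymptotic-binomial-
variance weights, reference = sample whose upper-quartile CPM is closest to
the mean upper-quartile, factors renormalized to geometric mean 1. A unit
test pins the factors to edgeR::calcNormFactors output frozen to 9 decimal
places. Note that scaling one sample's depth by c leaves every trimming
decision unchanged but shifts factors by ~1e-3: the reference half of each
pairwise weight does not rescale. This is inherent to inverse-variance
weighting, not an implementation artifact.

Batch adjustment is parametric empirical-Bayes location-scale correction:
per-gene batch effects estimated jointly with the covariate design,
standardized, shrunk toward normal/inverse-gamma priors fitted across
genes, removed, and finally recentered so each gene's grand mean is
preserved exactly (a pure location-scale correction has no business moving
the gene mean, and exact preservation keeps downstream DE invariant to the
adjustment's centering convention). A single batch is an identity
transform; a single-sample batch is an error. Constant covariates are
dropped from designs with a warning; genuine collinearity is an error that
names the offending columns.

Differential expression is plain OLS with a two-sided t-test on the
exposure coefficient — no empirical-Bayes variance moderation, because at
cohort scale (hundreds of samples) per-gene variances are well estimated
and moderation buys little; zero-variance genes are reported with beta 0,
p 1, and a `degenerate` flag rather than dropped, keeping the gene universe
aligned across all downstream modules. FDR control is Benjamini–Hochberg
throughout.

## Co-expression

Unsigned adjacency |cor|^β; the soft power is the smallest candidate whose
scale-free fit (signed R² of the log-log degree-frequency regression over
10 connectivity bins) reaches 0.8, else the best-fitting candidate.
Topological overlap: TOM_ij = (L_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij) with
zeroed diagonal, symmetrized; dissimilarity 1 − TOM is clustered with
average linkage and cut statically at height 0.99. The static 0.99 cut is
the classic choice and has the property both recovery regimes need:
correlated blocks merge far below it (block dissimilarities ~0.4 in the
planted-block tests) while unstructured genes merge essentially at 1 and
fall apart into sub-minimum fragments, so pure noise yields no spurious
giant module. Clusters below 20 genes are unassigned (label 0); modules
are renumbered by decreasing size.

Eigengenes are the first right singular vector of the gene-standardized
module submatrix, scaled to unit variance (ddof 1), signed to correlate
positively with the module's mean profile — a deterministic convention
independent of LAPACK sign choices. Eigengene–SES association reuses the DE
design; module–DEG enrichment is a one-sided (greater) Fisher exact test,
BH-adjusted across module×direction tests.

## Enrichment

ORA is the one-sided hypergeometric tail at the observed overlap, after
intersecting annotations with the universe (all genes surviving the
low-count filter, plus any regulator molecules in combined mode).
Cramér's V is computed on the 2×2 ORA table without continuity correction
(for 2×2 it equals |φ|); degenerate margins give V = 0 by convention.
Pooling assigns every ancestor within 3 levels of a tested node the minimum
p over its tested descendants, carrying that child's q-value rather than
re-adjusting (re-testing correlated children would double count), and the
union of descendants' contributing genes. Tested nodes are retained
alongside pooled ancestors; a tested ancestor whose descendant is more
significant inherits the smaller p. In combined multi-list mode a gene in
k query lists contributes 1/k to each, and per-pathway contributions are
normalized to sum to 1 — the fractional-split convention for overlap pie
charts.

## Upstream regulators and layers

Both score thresholds are strict (> 0.4 GRN confidence, > 0.7 PPI score),
so edges at exactly the threshold are excluded. Set B additionally requires
the DE TF to appear as a source of at least one above-threshold GRN edge —
a TF in the universe but absent from the tissue network does not qualify.
Set C is built from Set B only (protein neighbors of *differentially
expressed* TFs), and Sets B and D may overlap; the overlap is reported
rather than resolved. Direction tags propagate from recruiting genes; a
regulator recruited by both an up- and a down-regulated gene carries both
tags. GRN edges onto targets outside the measured universe are skipped with
a warning.

Layer bins: pathway-contribution count > 10 → layer 1, 6–10 → layer 2,
2–5 → layer 3, exactly 1 → layer 4; zero-count molecules are excluded. The
outer bins are fixed by the layer definitions; the middle split at 5 is a
config-exposed default chosen to divide the remaining range evenly on a
log-ish scale.

## Mediation

Quasi-Bayesian counterfactual mediation: coefficients of the mediator and
outcome models are drawn from normal approximations to their sampling
distributions (1000 draws by default); ACME = a·b per draw for continuous
mediators, and for binary mediators b·E[ΔP(M=1)] with the logistic mediator
model integrated over the sample using a unit exposure contrast centered on
each observation (x_i ± ½). Point estimates are draw means, intervals are
2.5/97.5 percentiles, and the ACME p-value is the two-sided add-one-
smoothed sign-crossing frequency. acme + ade = total holds by construction
per draw. No exposure–mediator interaction is included by default.

Proportions mediated are undefined (flagged, excluded but counted) when
|total| < 1e-8, and winsorized to ±5 before layer medians to tame near-zero
totals. The layer summary's "aggregated q" is a Fisher combination of the
cell's ACME p-values followed by BH across layer×mediator cells — one
specific, clearly-labeled choice for an otherwise underdetermined summary.
Under the complete null (no exposure→mediator path *and* no
mediator→outcome path) the product-of-coefficients test is conservative,
as is well known; its p-values are calibrated under the practically
relevant half-null where the mediator tracks the exposure but does not
affect the outcome, and that is what the test suite checks.

Per-gene seeds are derived from the master seed by a deterministic counter
schedule, so single (gene, mediator) cells can be recomputed in isolation
and full tables are bitwise reproducible.

## Randomization test

Random gene sets are drawn uniformly without replacement, one RNG per
replicate seeded from (master seed, replicate index), so partial reruns
reproduce. Null regulator sets reuse precomputed threshold-filtered
adjacency indexes, making 1000 replicates over the default networks a few
seconds of set algebra. Empirical p = (appearances + 1)/(n + 1) — add-one
smoothing guarantees p > 0 for the downstream log.

The per-set Fisher combination −2Σln p ~ χ²(2k) is reported as the set
statistic. Its inputs, however, are appearance *frequencies* — under the
null they concentrate near each molecule's recruitment rate (for Set A,
|A|/|universe| by construction) rather than being uniform — so the
chi-square reference is anti-conservative for large sets and the combined
p should be read as a descriptive index, not a calibrated tail
probability. The output therefore also includes `calibrated_p`: the
observed per-member mean Fisher statistic ranked (add-one smoothed)
against the same statistic computed for every null replicate's own derived
set, leave-one-out. This statistic is approximately uniform when the
observed set is itself a random draw, which the test suite verifies across
200 meta-replicates.

## Problem sizes and determinism

Default study scale: 500 samples × 2000 genes × 100 TFs, 120 pathways,
1000 randomization replicates, 1000 quasi-Bayesian draws, mediation run on
up to 200 layered DE genes (config `max_mediation_genes`) — sizes at which
every planted structure is comfortably recoverable and a full run takes
seconds on one core. Simulation-based tests use smaller grids (stated in
each test) chosen the same way. Everything random flows from one master
seed through named `SeedSequence` spawns; the pipeline manifest records
config hash, per-stage dimensions, and SHA-256 hashes of every output
table, and reruns with an unchanged config are bit-identical.

## Known limitations

Per-gene OLS assumes log-CPM normality — adequate at cohort n but
anti-conservative for very low counts; no voom-style precision weights.
Module detection uses a static cut, not dynamic tree cutting, so nested or
close modules may merge. The mediation models assume sequential
ignorability and are association-descriptive, not causal; no sensitivity
analysis is provided. The combined chi-square randomization p inherits the
miscalibration described above and should be interpreted alongside
`calibrated_p`. The synthetic generator's omissions are listed in the
design section; none of the acceptance-style checks speak to robustness
against real-data artifacts they exclude.
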