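# Methods

## Data model and coordinates

All intervals are 0-based half-open (BED convention). "Overlap" always
means at least one shared base, so touching intervals are neither merged
nor counted as intersecting. Chromosome names are matched exactly; a
`chr`-prefix normalization exists but is opt-in, never silent.

## Consensus regions and counting

Per-sample peaksets are pooled and merged single-linkage (a chain of
pairwise-overlapping peaks becomes one region); a region's support is
the number of distinct samples contributing at least one overlapping
peak, and regions with support < `min_samples` (default 3) are removed,
followed by sex chromosomes (default chrX/chrY). Fragments are assigned
to the region containing their *start base*. This rule means a
boundary-spanning fragment is counted once and a fragment overlapping a
region only past its start is not counted for it; since consensus
regions are disjoint, the rule only matters at boundaries, and it keeps
library-size bookkeeping exact (every fragment counts at most once).
Library size is the sample's total fragment count, in-region or not, as
RPKM's "per million" conventionally refers to total mapped fragments.

## Normalization

RPKM = count / (region length / 10³) / (library size / 10⁶), then
log2(RPKM + c) with pseudocount c = 0.5 (config-exposed; any positive
constant preserves contrasts asymptotically while keeping zeros finite).

Batch adjustment is the parametric empirical-Bayes location/scale model:
per-region OLS on batch indicators plus the protected covariates (group
with CON reference, sex when both present), standardization of the
residual batch deviations by the pooled variance, per-batch
normal/inverse-gamma priors estimated by moments, and iterative
posterior updates for the batch location γ* and scale δ* to an
element-wise relative tolerance of 1e-4 (cap 100 iterations). The
protected fit is restored after rescaling, so group and sex effects
survive adjustment. With a single batch the operation is the identity by
contract. The implementation agrees with the Bioconductor reference
(`sva::ComBat`) to < 1e-8 on a shared fixture (test-suite cross-check
via Rscript).

A documented limitation: adjusting first and testing afterwards on the
adjusted values is mildly anti-conservative, because subtracting
estimated batch locations removes part of the noise that the downstream
residual variance should see (about 6% of tests below p = 0.05 at a
nominal 5% with two batches of 15 samples; the reference implementation
behaves identically). The calibration checks therefore assess the
testing machinery on the single-batch configuration, where the
adjustment is exactly the identity, and this inflation is accepted as a
property of the published two-step design rather than an implementation
artifact.

## Differential testing and moderation

Each tier is an ordinary least-squares fit per region with treatment
coding: sex-concordant (`~ group + sex`, all 30 samples), female-only
and male-only (`~ group`, 15 samples each). Contrasts: PAEvCON = β_PAE,
PFvCON = β_PF, PAEvPF = β_PAE − β_PF; positive log fold change means
higher methylation enrichment in the first-named group.

Residual variances are shrunk empirically: with z = log s², the
hierarchical scaled-F model implies Var(z) = trigamma(d/2) +
trigamma(d₀/2); d₀ is recovered by Newton inversion of the trigamma
function on the excess spread and s₀² from the matching mean. When the
observed spread does not exceed the chi-square sampling spread, d₀ = ∞
and s₀² is the geometric-mean variance (the common value when all
variances are equal). The moderated t uses the posterior variance with
d₀ + d degrees of freedom; d₀ = 0 reproduces the classical t test
exactly (verified against statsmodels OLS). Benjamini-Hochberg
correction (statsmodels step-up, verified against a brute-force oracle)
is applied within each contrast × tier, matching how the study reports
per-contrast significance; a joint correction would change all counts.

The choice of a Gaussian moderated model on batch-adjusted log2-RPKM —
rather than a count-based negative-binomial GLM — reflects that the
batch-adjusted values are continuous and no longer counts; the
moderation retains the small-sample robustness that count-model
shrinkage would otherwise provide.

## DMR classification

Categories from the three significance flags (FDR < 0.05 by default):
PAE-specific (PAEvCON ∧ PAEvPF ∧ ¬PFvCON), PF-specific (PFvCON ∧ PAEvPF
∧ ¬PAEvCON), shared (PAEvCON ∧ PFvCON); the rules are mutually
exclusive. All tiers share one consensus region set, so cross-tier
"overlap" is identity of region ids: a combined-sex call that also
appears (same category) in a sex tier is removed from the combined-sex
tier — it is taken to be driven primarily by that sex. A region called
in both sex tiers is kept in both with a logged warning. Direction uses
the two contrasts that define the category, with the PF-specific second
contrast sign-flipped so that "down in PF" means PF lower than both
comparison groups; the robustness flag requires |logFC| ≥ log2(1.5) in
both. The direction balance test is the Monte-Carlo goodness-of-fit χ²
against an expected 50/50 split with B = 2000 binomial replicates and
the add-one p-value (1 + #{χ²_rep ≥ χ²_obs})/(B + 1) — the convention of
R's simulated-p chi-squared test. Its floor is 1/(B+1) ≈ 0.0005, and an
odd total forces p = 1 whenever the observed split is the most balanced
achievable.

## Feature annotation and permutation enrichment

A region receives every feature class it overlaps by ≥ 1 base. Promoters
are defined on the coding strand: [TSS−200, TSS) and [TSS−1500, TSS) for
+ genes, [TSS, TSS+200) and [TSS, TSS+1500) for − genes. A region
overlapping an exon and an intron *of the same gene* is an intron/exon
boundary; a region with no gene-derived feature is intergenic (a CpG
island alone does not rescue a region from intergenic status).

The enrichment null draws, without replacement, random subsets of the
tested (autosomal) region universe of the same size as the DMR set —
the only construction that yields a non-degenerate null for feature
proportions — 10,000 times by default. The p-value is one-sided with an
add-one correction, on the side of the observed deviation, labelled
enriched or depleted. Subset lengths and chromosomes are not matched;
the null is a plain size-matched subset.

## Gene-score resampling

Gene score = −log10(best region p) for the contrast at hand, over the
regions annotated to the gene (body or promoter overlap). The set
statistic is the mean member score; the null resamples that many scores
from the scored-gene universe without replacement (10,000 iterations by
default, shared per set size), with add-one empirical p and BH across
retained sets (scored size within [2, 2000]). Resampling ties are
counted into the tail with a 1e-9 relative tolerance, since the observed
and null means take different floating-point summation paths.
Multifunctionality is handled by a leave-out re-run: the top ~1% most
set-promiscuous genes' scores are removed and the test repeated with the
same seed; sets that lose significance are flagged (and reported, not
dropped). Final pathway lists apply the same contrast-intersection rules
as the DMRs to set-level significance. External gene lists are matched
case-insensitively on symbols after deduplication.

## The synthetic cohort

The generator emulates the study design: 3 groups × 2 sexes ×
`n_per_cell` (default 5) animals, at most one animal per sex per litter,
two near-balanced batches; a miniature genome of four 30-Mb autosomes
plus one sex chromosome carrying ~400 genes with exon/intron partitions,
promoters, UTRs and CpG islands; ~5,000 non-overlapping enrichment
regions with log-normal lengths (median ≈ 465 bp, matching reported DMR
sizes); and negative-binomial fragment counts with mean
μ_rs = baseline_r · libfactor_s · 2^(batch + planted effect) and a
single common dispersion φ = 0.1 (variance μ + φμ²) — overdispersed
sequencing counts with the simplest dispersion structure. Library-size
factors are log-normal (0.2 log2 sd) and represent sequencing depth;
the batch effect (0.5 log2 units on all regions of a batch) models
enrichment-efficiency differences under fixed depth, so RPKM removes
depth but not batch. Planted DMRs (default 10% of regions, 1 log2 unit)
are spread evenly over every tier × category × direction cell and only
on autosomes. Sex-chromosome regions get a sex-dependent baseline on
purpose: a pipeline that forgets to drop them produces visible
artifacts. Per-sample peaksets jitter the true boundaries by ±30 bp
(regions are placed ≥ 80 bp apart so jittered peaks of neighbours never
merge) with independent dropout; fragment starts are uniform within
their region, so start-base counting reproduces the count matrix
exactly, and background fragments start strictly outside every region.

What the generator does **not** emulate: region-specific dispersions,
litter random effects, correlated neighbouring regions,
immunoprecipitation chemistry, or read-level sequence content. Passing
recovery tests therefore demonstrates the statistical machinery under
the stated design, not robustness to every property of real meDIP-seq
data.

### Power at the study's sample size

With φ = 0.1 the per-sample standard deviation of log2 signal is ≈ 0.47,
so a 1 log2 effect gives a noncentrality of ≈ 4.9 in the combined-sex
tier (10 vs 10) but only ≈ 3.4 in a single-sex tier (5 vs 5). Against an
adaptive BH cutoff near z ≈ 3.2 and the requirement that *both* defining
contrasts be significant, single-sex detection probability is ≈ 0.4 per
planted region while combined-sex detection is ≈ 0.9. The benchmark
reports sensitivity per tier for this reason; low sex-specific recovery
at n = 5 per cell is a property of the design (and mirrors the study's
own observation that its sample size limited sex-specific detection),
not of the implementation.

## Orchestration and determinism

`medipdmr.pipeline` validates configs (unknown keys rejected, ranges
checked, study defaults injected: min support 3, FDR 0.05, pseudocount
0.5, 10,000 permutations, gene-set bounds [2, 2000] with 10,000
iterations, B = 2000) and runs the stages in dependency order. Every
stage draws its seed from the master seed by a fixed spawn key (its
position in the stage list), so skipping or resizing one stage never
shifts another stage's randomness; re-running an identical config
reproduces byte-identical outputs, verified by content hashes in the run
manifest. The `analysis/` scripts are the narrative per-stage surface
over the same library. Problem sizes used in tests and the acceptance
harness (cohorts of 300–5,000 regions, permutation counts of 500–10,000)
are chosen so each check exercises the statistic it targets at
Monte-Carlo error well below its tolerance.

## Known limitations

* Adjust-then-test anti-conservativeness (above) is inherited from the
  two-step design; modelling batch inside the per-region regression
  would remove it but depart from the published procedure.
* The multifunctionality correction is a leave-out robustness re-run,
  an explicit approximation of the cited tool's internal correction,
  which is not publicly specified at the version used.
* The enrichment null does not length- or GC-match its subsets.
* Printed χ² statistics for direction tests are the plain goodness-of-fit
  values; the Monte-Carlo p-value is the inferential quantity.
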