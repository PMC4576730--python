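# Methods

This note documents the statistical procedures implemented in `crosstrait`,
the synthetic-data model used to exercise them, the defaults and why they
were chosen, and the numerical decisions a maintainer would want written
down.

## Harmonization

Two summary-statistic tables are joined by rsID (not chrom:pos): lookups
between consortium datasets are rsID-keyed in practice, and proxy
substitution for untyped SNPs is deliberately left to the caller. Effects
are betas on the additive scale throughout; odds-ratio columns are converted
by natural log at read time so no downstream code branches on the effect
scale. Where the second table's effect allele equals the first's other
allele, its beta sign is flipped and its frequency replaced by 1−EAF. No
strand column exists in the canonical dialect, so strand can only be
resolved by allele matching — which fails silently for palindromic A/T and
C/G pairs; those are therefore removed (default on). SNPs with
min(EAF, 1−EAF) ≤ 0.01 on either trait are removed; the boundary is
excluded, i.e. a MAF of exactly 0.01 is dropped. Every filter's removal
count is logged and returned, and retained + removed always equals the join
size (tested).

Harmonization is idempotent, and flipping the allele frame of an input
leaves the result unchanged (both are property-tested).

## LD pruning

Greedy tail-first pruning: repeatedly retain the SNP with the smallest
discovery p-value among those not yet eliminated, then eliminate every SNP
with r² > 0.2 against it. The LD source is either a sparse precomputed
pairwise r² table (absent pairs are r² = 0, mirroring a sparse lookup
table) or r² computed as squared Pearson correlation of dosage vectors
within a window. Ties on p-value break to the lexicographically smallest
rsID, which makes the output independent of input row order (tested by
permuting rows). The result records, for every eliminated SNP, which
retained SNP eliminated it, so the partition can be audited. Which trait's
p-values order the pass is a parameter (`rank_by`); the pipeline runs one
pruning per discovery direction, since the most defensible reading of the
procedure is per-discovery-trait pruning.

## Enrichment tests

Threshold semantics are strict `<` on both axes (a SNP exactly at a
threshold falls in the "not associated" stratum). The 2×2 test is Pearson's
χ² with Yates' continuity correction, with the correction term clamped at
zero: stat = Σ max(0, |O−E|−½)²/E. The clamp matters only when |O−E| < ½
and makes a perfectly proportional table score exactly 0 instead of being
over-corrected; away from that region the statistic agrees with the
standard corrected χ² to 1e-10 (tested against an independent formula
evaluation and against `scipy.stats.chi2_contingency`). A zero margin makes
the test undefined; single tests raise, grid cells are flagged invalid
rather than fatal.

The binomial lookup test at genome-wide significant loci is the exact
one-sided upper tail P(X ≥ k), X ~ Bin(n, p₀) — enrichment ("lower
p-values than expected") is inherently directional. Per-stratum proportions
get Wilson score intervals, which behave sensibly at the small counts that
occur in discovery tails; the bounds are exactly 0 at k=0 and 1 at k=n and
are clamped against roundoff.

Q–Q summaries use expected quantile i/(N+1) for rank i of N and report the
genomic inflation factor λ as the median observed 1-df χ² over the χ²₁
median. λ is computed on the full harmonized set, not the pruned one:
pruning retains the most significant SNP per LD clump, which biases the
p-value quantiles low and would inflate λ by construction.

## Permutation null

Each draw samples, without replacement, as many SNPs from the pruned
lookup-trait pool as sit in the discovery tail, and counts those passing
the lookup threshold; the empirical p is the plain fraction of draws
meeting or exceeding the observed count, with no +1 pseudo-count (an
empirical 26/10000 is reported as 2.6×10⁻³, and 0/draws is reported
numerically as 0 with a "< 1/draws" annotation in text output). Because
draws are without replacement from a fixed pool, the per-draw count is
exactly hypergeometric; the implementation is tested against that closed
form within Monte-Carlo error. The pool defaults to all pruned SNPs,
discovery-tail members included; an exclusion mask is available. A single
seeded generator drives all draws, so results are bit-identical for a given
seed. By default the pipeline runs the permutation only where the χ² p is
below 0.10, where an empirical confirmation is informative.

## Polygenic profile scores

Score SNPs are the pruned discovery-trait SNPs below each threshold in
{0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.75} (nested by construction);
weights are the signed discovery betas — mathematically equivalent to
|β| with allele switching, but with a simpler audit trail. Dosage columns
coded on the other allele are flipped d → 2−d; missing dosages are imputed
with the observed column mean (= 2f̂ of the score allele), the standard
profile-scoring convention. Association uses a Welch two-sample comparison
of case and control means and a logistic regression of status on the
standardized score (slope = log-OR per SD, comparable across thresholds),
fitted by IRLS to tolerance 1e-8; Nagelkerke pseudo-R² is the
variance-explained summary. Complete separation is flagged, not fatal.

## Direction of effect

Concordance is sign(β_A) = sign(β_B) on the shared allele frame; loci with
an exactly-zero effect carry no direction and are dropped with a logged
count. The two-sided binomial test against P = 0.5 doubles the smaller
tail and caps at 1 — the simplest defensible two-sided construction; the
minimum-likelihood method is a documented alternative that differs only in
asymmetric cases. The regression is OLS with intercept of trait-A betas on
trait-B betas, slope p from t on n−2 df; R² equals the squared Pearson
correlation (tested).

## Pathways

Each SNP maps to the closest gene within 1 Mb (distance 0 inside the gene
body, else the gap to the nearer end; 1-based inclusive coordinates
internally, with a converter from 0-based half-open BED). SNPs with no gene
within the window are excluded and counted; equidistant ties break to the
lexicographically smallest symbol, logged. Genes hit by several SNPs enter
the test set once — overrepresentation counts genes, not SNP–gene pairs.
Each pathway is tested with a one-sided (enrichment) Fisher exact test on
the 2×2 of set membership × pathway membership over the catalog universe,
equivalent to the hypergeometric upper tail (tested against enumeration).
The Bonferroni denominator is caller-supplied rather than recomputed from
the catalog, because the appropriate family size is an analysis decision
(sub-catalogs, merged ontologies) that the test should not guess.

## Synthetic data model

The generator is the package's study-condition definition, not a
convenience fixture. SNPs sit in `n_blocks` blocks of `block_size` with
within-block correlation Corr(zᵢ, zⱼ) = ρ_LD^|i−j| and independence across
blocks. A block is causal for trait A only, B only, both, or neither, in
fractions π_A, π_B, π_shared; at most one tag SNP per block carries the
effect. Shared blocks draw (β_A, β_B) from a bivariate normal with
correlation ρ_effect (drawn via an eigendecomposition so the degenerate
ρ = ±1 cases work). Effects live on the standardized-genotype scale, so
per-SNP power is frequency-independent; allelic betas are obtained via
β_allelic = β_std/√(2f(1−f)). Marginal z-scores are multivariate normal
with mean equal to the tag's noncentrality √n·β_std propagated through the
LD (the tag-correlation column of the block matrix) — what an
individual-level GWAS produces in expectation, generated directly at the
z level for speed. Two-sided p-values follow from the normal; reported SEs
are 1/√(2f(1−f)n). The LD table emitted alongside contains the true
within-block r² = ρ_LD^(2|i−j|) above a floor (0.05 by default), mirroring
a sparse precomputed reference table.

Defaults are one fixed set of study conditions: 10⁴ SNPs (400 blocks of
25), ρ_LD = 0.8, MAF ~ U(0.05, 0.5), n_A = 10,254 (a surgically confirmed
case–control GWAS of 3,194 cases and 7,060 controls), n_B = 77,167 (a large
quantitative anthropometric meta-GWAS), standardized effect SDs 0.02
(trait A) and 0.01 (trait B) — sized so top causal tags reach z ≈ 4–6,
matching the strongest single-locus signals such scans report — and
ρ_effect = −0.5, the discordant direction observed at real shared
disease/fat-distribution loci. π_shared defaults to 0.03 with π_A = π_B
= 0.05.

Case–control genotypes for the scoring stage are Binomial(2, f) per SNP
(no LD — the score SNPs are already pruned), with a liability-threshold
model: liability = Σ β_std·(g−2f)/√(2f(1−f)) + ε, ε scaled so total
variance is 1, cases above the upper `prevalence` quantile, sampled in
batches until the quotas are met.

What the generator does **not** emulate: imputation uncertainty and INFO
filtering, population stratification and relatedness, realistic
heterogeneous LD maps, allele-frequency–dependent genetic architecture, and
case–control genotypes in LD. Passing tests therefore demonstrate
correctness of the statistical machinery under a clean polygenic model, not
robustness to those real-data complications.

## Calibration and problem sizes

The null-calibration checks run 300–500 replicates of the full
harmonize→prune→test path on 10⁴-SNP null datasets (π = 0 everywhere), and
evaluate the χ² rejection rate at discovery = lookup = 0.1. That operating
point is chosen for test validity: after pruning (~2,200 SNPs retained) the
smallest expected cell is ≈22 there, inside the χ² approximation's
validity region, whereas at the pipeline's default discovery tail (10⁻³)
a desk-scale null dataset has a 2–3 SNP tail where the Yates-corrected test
is strongly conservative. That conservativeness is itself asserted as a
property (the sparse-tail test never rejects above nominal under the null).
Power checks use π_shared ∈ {0.01, 0.03, 0.05} at ρ_effect = −0.5 with
60–100 replicates per setting. These sizes are the package's reference
problem sizes for its own validation; all are parameters.

## Known limitations

- The greedy pruner is exact but quadratic in the worst case for dense LD
  tables; it is intended for sparse precomputed r² tables.
- The permutation loop draws index sets one draw at a time; at very large
  pool × draws products the hypergeometric closed form (which the
  permutation provably converges to) is the cheaper route.
- Logistic fits use no covariates (no ancestry principal components);
  confounding control is out of scope.
- The two-sided sign-test construction (tail doubling) can exceed the
  minimum-likelihood two-sided p in asymmetric cases; both conventions are
  defensible, one is implemented.
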