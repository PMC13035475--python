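# Methods

This note documents the models, estimators and numerical choices behind
`mosaicpool`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Setting

A pooled ("mosaic") experiment mixes L cell lines into one culture or
xenograft, splits the pool into hashed samples (vehicle and one or more
drugs/doses, with replicates), and profiles the surviving cells by scRNA-seq.
Two identities must be recovered per droplet — the sample (hashtag oligos)
and the line of origin (natural genetic variation) — after which the pool
becomes L parallel drug-response experiments read out in one assay: cell
counts carry survival phenotypes, transcriptomes carry response programs.

## Demultiplexing

**Hash calls.** Hashtag counts are CLR-transformed per cell
(log1p counts minus the cell's mean log1p). Each channel gets an across-cell
positivity threshold from a one-dimensional two-class Otsu split (maximal
between-class variance), chosen because it is deterministic and
parameter-free; a quantile threshold is available as an override. One
positive channel → that sample, several → hash doublet, none (or an all-zero
cell) → unassigned.

**Genotype calls.** Per cell and candidate line, allele reads at SNP v follow
alt ~ Binomial(n_v, p_v), p_v = (1−ε)d_v + ε(1−d_v), with d_v the line's alt
dosage (0, ½, 1; missing dosages are skipped) and ε the per-read error
(default 0.01, the sequencing-error scale). A doublet hypothesis uses the
fixed-α mixture of two lines' dosages with α = 0.5 — a doublet is an equal
mix of two cells. The call maximizes the posterior over L singlets and
L(L−1)/2 unordered pairs, with prior mass doublet_prior (default 0.05) spread
over pairs. Cells with fewer than 10 informative reads are left ambiguous:
below that, posterior margins are noise-dominated in simulation. Ties break
lexicographically and are logged. The likelihood is computed sparsely for all
hypotheses at once, so 36 hypotheses × thousands of cells is sub-second.

**Cluster → line maps.** When per-cell calls are unreliable, expression
clusters (any upstream clustering; clustering itself is out of scope) are
assigned by pooling member cells' alt fractions per variant and taking the
line whose dosage vector has the highest Pearson correlation.

## QC and phenotype

Apoptotic cells are flagged, not removed, by fixed thresholds — fewer than
1,000 detected genes, fewer than 2,000 UMIs, or mitochondria-encoded fraction
above 0.15 (symbol prefix `MT-`, overridable by annotation). The flagged
compartment is itself a phenotype (composition χ² across conditions).

Cell-cycle scores use CP10k/log1p expression: score = mean over the geneset
minus mean over a seeded random control set matched on average expression
(25 equal-frequency bins, 50 controls per target gene — standard practice
for geneset scoring, deterministic given the seed). Phase is G1 iff both S
and G2M scores are ≤ 0, else the larger score's phase. The G1-fraction dose
trend is OLS on log10(dose) over nonzero doses (vehicle excluded; a
vehicle-anchored variant normalizes fractions to DMSO first), with Pearson-R
significance, sidedness configurable.

## Sensitivity

Growth rate r = ln(Y_t/Y_0)/t. "Inverse balancing" of seeding is ambiguous
between seeds ∝ 1/r and seeds ∝ exp(−rT); the default is exp(−rT) (equal
expected representation at horizon T), with the literal 1/r mode behind a
flag (requires r > 0). Counts round by largest remainder so they sum exactly.

Zero cell counts get a Haldane–Anscombe pseudocount of 0.5 before fractions.
Replicate fractions are averaged within an arm before ratios. Relative
survival is log2(f_treated/f_vehicle); group scores average member lines and
report replicate mean ± SD. The dose slope fits log10(ratio vs vehicle) on
log10(dose) (≥3 nonzero doses) with a one-sided p in the depletion
direction. The mutation lasso regresses survival scores on mutation
indicators present in ≥2 lines (singletons are unidentifiable at ~11 lines),
λ by leave-one-out CV; negative coefficients mean sensitizing.

## Heterogeneity

Cluster-shift Gini: per cluster, relative count = (treated in cluster /
cluster size) / (overall treated share); G = Σᵢⱼ|xᵢ−xⱼ|/(2n²x̄) over
clusters. The null permutes condition labels within the line with cluster
sizes fixed — under that permutation the per-cluster treated counts are
multivariate hypergeometric, which is sampled directly (no explicit
shuffling), making thousands of permutations cheap. z = (G − null mean)/null
SD; defaults n_perm = 1,000, seeded. Published values of this statistic on
real pooled datasets depend on the dataset and its upstream clustering and
cannot be reproduced from simulation; the package instead verifies
calibration (null z ~ N(0,1)) and power (confined survivors ⇒ z ≥ 3) on
synthetic pools.

MI enrichment quantizes a continuous vector into equal-frequency bins by
stable rank (bin sizes differ by ≤1; constant vectors split into consecutive
blocks), then MI in nats between bins and a binary membership, with a z from
membership shuffles (default 1,000) and per-bin two-tailed hypergeometric
tail p, signed + for over-representation. The cell-level application — bins =
expression deciles, membership = treated — is exposed as
`treated_enrichment_by_quantile`.

## Cross-model differential expression

Per line: log2FC of mean CP10k expression (pseudocount 1) treated vs
control, with a two-sided rank-sum p per gene; lines with < 20 cells in
either arm are skipped. Across lines: each line's log2FC vector is z-scored
across genes and averaged per gene (mean difference z).

The bootstrap null needed a design decision. Resampling whole gene rows
(preserving inter-line correlation) reproduces the marginal distribution of
the observed statistic, and empirical p-values taken against one's own
marginal distribution are ≈ rank/m — after BH, no gene can reach a small q
no matter how strong its signal. The default null therefore draws each
line's z from an independently resampled gene: this destroys exactly the
cross-line linkage that a real shared signal carries while preserving each
line's marginal z distribution. The row-resampling variant remains available
(`resample='rows'`) for conservative use. B = 10,000 by default, seeded;
p = (1 + #{|null| ≥ |obs|})/(B + 1); BH within a contrast.

Group deltas (e.g. 8 G12C vs 2 non-G12C lines) are per-gene differences of
group mean log2FC with Welch t p (withheld for groups of size < 2). Geneset
shift tests report both Mann–Whitney and two-sample t p of geneset vs
background values; a set equal to its background has no contrast and returns
p = 1. Model downsampling reruns the aggregation and geneset tests on random
k-line subsets, recording median p per geneset and per size-matched random
set; random-set flatness is best judged by a Spearman of p against k pooled
over all draws (per-set Spearman on a handful of k values is scale-free and
unstable).

## Synergy

Bliss expectation eA + eB − eA·eB on the inhibition scale; effects from
survival are 1 − survival/control clamped to [0, 1] (stimulation is reported
but excluded from synergy by default); with ≥3 replicates a two-tailed
one-sample t tests per-replicate synergy against 0. The G1-arrest variant
uses effect = max(0, (G1 − G1_vehicle)/(1 − G1_vehicle)) — the fraction of
the remaining non-G1 pool pushed into arrest — with a raw-difference
alternative behind a flag.

Gene-level synergy covariates come from pseudobulk (cells summed per line ×
condition × replicate) log-linear count models: log μ = log(size factor) +
line + treatment, median-of-ratios size factors, batched IRLS shared across
genes (Poisson pass, then one NB reweighting with per-gene method-of-moments
dispersion, floor 1e-8 — no empirical-Bayes shrinkage; recovery, not
estimator identity, is what the tests check). Coefficients are natural-log
scale. s = (βA + βB) − βAB per gene per line, averaged over lines. The
bootstrap null (gene resampling of mean s) uses robust moments
(median / 1.4826·MAD): a minority of genes with real interaction must not
shift the center that additive genes are scored against. Ranking is by the
t statistic (per-gene line spread vs the null center); a z against the null
scale is reported alongside. Note the size-factor invariance of β is exact
under fixed weights and approximate (≲0.02) once the data-driven dispersion
enters the weights.

## CRISPRi screens

Guide z is the pooled two-proportion statistic on guide count over library
size — the score test of the binomial (logit) model of per-read guide
membership, weighted by total reads; replicates are summed within arm by
default. Raw z are overdispersed (biological variability between replicate
cultures exceeds binomial noise), so they are standardized before
aggregation. The default null scale comes from replicate consistency: z is
recomputed per matched replicate pair, and the within-guide variance across
pairs — which cancels the guide's true effect — estimates the null variance
of the summed-arm z (both noise components scale as 1/m over m replicates,
so the per-pair and summed-arm z have equal null variance). This uses every
guide, is immune to contamination by real effects, and calibrates the null
ρ SD to ~1 even when a fifth of the library carries strong effects; a
rank-based inverse-normal transform (Blom offset) rescaled to the
non-targeting controls is the fallback when fewer than two replicate pairs
exist, and is exposed as `normalize_z`. Per gene, ρ = mean(z)·√k (Stouffer —
the canonical combination for a "combined z"), two-tailed normal p, BH
across genes with non-targeting controls excluded. Group tests: one-sample
t of a gene group's ρ against 0; two-sample t between screens.

## Synthetic data

The generator collapses growth and treatment into per-sample multinomial
weights ∝ baseline weight × exp(r·t) × survival(dose) — the readout of the
assay is end-point representation, so agent-based dynamics would add nothing
testable. Survival follows a Hill form (max_kill, IC50, slope); the true
dose–response shape of real lines is unknown, so Hill is a simulator choice,
not a claim. Counts are NB (gamma–Poisson) with a single global dispersion
(default 0.3 at the cell level, 0.02-0.05 at pseudobulk scale) around
per-line lognormal expression profiles; library sizes are lognormal.
Planted programs multiply member genes by 2^shift in treated survivors, with
a compositional correction so the realized fold change in normalized
expression equals the planted value (profiles sum to 1, so an uncorrected
multiplier is damped by the program's expression share; the correction
spreads the complementary compression over non-program genes). Doublets sum
two cells' counts with the partner drawn from a different line (a same-line
doublet is genotypically a singlet). Apoptotic cells scale library size by
0.25 and inflate the mitochondrial share to ~0.35 so they cross the QC
thresholds by construction. Allele reads are Poisson-total per cell spread
uniformly over variants with the same binomial error model the caller
assumes; guide screens plant 2^effect fold changes on targeting guides.

What passing these tests shows: the estimators recover what they claim from
data that matches their model assumptions at realistic depths and sizes.
What they do not show: robustness to ambient RNA, line-specific doublet
rates, batch effects, empty droplets, variable guide efficiency, clustering
artifacts, or misspecified dose–response shapes — none of which the
generator emulates.

## Validation experiment sizes

The validation battery (`mosaicpool.validation`, run by
`scripts/acceptance.py` and the acceptance tests) uses: 2,000 cells / 8
lines / 200 SNPs / mean depth 60 / ε = 0.01 / 5% doublets for
demultiplexing; 10 lines × 5,000 cells/arm × 3 doses × 2 replicates for
survival recovery (5 independent pools; slope errors judged on lines with
true slope ≤ −0.1 per decade, since the relative error of a near-flat slope
is pure counting noise); 200 null + 200 planted simulations with 300
permutations each for Gini calibration; enumeration oracles up to length 12
for MI/hypergeometric exactness; 100 simulations each for Bliss and for
synergy-covariate recovery (2,000 genes, 50 planted interactions, 4 lines ×
2 replicates); 10 screens of 46 + 46 + 400 genes × 5 guides (FDR pooled
across screens — a single screen's empirical FDR at ~100 discoveries is
quantized too coarsely to be a stable estimate); and 8 lines × 1,200 genes ×
400 cells/arm with a 50-gene program at −0.1 log2 for the cross-model
downsampling analysis.

## Known limitations

- The genotype caller assumes a correct reference; contaminated or drifted
  lines degrade both accuracy and the doublet/singlet boundary.
- The pseudobulk GLM uses moment dispersion without shrinkage; at very few
  replicates per condition its per-gene dispersion is noisy (coefficients are
  still consistent, standard errors are not reported for that reason).
- The cross-model bootstrap treats genes as exchangeable within a line;
  expression-level-dependent log2FC noise makes weakly expressed genes
  overrepresented in the tails of any single line.
- Bliss synergy inherits the usual caveats of effect-scale choice; no
  Loewe/HSA/ZIP alternatives are provided.
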