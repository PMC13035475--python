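# mosaicpool

Analysis of **pooled multi-cell-line single-cell drug-response experiments** —
"mosaic" pools in which many genetically distinct cancer models are mixed in
one 3D culture or xenograft, treated with drugs, and read out by single-cell
RNA-seq. One sequencing run then measures, for every model simultaneously,
how many cells survived each treatment and what transcriptional state the
survivors adopted.

The package is aimed at computational biologists analyzing such pools (or
benchmarking methods for them). It covers the full desk-side pipeline:

| stage | module | what it computes |
|---|---|---|
| demultiplexing | `mosaicpool.demux` | hashtag sample calls (CLR + per-channel Otsu split); line-of-origin from SNP allele reads under a binomial model with α = 0.5 doublet mixtures; cluster→line maps by pseudobulk allele correlation |
| QC / phenotype | `mosaicpool.qc` | apoptotic flags (n_genes < 1,000, n_counts < 2,000, mito_frac > 0.15); S/G2M cell-cycle scores with expression-matched controls; composition χ²; G1-fraction dose trends |
| sensitivity | `mosaicpool.sensitivity` | growth rates r = ln(Y_t/Y_0)/t and inverse-balanced seeding; pool fractions; relative survival log2(f_drug/f_vehicle); log–log dose slopes; mutation–phenotype lasso |
| heterogeneity | `mosaicpool.heterogeneity` | Gini concentration of treated cells over expression clusters with a permutation z; mutual-information enrichment over equal-frequency bins with per-bin hypergeometric tails |
| differential expression | `mosaicpool.diffexp` | per-line log2FC + rank-sum p; cross-model mean difference z with bootstrap p and BH q; group deltas (e.g. KRAS-G12C vs non-G12C) with Welch t; geneset shift tests; model-downsampling curves |
| synergy | `mosaicpool.synergy` | Bliss independence eA + eB − eA·eB on survival and on G1-arrest phenotypes; pseudobulk count GLMs; gene-level synergy covariates s = (βA + βB) − βAB |
| CRISPRi screens | `mosaicpool.screen` | per-guide binomial-logit z; noise-calibrated normalization; per-gene combined ρ = mean(z)·√k with BH q; protective/sensitizing group tests |
| synthetic data | `mosaicpool.simdata` | pooled experiments with known ground truth: multinomial line sampling with growth × Hill-survival weights, NB counts with planted programs, doublets, apoptotic cells, hashes, SNP allele reads, guide screens |

`mosaicpool.core` holds the shared containers (`PooledExperiment`,
`GenotypeReference`, `CellAlleleCounts`, `QCThresholds`, `MutationMatrix`) and
readers for VCF genotypes and MatrixMarket count triplets.

## The core statistics

**Genotype demultiplexing.** For a cell with ref/alt read counts at SNP v and
a candidate line with alt dosage d_v ∈ {0, ½, 1}, the read model is
alt ~ Binomial(n_v, p_v) with p_v = (1−ε)d_v + ε(1−d_v). Doublets are scored
as the α = 0.5 mixture of two lines' dosages; the call is the
maximum-posterior hypothesis over all singlets and unordered pairs.

**Relative survival and dose slope.** A line's sensitivity is
log2(f_treated/f_vehicle) of its pool fraction (pseudocount 0.5); the slope
of log10(representation ratio) on log10(dose) summarizes the dose response,
with a one-sided Pearson-R p in the depletion direction.

**Heterogeneity.** Per cluster, the relative count is the treated share of
the cluster over the line's overall treated share; the Gini
G = Σᵢⱼ|xᵢ−xⱼ|/(2n²x̄) of these values is compared with a null that permutes
condition labels (cluster sizes fixed), giving z = (G − μ₀)/σ₀. MI enrichment
quantizes a continuous statistic into equal-frequency bins and tests
MI(bins; membership) against shuffles, with signed per-bin hypergeometric
tail p values.

**Cross-model DE.** Per-line log2FC vectors are z-scored across genes and
averaged per gene (mean difference z); significance comes from a bootstrap
null that resamples each line's z from an independent random gene, then BH.

**Synergy.** Bliss expectation eA + eB − eA·eB; observed minus expected is
synergy. Gene-level: log-linear count models (median-of-ratios offsets,
line + treatment factors, method-of-moments NB dispersion) on pseudobulk give
βA, βB, βAB, and s = (βA + βB) − βAB ranks genes by deviation from additivity.

**Screens.** Guide z is the read-weighted two-proportion (binomial-logit
score) statistic; guide scores are standardized by a replicate-consistency
noise scale, combined per gene as ρ = mean(z)·√k, and BH-corrected.

## Worked example

```bash
python examples/01_demultiplex_pool.py
```

```
cells: 2000, true doublets: 101
singlet line accuracy:  0.999
doublet recall:         0.980
hash call accuracy:     1.000
```

A simulated 4-line pool with 5% doublets and ~50 allele reads per cell is
demultiplexed from scratch: 99.9% of singlets get the right line, 98% of
doublets are flagged (their reads fit a 50:50 two-line mixture better than
any single line). The other scripts in `examples/` walk through sensitivity
scoring, heterogeneity statistics, cross-model DE with model downsampling,
Bliss/covariate synergy, and screen scoring the same way, each printing the
numbers it computes and what they mean.

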