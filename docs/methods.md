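# Methods notes

This note records the models behind each pipeline stage, the parameter
choices that matter, the numerical conventions, and the places where the
design was genuinely open and a choice had to be made.

## Genotypes, frequencies, polarization

Genotypes are unphased ALT-allele dosages (0–4 for tetraploids; the
outgroup panel may be haploid or diploid). Phase separators in VCF GT
fields are ignored because every statistic downstream is frequency-based.
Filtering follows the conventions of reduced-coverage resequencing of
polyploids: biallelic SNPs only, per-individual depth ≥ 4 reads
(genotypes below it are set missing, not the whole site), and a
population's frequency at a site requires ≥ 5 genotyped individuals.

The *derived* allele at a site is the allele not carried by the outgroup
consensus. Sites where the outgroup panel is missing or polymorphic at a
minor-allele frequency above 0.2 are kept but flagged unpolarizable and
skipped by polarization-dependent statistics (Fay & Wu's H, ABBA-BABA).
The 0.2 cutoff is a judgment call: strict enough that the consensus is
meaningful, loose enough that a single discordant outgroup genome does
not discard the site. Sites missing from the genotype-based panel can be
filled from pooled read counts (ALT reads / total reads); such entries
are flagged and carry no chromosome count, so statistics that need one
fall back to plug-in formulas there.

## Window statistics

Windows are non-overlapping blocks of 25 consecutive usable SNPs, never
spanning scaffolds; trailing shorter windows are emitted but flagged.
Disjoint windows keep the block jackknife and empirical quantiles
honest; a stride parameter provides sliding windows when wanted.

* **G_ST** is aggregated ratio-of-sums: Σ(H_T − H_S) / Σ H_T with H_S
  the unweighted mean within-population gene diversity 2p(1−p) and H_T
  the diversity of the unweighted mean frequency. Ratio-of-sums was
  chosen over the mean of per-site ratios for stability at
  low-diversity sites.
* **Tajima's D** uses the standard a₁…e₂ constants evaluated at
  n = 4 × (median genotyped individuals across the window's sites); the
  median is a pragmatic answer to per-site missingness, which varies the
  realized chromosome count. Per-site θ_π applies the n/(n−1) unbiasedness
  correction using each site's own chromosome count.
* **Fay & Wu's H** is the original unnormalized θ_π − θ_H
  (θ_H = Σ 2p²·n/(n−1) over derived frequencies). The unnormalized form
  pairs with empirical genome-wide quantiles rather than a parametric
  null, which is how the outlier machinery consumes it.

Outlier tails are fixed as: G_ST upper tail; H and Tajima's D lower
tails (the selection-relevant directions). Empirical cutoffs are
order statistics (the `inverted_cdf` quantile); outliers are strict
inequalities, so a degenerate all-equal distribution flags nothing.
Gene-level values take the directed extreme over all windows whose
first-to-last-SNP bp span intersects the gene interval (1-based,
closed); reduction across several population comparisons takes the
*least* extreme value, a deliberately conservative summary.

## ABBA-BABA estimators

D, f_hom and f_d follow the frequency-weighted site-pattern form (see
README for the formulas). An *informative* site is biallelic,
polarizable, non-missing in all four quartet populations, with
ABBA + BABA > 0; the outgroup slot defaults to the polarization panel
itself.

**Unbiased donor product.** The f_hom and f_d denominators contain the
product of two frequencies from the same population (the substituted
donor). The plug-in p̂² is inflated by within-population sampling
(E[p̂²] = p² + pq/n), which at 6–8 tetraploid individuals per population
biases the estimators downward by roughly 10% — enough to matter when
the point of the statistic is an absolute admixture fraction. The
duplicated slot therefore uses the unbiased product k(k−1)/(n(n−1)),
i.e. the expectation over two *distinct* chromosomes; the test-suite
oracle enumerates donor pairs without replacement and agrees to 1e-9.
On frequency-only panels (no chromosome counts, e.g. read-count
entries) the plug-in form is used, which also preserves the algebraic
identities f_hom = 1 when p₂ ≡ p₃ and f_d ∈ {0, 1} in the degenerate
constructions.

f_d with a negative numerator is reported as 0: the dynamic-donor
estimator is meaningful only where the D numerator is positive.
Jackknife SDs are delete-one-block over contiguous runs of informative
sites (default block 1000 informative SNPs — long enough to absorb
local LD in data of this density; `block_size=None` targets 50 blocks);
fewer than 10 blocks is an error rather than a silently unstable SD.

**Candidate genes.** A gene (strictly more than 25 informative SNPs per
quartet) is called introgressed when its f_d exceeds 3 × the
genome-wide f_hom of the corresponding quartet, in *all* background ×
donor quartets. A known limitation, demonstrated by the acceptance
suite: the rule is only meaningful when genome-wide admixture is
significantly positive. When f_hom ≈ 0 the threshold collapses to ~0
(and is negative about half the time, making the comparison vacuous
against the clamped f_d ≥ 0), so in a panel with no gene flow the rule
calls a large fraction of genes. The caller implements the rule as
stated; users should check f_hom against its jackknife SD before
interpreting candidate lists.

## BSA / F2 mapping

Phenotypes of individuals that never bolt are entered at the experiment
end date with a censoring flag (the default policy; dropping them is an
option). Per marker, OLS of the phenotype on three encodings of
tetraploid dosage — additive (dosage), dominant (any copy), recessive
(all four copies; the natural tetraploid analogues of the diploid
notions) — and the encoding with the highest LOD wins.
LOD = (n/2)·log₁₀(RSS₀/RSS₁) in the classical form without
degrees-of-freedom correction. Missing genotypes drop only that
marker's rows. The reported p-value is the F-test of the selected
model; under model selection it is anti-conservative relative to a
single pre-specified encoding (the null-uniformity property in the test
suite therefore checks the additive-only scan).

Permutation significance permutes the phenotype vector and reports both
the maximum of per-permutation maximum LOD (max-of-max, an unusually
stringent quantity preserved for comparability with the study design
this package mirrors) and the conventional 95th percentile. The
stepwise multiple-marker model is forward selection on the partial
F-test (complete-case rows within the candidate set); collinear markers
are skipped; each retained marker is reported with its semi-partial
correlation (√ of the R² increment when added last) and its
single-marker PVE.

## Expression

Size factors are median-of-ratios against the per-gene geometric-mean
pseudo-reference over genes with non-zero counts in all samples.
Classification runs a one-way ANOVA across the classes {BGS, MT, RW}
and Tukey HSD pairwise p-values (scipy's studentized-range
implementation; unbalanced classes get the Tukey–Kramer adjustment) on
normalized counts without a log transform (an option exists): DE iff
p(RW−MT) < 0.05; mountain-like additionally requires p(BGS−RW) < 0.05
and p(BGS−MT) > 0.5; railway-like mirrors it. The p > 0.5 similarity
criterion is a literal Tukey p-value threshold, not an equivalence
test; with only three focal-class replicates its sensitivity for a
truly equal pair is ~80–85%, which bounds per-class recall — the
acceptance check therefore scores overall class-assignment accuracy
across all planted genes.

The flowering-correlation scan filters genes to normalized counts > 10
in at least one sample and to railway–mountain differential expression
(the same Tukey p, for internal consistency), correlates per-population
mean expression with per-population mean flowering time with the focal
population excluded, and keeps the top 1% by |r| of the filtered set
(the filtered-then-top-1% order; the alternative is a flag). The
excluded population's deviation is scored against the fitted trend with
*orthogonal* residuals (total least squares; vertical residuals are an
option): p = 2(1 − Φ(|d|/σ̂)) with σ̂ the RMS of the included
populations' residuals about zero.

qPCR relative expression is the efficiency-corrected 2^−ΔΔCt ratio
(1+E)^−ΔCt_target / (1+E)^−ΔCt_reference with first-order (delta-method)
propagation of the technical-replicate Ct variances through log-ratio
space; efficiencies are validated into (0, 1.5].

## Simulators: what they emulate, and what they do not

* **Drift panels** use the Balding–Nichols construction: ancestral
  frequency per site (uniform by default), population frequency
  ~ Beta(p(1−F)/F, (1−p)(1−F)/F), chromosomes Bernoulli, dosage the sum
  of an individual's four chromosomes. An optional two-level version
  draws lineage tracks first, so that sister populations share drift —
  required for any scenario where two donor populations must carry the
  same introgressed material. The default `railway_mountain_model`
  mirrors the study design this package targets: mountain clade
  (lineage F = 0.1; members HO, KA and the focal BGS, within-lineage
  F = 0.02), railway lineage (F = 0.3; TBG, STE, within F = 0.02), and
  a 23-genome diploid outgroup (F = 0.9, a separate near-fixed
  species), with 7/8/8/6/8 tetraploid individuals — the resequencing
  sample sizes. These panels have no linkage disequilibrium beyond the
  tract structure that introgression introduces, no mutation-rate
  heterogeneity, and a flat (non-coalescent) ancestral SFS, so
  passing tests show estimator correctness under the drift model, not
  robustness to real LD or demography. (The Tajima's D null check uses
  msprime coalescent panels instead, precisely because the flat SFS is
  not neutral.)
* **Introgression** is simulated at the frequency-track level —
  contiguous tracts (default 100 sites) on each recipient chromosome
  resampled from the donor track — not by haplotype copying; all target
  statistics are frequency-based, so this is sufficient and much
  cheaper. Gene-level planting replaces all recipient chromosomes at
  the gene's sites.
* **F2 crosses** model bivalent pairing only: four homologs pair
  uniformly at random into two bivalents, each contributing one
  recombinant chromatid, which transmits 2 of 4 homologs uniformly
  without replacement; double reduction is ignored (the mapping model
  treats markers as dosage regressors and never models it).
  Recombination between adjacent markers is r = 0.01 within a scaffold
  by default and free across scaffolds. The QTL-recovery acceptance
  scenario uses r = 0.1 so that the causal marker is identifiable at
  marker resolution (at r = 0.01 adjacent markers are near-copies and
  "the top marker" is not a well-posed truth query).
* **Expression counts** are negative-binomial (gamma-Poisson) with
  per-class means, planted focal-population classes, a 10-fold DE
  effect in a random direction, log-normal per-sample depth factors
  (sd 0.2), and dispersion 0.05 — ordinary biological-replicate noise
  for this assay type.

## Problem sizes used by the acceptance suite

Admixture recovery: 50k sites, α ∈ {0, 0.10, 0.30}, ~50 jackknife
blocks. Candidate calling: 1000 genes × 200 SNPs (10–15 kb gene regions
at ~14.5 SNP/kb), 30 planted genes on a 10% background, plus 20
no-gene-flow seeds for the false-positive rate. QTL mapping: 20
replicates of 300 F2s × 500 markers with 500 permutations each, plus 20
null replicates. Expression: 400 genes with 40/40/40 planted classes.
All generators are deterministic given a seed, and the CLI writes
byte-identical output on reruns with the same seed.

## Known limitations

Multiallelic sites are excluded throughout; phased-haplotype statistics
(EHH-type), interval mapping with HMM genotype probabilities, and
linkage-map construction are out of scope; the candidate-calling rule
degenerates without genome-wide admixture (above); and the Tukey
similarity criterion bounds per-class recall at small replicate counts
(above).
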