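# tetrapop

Population-genomic and quantitative-genetic scans for **autotetraploid**
SNP panels, built for dissecting hybrid populations in which a focal
population (here called BGS, after its railway-site archetype) mixes a
"mountain" genetic background with alleles introgressed from a widespread
"lowland railway" lineage. The package provides, as a tested and
composable library with a thin CLI:

* **Tetraploid allele frequencies** — genotypes are unphased ALT-allele
  dosages 0–4; per-population derived-allele frequencies are polarized
  against an outgroup panel (e.g. a diploid sister species), with a
  read-count fallback for sites that fail genotype-level filters.
* **Windowed differentiation and selection statistics** over fixed
  25-SNP windows: Nei's G_ST (ratio-of-sums), Tajima's D, and Fay & Wu's
  H, plus gene-level aggregation (most extreme overlapping window),
  conservative least-extreme reduction across population comparisons,
  empirical outlier quantiles, and the railway-specific
  selection-candidate intersection.
* **ABBA-BABA introgression estimation** — Patterson's D and the
  admixture-fraction estimators f_hom (genome-wide, homogeneous donor)
  and f_d (per-gene, dynamic donor), with delete-one block-jackknife
  standard deviations and the gene-level candidate rule
  *f_d > 3 × f_hom in every background × donor quartet*.
* **Bulked-segregant F2 QTL mapping** — per-marker OLS with additive,
  dominant and recessive dosage encodings, LOD = −(n/2)·log₁₀(1−R²),
  genome-wide permutation thresholds, and forward-stepwise multiple-marker
  models with semi-partial correlations and per-marker PVE.
* **Expression analysis** — median-of-ratios depth normalization,
  PCA on the most variable genes, one-way ANOVA + Tukey HSD
  classification of the focal population's expression state
  (mountain-like / railway-like / intermediate), a flowering-time
  correlation scan with an orthogonal-residual outlier test, and
  efficiency-corrected qPCR relative expression (2^−ΔΔCt) with
  delta-method error propagation.
* **Truth-tracked simulators** for every stage: Balding–Nichols drift
  panels (optionally with shared lineage epochs), tract- and gene-level
  introgression, sweep-like SFS distortion, tetraploid F2 meiosis
  (bivalent pairing, 2-of-4 homolog transmission, censored phenotypes),
  and negative-binomial expression counts with planted classes.

## The statistics in brief

For a quartet (((P1, P2), P3), O) with derived-allele frequencies
p₁, p₂, p₃, p_O, site patterns are weighted as

```
ABBA = (1 − p₁) p₂ p₃ (1 − p_O)      BABA = p₁ (1 − p₂) p₃ (1 − p_O)
D    = Σ(ABBA − BABA) / Σ(ABBA + BABA)
f_hom = S(P1, P2, P3, O) / S(P1, P3, P3, O)
```

where S is the summed ABBA−BABA numerator and the duplicated donor slot
uses the unbiased two-chromosome product k(k−1)/(n(n−1)) rather than p̂²
(see `docs/methods.md` for why this matters at 6–8 individuals per
population). f_d substitutes per site whichever of P2/P3 has the higher
derived frequency, and is clamped to 0 when the numerator is negative.

Window statistics use per-site gene diversity 2p(1−p) with the n/(n−1)
unbiasedness correction; Tajima's constants are evaluated at n = 4 ×
(median genotyped individuals); Fay & Wu's H is the original unnormalized
θ_π − θ_H. Tetraploid Hardy–Weinberg probabilities come from the
multinomial expansion of (Σpᵢ)⁴.

## Worked example

Simulate the five-population study design (two mountain populations, the
admixed focal population BGS, two railway donors, a diploid outgroup)
with 10% of each BGS chromosome introgressed from the railway lineage,
then estimate the admixture fraction:

```sh
tetrapop simulate --kind panel --n-sites 20000 --alpha 0.1 --seed 11 --out-dir sim
tetrapop scan-introgression --vcf sim/panel.vcf --popmap sim/popmap.tsv \
    --gff genes.gff3 --p1 HO --p1 KA --p2 BGS --p3 TBG --p3 STE --out-dir intro
```

`intro/quartets.tsv` then reads:

```
quartet                 D          D_sd        f_hom     f_hom_sd    n_informative  n_blocks
HO,BGS,TBG,outgroup     0.047672   0.00452991  0.108037  0.00939194  13358          50
HO,BGS,STE,outgroup     0.046523   0.00445481  0.105998  0.00963171  13618          50
KA,BGS,TBG,outgroup     0.0460985  0.0035912   0.105149  0.00767433  13382          50
KA,BGS,STE,outgroup     0.0443674  0.00367163  0.1019    0.00790552  13652          50
```

Every quartet's f_hom recovers the planted 10% admixture within about
one jackknife SD, and D is strongly positive, as expected under gene
flow from the donor side. `intro/gene_fd.tsv` holds per-gene f_d values
for each quartet (genes with more than 25 informative SNPs), and
`intro/candidates.tsv` the genes exceeding 3 × f_hom in all four
quartets — none here, since the simulated introgression is uniform
background rather than locus-specific.

The tetraploid Hardy–Weinberg helper answers questions like "how many
plants carry no copy of a haplotype at 30% frequency?":

```python
>>> from tetrapop import hwe_genotype_prob
>>> hwe_genotype_prob({"B": 0.3, "B2": 0.3, "A": 0.4}, ("zero_copies", {"B"}))
0.2400999...   # 24% lack it entirely
>>> hwe_genotype_prob({"B": 0.3, "B2": 0.3, "A": 0.4}, ("homozygous", "A"))
0.0256         # only 2.6% are homozygous for the ancestral haplotype
```

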