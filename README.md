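# sibqtl

Growth-trait gene mapping in a transgenic carp full-sib family.

A single het × het parent pair can produce offspring whose growth traits
split into two sharply separated peaks. This package re-implements, as a
tested and reusable pipeline, the mapping strategy used to find the loci
behind such a split: pooled bulked-segregant analysis (BSA) of the two
phenotypic extremes, dual-barcode amplicon re-sequencing of candidate loci
in every individual, mixed-linear-model (MLM) association with a genomic
kinship, and a verification stage that quantifies "dominant" genotypes and
two-locus genotype combinations. It is written for quantitative geneticists
and bioinformaticians who want the whole chain — from pooled read counts to
a dominance table — runnable, inspectable and testable on a desk.

Because no raw data are deposited for this kind of study, the package ships
a first-class synthetic data generator (`sibqtl.simulate`) that emulates the
study design: 442 full-sib offspring segregating 1:2:1 at unlinked
biallelic markers, a major growth locus (genotypes TT < TG < GG) plus a
helper locus acting through a free 3×3 two-locus mean table, a bimodal
weight/length distribution, pooled sequencing of the 30 individuals nearest
each phenotype peak at ~40× depth, and barcoded PE150 amplicon reads with a
configurable non-specific fraction.

## The statistics at the core

**Pool-seq Fst.** For each SNP, with fN the frequency of nucleotide
N ∈ {A,C,G,T} in one pool,

    Pi        = 1 − fA² − fT² − fC² − fG²
    Pi_within = (Pi_pool1 + Pi_pool2) / 2
    Fst       = (Pi_total − Pi_within) / Pi_total

where Pi_total is the Pi of the combined (unweighted mean) frequency vector.
Sites with every reported allele supported by ≥ 4 reads, Fst > 0.5 and
coverage > 20× in both pools, lying in exon or promoter features, become
candidate genes.

**Dual-barcode demultiplexing.** Each individual carries a unique
(F-barcode, R-barcode) pair; a read pair is assigned to a sample iff the
12-mers at bases 9–20 of both barcodes match exactly near the 5′ ends of the
two mates. Conflicting double-matches are discarded, not arbitrated.

**MLM association.** y = μ + xβ + g + e with g ~ N(0, σ²_g K) over the
Centered-IBS kinship K (mean-centered dosages, normalized to mean diagonal
1) and e ~ N(0, σ²_e I). Variance components are REML-estimated once under
the null (P3D) via an EMMA-style eigendecomposition, then each marker gets a
generalized-least-squares F test on (1, n−2) df. Genotyped sites are first
screened at minor allele frequency > 0.05 and call rate > 90%.

**Dominance summaries.** The family splits into fast/slow subgroups at the
weight-density valley; per genotype and per two-locus combination the
pipeline reports n, n(weight > 500 g), the frequency % over that threshold,
and mean ± sd weight and length, ranking classes by their percentage-point
advantage over the family-wide rate.

## Worked example

The numbered scripts under `analysis/` run the pipeline stage by stage on
one seeded synthetic family and write their tables under `results/analysis`:

```
python analysis/01_simulate_family.py --seed 1
python analysis/02_bsa_scan.py        --seed 1
python analysis/03_demux_genotype.py  --seed 1
python analysis/04_mlm_association.py --seed 1
python analysis/05_genotype_effects.py --seed 1
python analysis/06_replicate_recovery.py --seed 1 --replicates 30
```

With seed 1 this prints (abridged):

```
family: n=442, mean weight 803.7 g, mean length 291.5 mm
bimodal: True (valley at 499 g, modes 224/1036 g)
individuals over 500 g: 332 (75.11%)

scanned 200 SNPs in both pools
top site: m0066 (Fst 0.367; true major locus is m0066)

read pairs: 212160, assigned 65.5% (non-specific fraction 0.33)
sites passing MAF/call-rate screens: 12
mean call rate: 0.996; genotype concordance with simulated truth: 1.0000

weight_g: top locus m0066: beta=474.1, -log10 p=3.3

one-way ANOVA at top locus m0066: F=1029.5, p=7.03e-166
letter groups (Welch/Bonferroni at 0.01): {'GG': 'A', 'TG': 'B', 'TT': 'C'}
dominant classes: m0066:GG: 100.00% (n=115, +24.89 points)

causal locus first by Fst:      100.0%
causal locus first by -log10 p: 100.0%
median causal Fst: 0.574; median scan hits: 1
```

Reading this: the family is bimodal with peaks near 224 g and 1036 g; the
true major locus tops the 200-SNP Fst ranking (its per-seed Fst hovers
around the 0.5 cutoff at 30+30 pools and 40× depth, so the re-sequencing
panel is taken from the Fst ranking); two thirds of the pooled amplicon
reads demultiplex into the 442 samples; the MLM puts the causal locus first
for both traits; and its GG class beats the family-wide 75.11% rate of
exceeding 500 g by ~25 percentage points. Across 30 replicate families the
causal locus is recovered first by both statistics in every run.

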