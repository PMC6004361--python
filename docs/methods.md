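# Methods

This note documents the models, parameter choices and numerical decisions
behind `sibqtl`, and what the synthetic study design does and does not
emulate.

## Study design being emulated

One heterozygous × heterozygous parent pair produces a large full-sib
family (default n = 442) whose body weight and length split into two
well-separated peaks. Extreme pools (30 individuals nearest each peak) are
sequenced to ~40× to find allele-frequency-divergent SNPs; candidate loci
are re-sequenced in every individual with dual-barcoded amplicons; and a
kinship mixed model plus genotype-class summaries verify which genotypes
and two-locus combinations carry the growth advantage.

## Synthetic family generator (`simulate`)

**Genetics.** All markers are biallelic, unlinked, and heterozygous in both
parents, so offspring dosages are iid Binomial(2, ½) and segregate 1:2:1.
Linkage is deliberately absent: nothing downstream uses a genetic map, and
unlinked markers make per-site sampling properties exact. Two causal loci
are planted: a "major" locus (alleles T/G; TT < TG < GG for growth) and a
"helper" locus (alleles C/T) that modulates class means.

**Phenotypes.** Weight and length are a free 3×3 two-locus class-mean table
plus iid Gaussian noise per trait; the free table (rather than an additive
model) lets non-additive patterns — the GG+CC and GG+TT combinations
leading the GG row — be expressed. Defaults (grams; lengths scale
accordingly, residual sd 120 g / 20 mm):

| major \ helper | CC   | CT   | TT   |
|----------------|------|------|------|
| GG             | 1210 | 1180 | 1200 |
| TG             | 1100 | 900  | 700  |
| TT             | 250  | 200  | 230  |

These values were chosen once to reproduce the emulated study's observable
structure: a bimodal weight distribution with a slow peak near 220 g and a
fast peak near 1050 g (roughly a quarter versus three quarters of the
family), the single-locus ordering GG > TG > TT, and the GG+CC / GG+TT
combinations as the top-ranked classes. A subtlety forced this choice: the
published per-genotype means (≈920/747/419 g with within-class sd ≈450 g)
cannot arise from a "class mean + noise" model *and* produce the strongly
bimodal family distribution the study reports — in the real family the
within-class spread is itself generated by the bimodal split (the study
attributes it to feeding competition), a mechanism outside this model. The
generator therefore makes the major locus the driver of the bimodality,
with the helper spreading the heterozygous TG row; that spreading is what
places the fast density peak on the GG classes, so that peak-proximal pool
selection enriches the G allele the way the study's pools evidently were
enriched. Weights are floored at 20 g (lengths at 30 mm), a juvenile
minimum, so the slow tail stays positive.

**Pools.** The family is split at the weight-density valley (below), and
each pool takes the `pool_size` = 30 individuals whose weights are nearest
the *subgroup's own* density peak — the operational reading of selecting
from "the nearest peak region" of each subgroup. Per site, pool depth is
Poisson(40) and allele reads are Binomial(depth, pool allele frequency);
sequencing error substitutes a uniformly random other base at rate 0.001.

**Amplicon reads.** Fixed PE150 reads: read 1 = 20 bp F-barcode + the first
130 bp of the amplicon, read 2 = 20 bp R-barcode + the reverse complement of
the last 130 bp. Amplicons are 200 bp (≤ 290 bp enforced) with the SNP at
offset 101, so both mates cover it. Heterozygotes emit each allele with
probability ½ per read. A `nonspecific_fraction` (default 0.33, the
emulated split-rate regime: two thirds of pooled data assignable) of pairs
carries random barcodes. Qualities are constant Q30 placeholders; there are
no indels. Barcode schemes are combinatorial: ~⌈√n⌉ F-barcodes × R-barcodes,
each sample a unique pair, all 12-mer keys distinct.

**Determinism.** Every operation draws from `np.random.default_rng([seed,
stage])`, so identical configs give bit-identical output and stages are
independently reproducible.

## Pool-seq Fst scan (`bsa`)

Per site, Pi = 1 − Σ fN², Pi_within is the unweighted mean of the two
pools' Pi, and Pi_total is the Pi of the *unweighted mean* frequency vector
(the pools are designed equal-sized; read-count-weighted pooling is
available behind `weighted=True`). Fst = (Pi_total − Pi_within)/Pi_total.
Monomorphic sites (Pi_total = 0) are undefined — excluded, not set to 0,
since 0/0 is not evidence of no differentiation. Under unweighted
averaging, concavity of Pi guarantees Fst ∈ [0, 1]; this is property-tested.

Filters: within each pool, alleles with fewer than 4 supporting reads are
masked to zero before frequencies are computed (the caller-side
allele-support rule; a variant-caller "SNP quality ≥ 20" metric has no
analogue on raw counts and is deliberately not imitated); a site must stay
polymorphic across the pool union; coverage > 20× is enforced in *both*
pools (the stricter reading — one shallow pool makes the frequency estimate
unreliable); Fst > 0.5. Candidate annotation intersects hits with exon and
promoter intervals (1-based inclusive; strand ignored — a SNP position is
strandless; promoters must be provided explicitly, no default upstream
window is invented). BED input is converted from 0-based half-open; GFF3 is
taken as 1-based inclusive.

## Demultiplexer (`demux`)

The 12-mer at barcode positions 9–20 is the key. A pair belongs to sample s
iff one mate contains s's F-key and the other s's R-key, each starting
within the first 9 read positions (the key begins at barcode offset 9, so
this honors a 5′-end barcode while limiting false internal matches), with
exact matching only — no mismatch tolerance, since tolerance inflates
cross-sample conflicts. Both mate orientations are accepted. Pairs matching
two different samples are discarded as conflicting (misassignment is worse
than loss for genotyping). Conservation (assigned + unassigned = total) is
asserted on every run.

## Amplicon genotyper (`genotyping`)

Reads are anchored to amplicons by exact primer-region match (the 20 bases
after the barcode) rather than alignment: amplicons are short known
references, so an aligner changes nothing about the tally while adding a
dependency. The base at each SNP offset is read from whichever mate covers
it. Calls from ACGT counts: depth < 10 → missing; top-allele fraction
≥ 0.9 → homozygous; second-allele fraction in [0.25, 0.75] → heterozygous;
otherwise missing(ambiguous). These thresholds are this package's choice
(the original calling was delegated to a variant caller whose internals are
not reproducible from counts), conservative at ~40× amplicon depth, and
exposed as parameters. MAF is computed on allele counts (2n) over called
genotypes; call rate = called/total individuals; screens are strict
(MAF > 0.05, call rate > 0.9) and idempotent.

## Mixed-model association (`mlm`)

Centered-IBS kinship: missing dosages mean-imputed, sites centered,
K = ZZᵀ/c with c the mean diagonal, giving mean(diag K) = 1. The exact
scaling used by GUI GWAS tools is not derivable from their documentation;
ours is stated rather than claimed identical.

Null REML (P3D): with K = U S Uᵀ, the restricted likelihood is maximized
over log₁₀ of the variance ratio σ²_g/σ²_e by bounded scalar search in
[−8, 8] (xatol 1e−8) — exact for this two-component model, O(n³) once.
Ratios at the lower bound are truncated to σ²_g = 0. Per marker, V = σ²_g K
+ σ²_e I is held fixed (estimated once, reused — P3D); the marker model is
whitened by the Cholesky factor of V and the overall scale re-estimated
from its residuals, so the test is an F on (1, n−2) df and reduces *exactly*
to the ordinary regression F test when K ∝ I — the module's primary oracle,
checked to 1e−8, alongside a dense explicit-inverse GLS oracle. Missing
dosages drop individuals pairwise (K stays fixed; tests stay honest).
Compressed MLM is not implemented: at n in the hundreds the uncompressed
model is tractable and compression only approximates it. An optional
per-marker REML mode re-estimates the null components on each marker's
complete cases. No covariates or principal components are fitted — a single
full-sib family has no population structure beyond kinship. Raw p values
are reported; the emulated analysis used no multiplicity adjustment. Weight
and length are scanned independently.

## Effect verification (`effects`)

The fast/slow split places the threshold at the minimum of a
Silverman-bandwidth Gaussian KDE between the two largest density modes
(largest-gap midpoint for n < 30; a unimodal density returns a flagged
no-split). The *reported* threshold is then the midpoint between the
largest slow and smallest fast weight, which always separates the labeled
subgroups; note that when the two clusters nearly touch, the exact boundary
between their extreme members is not identifiable from the marginal
distribution, so partitions are validated by label accuracy rather than by
a particular boundary value.

Summaries count weight strictly above 500 g (the published table cannot
disambiguate ≥ from >; strict is chosen and stated) and report frequencies
to 2 decimals. Dominance ranks classes by that frequency (ties: mean
weight, then label — deterministic), annotates the percentage-point
advantage over the family-wide rate, and flags classes with n < 10 as too
small for statistical claims. ANOVA is standard one-way (groups with n < 2
excluded; all-constant input defined as F = 0); the letter groupings use
pairwise Welch tests with Bonferroni correction at 0.01 — a stated stand-in,
since the original post-hoc procedure is unspecified. Two-locus combination
screening admits loci passing p < 0.1 in *either* trait's scan (the union;
which trait the original screen used is ambiguous) and takes the two
smallest-p loci.

## Pipeline and problem sizes

`pipeline.run_study` chains all stages on one family. The re-sequencing
panel takes annotated candidates first and pads with the next Fst-ranked
covered sites to a panel of 12 — mirroring a design that widens a candidate
list for re-sequencing — so verification proceeds even for seeds where the
causal locus's Fst fluctuates below the 0.5 cutoff (its sampling spread at
30+30 pools and 40× depth straddles that line; it still tops the ranking
essentially always). Analyses are sized for a desk: 200 markers per family,
a 12-locus panel, amplicon depth 24 in replicate runs (40 in single-study
runs), 150 null simulations in the acceptance script and 100–200 elsewhere.
Kinship in the association stage is built from the genotyped panel itself,
as in the emulated analysis; with a strong causal locus in a small panel
this "proximal contamination" absorbs part of the causal signal into σ²_g,
deflating its −log₁₀ p — rank order, which the verification stage uses, is
unaffected in practice.

## What passing tests do and do not show

The generator reproduces the *statistical skeleton* of the study — Mendelian
segregation, bimodality, pool construction, binomial read sampling, barcode
structure, split rates — but not PCR chemistry (locus dropout is only
phenomenological via depth and the non-specific fraction), mapping/caller
artifacts, linkage, or the biological mechanism behind the bimodal split.
End-to-end recovery rates therefore validate the pipeline's statistical
machinery under the declared design, not the original wet-lab discovery.

## Known limitations

- Per-SNP Fst only; no sliding windows or alternative BSA statistics.
- Biallelic targets only; no indels, no base-quality modeling.
- The KDE split assumes one dominant valley; heavily multimodal phenotypes
  would need a different rule.
- Kinship from a dozen panel markers is a coarse relatedness estimate; the
  mixed model remains well-calibrated (type-I error is tested) but σ²_g is
  not interpretable as a heritability estimate there.
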