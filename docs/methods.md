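# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions.

## Data model

All statistics operate on a samples × sites matrix of derived-allele
dosages in {0, 1, 2, missing} plus a per-site table of coordinates, alleles,
ancestral state and functional annotation (gene symbol, consequence in
{synonymous, missense, other}, GERP RS score, optional CADD and PolyPhen).
Coordinates are 1-based inclusive, VCF convention.  Dosages are alt-allele
counts after reading and derived-allele counts after polarization; sites
whose ancestral allele is unknown, or matches neither REF nor ALT, are
removed at polarization (the latter with a warning — a conservative choice,
since such sites are un-polarizable without extra evidence).

## Quality control

Per-genotype calls below `min_depth` (5 reads) or `min_gq` (phred 20) are
set to missing *first*; site missingness (> 5%) and the Hardy–Weinberg test
are then evaluated on the masked matrix.  The HWE test is the exact
conditional test (enumeration of heterozygote counts given allele counts)
rather than a chi-square, because per-population sample sizes in this
design are small (8–50 diploids); a site fails if p < 10⁻³ in *any* panel
population.  Monomorphic-in-dataset sites are removed structurally (this
can be switched off for lossless round-trips).  Sample filters: total
missingness > 10%, or heterozygosity beyond 4 SD of the sample's own
population mean (a zero-SD population yields no outliers).  Sex chromosomes
are recognized by label ({X, Y, chrX, chrY, 23, 24}, configurable).
Removal counts are reported per rule with precedence monomorphic →
missingness → HWE, so every removed site is attributed to one rule.

## Diversity

θπ sums the unbiased per-site heterozygosity 2c(2n−c)/(2n(2n−1)), where c
is the derived count and 2n the *non-missing* haplotype count at that site
(per-site adjustment is the standard unbiased treatment of sporadic
missingness).  θw = S/a₁ uses a single a₁ from the population's full
diploid count — one global denominator even where some sites have missing
calls — with a per-site-a₁ variant available.  πvar averages per-site π
over sites variable within the population.  Tajima's D uses the 1989
variance constants computed from the full haplotype count.  Diversity is
computed on synonymous sites by default, as the least constrained class.

"Segregating sites carried per individual" is defined as the number of
population-segregating sites at which the individual carries ≥ 1 derived
allele; the definition is an interpretation (the quantity is usually left
operationally vague) and is isolated in one function.

## Block bootstrap

Sites in genomic order are split into 1000 contiguous near-equal blocks;
each of 1000 replicates concatenates 1000 blocks drawn with replacement and
recomputes the statistic; intervals are the 0.025/0.975 replicate
quantiles.  For ratio statistics the two-sided p-value is
2·min(frac ≤ 1, frac ≥ 1), floored at 2/n_reps.  Block construction is by
contiguous equal counts, the simplest scheme consistent with "divide the
exome into 1000 blocks"; blocks preserve local LD so the intervals absorb
the extra variance that demography induces among linked sites.

## SFS

Spectra are built on a fixed-size subsample of individuals drawn without
replacement (default 8; 18 for the two-population density comparison, the
isolate's sample size).  Sites with any missing call within the subsample
are dropped and counted; bins 0 and 2n are removed and the rest normalized.
Deleteriousness classes use left-closed intervals ([2, 4) etc.), so a
boundary score belongs to the upper class deterministically.

The density-difference test resamples individuals with replacement (1000
replicates), builds per-class spectra, and records the per-bin density
difference over the first 10 bins.  Sequential classes (neutral→moderate,
moderate→large, large→extreme) are compared by a z-test in which the
bootstrap standard deviations serve as standard errors — the replicates
estimate the sampling distribution of each class's mean difference, so
their SD (not SD/√replicates) is the correct scale; treating replicates as
independent observations would make any nonzero difference "significant".
Both signed differences and magnitudes are computed and reported; the
signed test is the default because its null expectation is exactly zero in
every class, whereas magnitudes grow mechanically as class site-counts
shrink.

Low vs. common proportions classify deleterious (GERP ≥ 2) variants on the
*subsampled* counts — singletons and doubletons vs. tripletons and above —
with Wald 95% CIs p̂ ± 1.96√(p̂(1−p̂)/m) clipped to [0, 1].

## Mutational load

N_alleles (additive) and N_hom (recessive) are per-individual sums over the
masked sites; missing genotypes contribute 0 and are counted (an optional
rescaling by the non-missing fraction exists but is off by default — at
≤ 5% missingness it changes nothing material).  Population contrasts are
ratios of per-individual means; because each population's mean burden is a
sum of per-site column means, the bootstrap resamples site blocks and
recomputes the ratio.  Significance defaults to p < 0.001.  The optional
consequence filter intersects deleterious classes with missense labels and
the neutral class with synonymous labels.

The selection-coefficient load evaluates 1 − w = 2q(1−q)sh + sq² per site
with the population's own derived frequency q, class-specific s
(moderate 4.5×10⁻⁴, large 4.5×10⁻³, extreme 10⁻²) and h = 0.5 or 0,
summed within classes; the neutral class has no defined s and is excluded.

## ROH

With zero heterozygotes allowed and a 50-SNP minimum, PLINK-style sliding
windows reduce to maximal-run calling, which is what is implemented: a run
is a maximal stretch of consecutive non-missing homozygous calls with no
inter-SNP gap above 1 Mb, kept if it has ≥ 50 SNPs and spans ≥ 1 Mb
(end − start + 1, inclusive).  Missing calls break runs (strict default; a
tolerance flag is the natural extension but exome SNP spacing makes it
moot).  LD pruning before detection is greedy left-to-right over 50-kb
windows advancing 5 SNPs, removing the later site of any pair with squared
dosage correlation > 0.8 over pairwise-complete samples — deterministic and
equal to all-pairs greedy pruning when the window covers the data.

The zygosity ratio counts, per individual and region (inside all ROHs,
outside, inside each length class), dosage-2 genotypes at missense sites of
a GERP class over dosage-2 genotypes at synonymous GERP < 2 sites;
individuals with a zero denominator are excluded from the paired
inside-vs-outside t-tests and counted.

## Fst and enrichment

Per-site Fst is the Weir & Cockerham (1984) two-population estimator from
variance components a (among populations), b (among individuals within
populations) and c (within individuals), using the observed heterozygosity
term; sites monomorphic in both populations are undefined (NaN), never
zero, and are excluded before quantile computations.  The population-pair
summary is the ratio of sums Σa/Σ(a+b+c) over defined sites, optionally
thinning to equal sample sizes.

Candidate subsets apply, in order: missense → deleteriousness category
(three GERP classes, two PolyPhen damaging labels) → Fst at or above the
subset's own 95th percentile (ties kept inclusively) → strictly higher
derived frequency in the target population.  The "all_categories" subset
merges the five post-category sets before taking its own top 5%.  The
filter order matters and is regression-tested.  Variant→gene mapping uses
the annotation's gene column only; empty genes are dropped and counted.

Over-representation uses the upper-tail hypergeometric test against the
universe of all genes in the dataset's annotation, BH-FDR across tested
sets, and a three-tier significance cascade: FDR < 0.05; else p < 0.05 with
an enrichment ratio above the mean ratio of tested sets; else p < 0.05.
The bootstrap (Q95) mode draws query-sized gene sets without replacement
from a source list (trait-catalog genes or dataset genes — both supported),
recounts per trait, and flags a trait when its observed count reaches the
95th percentile of the replicate counts; a zero observed count is never
flagged, since Q95 itself is frequently zero for small traits and "0 ≥ 0"
carries no evidence.  Because counts are discrete, the realized null flag
rate sits slightly above 5% (by at most the probability mass at Q95).

Fst peaks are single-linkage chains of ≥ 2 top-1% sites on one chromosome
with consecutive members < 10 kb apart; LD between peak members is the
squared dosage correlation.

## Synthetic-data generator

The generator reproduces the qualitative contrasts the pipeline is meant to
detect, with exact ground truth; it does not simulate selection forward in
time, recombination maps, or coalescent genealogies.

* Sites are uniform over 10 chromosomes of 25 Mb (50,000 sites by default —
  the analysis scale chosen for desk runtime; real exome datasets are ~6×
  larger).  Positions, classes and scores are drawn per site.
* Class proportions default to 62.7 / 18.0 / 18.6 / 0.7 % for
  neutral/moderate/large/extreme — the approximate composition of a GERP-
  annotated human exome SNP set.
* Ancestral frequencies follow the neutral-equilibrium 1/i law on a grid of
  99 frequencies, then are down-weighted per class by 1/(1 + C·s) with
  C = 200, a deterministic stand-in for mutation–selection balance that
  makes more deleterious classes rarer without forward simulation.
* The reference population (46 diploids) is binomial at the ancestral
  frequencies.  The isolate's frequencies pass through binomial
  Wright–Fisher resampling at 2N = 60 for 40 generations (heterozygosity
  decay (1 − 1/2N)^g ≈ 0.51, matching the roughly halved diversity of a
  strongly bottlenecked isolate); its 18 diploids are then drawn with
  inbreeding: per sample, autozygous tracts with exponential lengths
  (mean 2.5 Mb) alternate with exponential gaps sized so the expected
  genome fraction covered is f = 0.125; inside a tract the genotype is
  homozygous for a single allele draw, outside binomial.  Tract placement
  is an alternating renewal process, so coverage is exact in expectation;
  the first segment ignores the inspection-paradox length bias, a
  negligible edge effect at these tract densities.
* A planted high-drift gene region (30 consecutive extreme-class missense
  sites, isolate frequency 0.95 vs. reference 0.02) provides a known
  positive control for the candidate-subset and enrichment stages, and a
  toy trait catalog ties its gene to one trait.
* 30% of sites store the derived allele as VCF REF (exercising
  polarization) and 2% have unknown ancestral state (exercising removal).

What passing tests on this generator do *not* show: robustness to calling
error, to batch effects, to realistic LD (sites are independent given
frequencies, so LD pruning is nearly a no-op on simulated data), or to
misspecified ancestral states; those require real data.

## Determinism and seeds

Every random stage takes a seed; the pipeline fans one master seed into
per-stage `SeedSequence` children, so reruns are byte-identical (TSV floats
are formatted with %.10g) and a stage rerun in isolation with its recorded
seed reproduces its slice of the full run.

## Known limitations

* The sequential-category SFS test is approximately calibrated (bootstrap
  SDs as standard errors, cross-class correlation ignored — conservative
  under the null).
* The Q95 enrichment rule inherits the discreteness of count data; its
  realized null rate is near, not exactly, 5%.
* ROH detection assumes reasonably dense, LD-pruned SNPs; tracts shorter
  than ~1 Mb or covered by < 50 SNPs are invisible by design.
* Burden ratios use all non-missing genotypes per population rather than
  the intersected complete-case site set; with ≤ 5% missingness the two
  agree closely, and the complete-case alternative is a one-line mask.
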