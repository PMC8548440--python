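# isodist

Analysis of how recent isolation, drift and inbreeding reshape the
distribution of functional (putatively deleterious) exome variation, in a
two-population design: a small, recently bottlenecked and inbred **isolate**
against a larger panmictic **reference**.

Population isolates accumulate long runs of homozygosity and shift their
site frequency spectrum away from rare variants; whether this also relaxes
purifying selection on deleterious alleles is usually asked through a fixed
set of summary statistics rather than direct fitness measurements.  This
package implements that toolkit end to end for multi-sample VCF data with
per-site deleteriousness annotation, plus a synthetic-data generator that
emulates the demographic contrast so the entire pipeline runs and is tested
with no external data.

## What it computes

* **Variant store / QC** — biallelic autosomal SNPs with per-genotype
  DP/GQ masking, site missingness and exact Hardy–Weinberg filters,
  per-sample missingness and heterozygosity-outlier filters, and
  polarization to derived-allele dosages from an ancestral-allele column.
* **Diversity** — pairwise nucleotide diversity θπ = Σ 2c(2n−c)/(2n(2n−1)),
  Watterson's θw = S/a₁, per-variable-site diversity πvar, and Tajima's D,
  with confidence intervals from a 1000-block site bootstrap
  (0.025/0.975 quantiles).
* **SFS** — unfolded site frequency spectra on fixed-size subsamples,
  stratified by GERP RS score class ("neutral" < 2, "moderate" [2, 4),
  "large" [4, 6), "extreme" ≥ 6; CADD and PolyPhen schemes supported),
  an individual-resampling bootstrap of the per-bin density difference
  between populations, and low-frequency (singleton+doubleton) vs. common
  deleterious proportions with Wald 95% CIs.
* **Mutational load** — per-individual derived-allele count N_alleles
  (additive model) and homozygous-derived count N_hom (recessive model);
  between-population ratios of their means with block-bootstrap intervals;
  and the selection-coefficient load
  `1 − w = 2q(1−q)sh + sq²` with per-GERP-class s
  (4.5×10⁻⁴ / 4.5×10⁻³ / 10⁻²) and h = 0.5 (additive) or 0 (recessive).
* **ROH** — LD pruning (r² > 0.8 in 50-kb windows, 5-SNP steps), detection
  of runs of ≥ 50 consecutive homozygous SNPs spanning ≥ 1 Mb, length-class
  summaries (1–2.5 / 2.5–5 / > 5 Mb) with t-tests, and the
  missense/synonymous homozygote ratio inside vs. outside ROHs.
* **Differentiation & enrichment** — per-site Weir & Cockerham (1984) Fst
  from variance components a/(a+b+c), candidate subsets (missense →
  deleteriousness class → top-5% Fst → higher derived frequency in the
  target population) mapped to genes, hypergeometric over-representation
  with BH-FDR significance tiers, a bootstrap (Q95) null against trait
  catalogs, Fst peak detection (top-1% sites within 10 kb) and pairwise r².
* **Synthetic data** — two diploid populations over exome-like sites:
  equilibrium 1/i frequencies down-weighted per deleteriousness class,
  binomial Wright–Fisher resampling through a bottleneck for the isolate,
  and explicit autozygous-tract placement for inbreeding, with exact ground
  truth (true frequencies, class labels, tract coordinates).

## Worked example

```python
from isodist.simulate import ScenarioParams, simulate_scenario
from isodist import diversity as div, load, sfs, roh

sc = simulate_scenario(ScenarioParams(n_sites=10_000,
                                      chrom_lengths=(25_000_000,) * 6,
                                      seed=42))
syn = (sc.sites["consequence"] == "synonymous").to_numpy()
for pop in ("ISO", "REF"):
    r = div.diversity_with_ci(sc.gm, sc.panel, pop, site_mask=syn,
                              n_blocks=500, n_reps=300, seed=0)["theta_pi"]
    print(f"{pop}: theta_pi = {r.estimate:.1f} [{r.lo:.1f}, {r.hi:.1f}]")

mask = load.category_mask(sc.sites, sfs.scheme("gerp"), "moderate")
rec = load.load_ratio(sc.gm, sc.panel, "ISO", "REF", site_mask=mask,
                      model="recessive", n_blocks=500, n_reps=500, seed=0)
print(f"N_hom ratio (moderate, ISO/REF) = {rec.estimate:.2f} "
      f"[{rec.lo:.2f}, {rec.hi:.2f}], p = {rec.p_value:.3f}")
```

prints

```
ISO: theta_pi = 555.5 [528.1, 582.0]
REF: theta_pi = 1121.0 [1095.5, 1152.3]
N_hom ratio (moderate, ISO/REF) = 1.60 [1.49, 1.72], p = 0.004
```

The isolate's synonymous diversity is about half the reference's, with
disjoint bootstrap intervals, while its per-individual burden of homozygous
derived genotypes in the moderate GERP class is ~1.6× the reference's —
the recessive-model load excess expected after a bottleneck with inbreeding.
The same dataset yields a mean of ~8 ROHs ≥ 1 Mb per isolate individual and
essentially none in the reference.

## Command line

```sh
isodist simulate --seed 1 --out data/          # synthetic dataset
isodist qc --vcf in.vcf --panel panel.tsv --annot annot.tsv --out qc/
isodist diversity --vcf in.vcf --panel panel.tsv --annot annot.tsv \
    --mask synonymous --boot 1000x1000 --seed 1 --out diversity.tsv
isodist run --config run.yaml                  # full pipeline
```

The YAML config names either input files (`vcf`, `panel`, `annotation`,
optional `catalog`) or a `simulate:` block, plus stage parameters; one
master `seed` is fanned out deterministically to every stage, and rerunning
the same config reproduces byte-identical outputs.

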