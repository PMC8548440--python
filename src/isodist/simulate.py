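"""Two-population exome-like dataset generator.

Emulates the demographic contrast at the core of the analysis: a panmictic
reference population sampled at equilibrium frequencies, and an isolate that
passed a recent bottleneck (binomial Wright-Fisher resampling of allele
frequencies for a configurable number of generations at small size) followed
by inbreeding, modeled as per-individual autozygous tracts with exponential
lengths placed to cover an expected genome fraction f.  Each site carries a
deleteriousness class with a GERP-like score; more deleterious classes start
rarer via a deterministic frequency down-weighting 1/(1 + C s).  The default
class proportions mirror a typical exome annotation (~63% neutral, 18%
moderate, 19% large, 0.7% extreme).

Selection is not simulated forward in time; the generator reproduces the
qualitative contrasts the pipeline is meant to detect (flatter isolate SFS,
long ROHs, excess homozygous derived genotypes) with exact ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .store import MISSING, GenotypeMatrix

CLASSES = ("neutral", "moderate", "large", "extreme")
#: GERP-like score ranges per class (left-closed)
SCORE_RANGES = {"neutral": (-3.0, 2.0), "moderate": (2.0, 4.0),
                "large": (4.0, 6.0), "extreme": (6.0, 10.0)}


@dataclass
class PlantedRegion:
    """A high-drift missense gene region with fixed frequencies in both
    populations, used to validate candidate-subset recovery."""

    gene: str = "PLANTED1"
    chrom_index: int = 0
    n_sites: int = 30
    ref_freq: float = 0.02
    iso_freq: float = 0.95
    gerp: float = 8.0


@dataclass
class ScenarioParams:
    """Parameters of the isolate-vs-reference scenario.

    Defaults model a reference of 46 diploids and an isolate of 18 (the
    two-population design's sample sizes), a bottleneck of 30 diploids held
    for 40 generations, and autozygosity covering 12.5% of each isolate
    genome in tracts of mean 2.5 Mb.
    """

    n_sites: int = 50_000
    chrom_lengths: tuple = tuple([25_000_000] * 10)
    n_ref: int = 46
    n_iso: int = 18
    bottleneck_size: int = 30
    bottleneck_generations: int = 40
    inbreeding_f: float = 0.125
    tract_mean_length: float = 2_500_000.0
    sel_class_probs: dict = field(default_factory=lambda: {
        "neutral": 0.627, "moderate": 0.180, "large": 0.186, "extreme": 0.007})
    sel_coeffs: dict = field(default_factory=lambda: {
        "neutral": 0.0, "moderate": 4.5e-4, "large": 4.5e-3, "extreme": 1e-2})
    freq_weight_c: float = 200.0       # down-weight factor 1/(1 + C s)
    sfs_grid: int = 100                # 1/i law over derived counts 1..grid-1
    consequence_leakage: float = 0.05  # fraction labelled 'other'
    unknown_ancestral_frac: float = 0.02
    ref_is_derived_frac: float = 0.3   # sites whose VCF REF is the derived allele
    gene_window: int = 50_000          # bp per gene bin
    ref_label: str = "REF"
    iso_label: str = "ISO"
    planted: PlantedRegion | None = field(default_factory=PlantedRegion)
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.inbreeding_f < 1:
            raise ValueError("inbreeding_f must be in [0, 1)")
        if self.bottleneck_size < 2:
            raise ValueError("bottleneck_size must be >= 2")
        tot = sum(self.sel_class_probs.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError("sel_class_probs must sum to 1")


@dataclass
class Scenario:
    """In-memory simulation output plus exact ground truth."""

    gm: GenotypeMatrix            # polarized (derived dosages)
    sites: pd.DataFrame
    panel: pd.Series
    truth: dict
    params: ScenarioParams

    def write(self, out_dir) -> dict:
        """Emit VCF 4.2, annotation TSV, panel TSV and truth JSON; returns paths."""
        from .store import write_vcf

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"vcf": out / "simulated.vcf", "annotation": out / "annotation.tsv",
                 "panel": out / "panel.tsv", "truth": out / "truth.json"}
        write_vcf(self.gm, self.sites, paths["vcf"], source="isodist-simulate")
        cols = ["chrom", "pos", "ref", "alt", "ancestral", "gene", "consequence",
                "gerp_rs", "cadd", "polyphen"]
        self.sites[cols].to_csv(paths["annotation"], sep="\t", index=False,
                                float_format="%.6g")
        pd.DataFrame({"sample_id": self.gm.sample_ids,
                      "population": [self.panel[s] for s in self.gm.sample_ids]}
                     ).to_csv(paths["panel"], sep="\t", index=False, header=False)
        truth = dict(self.truth)
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=1, default=_jsonable)
        return {k: str(v) for k, v in paths.items()}


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer, np.floating)):
        return x.item()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def _wright_fisher(rng, freqs: np.ndarray, two_n: int, generations: int) -> np.ndarray:
    f = freqs.copy()
    for _ in range(generations):
        f = rng.binomial(two_n, f) / two_n
    return f


def _autozygous_tracts(rng, chrom_len: int, f: float, mean_len: float):
    """Alternating-renewal tract placement covering expected fraction f."""
    if f <= 0:
        return []
    gap_mean = mean_len * (1.0 - f) / f
    tracts = []
    pos = 0.0
    in_tract = rng.random() < f
    while pos < chrom_len:
        seg = rng.exponential(mean_len if in_tract else gap_mean)
        if in_tract:
            start = int(pos) + 1
            end = min(int(pos + seg), chrom_len)
            if end >= start:
                tracts.append((start, end))
        pos += seg
        in_tract = not in_tract
    return tracts


def simulate_scenario(params: ScenarioParams) -> Scenario:
    """Simulate the two-population dataset; identical params give identical output."""
    rng = np.random.default_rng(params.seed)
    n_chrom = len(params.chrom_lengths)
    total_len = float(sum(params.chrom_lengths))

    # --- positions, uniform along chromosomes, sorted, unique
    per_chrom = rng.multinomial(params.n_sites,
                                np.asarray(params.chrom_lengths) / total_len)
    chroms, positions = [], []
    for ci, (n_c, clen) in enumerate(zip(per_chrom, params.chrom_lengths)):
        raw = np.unique(rng.integers(1, clen + 1, size=int(n_c * 1.05) + 8))
        raw = rng.permutation(raw)[:n_c]
        raw.sort()
        positions.append(raw)
        chroms.append(np.full(len(raw), str(ci + 1), dtype=object))
    chrom = np.concatenate(chroms)
    pos = np.concatenate(positions)
    n_sites = len(pos)

    # --- deleteriousness classes, scores, consequences
    class_names = list(params.sel_class_probs)
    class_idx = rng.choice(len(class_names), size=n_sites,
                           p=list(params.sel_class_probs.values()))
    classes = np.array(class_names, dtype=object)[class_idx]
    gerp = np.empty(n_sites)
    for name in class_names:
        lo, hi = SCORE_RANGES[name]
        m = classes == name
        gerp[m] = rng.uniform(lo, hi, size=m.sum())
    leak = rng.random(n_sites) < params.consequence_leakage
    consequence = np.where(classes == "neutral", "synonymous", "missense")
    consequence = np.where(leak, "other", consequence).astype(object)
    # CADD-like score loosely increasing with GERP; PolyPhen from class
    cadd = np.clip(3.0 * gerp + rng.normal(0, 3, n_sites) + 8.0, 0, None)
    polyphen = np.select(
        [classes == "extreme", classes == "large", classes == "moderate"],
        ["probably_damaging", "possibly_damaging", "benign"], default="benign",
    ).astype(object)
    polyphen[consequence != "missense"] = "unknown"

    # --- ancestral frequencies: 1/i law, class down-weighted
    grid = np.arange(1, params.sfs_grid)
    p_law = (1.0 / grid) / np.sum(1.0 / grid)
    anc_freq = grid[rng.choice(len(grid), size=n_sites, p=p_law)] / params.sfs_grid
    s_arr = np.array([params.sel_coeffs.get(c, 0.0) for c in classes])
    anc_freq = anc_freq / (1.0 + params.freq_weight_c * s_arr)

    # --- isolate frequencies after the bottleneck
    iso_freq = _wright_fisher(rng, anc_freq, 2 * params.bottleneck_size,
                              params.bottleneck_generations)

    # --- genes: positional bins, one symbol per window
    gene = np.array([f"G{c}_{p // params.gene_window}"
                     for c, p in zip(chrom, pos)], dtype=object)

    # --- planted high-drift missense region
    planted_info = None
    if params.planted is not None and params.planted.n_sites > 0:
        pr = params.planted
        target_chrom = str(pr.chrom_index + 1)
        cand = np.where(chrom == target_chrom)[0]
        mid = len(cand) // 2
        sel = cand[mid:mid + pr.n_sites]
        classes[sel] = "extreme"
        gerp[sel] = pr.gerp
        consequence[sel] = "missense"
        polyphen[sel] = "probably_damaging"
        gene[sel] = pr.gene
        anc_freq[sel] = pr.ref_freq
        iso_freq[sel] = pr.iso_freq
        planted_info = {"gene": pr.gene, "site_idx": sel,
                        "chrom": target_chrom,
                        "start": int(pos[sel[0]]), "end": int(pos[sel[-1]])}

    # --- genotypes
    ref_gt = rng.binomial(2, anc_freq, size=(params.n_ref, n_sites)).astype(np.int8)
    iso_gt = np.empty((params.n_iso, n_sites), dtype=np.int8)
    tract_truth = {}
    chrom_of_site = chrom
    for i in range(params.n_iso):
        sample = f"{params.iso_label}{i + 1:03d}"
        tracts_all = {}
        in_tract = np.zeros(n_sites, dtype=bool)
        for ci, clen in enumerate(params.chrom_lengths):
            cname = str(ci + 1)
            tracts = _autozygous_tracts(rng, clen, params.inbreeding_f,
                                        params.tract_mean_length)
            if tracts:
                tracts_all[cname] = tracts
                csites = np.where(chrom_of_site == cname)[0]
                cpos = pos[csites]
                for start, end in tracts:
                    in_tract[csites[(cpos >= start) & (cpos <= end)]] = True
        hom_draw = 2 * rng.binomial(1, iso_freq)
        free_draw = rng.binomial(2, iso_freq)
        iso_gt[i] = np.where(in_tract, hom_draw, free_draw).astype(np.int8)
        tract_truth[sample] = tracts_all

    dosage = np.vstack([iso_gt, ref_gt])
    sample_ids = ([f"{params.iso_label}{i + 1:03d}" for i in range(params.n_iso)]
                  + [f"{params.ref_label}{i + 1:03d}" for i in range(params.n_ref)])
    panel = pd.Series([params.iso_label] * params.n_iso
                      + [params.ref_label] * params.n_ref, index=sample_ids)

    # --- allele encoding: ancestral base A, derived G; a fraction of sites
    # put the derived allele in the REF column (dosage in the VCF is then the
    # ancestral count), and a fraction has unknown ancestral state
    ref_is_derived = rng.random(n_sites) < params.ref_is_derived_frac
    unknown = rng.random(n_sites) < params.unknown_ancestral_frac
    ref_is_derived &= ~unknown  # unknown-state sites keep ancestral-as-REF orientation
    ref_allele = np.where(ref_is_derived, "G", "A").astype(object)
    alt_allele = np.where(ref_is_derived, "A", "G").astype(object)
    ancestral = np.where(unknown, ".", "A").astype(object)

    sites = pd.DataFrame({
        "chrom": chrom, "pos": pos.astype(np.int64), "ref": ref_allele,
        "alt": alt_allele, "ancestral": ancestral, "gene": gene,
        "consequence": consequence, "gerp_rs": gerp, "cadd": cadd,
        "polyphen": polyphen,
    })
    gm = GenotypeMatrix(sample_ids=sample_ids, dosage=dosage, polarized=True)

    mono = (dosage.sum(axis=0) == 0) | (dosage == 2).all(axis=0)
    truth = {
        "ancestral_freq": anc_freq, "isolate_freq": iso_freq,
        "classes": classes, "tracts": tract_truth,
        "monomorphic_fraction": float(mono.mean()),
        "planted": planted_info,
    }
    if truth["monomorphic_fraction"] > 0.9:
        import warnings
        warnings.warn(
            f"{truth['monomorphic_fraction']:.0%} of simulated sites are "
            "monomorphic; check bottleneck parameters")
    return Scenario(gm=gm, sites=sites, panel=panel, truth=truth, params=params)


def toy_trait_catalog(scenario: Scenario, n_traits: int = 20,
                      genes_per_trait: int = 15, seed=0) -> dict[str, list[str]]:
    """A small trait->genes catalog over the simulated gene universe.

    Trait 'planted_trait' contains the planted high-drift gene (if any) plus
    random genes; the remaining traits are random draws, so the catalog
    supports both positive-control and null enrichment checks.
    """
    rng = np.random.default_rng(seed)
    universe = sorted(set(scenario.sites["gene"]) - {""})
    catalog = {}
    for t in range(n_traits):
        picks = list(rng.choice(universe, size=genes_per_trait, replace=False))
        catalog[f"trait_{t:02d}"] = sorted(picks)
    if scenario.truth.get("planted"):
        planted_gene = scenario.truth["planted"]["gene"]
        extra = list(rng.choice(universe, size=genes_per_trait - 1, replace=False))
        catalog["planted_trait"] = sorted(set(extra) | {planted_gene})
    return catalog


# ---------------------------------------------------------------------------
# worked micro-fixture
# ---------------------------------------------------------------------------

def worked_fixture():
    """Deterministic micro-dataset with hand-computable expectations.

    Two populations of 4 diploids (ISO, REF).  Chromosome 1 carries the
    statistics sites, including one fixed difference (per-site Fst exactly 1),
    a monomorphic site and a high-missingness site for the QC counts;
    chromosome 2 carries a planted 60-SNP, ~1.5 Mb homozygous tract in sample
    ISO1.  Returns (gm, sites, panel, manifest) where the manifest freezes the
    expected values (computed with independent brute-force oracles when the
    fixture was authored).
    """
    iso = ["ISO1", "ISO2", "ISO3", "ISO4"]
    ref = ["REF1", "REF2", "REF3", "REF4"]
    samples = iso + ref
    panel = pd.Series(["ISO"] * 4 + ["REF"] * 4, index=samples)
    M = MISSING

    rows = []          # (chrom, pos, gene, consequence, gerp, dosages[8])
    pos = 10_000
    # 20 synonymous neutral sites: ISO dosages fixed pattern, REF another
    iso_patterns = [(1, 1, 0, 0), (2, 1, 1, 0), (0, 0, 0, 1), (2, 2, 2, 2)]
    ref_patterns = [(1, 0, 0, 0), (1, 1, 1, 1), (0, 1, 0, 1), (0, 0, 0, 0)]
    for k in range(20):
        ipat = iso_patterns[k % 4]
        rpat = ref_patterns[(k // 4) % 4]
        rows.append(("1", pos, f"GENE{k % 5}", "synonymous", 0.5,
                     ipat + rpat))
        pos += 5_000
    # 8 missense sites across GERP classes
    for k, (g, pat) in enumerate([
            (3.0, (2, 2, 1, 0, 0, 1, 0, 0)), (3.5, (2, 2, 2, 1, 0, 0, 1, 0)),
            (5.0, (1, 2, 2, 0, 0, 0, 0, 1)), (5.5, (2, 1, 0, 0, 1, 0, 0, 0)),
            (7.0, (2, 2, 2, 2, 0, 0, 0, 1)), (7.5, (1, 1, 2, 0, 0, 1, 0, 0)),
            (2.5, (1, 0, 1, 0, 0, 0, 1, 1)), (4.5, (2, 0, 1, 1, 1, 0, 0, 0))]):
        rows.append(("1", pos, f"GENE{5 + k % 3}", "missense", g, pat))
        pos += 5_000
    # fixed difference: ISO all homozygous derived, REF ancestral
    rows.append(("1", pos, "GENEFIX", "missense", 6.5, (2, 2, 2, 2, 0, 0, 0, 0)))
    pos += 5_000
    # monomorphic site (QC removes it)
    rows.append(("1", pos, "GENE0", "synonymous", 0.1, (0, 0, 0, 0, 0, 0, 0, 0)))
    pos += 5_000
    # high-missingness site (3/8 missing > 5%)
    rows.append(("1", pos, "GENE1", "synonymous", 0.2, (M, M, M, 1, 0, 1, 0, 0)))
    pos += 5_000
    # chromosome 2: 60-SNP homozygous tract in ISO1 spanning ~1.5 Mb;
    # other samples heterozygous at every 5th site so they carry no run
    pos2 = 1_000_000
    for k in range(60):
        others = [1 if (k + j) % 5 == 0 else 0 for j in range(7)]
        rows.append(("2", pos2, "GENEROH", "synonymous", 0.3,
                     tuple([2] + others)))
        pos2 += 25_000  # 59 * 25 kb ~ 1.475 Mb span
    sites = pd.DataFrame(
        [(c, p, "A", "G", "A", g, cons, gerp, np.nan, "unknown")
         for (c, p, g, cons, gerp, _d) in rows],
        columns=["chrom", "pos", "ref", "alt", "ancestral", "gene",
                 "consequence", "gerp_rs", "cadd", "polyphen"])
    dosage = np.array([d for (*_x, d) in rows], dtype=np.int8).T
    gm = GenotypeMatrix(sample_ids=samples, dosage=dosage, polarized=True)

    manifest = {
        # QC counts under default thresholds (DP/GQ absent -> skipped)
        "qc": {"monomorphic": 1, "missingness": 1, "hwe": 0, "retained": 89},
        # brute-force pairwise-difference theta_pi over the 20 synonymous
        # chr-1 sites (frozen at authoring time)
        "theta_pi_syn_iso": 6.25,
        "theta_pi_syn_ref": 6.0,
        "fixed_site_fst": 1.0,
        "planted_roh": {"sample_id": "ISO1", "chrom": "2", "n_snps": 60,
                        "start": 1_000_000, "end": 1_000_000 + 59 * 25_000},
        "n_sites": len(sites),
    }
    return gm, sites, panel, manifest
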