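"""Genotype/annotation store: VCF input, QC filters, polarization.

The central containers are a :class:`GenotypeMatrix` (samples x sites
derived- or alt-allele dosage, ``MISSING`` = -1) and a site table — a pandas
DataFrame with one row per biallelic autosomal SNP carrying coordinates,
alleles, the inferred ancestral allele and functional annotation columns
(gene, consequence, GERP RS score, optional CADD / PolyPhen).  All downstream
statistics consume these two objects plus a sample -> population panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1

#: chromosome labels treated as sex chromosomes and excluded up front
SEX_CHROM_LABELS = frozenset({"X", "Y", "chrX", "chrY", "23", "24"})

SITE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "ancestral",
    "gene",
    "consequence",
    "gerp_rs",
    "cadd",
    "polyphen",
]


@dataclass
class QCThresholds:
    """Variant- and sample-level QC thresholds.

    min_depth/min_gq act per genotype (set to missing below threshold);
    max_site_missingness and the exact Hardy–Weinberg test act per site;
    max_sample_missingness and the heterozygosity outlier rule act per sample.
    Set a threshold to ``None`` to disable that sub-filter.
    """

    min_depth: int | None = 5
    min_gq: int | None = 20
    max_site_missingness: float | None = 0.05
    hwe_alpha: float | None = 1e-3
    max_sample_missingness: float | None = 0.10
    het_sd_range: float | None = 4.0

    def __post_init__(self):
        for name in ("max_site_missingness", "max_sample_missingness"):
            v = getattr(self, name)
            if v is not None and not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("min_depth", "min_gq", "hwe_alpha", "het_sd_range"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")

    @classmethod
    def disabled(cls) -> "QCThresholds":
        """Thresholds object with every sub-filter switched off (monomorphic
        sites are still removed, as that rule is structural, not a threshold)."""
        return cls(min_depth=None, min_gq=None, max_site_missingness=None,
                   hwe_alpha=None, max_sample_missingness=None, het_sd_range=None)


@dataclass
class GenotypeMatrix:
    """Samples x sites dosage matrix.

    ``dosage[i, j]`` counts alt alleles (before :func:`polarize`) or derived
    alleles (after) for sample i at site j; ``MISSING`` marks no-calls.
    Optional per-genotype ``depth`` and ``gq`` arrays are carried along for
    the QC stage and dropped afterwards.
    """

    sample_ids: list[str]
    dosage: np.ndarray
    polarized: bool = False
    depth: np.ndarray | None = field(default=None, repr=False)
    gq: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x sites)")
        if self.dosage.shape[0] != len(self.sample_ids):
            raise ValueError("row count must equal number of sample_ids")
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosage values must be in {0, 1, 2, MISSING}")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[1]

    def sample_index(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not in genotype matrix") from None

    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            dosage=self.dosage[:, idx],
            polarized=self.polarized,
            depth=None if self.depth is None else self.depth[:, idx],
            gq=None if self.gq is None else self.gq[:, idx],
        )

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            dosage=self.dosage[idx],
            polarized=self.polarized,
            depth=None if self.depth is None else self.depth[idx],
            gq=None if self.gq is None else self.gq[idx],
        )


def population_indices(gm: GenotypeMatrix, panel: pd.Series, population: str) -> np.ndarray:
    """Row indices of ``gm`` belonging to ``population`` (panel: sample -> label)."""
    members = [s for s in gm.sample_ids if panel.get(s) == population]
    if not members:
        raise KeyError(f"population {population!r} has no samples in the matrix")
    return gm.sample_index(members)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_panel(path) -> pd.Series:
    """Two-column TSV (sample_id, population) -> Series sample_id -> population."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "population"],
                     dtype=str, comment="#")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample in panel: {dup}")
    return df.set_index("sample_id")["population"]


def read_annotations(path) -> pd.DataFrame:
    """Annotation TSV with header (chrom, pos, ref, alt, ancestral, gene,
    consequence, gerp_rs, cadd, polyphen)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str,
                                            "polyphen": str, "consequence": str})
    missing = {"chrom", "pos", "ref", "alt"} - set(df.columns)
    if missing:
        raise ValueError(f"annotation file lacks columns: {sorted(missing)}")
    df["pos"] = df["pos"].astype(np.int64)
    return df


def attach_annotations(sites: pd.DataFrame, annot: pd.DataFrame) -> pd.DataFrame:
    """Left-join annotation columns onto the site table by (chrom, pos, ref, alt)."""
    keep = [c for c in annot.columns if c in SITE_COLUMNS]
    merged = sites.merge(annot[keep], on=["chrom", "pos", "ref", "alt"], how="left",
                         suffixes=("", "_annot"))
    for col in ("ancestral", "gene", "consequence", "polyphen"):
        if col in merged.columns:
            merged[col] = merged[col].fillna("" if col in ("gene",) else ".")
    merged.index = sites.index
    return merged


def read_vcf(path, panel: pd.Series | None = None,
             sex_chroms=SEX_CHROM_LABELS):
    """Read a VCF 4.x into an (unpolarized) GenotypeMatrix plus a partial site table.

    Indel, multiallelic and sex-chromosome records are dropped; the returned
    report counts them.  If ``panel`` is given, the matrix is restricted to
    panel samples (all of which must exist in the VCF).
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path, gts012=True)
    vcf_samples = list(vcf.samples)
    if panel is not None:
        absent = [s for s in panel.index if s not in vcf_samples]
        if absent:
            raise KeyError(f"panel sample {absent[0]!r} absent from VCF")
        vcf.close()
        vcf = VCF(path, gts012=True, samples=list(panel.index))
    samples = list(vcf.samples)

    dosages, depths, gqs = [], [], []
    rows = []
    report = {"indel": 0, "multiallelic": 0, "sex_chrom": 0, "retained": 0}
    have_dp = have_gq = True
    for v in vcf:
        if v.CHROM in sex_chroms:
            report["sex_chrom"] += 1
            continue
        if len(v.ALT) != 1:
            report["multiallelic"] += 1
            continue
        if not v.is_snp:
            report["indel"] += 1
            continue
        gt = np.asarray(v.gt_types, dtype=np.int8)  # gts012: 0,1,2 and 3=unknown
        gt[gt == 3] = MISSING
        dosages.append(gt)
        if have_dp:
            try:
                dp = v.format("DP")
            except KeyError:
                dp = None
            if dp is None:
                have_dp = False
            else:
                depths.append(dp[:, 0].astype(np.int32))
        if have_gq:
            try:
                gq = v.format("GQ")
            except KeyError:
                gq = None
            if gq is None:
                have_gq = False
            else:
                gqs.append(np.asarray(gq, dtype=np.float32).reshape(len(samples), -1)[:, 0])
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
        report["retained"] += 1
    vcf.close()

    if not rows:
        raise ValueError(f"no biallelic autosomal SNPs retained from {path}")
    dosage = np.stack(dosages, axis=1)
    gm = GenotypeMatrix(
        sample_ids=samples,
        dosage=dosage,
        polarized=False,
        depth=np.stack(depths, axis=1) if have_dp and depths else None,
        gq=np.stack(gqs, axis=1) if have_gq and gqs else None,
    )
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    sites["chrom"] = sites["chrom"].astype(str)
    return gm, sites, report


def write_vcf(gm: GenotypeMatrix, sites: pd.DataFrame, path,
              source="isodist") -> None:
    """Write the matrix back out as a minimal plain-text VCF 4.2 with GT only.

    Dosages are written on the alt-allele scale the input used: for a
    polarized matrix whose site has ancestral == alt, the stored derived
    dosage is converted back so the emitted GT matches the REF/ALT columns.
    """
    dosage = gm.dosage
    if gm.polarized and "ancestral" in sites.columns:
        flip = (sites["ancestral"].to_numpy() == sites["alt"].to_numpy())
        dosage = dosage.copy()
        cols = np.where(flip)[0]
        sub = dosage[:, cols]
        valid = sub != MISSING
        sub[valid] = 2 - sub[valid]
        dosage[:, cols] = sub
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        if "ancestral" in sites.columns:
            fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        anc = sites["ancestral"].to_numpy() if "ancestral" in sites.columns else None
        chroms = sites["chrom"].to_numpy()
        poss = sites["pos"].to_numpy()
        refs = sites["ref"].to_numpy()
        alts = sites["alt"].to_numpy()
        for j in range(len(sites)):
            info = f"AA={anc[j]}" if anc is not None else "."
            gts = "\t".join(gt_str[int(d)] for d in dosage[:, j])
            fh.write(f"{chroms[j]}\t{poss[j]}\t.\t{refs[j]}\t{alts[j]}\t.\tPASS\t{info}\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=200_000)
def hwe_exact_p(n_het: int, n_hom_1: int, n_hom_2: int) -> float:
    """Exact conditional Hardy–Weinberg test p-value from genotype counts.

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the conditional probabilities not exceeding that of the
    observed configuration (the standard exact test for small samples).
    """
    n = n_het + n_hom_1 + n_hom_2
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom_1, n_hom_2) + n_het  # rare-allele copies
    # probabilities over het counts with the parity of n_rare, 0..min(n_rare, 2n-n_rare)
    max_het = min(n_rare, 2 * n - n_rare)
    het0 = n_rare % 2
    hets = list(range(het0, max_het + 1, 2))
    # unnormalized probs via recurrence: P(h+2)/P(h) = (nr-h)(2n-nr-h)/((h+2)(h+1)) * ... use log-free recurrence
    probs = {}
    h_mid = hets[len(hets) // 2]
    probs[h_mid] = 1.0
    # upward
    h = h_mid
    while h + 2 <= max_het:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[h + 2] = probs[h] * (4.0 * hom_r * hom_c) / ((h + 2.0) * (h + 1.0))
        h += 2
    # downward
    h = h_mid
    while h - 2 >= het0:
        hom_r = (n_rare - h) // 2 + 1
        hom_c = n - (h - 2) - hom_r
        probs[h - 2] = probs[h] * (h * (h - 1.0)) / (4.0 * hom_r * hom_c)
        h -= 2
    total = sum(probs.values())
    p_obs = probs[n_het] / total
    p = sum(v for v in probs.values() if v / total <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p)


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def qc_filter_sites(gm: GenotypeMatrix, sites: pd.DataFrame, panel: pd.Series,
                    thr: QCThresholds = QCThresholds(),
                    drop_monomorphic: bool = True):
    """Apply site-level QC.

    Genotypes below min_depth / min_gq become missing first; then sites are
    removed if monomorphic in the pooled dataset, if their missingness exceeds
    max_site_missingness, or if the exact HWE test rejects at hwe_alpha in at
    least one panel population.  Returns (gm, sites, report) where report
    carries per-rule removal counts and flags for skipped sub-filters.
    """
    dosage = gm.dosage.copy()
    report: dict = {"depth_masked": 0, "gq_masked": 0, "monomorphic": 0,
                    "missingness": 0, "hwe": 0, "retained": 0,
                    "skipped_filters": []}

    if thr.min_depth is not None:
        if gm.depth is None:
            report["skipped_filters"].append("depth")
        else:
            mask = (gm.depth < thr.min_depth) & (dosage != MISSING)
            report["depth_masked"] = int(mask.sum())
            dosage[mask] = MISSING
    if thr.min_gq is not None:
        if gm.gq is None:
            report["skipped_filters"].append("gq")
        else:
            mask = (gm.gq < thr.min_gq) & (dosage != MISSING)
            report["gq_masked"] = int(mask.sum())
            dosage[mask] = MISSING

    n_samples, n_sites = dosage.shape
    valid = dosage != MISSING
    n_valid = valid.sum(axis=0)

    # monomorphic in the pooled dataset (all non-missing calls identical hom)
    with np.errstate(invalid="ignore"):
        alt_count = np.where(valid, dosage, 0).sum(axis=0)
    mono = (alt_count == 0) | (alt_count == 2 * n_valid) | (n_valid == 0)
    if not drop_monomorphic:
        mono = np.zeros(n_sites, dtype=bool)

    miss_frac = 1.0 - n_valid / n_samples
    fail_miss = np.zeros(n_sites, dtype=bool)
    if thr.max_site_missingness is not None:
        fail_miss = miss_frac > thr.max_site_missingness

    fail_hwe = np.zeros(n_sites, dtype=bool)
    if thr.hwe_alpha is not None:
        pops = sorted(set(panel.get(s) for s in gm.sample_ids) - {None})
        for pop in pops:
            rows = population_indices(gm, panel, pop)
            sub = dosage[rows]
            n_het = (sub == 1).sum(axis=0)
            n_hom0 = (sub == 0).sum(axis=0)
            n_hom2 = (sub == 2).sum(axis=0)
            for j in range(n_sites):
                if fail_hwe[j]:
                    continue
                if hwe_exact_p(int(n_het[j]), int(n_hom0[j]), int(n_hom2[j])) < thr.hwe_alpha:
                    fail_hwe[j] = True

    # removal precedence for reporting: monomorphic, then missingness, then HWE
    report["monomorphic"] = int(mono.sum())
    report["missingness"] = int((fail_miss & ~mono).sum())
    report["hwe"] = int((fail_hwe & ~mono & ~fail_miss).sum())
    keep = ~(mono | fail_miss | fail_hwe)
    report["retained"] = int(keep.sum())
    if report["retained"] == 0:
        raise ValueError("site QC removed every site")

    gm_out = GenotypeMatrix(sample_ids=list(gm.sample_ids),
                            dosage=dosage[:, keep], polarized=gm.polarized)
    sites_out = sites.loc[keep].reset_index(drop=True)
    return gm_out, sites_out, report


def qc_filter_samples(gm: GenotypeMatrix, panel: pd.Series,
                      thr: QCThresholds = QCThresholds()):
    """Drop samples with excess missingness or outlying heterozygosity.

    Heterozygosity (het calls / non-missing calls) is compared against the
    sample's own population mean +/- het_sd_range standard deviations; a
    population with zero SD produces no outliers.  Returns (gm, report) where
    report["dropped"] maps sample -> reason.
    """
    if gm.n_samples < 3:
        raise ValueError("sample QC requires at least 3 samples")
    valid = gm.dosage != MISSING
    n_valid = valid.sum(axis=1)
    miss_frac = 1.0 - n_valid / gm.n_sites
    with np.errstate(invalid="ignore"):
        het = np.where(n_valid > 0, (gm.dosage == 1).sum(axis=1) / np.maximum(n_valid, 1), np.nan)

    dropped: dict[str, str] = {}
    if thr.max_sample_missingness is not None:
        for i, s in enumerate(gm.sample_ids):
            if miss_frac[i] > thr.max_sample_missingness:
                dropped[s] = "missingness"
    if thr.het_sd_range is not None:
        pops = sorted(set(panel.get(s) for s in gm.sample_ids) - {None})
        for pop in pops:
            rows = population_indices(gm, panel, pop)
            vals = het[rows]
            mu, sd = np.nanmean(vals), np.nanstd(vals)
            if sd == 0 or np.isnan(sd):
                continue
            for i in rows:
                s = gm.sample_ids[i]
                if s not in dropped and abs(het[i] - mu) > thr.het_sd_range * sd:
                    dropped[s] = "heterozygosity"

    keep = [i for i, s in enumerate(gm.sample_ids) if s not in dropped]
    if not keep:
        raise ValueError("sample QC removed every sample")
    report = {"dropped": dropped, "retained": len(keep)}
    return gm.take_samples(keep), report


# ---------------------------------------------------------------------------
# polarization & derived frequency
# ---------------------------------------------------------------------------

def polarize(gm: GenotypeMatrix, sites: pd.DataFrame):
    """Re-code dosages to count derived alleles using the ancestral column.

    Sites with unknown ancestral allele ('.', '', 'N') are removed; sites
    whose ancestral allele matches neither ref nor alt are dropped with a
    warning.  Where ancestral == alt, dosage d -> 2 - d (missing untouched).
    Returns (gm, sites, report).
    """
    if gm.polarized:
        raise ValueError("matrix already polarized")
    if "ancestral" not in sites.columns:
        raise ValueError("site table lacks an 'ancestral' column")
    anc = sites["ancestral"].fillna(".").astype(str).str.upper().to_numpy()
    ref = sites["ref"].astype(str).str.upper().to_numpy()
    alt = sites["alt"].astype(str).str.upper().to_numpy()

    unknown = np.isin(anc, [".", "", "N", "NAN"])
    is_ref = anc == ref
    is_alt = anc == alt
    mismatch = ~unknown & ~is_ref & ~is_alt
    if mismatch.any():
        log.warning("%d sites have an ancestral allele matching neither ref nor alt; dropped",
                    int(mismatch.sum()))
    keep = is_ref | is_alt

    dosage = gm.dosage[:, keep].copy()
    flip_cols = np.where(is_alt[keep])[0]
    sub = dosage[:, flip_cols]
    valid = sub != MISSING
    sub[valid] = 2 - sub[valid]
    dosage[:, flip_cols] = sub

    report = {"unknown_ancestral": int(unknown.sum()),
              "ancestral_mismatch": int(mismatch.sum()),
              "flipped": int(is_alt.sum()),
              "retained": int(keep.sum())}
    gm_out = GenotypeMatrix(sample_ids=list(gm.sample_ids), dosage=dosage, polarized=True)
    sites_out = sites.loc[keep].reset_index(drop=True)
    return gm_out, sites_out, report


def derived_freq(gm: GenotypeMatrix, sample_idx=None) -> np.ndarray:
    """Per-site derived allele frequency q over the given samples.

    q = sum(dosage) / (2 * non-missing count); NaN where every genotype is
    missing.  Requires a polarized matrix.
    """
    if not gm.polarized:
        raise ValueError("derived_freq needs a polarized matrix")
    d = gm.dosage if sample_idx is None else gm.dosage[np.asarray(sample_idx)]
    valid = d != MISSING
    n = valid.sum(axis=0)
    tot = np.where(valid, d, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(n > 0, tot / (2.0 * n), np.nan)
    return q
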