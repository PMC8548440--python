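"""Runs of homozygosity: LD pruning, detection, summaries, zygosity ratios.

A ROH is a maximal run of consecutive non-missing homozygous genotypes
(derived dosage 0 or 2) in one individual, with no heterozygote inside, at
least ``min_snps`` SNPs, a span of at least ``min_length`` bp, and no
inter-SNP gap above ``max_gap``.  With zero heterozygotes allowed, PLINK's
sliding-window calling reduces to maximal-run calling, which is what is
implemented.  Lengths are end - start + 1 (1-based inclusive SNP positions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .store import MISSING, GenotypeMatrix, population_indices

#: default length classes in bp: 1-2.5 Mb, 2.5-5 Mb, > 5 Mb
DEFAULT_LENGTH_CLASSES = ((1_000_000, 2_500_000), (2_500_000, 5_000_000),
                          (5_000_000, np.inf))


@dataclass
class ROHParams:
    r2_prune: float = 0.8
    prune_window_kb: float = 50.0
    prune_step_snps: int = 5
    min_snps: int = 50
    het_allowed: int = 0
    min_length: int = 1_000_000
    max_gap: int = 1_000_000
    missing_allowed: int = 0
    length_classes: tuple = DEFAULT_LENGTH_CLASSES

    def __post_init__(self):
        if self.het_allowed != 0 or self.missing_allowed != 0:
            raise NotImplementedError(
                "only strict runs (no het, no missing inside) are supported")


def dosage_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over pairwise-complete
    samples; NaN when either is constant on the shared set."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return float("nan")
    xs, ys = x[ok].astype(float), y[ok].astype(float)
    if xs.std() == 0 or ys.std() == 0:
        return float("nan")
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def ld_prune(gm: GenotypeMatrix, sites: pd.DataFrame, window_kb: float = 50.0,
             step_snps: int = 5, r2_threshold: float = 0.8) -> np.ndarray:
    """Greedy left-to-right LD pruning; returns a boolean keep-mask.

    Within each window (sites within window_kb of the window's first kept
    site), any pair with squared dosage correlation above the threshold loses
    its later member; the scan then advances by ``step_snps``.  Deterministic.
    """
    pos = sites["pos"].to_numpy()
    chrom = sites["chrom"].to_numpy()
    keep = np.ones(len(sites), dtype=bool)
    window_bp = window_kb * 1000.0
    for ch in pd.unique(chrom):
        idx = np.where(chrom == ch)[0]
        start = 0
        while start < len(idx):
            i0 = idx[start]
            in_win = idx[(pos[idx] >= pos[i0]) & (pos[idx] <= pos[i0] + window_bp)]
            members = [j for j in in_win if keep[j]]
            for a_i in range(len(members)):
                ja = members[a_i]
                if not keep[ja]:
                    continue
                for jb in members[a_i + 1:]:
                    if not keep[jb]:
                        continue
                    r2 = dosage_r2(gm.dosage[:, ja], gm.dosage[:, jb])
                    if np.isfinite(r2) and r2 > r2_threshold:
                        keep[jb] = False
            start += step_snps
    return keep


def detect_rohs(gm: GenotypeMatrix, sites: pd.DataFrame, sample,
                params: ROHParams = ROHParams()) -> pd.DataFrame:
    """ROHs for one sample (id or row index) as a DataFrame
    (sample_id, chrom, start, end, length, n_snps)."""
    if isinstance(sample, str):
        row = gm.sample_index([sample])[0]
    else:
        row = int(sample)
    sample_id = gm.sample_ids[row]
    d = gm.dosage[row]
    pos = sites["pos"].to_numpy()
    chrom = sites["chrom"].to_numpy()
    records = []
    for ch in pd.unique(chrom):
        cidx = np.where(chrom == ch)[0]
        p = pos[cidx]
        hom = (d[cidx] == 0) | (d[cidx] == 2)
        # break runs at non-homozygous calls and at oversized gaps
        gap_break = np.zeros(len(cidx), dtype=bool)
        gap_break[1:] = np.diff(p) > params.max_gap
        run_id = np.cumsum(~hom | gap_break)
        for seg in np.split(np.arange(len(cidx)), np.flatnonzero(np.diff(run_id)) + 1):
            seg = seg[hom[seg]]
            if seg.size < params.min_snps:
                continue
            start, end = int(p[seg[0]]), int(p[seg[-1]])
            length = end - start + 1
            if length < params.min_length:
                continue
            records.append((sample_id, ch, start, end, length, int(seg.size)))
    return pd.DataFrame(records, columns=["sample_id", "chrom", "start", "end",
                                          "length", "n_snps"])


def detect_rohs_all(gm: GenotypeMatrix, sites: pd.DataFrame,
                    params: ROHParams = ROHParams()) -> pd.DataFrame:
    """ROHs for every sample in the matrix."""
    frames = [detect_rohs(gm, sites, i, params) for i in range(gm.n_samples)]
    if not frames:
        return pd.DataFrame(columns=["sample_id", "chrom", "start", "end",
                                     "length", "n_snps"])
    return pd.concat(frames, ignore_index=True)


def rohs_to_bed(rohs: pd.DataFrame, path) -> None:
    """Write ROHs as BED (0-based half-open), name = sample_id, score = n_snps."""
    with open(path, "w") as fh:
        for _, r in rohs.iterrows():
            fh.write(f"{r['chrom']}\t{r['start'] - 1}\t{r['end']}\t"
                     f"{r['sample_id']}\t{r['n_snps']}\n")


def _class_label(length, classes) -> str:
    for lo, hi in classes:
        if lo <= length < hi:
            return f"{lo / 1e6:g}-{'inf' if np.isinf(hi) else f'{hi / 1e6:g}'}Mb"
    return "below_min"


def _sig_tier(p: float) -> str:
    if not np.isfinite(p):
        return ""
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def roh_summaries(rohs: pd.DataFrame, panel: pd.Series, sample_ids,
                  length_classes=DEFAULT_LENGTH_CLASSES,
                  population_pairs=None):
    """Per-individual ROH summaries per length class plus Welch t-tests.

    ``sample_ids`` fixes the full sample list so individuals with zero ROHs
    appear with zero counts.  ``population_pairs`` (list of (popA, popB))
    selects the comparisons; t-tests compare per-individual counts per class
    and overall, annotated with 0.05/0.01/0.001 significance stars.
    """
    class_names = [_class_label((lo + min(hi, lo + 1)) / 2, length_classes)
                   for lo, hi in length_classes]
    rows = []
    roh_by_sample = dict(tuple(rohs.groupby("sample_id"))) if len(rohs) else {}
    for s in sample_ids:
        sub = roh_by_sample.get(s)
        lengths = sub["length"].to_numpy() if sub is not None else np.array([])
        entry = {"sample_id": s, "population": panel.get(s)}
        entry["count_total"] = len(lengths)
        entry["length_total"] = float(lengths.sum())
        entry["length_mean"] = float(lengths.mean()) if len(lengths) else 0.0
        for (lo, hi), name in zip(length_classes, class_names):
            in_class = lengths[(lengths >= lo) & (lengths < hi)]
            entry[f"count_{name}"] = len(in_class)
            entry[f"length_{name}"] = float(in_class.sum())
        rows.append(entry)
    per_ind = pd.DataFrame(rows)

    tests = []
    if population_pairs:
        for pop_a, pop_b in population_pairs:
            va = per_ind[per_ind["population"] == pop_a]
            vb = per_ind[per_ind["population"] == pop_b]
            for name in ["total"] + class_names:
                xa = va[f"count_{name}"].to_numpy(dtype=float)
                xb = vb[f"count_{name}"].to_numpy(dtype=float)
                if xa.sum() == 0 and xb.sum() == 0:
                    tests.append({"pop_a": pop_a, "pop_b": pop_b, "class": name,
                                  "mean_a": 0.0, "mean_b": 0.0, "p": np.nan,
                                  "stars": "", "skipped": True})
                    continue
                t = sstats.ttest_ind(xa, xb, equal_var=False)
                tests.append({"pop_a": pop_a, "pop_b": pop_b, "class": name,
                              "mean_a": float(xa.mean()), "mean_b": float(xb.mean()),
                              "p": float(t.pvalue), "stars": _sig_tier(t.pvalue),
                              "skipped": False})
    return per_ind, pd.DataFrame(tests)


def _in_roh_mask(sample_rohs: pd.DataFrame, sites: pd.DataFrame,
                 length_range=None) -> np.ndarray:
    """Boolean per-site mask: inside any of this sample's ROHs (optionally
    restricted to a length range)."""
    mask = np.zeros(len(sites), dtype=bool)
    if sample_rohs is None or not len(sample_rohs):
        return mask
    sub = sample_rohs
    if length_range is not None:
        lo, hi = length_range
        sub = sub[(sub["length"] >= lo) & (sub["length"] < hi)]
    pos = sites["pos"].to_numpy()
    chrom = sites["chrom"].to_numpy()
    for _, r in sub.iterrows():
        mask |= (chrom == r["chrom"]) & (pos >= r["start"]) & (pos <= r["end"])
    return mask


def roh_zygosity_ratio(gm: GenotypeMatrix, sites: pd.DataFrame,
                       rohs: pd.DataFrame, panel: pd.Series,
                       gerp_classes=("moderate", "large", "extreme"),
                       length_classes=DEFAULT_LENGTH_CLASSES):
    """Missense/synonymous homozygote ratio per individual per region.

    For each individual the regions are: inside any ROH, outside all ROHs,
    and inside ROHs of each length class.  Within a region and GERP class,
    the ratio is (# dosage-2 genotypes at missense sites of that class) /
    (# dosage-2 genotypes at synonymous sites with GERP < 2).  Individuals
    with a zero denominator get NaN and are excluded from the paired
    inside-vs-outside t-tests, reported per population and class.
    """
    from .sfs import gerp_category

    labels = gerp_category(sites["gerp_rs"].to_numpy(dtype=float))
    cons = sites["consequence"].fillna("").to_numpy()
    syn_mask = (cons == "synonymous") & (labels == "neutral")
    mis_masks = {c: (cons == "missense") & (labels == c) for c in gerp_classes}

    class_names = {cl: _class_label((cl[0] + min(cl[1], cl[0] + 1)) / 2,
                                    length_classes) for cl in length_classes}
    roh_by_sample = dict(tuple(rohs.groupby("sample_id"))) if len(rohs) else {}
    rows = []
    for i, s in enumerate(gm.sample_ids):
        d = gm.dosage[i]
        hom_derived = d == 2
        inside = _in_roh_mask(roh_by_sample.get(s), sites)
        regions = {"inside": inside, "outside": ~inside}
        for cl, name in class_names.items():
            regions[f"inside_{name}"] = _in_roh_mask(roh_by_sample.get(s),
                                                     sites, cl)
        for region, rmask in regions.items():
            n_syn = int((hom_derived & syn_mask & rmask).sum())
            for gclass, mmask in mis_masks.items():
                n_mis = int((hom_derived & mmask & rmask).sum())
                rows.append({"sample_id": s, "population": panel.get(s),
                             "region": region, "gerp_class": gclass,
                             "n_missense_hom": n_mis, "n_syn_hom": n_syn,
                             "ratio": n_mis / n_syn if n_syn > 0 else np.nan})
    per_ind = pd.DataFrame(rows)

    tests = []
    for pop in sorted(set(panel.get(s) for s in gm.sample_ids) - {None}):
        for gclass in gerp_classes:
            sub = per_ind[(per_ind["population"] == pop)
                          & (per_ind["gerp_class"] == gclass)]
            inside = sub[sub["region"] == "inside"].set_index("sample_id")["ratio"]
            outside = sub[sub["region"] == "outside"].set_index("sample_id")["ratio"]
            both = pd.concat([inside, outside], axis=1, keys=["in", "out"]).dropna()
            if len(both) < 2 or np.allclose(both["in"], both["out"]):
                tests.append({"population": pop, "gerp_class": gclass,
                              "n": len(both), "p": np.nan, "stars": ""})
                continue
            t = sstats.ttest_rel(both["in"], both["out"])
            tests.append({"population": pop, "gerp_class": gclass,
                          "n": len(both), "mean_inside": float(both["in"].mean()),
                          "mean_outside": float(both["out"].mean()),
                          "p": float(t.pvalue), "stars": _sig_tier(t.pvalue)})
    return per_ind, pd.DataFrame(tests)
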