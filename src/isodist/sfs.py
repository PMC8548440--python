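"""Unfolded site frequency spectra by deleteriousness category.

The SFS is built on a fixed-size subsample of individuals (so populations of
different size are comparable), fixed bins (derived count 0 and 2n) are
removed, and the remaining bin counts are normalized to densities.  Sites
with any missing call within the subsample are excluded and counted.

Deleteriousness categorization schemes map per-site scores to ordered class
labels; the GERP RS scheme uses "neutral" (< 2), "moderate" [2, 4),
"large" [4, 6) and "extreme" (>= 6), with left-closed boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .store import MISSING, GenotypeMatrix

GERP_CATEGORIES = ("neutral", "moderate", "large", "extreme")
GERP_EDGES = (2.0, 4.0, 6.0)

POLYPHEN_CATEGORIES = ("benign", "possibly_damaging", "probably_damaging")


def gerp_category(scores) -> np.ndarray:
    """Map GERP RS scores to class labels (left-closed intervals, NaN -> '')."""
    scores = np.asarray(scores, dtype=float)
    out = np.full(scores.shape, "", dtype=object)
    out[scores < GERP_EDGES[0]] = "neutral"
    out[(scores >= GERP_EDGES[0]) & (scores < GERP_EDGES[1])] = "moderate"
    out[(scores >= GERP_EDGES[1]) & (scores < GERP_EDGES[2])] = "large"
    out[scores >= GERP_EDGES[2]] = "extreme"
    out[np.isnan(scores)] = ""
    return out


@dataclass
class CategoryScheme:
    """A partition of sites into ordered deleteriousness classes.

    ``labels(sites)`` returns one label per site row ('' = unclassifiable,
    excluded from per-category spectra).
    """

    name: str
    categories: tuple
    _fn: callable = field(repr=False)

    def labels(self, sites: pd.DataFrame) -> np.ndarray:
        return self._fn(sites)


def scheme(name: str, cadd_cut: float = 15.0) -> CategoryScheme:
    """Build a categorization scheme: 'gerp', 'polyphen' or 'cadd'.

    polyphen uses the predictor's own labels with 'unknown' left out; cadd
    splits at a configurable phred score (default 15).
    """
    if name == "gerp":
        return CategoryScheme("gerp", GERP_CATEGORIES,
                              lambda s: gerp_category(s["gerp_rs"].to_numpy()))
    if name == "polyphen":
        def _pp(s):
            lab = s["polyphen"].fillna("").astype(str).to_numpy()
            lab = np.where(np.isin(lab, POLYPHEN_CATEGORIES), lab, "")
            return lab.astype(object)
        return CategoryScheme("polyphen", POLYPHEN_CATEGORIES, _pp)
    if name == "cadd":
        def _cadd(s):
            v = s["cadd"].to_numpy(dtype=float)
            out = np.where(v >= cadd_cut, "high", "low").astype(object)
            out[np.isnan(v)] = ""
            return out
        return CategoryScheme("cadd", ("low", "high"), _cadd)
    raise ValueError(f"unknown scheme {name!r}")


@dataclass
class SFS:
    """Normalized unfolded spectrum over derived-allele-count bins 1..2n-1."""

    n_individuals: int
    counts: np.ndarray          # length 2n-1, bin i at index i-1
    n_dropped_missing: int = 0
    n_fixed: int = 0
    category: str | None = None

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())

    @property
    def densities(self) -> np.ndarray:
        tot = self.counts.sum()
        if tot == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / tot

    def density(self, bin_: int) -> float:
        return float(self.densities[bin_ - 1])


def _spectrum_counts(dosage_sub: np.ndarray, n_sub: int):
    """Bin counts 1..2n-1 from a subsample dosage block (samples x sites)."""
    valid = (dosage_sub != MISSING).all(axis=0)
    c = dosage_sub[:, valid].sum(axis=0)
    counts_all = np.bincount(c, minlength=2 * n_sub + 1)
    n_fixed = int(counts_all[0] + counts_all[2 * n_sub])
    return counts_all[1:2 * n_sub], int((~valid).sum()), n_fixed


def build_sfs(gm: GenotypeMatrix, sample_idx, n_sub: int = 8, seed=None,
              site_mask=None, category: str | None = None,
              replace: bool = False) -> SFS:
    """Unfolded SFS on a random subsample of ``n_sub`` individuals.

    The subsample is drawn uniformly without replacement (with replacement if
    ``replace``); sites missing in any subsampled individual are dropped and
    counted; fixed bins (0, 2n) are removed.
    """
    if not gm.polarized:
        raise ValueError("SFS needs a polarized matrix")
    sample_idx = np.asarray(sample_idx)
    if not replace and len(sample_idx) < n_sub:
        raise ValueError(
            f"population has {len(sample_idx)} individuals < n_sub={n_sub}; "
            "reduce n_sub")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(sample_idx, size=n_sub, replace=replace)
    d = gm.dosage[chosen]
    if site_mask is not None:
        d = d[:, np.asarray(site_mask)]
    counts, n_miss, n_fixed = _spectrum_counts(d, n_sub)
    return SFS(n_individuals=n_sub, counts=counts, n_dropped_missing=n_miss,
               n_fixed=n_fixed, category=category)


def sfs_by_category(gm: GenotypeMatrix, sample_idx, sites: pd.DataFrame,
                    scheme: CategoryScheme, n_sub: int = 8, seed=None,
                    site_mask=None) -> dict[str, SFS]:
    """One SFS per deleteriousness category, sharing a single subsample draw."""
    sample_idx = np.asarray(sample_idx)
    if len(sample_idx) < n_sub:
        raise ValueError(f"population smaller than n_sub={n_sub}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(sample_idx, size=n_sub, replace=False)
    labels = scheme.labels(sites)
    base = np.ones(len(sites), dtype=bool) if site_mask is None else np.asarray(site_mask)
    out = {}
    for cat in scheme.categories:
        mask = base & (labels == cat)
        d = gm.dosage[chosen][:, mask]
        counts, n_miss, n_fixed = _spectrum_counts(d, n_sub)
        out[cat] = SFS(n_individuals=n_sub, counts=counts,
                       n_dropped_missing=n_miss, n_fixed=n_fixed, category=cat)
    return out


@dataclass
class DensityDifferenceResult:
    """Replicate summary of per-bin SFS density differences (popB - popA)."""

    per_bin: pd.DataFrame       # category, bin, mean_diff, sd_diff
    sequential: pd.DataFrame    # pair, z_signed, p_signed, z_abs, p_abs
    n_reps: int


def density_difference_test(gm: GenotypeMatrix, idx_a, idx_b,
                            sites: pd.DataFrame, scheme: CategoryScheme,
                            n_sub: int = 18, n_bins: int = 10,
                            n_reps: int = 1000, seed=None,
                            site_mask=None) -> DensityDifferenceResult:
    """Bootstrap the SFS over individuals and compare density differences
    across sequential deleteriousness categories.

    Each replicate resamples ``n_sub`` individuals per population with
    replacement, builds the per-category SFS, and records the density
    difference (popB - popA) in the first ``n_bins`` bins.  Sequential
    categories are compared by a z-test whose standard errors are the
    bootstrap standard deviations of the per-category mean difference —
    replicates estimate the sampling distribution, so their SD (not SD/sqrt
    of replicate count) is the standard error.  Both signed differences and
    their magnitudes are tested; the signed test is the calibrated default.
    """
    if n_bins > 2 * n_sub - 1:
        raise ValueError(f"n_bins={n_bins} exceeds 2*n_sub-1={2 * n_sub - 1}")
    idx_a, idx_b = np.asarray(idx_a), np.asarray(idx_b)
    rng = np.random.default_rng(seed)
    labels = scheme.labels(sites)
    base = np.ones(len(sites), dtype=bool) if site_mask is None else np.asarray(site_mask)
    cat_cols = {cat: np.where(base & (labels == cat))[0] for cat in scheme.categories}

    diffs = {cat: np.full((n_reps, n_bins), np.nan) for cat in scheme.categories}
    for r in range(n_reps):
        rows_a = rng.choice(idx_a, size=n_sub, replace=True)
        rows_b = rng.choice(idx_b, size=n_sub, replace=True)
        for cat, cols in cat_cols.items():
            if cols.size == 0:
                continue
            ca, _, _ = _spectrum_counts(gm.dosage[np.ix_(rows_a, cols)], n_sub)
            cb, _, _ = _spectrum_counts(gm.dosage[np.ix_(rows_b, cols)], n_sub)
            if ca.sum() == 0 or cb.sum() == 0:
                continue
            da = ca / ca.sum()
            db = cb / cb.sum()
            diffs[cat][r] = (db - da)[:n_bins]

    rows = []
    for cat in scheme.categories:
        m = np.nanmean(diffs[cat], axis=0)
        s = np.nanstd(diffs[cat], axis=0)
        for b in range(n_bins):
            rows.append({"category": cat, "bin": b + 1,
                         "mean_diff": m[b], "sd_diff": s[b]})
    per_bin = pd.DataFrame(rows)

    # per-replicate scalar aggregates over the first n_bins bins
    agg_signed = {c: np.nanmean(diffs[c], axis=1) for c in scheme.categories}
    agg_abs = {c: np.nanmean(np.abs(diffs[c]), axis=1) for c in scheme.categories}
    seq_rows = []
    for lo, hi in zip(scheme.categories[:-1], scheme.categories[1:]):
        row = {"pair": f"{lo}->{hi}"}
        for kind, agg in (("signed", agg_signed), ("abs", agg_abs)):
            x, y = agg[lo], agg[hi]
            mx, my = np.nanmean(x), np.nanmean(y)
            sx, sy = np.nanstd(x), np.nanstd(y)
            denom = np.sqrt(sx**2 + sy**2)
            z = (my - mx) / denom if denom > 0 else np.nan
            row[f"z_{kind}"] = z
            row[f"p_{kind}"] = float(2 * sstats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
        seq_rows.append(row)
    return DensityDifferenceResult(per_bin=per_bin,
                                   sequential=pd.DataFrame(seq_rows),
                                   n_reps=n_reps)


def low_vs_common_proportions(gm: GenotypeMatrix, sample_idx,
                              sites: pd.DataFrame, deleterious_mask=None,
                              n_sub: int = 18, seed=None) -> dict:
    """Proportions of deleterious variants at low (1-2 copies) vs common
    (>= 3 copies) derived counts in a subsample, with Wald 95% CIs.

    ``deleterious_mask`` defaults to GERP RS >= 2.  Counts are taken on the
    thinned (subsampled) spectrum; fixed and monomorphic-in-subsample sites
    do not contribute.
    """
    if deleterious_mask is None:
        deleterious_mask = sites["gerp_rs"].to_numpy(dtype=float) >= 2.0
    s = build_sfs(gm, sample_idx, n_sub=n_sub, seed=seed,
                  site_mask=np.asarray(deleterious_mask))
    counts = s.counts
    n_low = int(counts[:2].sum())        # singletons + doubletons
    n_com = int(counts[2:].sum())
    m = n_low + n_com
    if m == 0:
        return {"n_low": 0, "n_common": 0, "p_low": float("nan"),
                "p_common": float("nan"), "ci_low": (float("nan"),) * 2,
                "ci_common": (float("nan"),) * 2}
    out = {"n_low": n_low, "n_common": n_com}
    for name, k in (("low", n_low), ("common", n_com)):
        p = k / m
        half = 1.96 * np.sqrt(p * (1 - p) / m)
        out[f"p_{name}"] = p
        out[f"ci_{name}"] = (max(0.0, p - half), min(1.0, p + half))
    return out
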