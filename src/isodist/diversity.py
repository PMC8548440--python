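"""SFS-based diversity indexes per population.

Implements pairwise nucleotide diversity θπ (unbiased per-site
heterozygosity summed over sites), Watterson's θw, per-variable-site
diversity πvar, Tajima's D with the standard 1989 variance constants, and
segregating-site summaries, all on the derived-allele dosage matrix.
Missing genotypes are handled per site: the haplotype count 2n at a site is
twice the number of non-missing diploids there.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bootstrap import BootstrapResult, block_bootstrap
from .store import MISSING, GenotypeMatrix, population_indices


def _counts(gm: GenotypeMatrix, sample_idx, site_mask=None):
    """Per-site derived-allele count c and haplotype count 2n over samples."""
    d = gm.dosage[np.asarray(sample_idx)]
    if site_mask is not None:
        d = d[:, np.asarray(site_mask)]
    valid = d != MISSING
    two_n = 2 * valid.sum(axis=0)
    c = np.where(valid, d, 0).sum(axis=0)
    return c.astype(np.int64), two_n.astype(np.int64)


def per_site_pi(gm: GenotypeMatrix, sample_idx, site_mask=None) -> np.ndarray:
    """Unbiased per-site heterozygosity 2 c (2n - c) / (2n (2n - 1)).

    Sites with fewer than two non-missing haplotypes yield NaN (skipped by
    the summing statistics and counted by callers).
    """
    if not gm.polarized:
        raise ValueError("diversity statistics need a polarized matrix")
    c, two_n = _counts(gm, sample_idx, site_mask)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * c * (two_n - c) / (two_n * (two_n - 1.0))
    pi[two_n < 2] = np.nan
    return pi


def theta_pi(gm: GenotypeMatrix, sample_idx, site_mask=None) -> float:
    """Sum of per-site π over the masked sites (pairwise nucleotide diversity)."""
    return float(np.nansum(per_site_pi(gm, sample_idx, site_mask)))


def harmonic(k: int) -> float:
    return float(np.sum(1.0 / np.arange(1, k + 1))) if k >= 1 else 0.0


def segregating(gm: GenotypeMatrix, sample_idx, site_mask=None) -> np.ndarray:
    """Boolean per-site indicator: 0 < c < 2n within the sample set."""
    c, two_n = _counts(gm, sample_idx, site_mask)
    return (c > 0) & (c < two_n)


def watterson_theta(gm: GenotypeMatrix, sample_idx, site_mask=None,
                    per_site_a: bool = False) -> float:
    """Watterson's estimator S / a with a = sum_{i=1}^{2n-1} 1/i.

    By default a single a from the population's full diploid count is used
    even where some sites have missing calls; ``per_site_a=True`` instead
    accumulates 1/a(2n_site) per segregating site.
    """
    if not gm.polarized:
        raise ValueError("diversity statistics need a polarized matrix")
    n_dip = len(np.asarray(sample_idx))
    if n_dip < 2:
        raise ValueError("Watterson's estimator needs at least 2 diploids")
    c, two_n = _counts(gm, sample_idx, site_mask)
    seg = (c > 0) & (c < two_n)
    if per_site_a:
        a_site = np.array([harmonic(int(t) - 1) if t >= 2 else np.nan for t in two_n])
        return float(np.nansum(np.where(seg, 1.0 / a_site, 0.0)))
    return float(seg.sum() / harmonic(2 * n_dip - 1))


def pi_var(gm: GenotypeMatrix, sample_idx, site_mask=None) -> float:
    """θπ restricted to sites variable in the population, per variable site.

    Returns NaN when the population has no variable site in the mask.
    """
    pi = per_site_pi(gm, sample_idx, site_mask)
    var = np.nan_to_num(pi) > 0
    if var.sum() == 0:
        return float("nan")
    return float(np.nansum(pi[var]) / var.sum())


def tajima_constants(n_hap: int) -> dict:
    """Tajima (1989) variance constants for haplotype count n_hap."""
    n = n_hap
    a1 = harmonic(n - 1)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def tajimas_d(gm: GenotypeMatrix, sample_idx, site_mask=None) -> float:
    """(θπ - θw) / sqrt(e1 S + e2 S (S-1)); NaN when S = 0."""
    sample_idx = np.asarray(sample_idx)
    tp = theta_pi(gm, sample_idx, site_mask)
    s = int(segregating(gm, sample_idx, site_mask).sum())
    if s == 0:
        return float("nan")
    n_hap = 2 * len(sample_idx)
    const = tajima_constants(n_hap)
    tw = s / const["a1"]
    var = const["e1"] * s + const["e2"] * s * (s - 1)
    return float((tp - tw) / np.sqrt(var))


def segregating_site_summaries(gm: GenotypeMatrix, panel: pd.Series,
                               site_mask=None) -> pd.DataFrame:
    """Per population: S, private S, and mean segregating sites carried per individual.

    A site is private to a population when it segregates there and carries
    zero derived alleles in every other population.  "Carried" counts, for
    each individual, the population-segregating sites where that individual
    has dosage >= 1.
    """
    pops = sorted(set(panel.get(s) for s in gm.sample_ids) - {None})
    seg_by_pop, c_by_pop = {}, {}
    for pop in pops:
        rows = population_indices(gm, panel, pop)
        c, two_n = _counts(gm, rows, site_mask)
        seg_by_pop[pop] = (c > 0) & (c < two_n)
        c_by_pop[pop] = c
    out = []
    for pop in pops:
        rows = population_indices(gm, panel, pop)
        seg = seg_by_pop[pop]
        others_zero = np.ones_like(seg)
        for other in pops:
            if other != pop:
                others_zero &= c_by_pop[other] == 0
        d = gm.dosage[rows]
        if site_mask is not None:
            d = d[:, np.asarray(site_mask)]
        carried = ((d[:, seg] >= 1) & (d[:, seg] != MISSING)).sum(axis=1)
        out.append({"population": pop, "s_seg": int(seg.sum()),
                    "private_s": int((seg & others_zero).sum()),
                    "mean_carried": float(carried.mean())})
    return pd.DataFrame(out)


def diversity_with_ci(gm: GenotypeMatrix, panel: pd.Series, population: str,
                      site_mask=None, n_blocks: int = 1000, n_reps: int = 1000,
                      seed=None) -> dict[str, BootstrapResult]:
    """θπ, θw, πvar and Tajima's D for one population with block-bootstrap CIs.

    The bootstrap resamples contiguous site blocks within the mask; all four
    statistics are recomputed per replicate on the resampled site multiset.
    """
    rows = population_indices(gm, panel, population)
    if site_mask is None:
        site_idx = np.arange(gm.n_sites)
    else:
        site_idx = np.where(np.asarray(site_mask))[0]
    n = len(site_idx)
    # precompute per-site quantities once; replicate statistics index into them
    c, two_n = _counts(gm, rows, site_idx)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi_site = 2.0 * c * (two_n - c) / (two_n * (two_n - 1.0))
    pi_site[two_n < 2] = np.nan
    seg = (c > 0) & (c < two_n)
    n_hap = 2 * len(rows)
    a1 = harmonic(n_hap - 1)
    const = tajima_constants(n_hap) if n_hap >= 4 else None

    def _theta_pi(idx):
        return np.nansum(pi_site[idx])

    def _theta_w(idx):
        return seg[idx].sum() / a1

    def _pi_var(idx):
        p = pi_site[idx]
        var = np.nan_to_num(p) > 0
        return np.nansum(p[var]) / var.sum() if var.sum() else np.nan

    def _tajimas_d(idx):
        s = int(seg[idx].sum())
        if s == 0 or const is None:
            return np.nan
        variance = const["e1"] * s + const["e2"] * s * (s - 1)
        return (np.nansum(pi_site[idx]) - s / a1) / np.sqrt(variance)

    stats = {"theta_pi": _theta_pi, "theta_w": _theta_w,
             "pi_var": _pi_var, "tajimas_d": _tajimas_d}
    results = {}
    # one seed per statistic, derived deterministically
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    for (name, fn), child in zip(stats.items(), ss.spawn(len(stats))):
        results[name] = block_bootstrap(fn, n, n_blocks=n_blocks, n_reps=n_reps,
                                        seed=child)
    return results
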