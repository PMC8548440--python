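"""Independent brute-force / literal-formula oracles used by the tests.

Everything here is written directly from the defining formulas, separately
from the package implementation, so agreement is an actual cross-check.
"""

import itertools
import math

import numpy as np

from isodist.store import MISSING


def theta_pi_bruteforce(dosage: np.ndarray) -> float:
    """Average pairwise difference over all allele-copy pairs, summed over
    sites; sites with any missing call are skipped (no-missing subset)."""
    n_samples, n_sites = dosage.shape
    total = 0.0
    for j in range(n_sites):
        col = dosage[:, j]
        if (col == MISSING).any():
            continue
        copies = []
        for d in col:
            copies += [1] * int(d) + [0] * (2 - int(d))
        diffs = sum(a != b for a, b in itertools.combinations(copies, 2))
        npairs = math.comb(len(copies), 2)
        total += diffs / npairs
    return total


def tajimas_d_literal(theta_pi: float, s_seg: int, n_hap: int) -> float:
    """Literal transcription of Tajima's (1989) D with its constants."""
    n = n_hap
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    theta_w = s_seg / a1
    return (theta_pi - theta_w) / math.sqrt(e1 * s_seg + e2 * s_seg * (s_seg - 1))


def wc_fst_literal(geno_a, geno_b):
    """Weir & Cockerham (1984) per-site theta-hat for two samples of diploid
    genotypes (lists of dosages, no missing), typed out from the published
    component equations.  Returns (a, b, c)."""
    r = 2
    n_i = [len(geno_a), len(geno_b)]
    p_i = [sum(g) / (2 * len(g)) for g in (geno_a, geno_b)]
    h_i = [sum(1 for x in g if x == 1) / len(g) for g in (geno_a, geno_b)]
    n_bar = sum(n_i) / r
    n_c = (r * n_bar - sum(n**2 for n in n_i) / (r * n_bar)) / (r - 1)
    p_bar = sum(n * p for n, p in zip(n_i, p_i)) / (r * n_bar)
    s_sq = sum(n * (p - p_bar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * n_bar)
    h_bar = sum(n * h for n, h in zip(n_i, h_i)) / (r * n_bar)
    a = (n_bar / n_c) * (s_sq - (1.0 / (n_bar - 1))
                         * (p_bar * (1 - p_bar) - ((r - 1.0) / r) * s_sq
                            - h_bar / 4.0))
    b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar)
                                 - ((r - 1.0) / r) * s_sq
                                 - ((2 * n_bar - 1) / (4.0 * n_bar)) * h_bar)
    c = h_bar / 2.0
    return a, b, c


def hwe_exact_p_direct(n_het, n_hom_1, n_hom_2):
    """Exact HWE p by direct evaluation of the conditional probabilities
    with factorials (no recurrence)."""
    n = n_het + n_hom_1 + n_hom_2
    n_rare = 2 * min(n_hom_1, n_hom_2) + n_het

    def weight(h):
        # integer multinomial weight: ways to realize h hets given allele counts
        hom_r = (n_rare - h) // 2
        return math.comb(n, h) * math.comb(n - h, hom_r) * 2**h

    hets = range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    p_obs = weights[n_het] / total
    return min(1.0, sum(w for w in weights.values()
                        if w / total <= p_obs * (1 + 1e-12)) / total)


def roh_scan_bruteforce(hom, pos, min_snps, min_length, max_gap):
    """Naive expanding scanner for maximal homozygous runs.

    hom: boolean array (non-missing homozygous), pos: sorted positions on one
    chromosome.  Returns list of (start_idx, end_idx) inclusive.
    """
    n = len(hom)
    runs = []
    i = 0
    while i < n:
        if not hom[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and hom[j + 1] and (pos[j + 1] - pos[j]) <= max_gap:
            j += 1
        n_snps = j - i + 1
        span = pos[j] - pos[i] + 1
        if n_snps >= min_snps and span >= min_length:
            runs.append((i, j))
        i = j + 1
    return runs


def ld_prune_bruteforce(dosage, r2_threshold):
    """Greedy all-pairs pruning (keep the earlier site of a correlated pair)."""
    n_sites = dosage.shape[1]
    keep = [True] * n_sites
    for i in range(n_sites):
        if not keep[i]:
            continue
        for j in range(i + 1, n_sites):
            if not keep[j]:
                continue
            x, y = dosage[:, i].astype(float), dosage[:, j].astype(float)
            ok = (dosage[:, i] != MISSING) & (dosage[:, j] != MISSING)
            if ok.sum() < 2 or x[ok].std() == 0 or y[ok].std() == 0:
                continue
            r = np.corrcoef(x[ok], y[ok])[0, 1]
            if r * r > r2_threshold:
                keep[j] = False
    return np.array(keep)


def hypergeom_p_direct(obs, m_universe, k_set, n_query):
    """Upper-tail hypergeometric p by direct summation with binomials."""
    denom = math.comb(m_universe, n_query)
    p = 0.0
    for x in range(obs, min(k_set, n_query) + 1):
        p += math.comb(k_set, x) * math.comb(m_universe - k_set, n_query - x) / denom
    return p
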