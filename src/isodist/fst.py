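"""Per-site Weir & Cockerham Fst, candidate subsets and gene-set enrichment.

Per-site Fst between two populations uses the Weir & Cockerham (1984)
variance components a (among populations), b (among individuals within
populations) and c (within individuals), computed from genotype counts
including the observed-heterozygosity term; Fst = a / (a + b + c), undefined
(NaN, never zero) where the denominator vanishes.  Candidate subsets follow
a fixed filter cascade (missense -> deleteriousness category -> top-5% Fst
within the subset -> higher derived frequency in the target population) and
are mapped to genes for over-representation (hypergeometric + BH FDR) or
bootstrap-null (Q95) enrichment against local gene-set catalogs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .store import MISSING, GenotypeMatrix, derived_freq, population_indices


def wc_components(gm: GenotypeMatrix, idx_a, idx_b, site_mask=None):
    """Weir & Cockerham (1984) two-population variance components per site.

    Returns (a, b, c) arrays; all three are NaN where either population has
    fewer than 2 non-missing diploids.
    """
    idx_a, idx_b = np.asarray(idx_a), np.asarray(idx_b)
    if np.intersect1d(idx_a, idx_b).size:
        raise ValueError("populations share samples")
    cols = slice(None) if site_mask is None else np.asarray(site_mask)
    out = []
    for idx in (idx_a, idx_b):
        d = gm.dosage[idx][:, cols] if site_mask is not None else gm.dosage[idx]
        valid = d != MISSING
        n = valid.sum(axis=0).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(valid, d, 0).sum(axis=0) / (2.0 * n)
            h = (d == 1).sum(axis=0) / n
        out.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = out

    with np.errstate(divide="ignore", invalid="ignore"):
        n_bar = (n1 + n2) / 2.0
        n_c = 2.0 * n_bar - (n1**2 + n2**2) / (2.0 * n_bar)
        p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / n_bar
        h_bar = (n1 * h1 + n2 * h2) / (n1 + n2)
        a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar) - s2 / 2.0 - h_bar / 4.0)
                             / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * (p_bar * (1 - p_bar) - s2 / 2.0
                                       - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar)
        c = h_bar / 2.0
    bad = (n1 < 2) | (n2 < 2)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def per_site_fst(gm: GenotypeMatrix, panel: pd.Series, pop_a: str, pop_b: str,
                 site_mask=None) -> pd.DataFrame:
    """Per-site Fst records (a, b, c, fst); fst is NaN where a+b+c == 0."""
    idx_a = population_indices(gm, panel, pop_a)
    idx_b = population_indices(gm, panel, pop_b)
    a, b, c = wc_components(gm, idx_a, idx_b, site_mask)
    denom = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(denom != 0, a / denom, np.nan)
    return pd.DataFrame({"a": a, "b": b, "c": c, "fst": fst})


def mean_pairwise_fst(gm: GenotypeMatrix, panel: pd.Series, pop_a: str,
                      pop_b: str, site_mask=None, n_per_pop: int | None = None,
                      seed=None) -> float:
    """Ratio-of-sums Fst  (sum a) / (sum a+b+c)  over defined sites,
    optionally thinning each population to ``n_per_pop`` random individuals."""
    idx_a = population_indices(gm, panel, pop_a)
    idx_b = population_indices(gm, panel, pop_b)
    if n_per_pop is not None:
        rng = np.random.default_rng(seed)
        idx_a = rng.choice(idx_a, size=n_per_pop, replace=False)
        idx_b = rng.choice(idx_b, size=n_per_pop, replace=False)
    a, b, c = wc_components(gm, idx_a, idx_b, site_mask)
    denom = a + b + c
    ok = np.isfinite(denom) & (denom != 0)
    if ok.sum() == 0:
        return float("nan")
    return float(a[ok].sum() / denom[ok].sum())


# ---------------------------------------------------------------------------
# candidate subsets
# ---------------------------------------------------------------------------

@dataclass
class CandidateSubset:
    name: str
    site_idx: np.ndarray
    genes: list[str]
    fst_threshold: float


#: base subsets: (name, column, predicate over the site table)
_BASE_SUBSETS = [
    ("moderate", "gerp"),
    ("large", "gerp"),
    ("extreme", "gerp"),
    ("polyphen_possibly", "polyphen"),
    ("polyphen_probably", "polyphen"),
]


def build_candidate_subsets(sites: pd.DataFrame, fst: np.ndarray,
                            gm: GenotypeMatrix, panel: pd.Series,
                            target_pop: str, other_pop: str,
                            top_fraction: float = 0.05) -> dict[str, CandidateSubset]:
    """Apply the candidate filter cascade and map survivors to genes.

    Cascade per subset: missense sites -> the subset's deleteriousness
    category -> Fst at or above the subset's own (1 - top_fraction) quantile
    (NaN Fst excluded before the quantile; ties kept inclusively) -> strictly
    higher derived frequency in ``target_pop`` than in ``other_pop``.  The
    'all_categories' subset merges the five post-category site sets and takes
    its own top fraction.
    """
    from .sfs import gerp_category

    fst = np.asarray(fst, dtype=float)
    labels = gerp_category(sites["gerp_rs"].to_numpy(dtype=float))
    cons = sites["consequence"].fillna("").to_numpy()
    pp = sites["polyphen"].fillna("").astype(str).to_numpy() \
        if "polyphen" in sites.columns else np.full(len(sites), "")
    missense = cons == "missense"

    q_target = derived_freq(gm, population_indices(gm, panel, target_pop))
    q_other = derived_freq(gm, population_indices(gm, panel, other_pop))
    higher_in_target = q_target > q_other

    cat_masks = {
        "moderate": missense & (labels == "moderate"),
        "large": missense & (labels == "large"),
        "extreme": missense & (labels == "extreme"),
        "polyphen_possibly": missense & (pp == "possibly_damaging"),
        "polyphen_probably": missense & (pp == "probably_damaging"),
    }
    merged = np.zeros(len(sites), dtype=bool)
    for m in cat_masks.values():
        merged |= m
    cat_masks["all_categories"] = merged

    genes_col = sites["gene"].fillna("").astype(str).to_numpy()
    out = {}
    for name, mask in cat_masks.items():
        idx = np.where(mask & np.isfinite(fst))[0]
        if idx.size == 0:
            out[name] = CandidateSubset(name, np.array([], dtype=int), [],
                                        float("nan"))
            continue
        thr = float(np.quantile(fst[idx], 1.0 - top_fraction))
        idx = idx[fst[idx] >= thr]
        idx = idx[higher_in_target[idx]]
        genes = sorted(set(genes_col[idx]) - {""})
        out[name] = CandidateSubset(name, idx, genes, thr)
    return out


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def read_catalog(path) -> dict[str, list[str]]:
    """Catalog TSV (set_name, gene) -> mapping set_name -> unique gene list."""
    df = pd.read_csv(path, sep="\t", header=None, names=["set_name", "gene"],
                     dtype=str, comment="#")
    return {k: sorted(set(v)) for k, v in df.groupby("set_name")["gene"]}


def ora(genes, universe, catalog: dict) -> pd.DataFrame:
    """Hypergeometric over-representation analysis with BH FDR and tiers.

    Per set: observed = |query ∩ set ∩ universe|, expected = |set ∩ universe|
    * |query| / |universe|, p = upper-tail hypergeometric.  Significance
    tiers follow a cascade: tier 1 FDR < 0.05; tier 2 p < 0.05 with an
    enrichment ratio above the mean ratio of tested sets; tier 3 remaining
    p < 0.05.  Sets with no universe overlap are skipped and counted in the
    attrs of the returned frame.
    """
    genes = set(genes)
    universe = set(universe)
    if not genes <= universe:
        raise ValueError("query genes must be a subset of the universe")
    m_tot = len(universe)
    n_query = len(genes)
    rows, skipped = [], 0
    for name, members in catalog.items():
        in_universe = set(members) & universe
        k_set = len(in_universe)
        if k_set == 0:
            skipped += 1
            continue
        obs = len(genes & in_universe)
        expected = k_set * n_query / m_tot
        p = float(sstats.hypergeom.sf(obs - 1, m_tot, k_set, n_query))
        rows.append({"set_name": name, "n_set": k_set, "observed": obs,
                     "expected": expected,
                     "enrichment_ratio": obs / expected if expected > 0 else np.nan,
                     "p": p})
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = sstats.false_discovery_control(table["p"], method="bh")
        mean_ratio = table["enrichment_ratio"].mean()
        tier = np.zeros(len(table), dtype=int)
        tier[(table["p"] < 0.05)] = 3
        tier[(table["p"] < 0.05) & (table["enrichment_ratio"] > mean_ratio)] = 2
        tier[table["fdr"] < 0.05] = 1
        table["tier"] = tier
        table = table.sort_values(["tier", "p"],
                                  key=lambda s: s.replace(0, 99) if s.name == "tier" else s
                                  ).reset_index(drop=True)
    table.attrs["skipped_sets"] = skipped
    return table


def catalog_bootstrap_enrichment(genes, trait_catalog: dict, source_genes,
                                 n_reps: int = 1000, seed=None) -> pd.DataFrame:
    """Bootstrap-null (Q95) enrichment against a trait catalog.

    Observed per-trait counts come from the query; each replicate draws
    |genes| genes uniformly without replacement from ``source_genes`` and
    recounts.  A trait is flagged when its observed count is at or above the
    95th percentile of its replicate counts.
    """
    genes = sorted(set(genes))
    source = sorted(set(source_genes))
    if len(genes) > len(source):
        raise ValueError("query larger than the resampling source")
    rng = np.random.default_rng(seed)
    traits = sorted(trait_catalog)
    src_index = {g: i for i, g in enumerate(source)}
    member = np.zeros((len(traits), len(source)), dtype=bool)
    for t_i, t in enumerate(traits):
        for g in trait_catalog[t]:
            j = src_index.get(g)
            if j is not None:
                member[t_i, j] = True
    observed = np.array([len(set(trait_catalog[t]) & set(genes)) for t in traits])
    counts = np.empty((n_reps, len(traits)), dtype=np.int32)
    for r in range(n_reps):
        draw = rng.choice(len(source), size=len(genes), replace=False)
        counts[r] = member[:, draw].sum(axis=1)
    q95 = np.quantile(counts, 0.95, axis=0, method="higher")
    # a zero observed count is never evidence of enrichment, even when the
    # null distribution is itself almost all zeros (Q95 = 0)
    return pd.DataFrame({"trait": traits, "observed": observed,
                         "q95": q95.astype(int),
                         "flagged": (observed >= q95) & (observed > 0)})


# ---------------------------------------------------------------------------
# Fst peaks and LD
# ---------------------------------------------------------------------------

def fst_peaks(sites: pd.DataFrame, fst: np.ndarray, top_fraction: float = 0.01,
              max_pair_distance: int = 10_000) -> pd.DataFrame:
    """Single-linkage clusters of top-Fst sites.

    A peak is a maximal same-chromosome cluster of >= 2 sites in the top
    ``top_fraction`` of the (defined) Fst distribution, each member within
    ``max_pair_distance`` bp of at least one other member.
    """
    fst = np.asarray(fst, dtype=float)
    defined = np.isfinite(fst)
    if defined.sum() == 0:
        return pd.DataFrame(columns=["peak_id", "chrom", "start", "end",
                                     "n_sites", "site_idx"])
    thr = float(np.quantile(fst[defined], 1.0 - top_fraction))
    top = np.where(defined & (fst >= thr))[0]
    pos = sites["pos"].to_numpy()
    chrom = sites["chrom"].to_numpy()
    peaks = []
    for ch in pd.unique(chrom[top]):
        members = top[chrom[top] == ch]
        members = members[np.argsort(pos[members])]
        cluster = [members[0]]
        for j in members[1:]:
            if pos[j] - pos[cluster[-1]] < max_pair_distance:
                cluster.append(j)
            else:
                if len(cluster) >= 2:
                    peaks.append((ch, cluster))
                cluster = [j]
        if len(cluster) >= 2:
            peaks.append((ch, cluster))
    rows = []
    for k, (ch, cluster) in enumerate(peaks):
        rows.append({"peak_id": k, "chrom": ch,
                     "start": int(pos[cluster[0]]), "end": int(pos[cluster[-1]]),
                     "n_sites": len(cluster),
                     "site_idx": np.array(cluster, dtype=int)})
    return pd.DataFrame(rows)


def ld_r2(gm: GenotypeMatrix, site_pairs, sample_idx=None) -> np.ndarray:
    """Squared dosage correlation for each (i, j) site pair, optionally
    restricted to one population's samples; NaN for zero-variance sites."""
    from .roh import dosage_r2

    d = gm.dosage if sample_idx is None else gm.dosage[np.asarray(sample_idx)]
    return np.array([dosage_r2(d[:, i], d[:, j]) for i, j in site_pairs])
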