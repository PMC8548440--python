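"""Mutational-load summary statistics and GERP-category selection load.

Two per-individual burdens approximate the load under different dominance
models: N_alleles (total derived alleles; additive) and N_hom (homozygous
derived genotypes; recessive).  Population contrasts are ratios of the
per-individual means, with block-bootstrap intervals and a two-sided
bootstrap p-value against 1.  The selection-coefficient load translates GERP
categories into s values and evaluates, per site,

    load = 1 - w = 2 q (1 - q) s h + s q^2

with q the population derived-allele frequency, h = 0.5 (additive) or 0
(recessive), summed within categories.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bootstrap import BootstrapResult, block_bootstrap
from .store import MISSING, GenotypeMatrix, derived_freq, population_indices
from .sfs import CategoryScheme

#: per-category selection coefficients for the GERP classes
DEFAULT_SELECTION_COEFFS = {"moderate": 4.5e-4, "large": 4.5e-3, "extreme": 1e-2}


def per_individual_burden(gm: GenotypeMatrix, site_mask=None) -> pd.DataFrame:
    """N_alleles and N_hom per sample over the masked sites.

    Missing genotypes contribute 0 and are counted in the n_missing column.
    """
    if not gm.polarized:
        raise ValueError("burdens need a polarized matrix")
    d = gm.dosage
    if site_mask is not None:
        d = d[:, np.asarray(site_mask)]
    if d.shape[1] == 0:
        raise ValueError("empty site mask")
    valid = d != MISSING
    return pd.DataFrame({
        "sample_id": gm.sample_ids,
        "n_alleles": np.where(valid, d, 0).sum(axis=1),
        "n_hom": (d == 2).sum(axis=1),
        "n_missing": (~valid).sum(axis=1),
    })


def category_mask(sites: pd.DataFrame, scheme: CategoryScheme, category: str,
                  consequence_filter: bool = False) -> np.ndarray:
    """Site mask for one deleteriousness category, optionally intersected
    with consequence labels (missense for deleterious classes, synonymous
    for the neutral class)."""
    mask = scheme.labels(sites) == category
    if consequence_filter:
        cons = sites["consequence"].fillna("").to_numpy()
        want = "synonymous" if category == scheme.categories[0] else "missense"
        mask = mask & (cons == want)
    return mask


def load_ratio(gm: GenotypeMatrix, panel: pd.Series, pop_a: str, pop_b: str,
               site_mask=None, model: str = "additive", n_blocks: int = 1000,
               n_reps: int = 1000, seed=None) -> BootstrapResult:
    """Ratio mean_A(N) / mean_B(N) of per-individual burdens with block bootstrap.

    ``model`` selects the burden: 'additive' sums dosages (N_alleles),
    'recessive' counts dosage-2 genotypes (N_hom).  The bootstrap resamples
    site blocks; p is two-sided against a ratio of 1.
    """
    if model not in ("additive", "recessive"):
        raise ValueError("model must be 'additive' or 'recessive'")
    rows_a = population_indices(gm, panel, pop_a)
    rows_b = population_indices(gm, panel, pop_b)
    d = gm.dosage
    if site_mask is not None:
        d = d[:, np.asarray(site_mask)]
    if d.shape[1] == 0:
        raise ValueError("no sites in category mask")
    if model == "additive":
        contrib = np.where(d != MISSING, d, 0)
    else:
        contrib = (d == 2).astype(np.int64)
    # per-site mean contribution per population; the ratio of site-sums is the
    # ratio of per-individual mean burdens
    col_a = contrib[rows_a].mean(axis=0)
    col_b = contrib[rows_b].mean(axis=0)

    def stat(idx):
        denom = col_b[idx].sum()
        if denom == 0:
            return np.nan
        return col_a[idx].sum() / denom

    return block_bootstrap(stat, d.shape[1], n_blocks=n_blocks, n_reps=n_reps,
                           seed=seed, null_value=1.0)


def per_site_selection_load(q, s: float, h: float) -> np.ndarray:
    """1 - w = 2 q (1-q) s h + s q^2, elementwise over frequencies q."""
    q = np.asarray(q, dtype=float)
    return 2.0 * q * (1.0 - q) * s * h + s * q**2


def gerp_score_load(gm: GenotypeMatrix, panel: pd.Series, population: str,
                    sites: pd.DataFrame, scheme: CategoryScheme,
                    coeffs: dict | None = None, model: str = "additive") -> dict:
    """Selection-coefficient load per GERP category for one population.

    Per-site loads use the population's own derived frequency and the
    category's s; h is 0.5 (additive) or 0 (recessive).  The neutral category
    has no defined s and is excluded.  Sites lacking a score are excluded and
    counted.  Returns {'per_category': {...}, 'total': float, 'n_unscored': int}.
    """
    coeffs = DEFAULT_SELECTION_COEFFS if coeffs is None else coeffs
    h = {"additive": 0.5, "recessive": 0.0}[model]
    rows = population_indices(gm, panel, population)
    q = derived_freq(gm, rows)
    labels = scheme.labels(sites)
    per_cat = {}
    for cat, s in coeffs.items():
        mask = (labels == cat) & np.isfinite(q)
        per_cat[cat] = float(per_site_selection_load(q[mask], s, h).sum())
    return {"per_category": per_cat,
            "total": float(sum(per_cat.values())),
            "n_unscored": int((labels == "").sum())}


def load_ratio_table(gm: GenotypeMatrix, panel: pd.Series, pop_a: str,
                     pop_b: str, sites: pd.DataFrame, scheme: CategoryScheme,
                     models=("additive", "recessive"),
                     consequence_filter: bool = False, n_blocks: int = 1000,
                     n_reps: int = 1000, seed=None,
                     alpha: float = 0.001) -> pd.DataFrame:
    """Burden ratios pop_a/pop_b for every category x model combination."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(scheme.categories) * len(models)))
    out = []
    for cat in scheme.categories:
        mask = category_mask(sites, scheme, cat, consequence_filter)
        for model in models:
            child = next(children)
            if mask.sum() == 0:
                out.append({"pop_a": pop_a, "pop_b": pop_b, "category": cat,
                            "model": model, "n_sites": 0, "estimate": np.nan,
                            "lo": np.nan, "hi": np.nan, "p": np.nan,
                            "significant": False})
                continue
            res = load_ratio(gm, panel, pop_a, pop_b, site_mask=mask,
                             model=model, n_blocks=n_blocks, n_reps=n_reps,
                             seed=child)
            out.append({"pop_a": pop_a, "pop_b": pop_b, "category": cat,
                        "model": model, "n_sites": int(mask.sum()),
                        "estimate": res.estimate, "lo": res.lo, "hi": res.hi,
                        "p": res.p_value,
                        "significant": bool(res.p_value is not None
                                            and res.p_value < alpha)})
    return pd.DataFrame(out)
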