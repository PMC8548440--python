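"""End-to-end two-population pipeline from a single declarative config.

Stage order: QC -> polarization -> diversity -> SFS -> mutational load ->
ROH -> Fst / enrichment.  One master seed is fanned out deterministically to
per-stage seeds (spawned seed sequences), so rerunning the same config
reproduces byte-identical TSV outputs, and a stage rerun in isolation with
its recorded seed matches the full run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity as div
from . import fst as fstmod
from . import load as loadmod
from . import roh as rohmod
from . import sfs as sfsmod
from .store import (QCThresholds, attach_annotations, polarize,
                    population_indices, qc_filter_samples, qc_filter_sites,
                    read_annotations, read_panel, read_vcf)

log = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"

STAGES = ("qc", "diversity", "sfs", "load", "roh", "fst")


@dataclass
class RunConfig:
    """Pipeline configuration: either explicit input paths or a simulation."""

    out_dir: str
    target_pop: str = "ISO"
    reference_pop: str = "REF"
    seed: int = 0
    # inputs: exactly one of (vcf, simulate)
    vcf: str | None = None
    panel: str | None = None
    annotation: str | None = None
    catalog: str | None = None
    simulate: dict | None = None
    # stage parameters
    qc: dict = field(default_factory=dict)
    scheme: str = "gerp"
    n_blocks: int = 1000
    n_reps: int = 1000
    n_sub_sfs: int = 8
    n_sub_diff: int = 18
    roh: dict = field(default_factory=dict)
    consequence_filter: bool = False
    enrichment_top_fraction: float = 0.05

    def __post_init__(self):
        if (self.vcf is None) == (self.simulate is None):
            raise ValueError("config must set exactly one of 'vcf' or 'simulate'")
        if self.vcf is not None and self.panel is None:
            raise ValueError("missing input: 'panel' is required with 'vcf'")
        if self.vcf is not None and self.annotation is None:
            raise ValueError("missing input: 'annotation' is required with 'vcf'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def stage_seeds(master_seed: int) -> dict[str, np.random.SeedSequence]:
    """Deterministic per-stage seed sequences from one master seed."""
    children = np.random.SeedSequence(master_seed).spawn(len(STAGES))
    return dict(zip(STAGES, children))


def _write(df: pd.DataFrame, path: Path):
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    return str(path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest = {"config": {k: v for k, v in asdict(config).items()},
                "outputs": {}, "reports": {}}

    # ------------------------------------------------------------------ input
    if config.simulate is not None:
        from .simulate import ScenarioParams, simulate_scenario

        params = ScenarioParams(**{**config.simulate, "seed": config.seed})
        scenario = simulate_scenario(params)
        in_dir = out / "inputs"
        paths = scenario.write(in_dir)
        manifest["outputs"]["inputs"] = paths
        vcf_path, panel_path, annot_path = (paths["vcf"], paths["panel"],
                                            paths["annotation"])
    else:
        vcf_path, panel_path, annot_path = config.vcf, config.panel, config.annotation

    panel = read_panel(panel_path)
    gm, sites, read_report = read_vcf(vcf_path, panel)
    sites = attach_annotations(sites, read_annotations(annot_path))
    manifest["reports"]["read_vcf"] = read_report

    # --------------------------------------------------------------------- qc
    thr = QCThresholds(**config.qc)
    gm, sites, site_report = qc_filter_sites(gm, sites, panel, thr)
    gm, sample_report = qc_filter_samples(gm, panel, thr)
    gm, sites, pol_report = polarize(gm, sites)
    manifest["reports"]["qc_sites"] = site_report
    manifest["reports"]["qc_samples"] = sample_report
    manifest["reports"]["polarize"] = pol_report
    qc_df = pd.DataFrame(
        [{"rule": k, "count": v} for k, v in {**read_report, **{
            k: v for k, v in site_report.items() if k != "skipped_filters"},
            **pol_report}.items()])
    manifest["outputs"]["qc_report"] = _write(qc_df, out / "qc_report.tsv")

    pops = [config.target_pop, config.reference_pop]
    for p in pops:
        population_indices(gm, panel, p)  # hard error if absent

    scheme = sfsmod.scheme(config.scheme)
    labels = scheme.labels(sites)
    syn_mask = sites["consequence"].fillna("").to_numpy() == "synonymous"

    # -------------------------------------------------------------- diversity
    rows = []
    div_seeds = seeds["diversity"].spawn(len(pops))
    for p, s in zip(pops, div_seeds):
        res = div.diversity_with_ci(gm, panel, p, site_mask=syn_mask,
                                    n_blocks=config.n_blocks,
                                    n_reps=config.n_reps, seed=s)
        for stat, r in res.items():
            rows.append({"population": p, "statistic": stat,
                         "estimate": r.estimate, "lo": r.lo, "hi": r.hi})
    manifest["outputs"]["diversity"] = _write(pd.DataFrame(rows),
                                              out / "diversity.tsv")
    seg = div.segregating_site_summaries(gm, panel)
    manifest["outputs"]["segregating"] = _write(seg, out / "segregating_sites.tsv")

    # -------------------------------------------------------------------- sfs
    sfs_seeds = seeds["sfs"].spawn(len(pops) + 2)
    sfs_rows = []
    for p, s in zip(pops, sfs_seeds[:len(pops)]):
        idx = population_indices(gm, panel, p)
        by_cat = sfsmod.sfs_by_category(gm, idx, sites, scheme,
                                        n_sub=config.n_sub_sfs, seed=s)
        for cat, spec in by_cat.items():
            for b, (cnt, dens) in enumerate(zip(spec.counts, spec.densities), 1):
                sfs_rows.append({"population": p, "category": cat, "bin": b,
                                 "count": int(cnt), "density": dens})
    manifest["outputs"]["sfs"] = _write(pd.DataFrame(sfs_rows), out / "sfs.tsv")

    idx_t = population_indices(gm, panel, config.target_pop)
    idx_r = population_indices(gm, panel, config.reference_pop)
    n_sub_diff = min(config.n_sub_diff, len(idx_t), len(idx_r))
    ddt = sfsmod.density_difference_test(
        gm, idx_r, idx_t, sites, scheme, n_sub=n_sub_diff,
        n_reps=config.n_reps, seed=sfs_seeds[len(pops)])
    manifest["outputs"]["sfs_density_diff"] = _write(ddt.per_bin,
                                                     out / "sfs_density_diff.tsv")
    manifest["outputs"]["sfs_sequential_tests"] = _write(
        ddt.sequential, out / "sfs_sequential_tests.tsv")
    lvc_rows = []
    for p, s in zip(pops, sfs_seeds[len(pops) + 1].spawn(len(pops))):
        idx = population_indices(gm, panel, p)
        res = sfsmod.low_vs_common_proportions(gm, idx, sites,
                                               n_sub=n_sub_diff, seed=s)
        lvc_rows.append({"population": p, **{k: v for k, v in res.items()
                                             if not k.startswith("ci_")},
                         "ci_low_lo": res["ci_low"][0], "ci_low_hi": res["ci_low"][1],
                         "ci_common_lo": res["ci_common"][0],
                         "ci_common_hi": res["ci_common"][1]})
    manifest["outputs"]["low_vs_common"] = _write(pd.DataFrame(lvc_rows),
                                                  out / "low_vs_common.tsv")

    # ------------------------------------------------------------------- load
    burden = loadmod.per_individual_burden(gm)
    burden["population"] = [panel.get(s) for s in burden["sample_id"]]
    manifest["outputs"]["burden"] = _write(burden, out / "burden.tsv")
    ratios = loadmod.load_ratio_table(
        gm, panel, config.target_pop, config.reference_pop, sites, scheme,
        consequence_filter=config.consequence_filter, n_blocks=config.n_blocks,
        n_reps=config.n_reps, seed=seeds["load"])
    manifest["outputs"]["load_ratios"] = _write(ratios, out / "load_ratios.tsv")
    gl_rows = []
    for p in pops:
        for model in ("additive", "recessive"):
            res = loadmod.gerp_score_load(gm, panel, p, sites, scheme,
                                          model=model)
            for cat, val in res["per_category"].items():
                gl_rows.append({"population": p, "model": model,
                                "category": cat, "load": val})
            gl_rows.append({"population": p, "model": model,
                            "category": "total", "load": res["total"]})
    manifest["outputs"]["gerp_load"] = _write(pd.DataFrame(gl_rows),
                                              out / "gerp_score_load.tsv")

    # -------------------------------------------------------------------- roh
    roh_params = rohmod.ROHParams(**config.roh)
    prune_mask = rohmod.ld_prune(gm, sites,
                                 window_kb=roh_params.prune_window_kb,
                                 step_snps=roh_params.prune_step_snps,
                                 r2_threshold=roh_params.r2_prune)
    gm_p = gm.take_sites(np.where(prune_mask)[0])
    sites_p = sites.loc[prune_mask].reset_index(drop=True)
    rohs = rohmod.detect_rohs_all(gm_p, sites_p, roh_params)
    manifest["outputs"]["roh"] = _write(rohs, out / "roh.tsv")
    per_ind, tests = rohmod.roh_summaries(
        rohs, panel, gm.sample_ids,
        population_pairs=[(config.target_pop, config.reference_pop)])
    manifest["outputs"]["roh_summary"] = _write(per_ind, out / "roh_summary.tsv")
    manifest["outputs"]["roh_tests"] = _write(tests, out / "roh_tests.tsv")
    zyg, zyg_tests = rohmod.roh_zygosity_ratio(gm, sites, rohs, panel)
    manifest["outputs"]["roh_zygosity"] = _write(zyg, out / "roh_zygosity.tsv")
    manifest["outputs"]["roh_zygosity_tests"] = _write(
        zyg_tests, out / "roh_zygosity_tests.tsv")

    # ---------------------------------------------------------- fst/enrichment
    fst_df = fstmod.per_site_fst(gm, panel, config.target_pop,
                                 config.reference_pop)
    fst_out = pd.concat([sites[["chrom", "pos"]], fst_df], axis=1)
    manifest["outputs"]["fst"] = _write(fst_out, out / "fst.tsv")
    manifest["reports"]["mean_fst"] = fstmod.mean_pairwise_fst(
        gm, panel, config.target_pop, config.reference_pop)
    subsets = fstmod.build_candidate_subsets(
        sites, fst_df["fst"].to_numpy(), gm, panel, config.target_pop,
        config.reference_pop, top_fraction=config.enrichment_top_fraction)
    sub_rows = [{"subset": s.name, "n_sites": len(s.site_idx),
                 "n_genes": len(s.genes), "fst_threshold": s.fst_threshold,
                 "genes": ";".join(s.genes)} for s in subsets.values()]
    manifest["outputs"]["candidate_subsets"] = _write(
        pd.DataFrame(sub_rows), out / "candidate_subsets.tsv")

    if config.catalog is not None or config.simulate is not None:
        if config.catalog is not None:
            catalog = fstmod.read_catalog(config.catalog)
        else:
            from .simulate import toy_trait_catalog

            catalog = toy_trait_catalog(scenario, seed=config.seed)
        universe = sorted(set(sites["gene"].dropna()) - {""})
        enr_seeds = seeds["fst"].spawn(len(subsets))
        ora_frames, boot_frames = [], []
        for (name, sub), es in zip(subsets.items(), enr_seeds):
            if not sub.genes:
                continue
            t = fstmod.ora(sub.genes, universe, catalog)
            t.insert(0, "subset", name)
            ora_frames.append(t)
            b = fstmod.catalog_bootstrap_enrichment(
                sub.genes, catalog, universe, n_reps=config.n_reps, seed=es)
            b.insert(0, "subset", name)
            boot_frames.append(b)
        if ora_frames:
            manifest["outputs"]["ora"] = _write(
                pd.concat(ora_frames, ignore_index=True), out / "enrichment_ora.tsv")
        if boot_frames:
            manifest["outputs"]["bootstrap_enrichment"] = _write(
                pd.concat(boot_frames, ignore_index=True),
                out / "enrichment_bootstrap.tsv")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
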