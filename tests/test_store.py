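"""Variant store: VCF reading, QC filters, polarization, derived frequency."""

import numpy as np
import pandas as pd
import pytest

from isodist.store import (MISSING, GenotypeMatrix, QCThresholds, derived_freq,
                           hwe_exact_p, polarize, population_indices,
                           qc_filter_samples, qc_filter_sites, read_panel,
                           read_vcf, write_vcf)

from conftest import random_matrix
from oracles import hwe_exact_p_direct


VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
##contig=<ID=chrX>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
"""


def _write_vcf(tmp_path, body, name="t.vcf"):
    p = tmp_path / name
    p.write_text(VCF_HEADER + body)
    return p


class TestReadVcf:
    def test_filters_indels_multiallelics_and_sex_chroms(self, tmp_path):
        body = (
            "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1\n"
            "1\t200\t.\tA\tAT\t.\tPASS\t.\tGT\t0/0\t0/1\n"      # indel
            "1\t300\t.\tC\tT\t.\tPASS\t.\tGT\t0/0\t0/1\n"
            "1\t400\t.\tC\tT,G\t.\tPASS\t.\tGT\t0/1\t0/2\n"     # multiallelic
            "chrX\t500\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/1\n"    # sex chrom
            "1\t600\t.\tG\tA\t.\tPASS\t.\tGT\t./.\t0/1\n"
        )
        gm, sites, report = read_vcf(_write_vcf(tmp_path, body))
        assert gm.n_sites == 3
        assert report == {"indel": 1, "multiallelic": 1, "sex_chrom": 1,
                          "retained": 3}
        assert list(sites["pos"]) == [100, 300, 600]
        # GT coding: 0/1 -> 1, ./. -> missing
        assert gm.dosage[0, 0] == 1 and gm.dosage[1, 0] == 2
        assert gm.dosage[0, 2] == MISSING

    def test_panel_sample_absent_is_hard_error(self, tmp_path):
        body = "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1\n"
        vcf = _write_vcf(tmp_path, body)
        panel = pd.Series({"S1": "A", "NOPE": "B"})
        with pytest.raises(KeyError, match="NOPE"):
            read_vcf(vcf, panel)

    def test_round_trip_preserves_sites_and_genotypes(self, tmp_path):
        rng = np.random.default_rng(3)
        gm = random_matrix(rng, 4, 30, missing_frac=0.1, polarized=False)
        sites = pd.DataFrame({
            "chrom": ["1"] * 30, "pos": np.arange(1, 31) * 100,
            "ref": ["A"] * 30, "alt": ["G"] * 30})
        out = tmp_path / "rt.vcf"
        write_vcf(gm, sites, out)
        gm2, sites2, _ = read_vcf(out)
        assert np.array_equal(gm.dosage, gm2.dosage)
        pd.testing.assert_frame_equal(sites, sites2[sites.columns])


class TestHWE:
    @pytest.mark.parametrize("counts", [
        (0, 50, 0), (50, 0, 0), (10, 20, 20), (3, 1, 0), (7, 8, 9), (0, 0, 4),
        (12, 30, 8), (1, 0, 1),
    ])
    def test_matches_direct_factorial_oracle(self, counts):
        assert hwe_exact_p(*counts) == pytest.approx(
            hwe_exact_p_direct(*counts), rel=1e-10)

    def test_all_het_in_50_fails_default_alpha(self):
        # the classic HWE violation: every diploid heterozygous
        assert hwe_exact_p(50, 0, 0) < 1e-3


class TestQcSites:
    def _mk(self, n=50):
        """8 QC-relevant sites + 2 clean ones for two populations of n."""
        rng = np.random.default_rng(0)
        cols = []
        # 2 clean sites near HWE at freq 0.5 / 0.3
        for f in (0.5, 0.3):
            cols.append(rng.binomial(2, f, size=2 * n))
        mono = np.zeros(2 * n, dtype=int)                      # monomorphic
        miss = rng.binomial(2, 0.4, size=2 * n)
        miss[: int(0.2 * 2 * n)] = MISSING                     # 20% missing
        hwe = np.ones(2 * n, dtype=int)                        # all het
        cols += [mono, miss, hwe]
        dosage = np.array(cols, dtype=np.int8).T
        gm = GenotypeMatrix([f"S{i}" for i in range(2 * n)], dosage)
        sites = pd.DataFrame({"chrom": ["1"] * 5, "pos": np.arange(1, 6) * 1000,
                              "ref": ["A"] * 5, "alt": ["G"] * 5})
        panel = pd.Series(["P1"] * n + ["P2"] * n,
                          index=[f"S{i}" for i in range(2 * n)])
        return gm, sites, panel

    def test_per_rule_counts(self):
        gm, sites, panel = self._mk()
        gm2, sites2, rep = qc_filter_sites(gm, sites, panel)
        assert rep["monomorphic"] == 1
        assert rep["missingness"] == 1
        assert rep["hwe"] == 1
        assert rep["retained"] == 2
        assert list(sites2["pos"]) == [1000, 2000]

    def test_idempotent(self):
        gm, sites, panel = self._mk()
        gm2, sites2, _ = qc_filter_sites(gm, sites, panel)
        gm3, sites3, rep = qc_filter_sites(gm2, sites2, panel)
        assert rep["retained"] == gm2.n_sites
        assert np.array_equal(gm2.dosage, gm3.dosage)

    def test_all_het_site_fails_hwe_in_one_population(self):
        n = 50
        site0 = np.ones(n, dtype=np.int8)                      # every diploid het
        site1 = np.random.default_rng(1).binomial(2, 0.5, n).astype(np.int8)
        gm = GenotypeMatrix([f"S{i}" for i in range(n)],
                            np.column_stack([site0, site1]))
        sites = pd.DataFrame({"chrom": ["1", "1"], "pos": [1, 2],
                              "ref": ["A"] * 2, "alt": ["G"] * 2})
        panel = pd.Series(["P"] * n, index=gm.sample_ids)
        _, sites2, rep = qc_filter_sites(gm, sites, panel)
        assert rep["hwe"] == 1 and list(sites2["pos"]) == [2]

    def test_depth_gq_masked_before_missingness(self):
        n = 20
        rng = np.random.default_rng(2)
        dosage = rng.binomial(2, 0.5, size=(n, 2)).astype(np.int8)
        depth = np.full((n, 2), 30, dtype=np.int32)
        depth[: n // 2, 0] = 2      # half the calls at site 0 below min_depth
        gm = GenotypeMatrix([f"S{i}" for i in range(n)], dosage, depth=depth,
                            gq=np.full((n, 2), 99.0))
        sites = pd.DataFrame({"chrom": ["1", "1"], "pos": [1, 2],
                              "ref": ["A"] * 2, "alt": ["G"] * 2})
        panel = pd.Series(["P"] * n, index=gm.sample_ids)
        _, sites2, rep = qc_filter_sites(gm, sites, panel,
                                         QCThresholds(hwe_alpha=None))
        assert rep["depth_masked"] == n // 2
        assert rep["missingness"] == 1 and list(sites2["pos"]) == [2]


class TestQcSamples:
    def test_missingness_drop_and_reason(self):
        rng = np.random.default_rng(4)
        gm = random_matrix(rng, 10, 100, polarized=False)
        d = gm.dosage.copy()
        d[0, :15] = MISSING   # 15% missing
        gm = GenotypeMatrix(gm.sample_ids, d)
        panel = pd.Series(["P"] * 10, index=gm.sample_ids)
        gm2, rep = qc_filter_samples(gm, panel)
        assert rep["dropped"] == {"S0": "missingness"}
        assert gm2.n_samples == 9

    def test_zero_sd_heterozygosity_drops_nobody(self):
        d = np.tile([1, 0, 2, 1], (6, 25)).astype(np.int8)
        gm = GenotypeMatrix([f"S{i}" for i in range(6)], d)
        panel = pd.Series(["P"] * 6, index=gm.sample_ids)
        _, rep = qc_filter_samples(gm, panel)
        assert rep["dropped"] == {}

    def test_het_outlier_dropped(self):
        rng = np.random.default_rng(5)
        n, m = 20, 400
        d = np.zeros((n, m), dtype=np.int8)
        d[:, :] = rng.binomial(2, 0.5, size=(n, m))
        # sample 0: heterozygous everywhere -> far above population mean
        d[0] = 1
        gm = GenotypeMatrix([f"S{i}" for i in range(n)], d)
        panel = pd.Series(["P"] * n, index=gm.sample_ids)
        _, rep = qc_filter_samples(gm, panel, QCThresholds(het_sd_range=4.0,
                                                           max_sample_missingness=None))
        assert rep["dropped"].get("S0") == "heterozygosity"


class TestPolarize:
    def _sites(self, anc):
        n = len(anc)
        return pd.DataFrame({"chrom": ["1"] * n, "pos": np.arange(1, n + 1),
                             "ref": ["A"] * n, "alt": ["G"] * n,
                             "ancestral": anc})

    def test_flip_and_unknown_removal(self):
        d = np.array([[1, 0, 2, 1]], dtype=np.int8)
        gm = GenotypeMatrix(["S0"], d)
        sites = self._sites(["A", "G", ".", "C"])
        gm2, sites2, rep = polarize(gm, sites)
        # kept: anc=A (unchanged), anc=G (flipped 0 -> 2)
        assert list(gm2.dosage[0]) == [1, 2]
        assert rep["unknown_ancestral"] == 1 and rep["ancestral_mismatch"] == 1
        assert gm2.polarized

    def test_missing_stays_missing_through_flip(self):
        gm = GenotypeMatrix(["S0"], np.array([[MISSING]], dtype=np.int8))
        gm2, _, _ = polarize(gm, self._sites(["G"]))
        assert gm2.dosage[0, 0] == MISSING

    def test_flip_is_involution(self):
        rng = np.random.default_rng(6)
        gm = random_matrix(rng, 8, 50, missing_frac=0.1, polarized=False)
        sites = self._sites(["G"] * 50)
        gm2, _, _ = polarize(gm, sites)
        gm2 = GenotypeMatrix(gm2.sample_ids, gm2.dosage, polarized=False)
        gm3, _, _ = polarize(gm2, sites)
        assert np.array_equal(gm.dosage, gm3.dosage)


class TestDerivedFreq:
    def test_examples(self):
        d = np.array([[2], [1], [0], [1]], dtype=np.int8)
        gm = GenotypeMatrix(["a", "b", "c", "d"], d, polarized=True)
        assert derived_freq(gm)[0] == 0.5
        d = np.array([[0], [0], [MISSING]], dtype=np.int8)
        gm = GenotypeMatrix(["a", "b", "c"], d, polarized=True)
        assert derived_freq(gm)[0] == 0.0
        gm = GenotypeMatrix(["a"], np.array([[MISSING]], dtype=np.int8),
                            polarized=True)
        assert np.isnan(derived_freq(gm)[0])

    def test_pooled_q_is_weighted_mean_of_population_q(self, null_scenario):
        gm, panel = null_scenario.gm, null_scenario.panel
        q_all = derived_freq(gm)
        parts = []
        for pop in ("ISO", "REF"):
            idx = population_indices(gm, panel, pop)
            valid = (gm.dosage[idx] != MISSING).sum(axis=0)
            parts.append((derived_freq(gm, idx), valid))
        num = sum(np.nan_to_num(q) * w for q, w in parts)
        den = sum(w for _, w in parts)
        assert np.allclose(q_all, num / den, equal_nan=True)
        assert np.nanmin(q_all) >= 0 and np.nanmax(q_all) <= 1
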