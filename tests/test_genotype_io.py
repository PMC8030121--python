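"""Genotype reading, effect-allele alignment, and QC metrics."""

import numpy as np
import pytest

import grsgdm as g
from grsgdm.genotype_io import (GenotypeError, GenotypeMatrix, call_rates,
                                duplicate_concordance, read_genotypes,
                                write_genotypes_tsv)
from grsgdm.panel import Panel, SnpPanelEntry

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
)


def mini_panel(entries):
    return Panel(name="FPG", entries=tuple(entries))


def entry(rsid, ea, oa, eaf=0.5, beta=0.1, **kw):
    return SnpPanelEntry(rsid=rsid, chrom="1", pos=1, locus="LOC",
                         effect_allele=ea, other_allele=oa, eaf=eaf,
                         beta=beta, **kw)


def write_vcf(tmp_path, samples, records):
    lines = [VCF_HEADER + "\t".join(samples)]
    for chrom, pos, rsid, ref, alt, gts in records:
        lines.append(f"{chrom}\t{pos}\t{rsid}\t{ref}\t{alt}\t.\t.\t.\tGT\t"
                     + "\t".join(gts))
    p = tmp_path / "g.vcf"
    p.write_text("\n".join(lines) + "\n")
    return p


class TestVcfAlignment:
    def test_alt_is_effect_counts_alt(self, tmp_path):
        panel = mini_panel([entry("rs1", "C", "T")])
        vcf = write_vcf(tmp_path, ["a", "b", "c", "d"],
                        [("1", 100, "rs1", "T", "C",
                          ["0/0", "0/1", "1/1", "./."])])
        gm = read_genotypes(vcf, "vcf", panel)
        np.testing.assert_array_equal(gm.dosages[:3, 0], [0, 1, 2])
        assert np.isnan(gm.dosages[3, 0])

    def test_representation_swap_invariant(self, tmp_path):
        """REF/ALT swapped with genotype indices updated gives same dosage."""
        panel = mini_panel([entry("rs1", "C", "T")])
        v1 = write_vcf(tmp_path, ["a"], [("1", 100, "rs1", "T", "C", ["0/1"])])
        gm1 = read_genotypes(v1, "vcf", panel)
        v2 = write_vcf(tmp_path, ["a"], [("1", 100, "rs1", "C", "T", ["1/0"])])
        gm2 = read_genotypes(v2, "vcf", panel)
        assert gm1.dosages[0, 0] == gm2.dosages[0, 0] == 1

    def test_strand_flip_resolved_by_reverse_complement(self, tmp_path):
        # panel C/T; file reports the other strand G/A: G is the effect allele
        panel = mini_panel([entry("rs1", "C", "T")])
        vcf = write_vcf(tmp_path, ["a", "b"],
                        [("1", 100, "rs1", "G", "A", ["0/0", "0/1"])])
        gm = read_genotypes(vcf, "vcf", panel)
        np.testing.assert_array_equal(gm.dosages[:, 0], [2, 1])

    def test_unmatchable_alleles_error_names_snp(self, tmp_path):
        panel = mini_panel([entry("rs1", "C", "T")])
        vcf = write_vcf(tmp_path, ["a"], [("1", 100, "rs1", "A", "C", ["0/1"])])
        with pytest.raises(GenotypeError, match="rs1"):
            read_genotypes(vcf, "vcf", panel)

    def test_palindromic_default_hard_error(self, tmp_path):
        panel = mini_panel([entry("rs1", "A", "T")])
        vcf = write_vcf(tmp_path, ["a"], [("1", 100, "rs1", "A", "T", ["0/1"])])
        with pytest.raises(GenotypeError, match="palindromic"):
            read_genotypes(vcf, "vcf", panel)

    def test_palindromic_freq_policy_orients_by_frequency(self, tmp_path):
        # panel eaf 0.9 for A; sample ALT=T freq 0.1 -> ALT is the other allele
        panel = mini_panel([entry("rs1", "A", "T", eaf=0.9)])
        gts = ["0/0"] * 9 + ["0/1"]
        vcf = write_vcf(tmp_path, [f"s{i}" for i in range(10)],
                        [("1", 100, "rs1", "A", "T", gts)])
        gm = read_genotypes(vcf, "vcf", panel, palindrome_policy="freq")
        assert gm.dosages[:9, 0].sum() == 18  # hom REF counted as 2 effect alleles
        assert gm.dosages[9, 0] == 1

    def test_non_panel_snps_ignored(self, tmp_path):
        panel = mini_panel([entry("rs1", "C", "T")])
        vcf = write_vcf(tmp_path, ["a"],
                        [("1", 100, "rs1", "T", "C", ["1/1"]),
                         ("1", 200, "rs999", "A", "G", ["0/1"])])
        gm = read_genotypes(vcf, "vcf", panel)
        assert gm.snp_ids == ["rs1"]

    def test_shipped_panel_palindromic_scan_is_frozen(self):
        """Scan of the shipped panels for A/T and C/G variants.

        These sites cannot be strand-oriented from alleles alone, so VCF
        input covering them needs palindrome_policy="freq" (or pre-aligned
        dosage TSVs, which carry no strand ambiguity).
        """
        expected = {
            ("FPG", None): {"rs11920090", "rs7944584", "rs10830963"},
            ("FPG", "HAPO"): {"rs11920090", "rs7944584", "rs10830963"},
            ("T2D", None): {"rs1801282", "rs7754840"},
            ("T2D", "HAPO"): {"rs1801282", "rs10830963", "rs12427353"},
        }
        for (name, cohort), rsids in expected.items():
            panel = g.packaged_panel(name, cohort=cohort)
            found = {e.rsid for e in panel.entries if e.is_palindromic}
            assert found == rsids


class TestTsvRoundTrip:
    def test_read_write_read_exact(self, tmp_path, fpg_panel):
        gm = g.simulate_genotypes(fpg_panel, 30, seed=1, missing_rate=0.2)
        path = tmp_path / "g.tsv"
        write_genotypes_tsv(gm, path)
        back = read_genotypes(path, "tsv", fpg_panel)
        assert back.sample_ids == gm.sample_ids
        assert back.snp_ids == gm.snp_ids
        np.testing.assert_array_equal(back.dosages, gm.dosages)

    def test_bad_dosage_value_rejected(self):
        with pytest.raises(GenotypeError, match="dosages outside"):
            GenotypeMatrix(["a"], ["rs1"], np.array([[3.0]]))

    def test_missing_file(self, fpg_panel):
        with pytest.raises(GenotypeError, match="not found"):
            read_genotypes("/nonexistent.tsv", "tsv", fpg_panel)


class TestCallRates:
    def test_simple_fraction(self):
        dos = np.ones((100, 1))
        dos[0, 0] = np.nan
        rep = call_rates(GenotypeMatrix([f"s{i}" for i in range(100)], ["rs1"], dos))
        assert rep.per_snp_call_rate["rs1"] == pytest.approx(0.99)
        assert rep.median_call_rate == pytest.approx(0.99)

    def test_all_missing_snp_is_zero(self):
        dos = np.column_stack([np.full(10, np.nan), np.ones(10)])
        rep = call_rates(GenotypeMatrix([f"s{i}" for i in range(10)],
                                        ["rs1", "rs2"], dos))
        assert rep.per_snp_call_rate["rs1"] == 0.0

    def test_zero_samples_error(self):
        gm = GenotypeMatrix([], ["rs1"], np.empty((0, 1)))
        with pytest.raises(GenotypeError):
            call_rates(gm)

    def test_simulated_missingness_matches_rate(self, fpg_panel, t2d_panel):
        """Median call rate ~= 1 - missing_rate at the reported 0.008."""
        gm = g.simulate_genotypes(t2d_panel, 5000, seed=7, missing_rate=0.008)
        rep = call_rates(gm)
        # binomial SE per SNP ~= sqrt(.008*.992/5000) ~= 0.00126
        assert rep.median_call_rate == pytest.approx(0.992, abs=0.003)

    def test_permutation_invariance(self, fpg_panel):
        gm = g.simulate_genotypes(fpg_panel, 50, seed=3, missing_rate=0.1)
        perm = np.random.default_rng(0).permutation(50)
        gm2 = GenotypeMatrix([gm.sample_ids[i] for i in perm], gm.snp_ids,
                             gm.dosages[perm])
        assert call_rates(gm2).per_snp_call_rate == call_rates(gm).per_snp_call_rate


class TestDuplicateConcordance:
    def _gm(self, rows, ids=None):
        rows = np.asarray(rows, float)
        ids = ids or [f"s{i}" for i in range(len(rows))]
        return GenotypeMatrix(ids, [f"rs{j}" for j in range(rows.shape[1])], rows)

    def test_identical_rows_full_concordance(self):
        gm = self._gm([[0, 1, 2], [0, 1, 2]])
        conc, n_used, flagged = duplicate_concordance(gm, [("s0", "s1")])
        assert conc == 1.0 and n_used == 1 and not flagged

    def test_one_in_fifty_discordant(self):
        a = np.tile([0, 1], 25).astype(float)
        b = a.copy()
        b[0] = 2
        gm = self._gm(np.vstack([a, b]))
        conc, _, _ = duplicate_concordance(gm, [("s0", "s1")])
        assert conc == pytest.approx(0.98)

    def test_pair_with_no_joint_calls_flagged_and_excluded(self):
        gm = self._gm([[0, 1], [np.nan, np.nan], [1, 1], [1, 1]])
        conc, n_used, flagged = duplicate_concordance(
            gm, [("s0", "s1"), ("s2", "s3")])
        assert conc == 1.0 and n_used == 1 and flagged == [("s0", "s1")]

    def test_absent_sample_errors(self):
        gm = self._gm([[0], [1]])
        with pytest.raises(GenotypeError, match="ghost"):
            duplicate_concordance(gm, [("s0", "ghost")])
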