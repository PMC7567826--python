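import numpy as np
import pytest

from cpelhap import (
    AlleleReadSet,
    MISSING,
    ObservedRead,
    PhasedSnpCluster,
    define_haplotypes,
)
from cpelhap.io import (
    read_methylation_tsv,
    read_phased_vcf,
    results_frame,
    write_methylation_tsv,
    write_results_bed,
)
from cpelhap.summaries import AlleleSummary, HaplotypeStats
from cpelhap.testing import HaplotypeResult


class TestDefineHaplotypes:
    def test_symmetric_expansion(self):
        cluster = PhasedSnpCluster("chr1", (1000, 1200))
        haps = define_haplotypes([cluster], 100, {"chr1": [950, 1100, 1250]})
        assert len(haps) == 1
        assert haps[0].expanded_span == (900, 1300)
        assert haps[0].raw_span == (1000, 1200)

    def test_split_into_equal_counts(self):
        # 45 CpG sites with n_max=20 -> 3 regions of 15 sites each
        sites = [1000 + 10 * i for i in range(45)]
        cluster = PhasedSnpCluster("chr2", (1100, 1300))
        haps = define_haplotypes([cluster], 200, {"chr2": sites}, n_max=20)
        assert len(haps) == 3
        counts = [h.layout1.n_sites for h in haps]
        assert counts == [15, 15, 15]

    def test_boundary_count_unsplit(self):
        sites = [1000 + 25 * i for i in range(20)]
        cluster = PhasedSnpCluster("chr3", (1200, 1250))
        haps = define_haplotypes([cluster], 500, {"chr3": sites}, n_max=20)
        assert len(haps) == 1
        assert haps[0].layout1.n_sites == 20

    def test_split_counts_differ_by_at_most_one(self):
        sites = [2000 + 7 * i for i in range(47)]
        cluster = PhasedSnpCluster("chr1", (2100,))
        haps = define_haplotypes([cluster], 200, {"chr1": sites}, n_max=10)
        counts = [h.layout1.n_sites for h in haps]
        assert max(counts) <= 10
        assert max(counts) - min(counts) <= 1
        assert sum(counts) == len([s for s in sites if 1900 <= s < 2300])

    def test_cluster_without_cpgs_dropped(self):
        cluster = PhasedSnpCluster("chr1", (5000,))
        assert define_haplotypes([cluster], 50, {"chr1": [100]}) == []

    def test_allele_specific_cpg_sets_share_sites(self):
        # allele 2 lacks one CpG site (SNP destroys it)
        cluster = PhasedSnpCluster("chr1", (1000,))
        haps = define_haplotypes(
            [cluster], 100,
            {"chr1": [950, 1000, 1050]},
            cpg_positions_allele2={"chr1": [950, 1050]},
        )
        hap = haps[0]
        assert hap.layout1.n_sites == 3
        assert hap.layout2.n_sites == 2
        assert hap.shared_sites_1 == (0, 2)
        assert hap.shared_sites_2 == (0, 1)


class TestMethylationTsv:
    def test_well_formed_fixture(self, tmp_path):
        path = tmp_path / "reads.tsv"
        path.write_text(
            "read_id\tchrom\thaplotype_id\tallele\tcpg_index_start\tobs_string\n"
            "r1\tchr1\thapA\t1\t1\t10.\n"
            "r2\tchr1\thapA\t1\t2\t01\n"
            "r3\tchr1\thapA\t2\t1\t111\n"
        )
        sets = read_methylation_tsv(path)
        by_key = {(s.haplotype_id, s.allele): s for s in sets}
        assert len(by_key[("hapA", 1)].reads) == 2
        assert len(by_key[("hapA", 2)].reads) == 1
        np.testing.assert_array_equal(by_key[("hapA", 1)].reads[0].obs, [1, 0, MISSING])
        np.testing.assert_array_equal(by_key[("hapA", 1)].reads[1].obs, [MISSING, 0, 1])

    def test_unassigned_reads_excluded(self, tmp_path):
        path = tmp_path / "reads.tsv"
        path.write_text("r1\tchr1\thapA\t0\t1\t101\n")
        assert read_methylation_tsv(path) == []

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "reads.tsv"
        path.write_text("r1\tchr1\thapA\t1\t1\t1x1\n")
        with pytest.raises(ValueError, match=":1:"):
            read_methylation_tsv(path)
        path.write_text("r1\tchr1\thapA\t1\n")
        with pytest.raises(ValueError, match="columns"):
            read_methylation_tsv(path)

    def test_round_trip_identity(self, tmp_path, rng):
        n = 6
        readsets = []
        for hap in ("h1", "h2"):
            for allele in (1, 2):
                reads = []
                for _ in range(8):
                    obs = rng.integers(0, 2, size=n).astype(np.int8)
                    obs[rng.random(n) < 0.3] = MISSING
                    if np.all(obs == MISSING):
                        obs[0] = 1
                    reads.append(ObservedRead(allele=allele, obs=obs))
                readsets.append(AlleleReadSet(hap, allele, reads))
        path = tmp_path / "rt.tsv"
        write_methylation_tsv(readsets, path)
        recovered = read_methylation_tsv(path, n_sites_by_hap={"h1": n, "h2": n})
        by_key = {(s.haplotype_id, s.allele): s for s in recovered}
        for rs in readsets:
            got = by_key[(rs.haplotype_id, rs.allele)]
            assert len(got.reads) == len(rs.reads)
            for orig, back in zip(rs.reads, got.reads):
                np.testing.assert_array_equal(orig.obs, back.obs)


class TestPhasedVcf:
    HEADER = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
    )

    def _write(self, tmp_path, records):
        path = tmp_path / "phased.vcf"
        path.write_text(self.HEADER + "".join(records))
        return path

    def test_same_phase_set_forms_one_cluster(self, tmp_path):
        path = self._write(tmp_path, [
            "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:PS\t0|1:77\n",
            "chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT:PS\t1|0:77\n",
        ])
        clusters = read_phased_vcf(path)
        assert len(clusters) == 1
        assert clusters[0].positions == (100, 200)
        assert clusters[0].chrom == "chr1"

    def test_same_ps_different_chromosomes_stay_separate(self, tmp_path):
        path = self._write(tmp_path, [
            "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:PS\t0|1:5\n",
            "chr2\t100\t.\tA\tG\t.\tPASS\t.\tGT:PS\t0|1:5\n",
        ])
        assert len(read_phased_vcf(path)) == 2

    def test_unphased_and_homozygous_skipped(self, tmp_path):
        path = self._write(tmp_path, [
            "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:PS\t0/1:9\n",  # unphased
            "chr1\t150\t.\tA\tG\t.\tPASS\t.\tGT:PS\t1|1:9\n",  # homozygous
            "chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT:PS\t0|1:9\n",
        ])
        clusters = read_phased_vcf(path)
        assert len(clusters) == 1
        assert clusters[0].positions == (200,)

    def test_agrees_with_cyvcf2_reference_parser(self, tmp_path):
        cyvcf2 = pytest.importorskip("cyvcf2")
        records = [
            "chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT:PS\t0|1:77\n",
            "chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT:PS\t1|0:77\n",
            "chr1\t300\t.\tC\tT\t.\tPASS\t.\tGT:PS\t0|1:88\n",
        ]
        path = self._write(tmp_path, records)
        clusters = {c.phase_set: c.positions for c in read_phased_vcf(path)}
        expected: dict = {}
        for v in cyvcf2.VCF(str(path)):
            if not v.gt_phases[0]:
                continue
            ps = str(v.format("PS")[0][0])
            expected.setdefault(ps, []).append(v.POS)
        assert {k: tuple(v) for k, v in expected.items()} == clusters


class TestResultsBed:
    def _result(self, hap_id, q_mml=0.5, q_nme=0.5, q_pdm=0.5):
        return HaplotypeResult(
            haplotype_id=hap_id,
            chrom="chr1",
            start=0,
            end=1000,
            summary1=AlleleSummary(0.5, 0.8, 4),
            summary2=AlleleSummary(0.6, 0.7, 4),
            stats=HaplotypeStats(0.1, 0.1, 0.02, 0.2, 0.75, 4),
            p_mml=0.1, p_nme=0.2, p_pdm=0.3,
            q_mml=q_mml, q_nme=q_nme, q_pdm=q_pdm,
        )

    def test_empty_results_write_header_only(self, tmp_path):
        write_results_bed([], tmp_path / "out")
        for suffix in (".bed", ".mml_haps.bed", ".nme_haps.bed", ".pdm_haps.bed"):
            lines = (tmp_path / f"out{suffix}").read_text().splitlines()
            assert len(lines) == 1
            assert lines[0].startswith("chrom\t")

    def test_significant_call_routed_to_one_list(self, tmp_path):
        results = [self._result("hapA", q_mml=0.04), self._result("hapB")]
        write_results_bed(results, tmp_path / "out")
        master = (tmp_path / "out.bed").read_text().splitlines()
        assert len(master) == 3  # header + both haplotypes
        mml_list = (tmp_path / "out.mml_haps.bed").read_text()
        assert "hapA" in mml_list and "hapB" not in mml_list
        assert len((tmp_path / "out.nme_haps.bed").read_text().splitlines()) == 1

    def test_frame_columns_are_bed_like(self):
        frame = results_frame([self._result("hapA")])
        assert list(frame.columns[:4]) == ["chrom", "start", "end", "id"]
        assert frame.loc[0, "T_PDM"] == 0.02


class TestNullCdfSerialization:
    def test_round_trip(self, tmp_path, rng):
        from cpelhap.io import read_null_cdfs, write_null_cdfs
        from cpelhap.testing import NullCdf

        cdfs = {
            s: NullCdf(s, 4, rng.uniform(0, 1, 150)) for s in ("T_MML", "T_PDM")
        }
        path = tmp_path / "null.tsv"
        write_null_cdfs(cdfs, path)
        back = read_null_cdfs(path)
        for s, cdf in cdfs.items():
            np.testing.assert_allclose(back[(s, 4)].samples, cdf.samples)
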