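"""Format ingestion and emission: VCF, BED, FASTA, TSV, Newick."""

import numpy as np
import pytest
from Bio import SeqIO

from ychrono.errors import InputError
from ychrono.model import (CALL_ALT, CALL_MISSING, CALL_REF, RegionMask,
                           SnpCatalog)
from ychrono.tree import PhyloTree
from ychrono.variant_io import (VcfReadReport, read_haploid_vcf, read_newick,
                                read_region_mask, read_sample_meta,
                                read_snp_catalog, write_haploid_vcf,
                                write_newick, write_sample_meta,
                                write_snp_catalog,
                                write_variable_sites_fasta)

from .conftest import mk_matrix

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chrY>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
"""


def write_vcf(tmp_path, body, name="in.vcf"):
    path = tmp_path / name
    path.write_text(VCF_HEADER + body)
    return path


class TestReadHaploidVcf:
    def test_identity_ingestion(self, tmp_path):
        body = "\n".join(
            f"chrY\t{pos}\t.\tA\tG\t.\tPASS\t.\tGT\t0\t1\t0"
            for pos in (100, 200, 300, 400, 500)) + "\n"
        m = read_haploid_vcf(write_vcf(tmp_path, body))
        assert m.sample_ids == ["s1", "s2", "s3"]
        assert m.n_sites == 5
        assert m.calls[:, 0].tolist() == [CALL_REF, CALL_ALT, CALL_REF]

    def test_missing_and_het_genotypes(self, tmp_path):
        body = ("chrY\t100\t.\tA\tG\t.\tPASS\t.\tGT\t.\t0/1\t1/1\n")
        rep = VcfReadReport()
        m = read_haploid_vcf(write_vcf(tmp_path, body), report=rep)
        # "." missing; diploid het -> missing (counted); hom-alt collapses
        assert m.calls[:, 0].tolist() == [CALL_MISSING, CALL_MISSING,
                                          CALL_ALT]
        assert rep.heterozygous_set_missing == 1

    def test_mask_excludes_records(self, tmp_path):
        body = "\n".join(
            f"chrY\t{pos}\t.\tA\tG\t.\tPASS\t.\tGT\t0\t1\t0"
            for pos in (10, 20, 30, 40, 50)) + "\n"
        mask = RegionMask.from_intervals([(15, 45)])  # covers 16..45
        m = read_haploid_vcf(write_vcf(tmp_path, body), mask=mask)
        # brute-force: positions with 15 <= pos-1 < 45
        expected = [p for p in (10, 20, 30, 40, 50) if 15 <= p - 1 < 45]
        assert m.positions.tolist() == expected

    def test_depth_from_format_field(self, tmp_path):
        body = "chrY\t100\t.\tA\tG\t.\tPASS\t.\tGT:DP\t0:7\t1:2\t0:.\n"
        m = read_haploid_vcf(write_vcf(tmp_path, body))
        assert m.depths[:, 0].tolist() == [7, 2, -1]

    def test_multiallelic_reduced_to_major_alt(self, tmp_path):
        body = "chrY\t100\t.\tA\tG,T\t.\tPASS\t.\tGT\t1\t1\t2\n"
        rep = VcfReadReport()
        m = read_haploid_vcf(write_vcf(tmp_path, body), report=rep)
        assert m.alt_allele[0] == "G"
        assert m.calls[:, 0].tolist() == [CALL_ALT, CALL_ALT, CALL_MISSING]
        assert rep.minor_alt_set_missing == 1

    def test_unreadable_file_is_input_error(self, tmp_path):
        with pytest.raises(InputError):
            read_haploid_vcf(tmp_path / "absent.vcf")

    def test_roundtrip_preserves_everything(self, tmp_path):
        m = mk_matrix(["x", "y"], [5, 9, 14],
                      [[0, 1, -1], [1, 0, 1]],
                      depths=[[3, 4, -1], [9, 2, 30]],
                      ref=["A", "C", "T"], alt=["G", "T", "A"])
        path = tmp_path / "round.vcf"
        write_haploid_vcf(m, path)
        back = read_haploid_vcf(path)
        assert back.sample_ids == m.sample_ids
        assert back.positions.tolist() == m.positions.tolist()
        assert list(back.ref_allele) == list(m.ref_allele)
        assert list(back.alt_allele) == list(m.alt_allele)
        assert np.array_equal(back.calls, m.calls)
        assert np.array_equal(back.depths, m.depths)


class TestRegionMaskIO:
    def test_bed_merge_and_length(self, tmp_path):
        p = tmp_path / "mask.bed"
        p.write_text("chrY\t0\t100\nchrY\t50\t150\nchrY\t300\t400\n")
        mask = read_region_mask(p)
        assert mask.intervals == [(0, 150), (300, 400)]
        assert mask.effective_length_bp == 250

    def test_empty_bed(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert read_region_mask(p).effective_length_bp == 0

    def test_bad_interval(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chrY\t100\t100\n")
        with pytest.raises(InputError):
            read_region_mask(p)


class TestVariableSitesFasta:
    def test_monomorphic_sites_omitted_and_missing_is_n(self, tmp_path):
        m = mk_matrix(["x", "y", "z"], [1, 2, 3],
                      [[0, 1, -1], [1, 1, 0], [1, 1, 1]],
                      ref=["A", "C", "G"], alt=["G", "A", "C"])
        path = tmp_path / "var.fasta"
        write_variable_sites_fasta(m, path)
        recs = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
        # site 2 is monomorphic-ALT over non-missing calls -> omitted;
        # the missing call at variable site 3 renders as N
        assert recs == {"x": "AN", "y": "GG", "z": "GC"}

    def test_column_count_equals_bruteforce_variable_count(self, tmp_path):
        rng = np.random.default_rng(7)
        calls = rng.choice([-1, 0, 1], size=(5, 40), p=[0.1, 0.5, 0.4])
        m = mk_matrix([f"s{i}" for i in range(5)],
                      list(range(1, 41)), calls)
        path = tmp_path / "v.fasta"
        write_variable_sites_fasta(m, path)
        n_var = sum(
            1 for j in range(40)
            if len({c for c in calls[:, j] if c != -1}) >= 2)
        for rec in SeqIO.parse(str(path), "fasta"):
            assert len(rec.seq) == n_var


class TestTsvAndNewick:
    def test_catalog_roundtrip_and_duplicates(self, tmp_path):
        p = tmp_path / "cat.tsv"
        p.write_text("name\tpos\tanc\tder\nM3\t100\tA\tG\nZ780\t200\tC\tT\n")
        cat = read_snp_catalog(p)
        assert len(cat) == 2 and cat.name_of(100) == "M3"
        out = tmp_path / "cat2.tsv"
        write_snp_catalog(cat, out)
        assert read_snp_catalog(out).entries == cat.entries
        p.write_text("name\tpos\tanc\tder\nM3\t100\tA\tG\nX\t100\tC\tT\n")
        with pytest.raises(InputError):
            read_snp_catalog(p)

    def test_sample_meta_roundtrip(self, tmp_path):
        p = tmp_path / "meta.tsv"
        p.write_text("sample\tpopulation\thigh_coverage\n"
                     "a\tPeru\ttrue\nb\tMexico\tfalse\n")
        meta = read_sample_meta(p)
        assert [m.high_coverage for m in meta] == [True, False]
        out = tmp_path / "meta2.tsv"
        write_sample_meta(meta, out)
        assert read_sample_meta(out) == meta

    def test_newick_roundtrip_with_polytomy(self, tmp_path):
        newick = "((a,b),(c,d,e));"
        t = PhyloTree.from_newick(newick)
        path = tmp_path / "t.nwk"
        write_newick(t, path)
        back = read_newick(path)
        assert back.clade_sets() == t.clade_sets()
        assert {frozenset({"c", "d", "e"})} <= back.clade_sets()
        assert sorted(back.tip_names) == ["a", "b", "c", "d", "e"]

    def test_unlabeled_tip_rejected(self):
        with pytest.raises(InputError):
            PhyloTree.from_newick("((,a),b);")
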