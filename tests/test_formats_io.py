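"""Alignment/VCF I/O: tag decoding, invariant enforcement, round-trips."""

from __future__ import annotations

import textwrap

import pysam
import pytest

from duophase.decision_path import PhasedCall
from duophase.formats_io import (
    AlignedReadView,
    TruthRecord,
    load_haplotag_table,
    read_alignments,
    read_sv_vcf,
    write_phased_vcf,
    write_truth_vcf,
)
from duophase.synthetic_data import SimConfig, simulate_truth_set

HEADER = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": "chr1", "LN": 100000}]}


def _write_bam(path, rows):
    """rows: (name, start, cigar, flag, mapq, tags)."""
    with pysam.AlignmentFile(str(path), "wb", header=HEADER) as bam:
        for name, start, cigar, flag, mapq, tags in sorted(rows, key=lambda r: r[1]):
            seg = pysam.AlignedSegment(bam.header)
            seg.query_name = name
            seg.reference_id = 0
            seg.reference_start = start
            seg.cigarstring = cigar
            seg.flag = flag
            seg.mapping_quality = mapq
            seg.set_tags(list(tags))
            bam.write(seg)
    pysam.index(str(path))


class TestReadAlignments:
    def test_secondary_alignments_and_low_mapq_are_skipped(self, tmp_path):
        bam = tmp_path / "a.bam"
        _write_bam(bam, [
            ("r1", 50, "200M", 0, 60, []),
            ("r2", 80, "200M", 0x100, 60, []),   # secondary
            ("r3", 120, "200M", 0, 60, []),
            ("r4", 130, "200M", 0, 5, []),       # below MAPQ floor
        ])
        views = list(read_alignments(bam, region="chr1:100-200"))
        assert sorted(v.read_id for v in views) == ["r1", "r3"]

    def test_haplotype_tags_are_decoded(self, tmp_path):
        bam = tmp_path / "a.bam"
        _write_bam(bam, [("r1", 10, "100M", 0, 60,
                          [("HP", 1, "i"), ("PS", 77, "i"), ("PC", 1500.0, "f")])])
        (view,) = read_alignments(bam)
        assert (view.hp_tag, view.ps_tag, view.pc_tag) == (1, 77, 1500.0)

    def test_hp_without_ps_is_rejected(self, tmp_path, caplog):
        bam = tmp_path / "a.bam"
        _write_bam(bam, [("r1", 10, "100M", 0, 60, [("HP", 1, "i")])])
        with caplog.at_level("WARNING", logger="duophase"):
            (view,) = read_alignments(bam)
        assert view.hp_tag is None and view.ps_tag is None and view.pc_tag is None
        assert any("HP without PS" in m for m in caplog.messages)

    def test_pc_without_hp_is_dropped(self, tmp_path):
        bam = tmp_path / "a.bam"
        _write_bam(bam, [("r1", 10, "100M", 0, 60, [("PC", 900.0, "f")])])
        (view,) = read_alignments(bam)
        assert view.pc_tag is None

    def test_malformed_tag_treated_as_absent(self, tmp_path, caplog):
        bam = tmp_path / "a.bam"
        _write_bam(bam, [("r1", 10, "100M", 0, 60, [("HP", "weird", "Z"), ("PS", 3, "i")])])
        with caplog.at_level("WARNING", logger="duophase"):
            (view,) = read_alignments(bam)
        assert view.hp_tag is None

    def test_phased_read_without_pc_gets_zero_confidence(self, tmp_path):
        bam = tmp_path / "a.bam"
        _write_bam(bam, [("r1", 10, "100M", 0, 60, [("HP", 2, "i"), ("PS", 5, "i")])])
        (view,) = read_alignments(bam)
        assert view.pc_tag == 0.0

    def test_supplementary_inherits_primary_haplotype(self, tmp_path):
        bam = tmp_path / "a.bam"
        _write_bam(bam, [
            ("r1", 10, "100M100S", 0, 60,
             [("HP", 2, "i"), ("PS", 9, "i"), ("PC", 400.0, "f")]),
            ("r1", 500, "100S100M", 0x800, 60, []),
        ])
        views = {(v.ref_start, v.is_supplementary): v for v in read_alignments(bam)}
        supp = views[(500, True)]
        assert (supp.hp_tag, supp.ps_tag, supp.pc_tag) == (2, 9, 0.0)

    def test_region_query_without_index_is_actionable(self, tmp_path):
        sam = tmp_path / "a.sam"
        with pysam.AlignmentFile(str(sam), "w", header=HEADER) as fh:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = "r1"
            seg.reference_id = 0
            seg.reference_start = 10
            seg.cigarstring = "100M"
            seg.mapping_quality = 60
            fh.write(seg)
        with pytest.raises(ValueError, match="samtools index"):
            list(read_alignments(sam, region="chr1:1-100"))

    def test_sidecar_table_overrides_tags(self, tmp_path):
        bam = tmp_path / "a.bam"
        _write_bam(bam, [("r1", 10, "100M", 0, 60, [])])
        sidecar = tmp_path / "tags.tsv"
        sidecar.write_text("#read_id\thp\tps\tpc\nr1\tH2\t31\t2700\n")
        (view,) = read_alignments(bam, sidecar=sidecar)
        assert (view.hp_tag, view.ps_tag, view.pc_tag) == (2, 31, 2700.0)
        assert load_haplotag_table(sidecar)["r1"] == (2, 31, 2700.0)


class TestAlignedReadViewInvariants:
    def test_cigar_reference_length_must_match(self):
        with pytest.raises(ValueError, match="CIGAR"):
            AlignedReadView("r", "chr1", 0, 100, cigar=(("M", 50),))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"hp_tag": 1},                    # HP requires PS
            {"pc_tag": 5.0},                  # PC requires HP
            {"hp_tag": 3, "ps_tag": 1},       # HP outside {1,2}
        ],
    )
    def test_tag_invariants(self, kwargs):
        with pytest.raises(ValueError):
            AlignedReadView("r", "chr1", 0, 100, cigar=(("M", 100),), **kwargs)


VCF_TEMPLATE = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1,length=1000000>
    ##ALT=<ID=DEL,Description="Deletion">
    ##ALT=<ID=INS,Description="Insertion">
    ##INFO=<ID=SVTYPE,Number=1,Type=String,Description="x">
    ##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="x">
    ##INFO=<ID=END,Number=1,Type=Integer,Description="x">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="x">
    ##FORMAT=<ID=PS,Number=1,Type=Integer,Description="x">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
    """)


def _write_vcf(path, body_lines):
    path.write_text(VCF_TEMPLATE + "".join(line + "\n" for line in body_lines))


class TestReadSvVcf:
    def test_del_with_end_and_phased_gt(self, tmp_path):
        vcf = tmp_path / "a.vcf"
        _write_vcf(vcf, ["chr1\t1000\t.\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=1500\tGT:PS\t0|1:9"])
        (rec,) = read_sv_vcf(vcf)
        assert rec == TruthRecord("chr1", 1000, 500, "DEL", "0|1", 9)

    def test_non_ins_del_classes_are_skipped(self, tmp_path):
        vcf = tmp_path / "a.vcf"
        _write_vcf(vcf, [
            "chr1\t1000\t.\tN\t<INV>\t.\tPASS\tSVTYPE=INV;END=1500\tGT\t0/1",
            "chr1\t2000\t.\tN\t<INS>\t.\tPASS\tSVTYPE=INS;SVLEN=120\tGT\t0/1",
        ])
        records = read_sv_vcf(vcf)
        assert [r.base_t for r in records] == ["INS"]

    def test_negative_svlen_is_taken_absolute(self, tmp_path):
        vcf = tmp_path / "a.vcf"
        _write_vcf(vcf, ["chr1\t1000\t.\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;SVLEN=-300\tGT\t1/1"])
        (rec,) = read_sv_vcf(vcf)
        assert rec.base_L == 300

    def test_record_without_svlen_or_end_is_skipped(self, tmp_path):
        vcf = tmp_path / "a.vcf"
        _write_vcf(vcf, ["chr1\t1000\t.\tN\t<INS>\t.\tPASS\tSVTYPE=INS\tGT\t0/1"])
        assert read_sv_vcf(vcf) == []

    def test_unphased_genotype_is_recorded_unphased(self, tmp_path):
        vcf = tmp_path / "a.vcf"
        _write_vcf(vcf, ["chr1\t1000\t.\tN\t<INS>\t.\tPASS\tSVTYPE=INS;SVLEN=80\tGT\t0/1"])
        (rec,) = read_sv_vcf(vcf)
        assert rec.genotype == "0/1" and not rec.is_phased


class TestWritePhasedVcf:
    def test_het_call_serialises_gt_and_ps(self, tmp_path):
        call = PhasedCall("chr1", 999, 500, "DEL", "1|0", phase_set=9)
        out = tmp_path / "o.vcf"
        write_phased_vcf([call], ["chr1"], out)
        (rec,) = read_sv_vcf(out)
        assert rec == TruthRecord("chr1", 1000, 500, "DEL", "1|0", 9)

    def test_empty_call_list_gives_header_only_vcf(self, tmp_path):
        out = tmp_path / "o.vcf"
        write_phased_vcf([], ["chr1"], out)
        assert read_sv_vcf(out) == []
        assert out.read_text().startswith("##fileformat")

    def test_unsorted_input_is_an_error(self, tmp_path):
        calls = [
            PhasedCall("chr1", 5000, 100, "INS", "1|1", phase_set=1),
            PhasedCall("chr1", 1000, 100, "INS", "1|1", phase_set=1),
        ]
        with pytest.raises(ValueError, match="sorted"):
            write_phased_vcf(calls, ["chr1"], tmp_path / "o.vcf")

    def test_filtered_calls_are_excluded_by_default(self, tmp_path):
        calls = [
            PhasedCall("chr1", 1000, 100, "INS", "0/0"),
            PhasedCall("chr1", 5000, 100, "INS", "1|1", phase_set=1),
        ]
        out = tmp_path / "o.vcf"
        write_phased_vcf(calls, ["chr1"], out)
        assert len(read_sv_vcf(out)) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_roundtrip_identity_on_generated_truth_sets(self, tmp_path, seed):
        """write -> read is the identity on (chrom, start, length, type,
        genotype, phase set) for simulated diploid truth sets."""
        config = SimConfig(n_true_sv=40, seed=seed)
        records = simulate_truth_set(config)
        path = tmp_path / "truth.vcf"
        write_truth_vcf(records, ["chr1"], path)
        assert read_sv_vcf(path) == records

    def test_multi_contig_roundtrip_in_header_order(self, tmp_path):
        calls = [
            PhasedCall("chr2", 100, 60, "INS", "0|1", phase_set=4),
            PhasedCall("chr1", 200, 90, "DEL", "1|1", phase_set=1),
        ]
        calls.sort(key=lambda c: (["chr2", "chr1"].index(c.chrom), c.pos))
        out = tmp_path / "o.vcf"
        write_phased_vcf(calls, ["chr2", "chr1"], out)
        records = read_sv_vcf(out)
        assert [(r.chrom, r.base_s, r.base_L, r.base_t, r.genotype) for r in records] == [
            ("chr2", 101, 60, "INS", "0|1"),
            ("chr1", 201, 90, "DEL", "1|1"),
        ]
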