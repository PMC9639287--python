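"""Mark extraction, loose clustering, and signature collection."""

from __future__ import annotations

import numpy as np
import pytest

from duophase.formats_io import AlignedReadView
from duophase.sv_signatures import (
    ClusterParams,
    ReadSignature,
    SVCandidate,
    SVMark,
    cluster_candidates,
    collect_signatures,
    extract_split_marks,
    extract_sv_marks,
)

from oracles import brute_force_clusters


def read_view(read_id, cigar, ref_start=0, chrom="chr1", **kwargs):
    ref_len = sum(ln for op, ln in cigar if op in "MDN=X")
    return AlignedReadView(read_id, chrom, ref_start, ref_start + ref_len,
                           cigar=tuple(cigar), **kwargs)


class TestExtractSvMarks:
    def test_deletion_operation_yields_del_mark(self):
        read = read_view("r1", [("M", 100), ("D", 50), ("M", 100)], ref_start=1000)
        (mark,) = extract_sv_marks(read, min_sv_size=30)
        assert (mark.pos, mark.length, mark.sv_type) == (1100, 50, "DEL")

    def test_operations_below_size_floor_are_ignored(self):
        read = read_view("r1", [("M", 100), ("I", 20), ("M", 100)])
        assert extract_sv_marks(read, min_sv_size=30) == []

    def test_mixed_cigar_coordinate_walk(self):
        # manual walk: 50M advances ref to 50 (INS point), 40I consumes no
        # reference, 50M advances to 100 (DEL start), 35D spans 100-135
        read = read_view("r1", [("M", 50), ("I", 40), ("M", 50), ("D", 35), ("M", 50)])
        marks = extract_sv_marks(read, min_sv_size=30)
        assert [(m.sv_type, m.pos, m.length) for m in marks] == [
            ("INS", 50, 40), ("DEL", 100, 35)]

    def test_marks_lie_within_read_reference_span(self, rng):
        """Every mark's position falls in [ref_start, ref_end)."""
        ops = ["M", "I", "D"]
        for _ in range(300):
            cigar = [("M", int(rng.integers(1, 200)))]
            for _ in range(int(rng.integers(0, 6))):
                cigar.append((ops[int(rng.integers(0, 3))], int(rng.integers(1, 120))))
            cigar.append(("M", int(rng.integers(1, 200))))
            start = int(rng.integers(0, 10000))
            read = read_view("r", cigar, ref_start=start)
            for mark in extract_sv_marks(read, min_sv_size=30):
                assert read.ref_start <= mark.pos < read.ref_end


class TestExtractSplitMarks:
    def test_reference_gap_becomes_deletion(self):
        a = read_view("r1", [("M", 500), ("S", 500)], ref_start=1000)
        b = read_view("r1", [("S", 500), ("M", 500)], ref_start=1900, is_supplementary=True)
        (mark,) = extract_split_marks([a, b], min_sv_size=30)
        assert (mark.sv_type, mark.pos, mark.length, mark.source) == ("DEL", 1500, 400, "split")

    def test_contiguous_segments_yield_nothing(self):
        a = read_view("r1", [("M", 500), ("S", 500)], ref_start=1000)
        b = read_view("r1", [("S", 500), ("M", 500)], ref_start=1500, is_supplementary=True)
        assert extract_split_marks([a, b]) == []

    def test_unaligned_read_bases_become_insertion(self):
        a = read_view("r1", [("M", 400), ("S", 600)], ref_start=1000)
        b = read_view("r1", [("S", 500), ("M", 500)], ref_start=1400, is_supplementary=True)
        (mark,) = extract_split_marks([a, b], min_sv_size=30)
        assert (mark.sv_type, mark.pos, mark.length) == ("INS", 1400, 100)

    def test_segments_on_different_chromosomes_yield_nothing(self):
        a = read_view("r1", [("M", 500), ("S", 500)], ref_start=1000, chrom="chr1")
        b = read_view("r1", [("S", 500), ("M", 500)], ref_start=1900, chrom="chr2",
                      is_supplementary=True)
        assert extract_split_marks([a, b]) == []

    def test_distant_joins_are_suppressed(self):
        a = read_view("r1", [("M", 500), ("S", 500)], ref_start=1000)
        b = read_view("r1", [("S", 500), ("M", 500)], ref_start=500_000,
                      is_supplementary=True)
        assert extract_split_marks([a, b], max_split_gap=100_000) == []


def mk(read_id, pos, length, sv_type="DEL", chrom="chr1"):
    return SVMark(read_id, chrom, pos, length, sv_type)


class TestClusterCandidates:
    def test_nearby_similar_marks_merge_with_median_summary(self):
        marks = [mk("r1", 1000, 300), mk("r2", 1050, 320), mk("r3", 1080, 310)]
        (cand,) = cluster_candidates(marks)
        assert (cand.comp_s, cand.comp_L, cand.comp_t) == (1050, 310, "DEL")

    def test_distant_singletons_are_dropped(self):
        marks = [mk("r1", 1000, 300), mk("r2", 1500, 300)]
        assert cluster_candidates(marks) == []

    def test_length_ratio_blocks_merging(self):
        marks = [mk("r1", 1000, 100, "INS"), mk("r2", 1000, 400, "INS")]
        # |100-400|/400 = 0.75 > 0.3: two singletons, both below support 2
        assert cluster_candidates(marks) == []

    def test_same_read_marks_count_as_single_support(self):
        marks = [mk("r1", 1000, 300), mk("r1", 1050, 310)]
        assert cluster_candidates(marks) == []

    def test_matches_brute_force_connected_components(self, rng):
        """Single-linkage output equals exhaustive pairwise clustering."""
        for _ in range(200):
            n = int(rng.integers(1, 21))
            marks = [
                mk(f"r{i}", int(rng.integers(0, 1500)), int(rng.integers(50, 800)),
                   str(rng.choice(["INS", "DEL"])))
                for i in range(n)
            ]
            marks.sort(key=lambda m: m.pos)
            expected = {
                frozenset((m.pos, m.length, m.sv_type, m.read_id) for i in comp
                          for m in [marks[i]])
                for comp in brute_force_clusters(marks)
                if len({marks[i].read_id for i in comp}) >= 2
            }
            got = {
                frozenset((m.pos, m.length, m.sv_type, m.read_id) for m in cand.marks)
                for cand in cluster_candidates(marks)
            }
            assert got == expected

    def test_supporting_reads_never_exceed_mark_carrying_reads(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 25))
            marks = sorted(
                (mk(f"r{int(rng.integers(0, 8))}", int(rng.integers(0, 2000)),
                    int(rng.integers(50, 400))) for _ in range(n)),
                key=lambda m: m.pos,
            )
            candidates = cluster_candidates(marks)
            supporting = set()
            for cand in candidates:
                supporting |= {m.read_id for m in cand.marks}
            assert len(supporting) <= len({m.read_id for m in marks})


class TestCollectSignatures:
    @staticmethod
    def _spanning_read(read_id, pos, hp=None, ps=None, pc=None):
        kwargs = {}
        if hp is not None:
            kwargs = {"hp_tag": hp, "ps_tag": ps or 1, "pc_tag": pc or 0.0}
        return read_view(read_id, [("M", 2000)], ref_start=pos - 1000, **kwargs)

    def test_signature_assembly_counts_marks_per_read(self):
        cand = SVCandidate("chr1", 5000, 100, "INS", marks=(
            mk("r1", 5000, 100, "INS"), mk("r1", 5020, 100, "INS"),
            mk("r2", 5010, 110, "INS"),
        ))
        reads = [self._spanning_read(f"r{i}", 5000, hp=1 if i <= 2 else None)
                 for i in range(1, 6)]
        filled = collect_signatures(cand, reads)
        by_id = {s.read_id: s for s in filled.signatures}
        assert len(filled.signatures) == 5
        assert by_id["r1"].vc == 2 and by_id["r2"].vc == 1
        assert all(by_id[f"r{i}"].vc == 0 for i in (3, 4, 5))
        assert by_id["r1"].hp == 1 and by_id["r4"].hp is None

    def test_candidate_without_spanning_support_is_discarded(self):
        cand = SVCandidate("chr1", 5000, 100, "INS", marks=(mk("r9", 5000, 100, "INS"),))
        reads = [self._spanning_read("r1", 5000)]  # r9 itself does not span
        assert collect_signatures(cand, reads) is None

    def test_read_ending_before_locus_is_excluded(self):
        cand = SVCandidate("chr1", 5000, 100, "INS", marks=(mk("r1", 5000, 100, "INS"),))
        near_miss = read_view("r2", [("M", 1000)], ref_start=3900)  # ends at 4900 < comp_s
        reads = [self._spanning_read("r1", 5000), near_miss]
        filled = collect_signatures(cand, reads)
        assert [s.read_id for s in filled.signatures] == ["r1"]


class TestReadSignatureInvariants:
    def test_unphased_signature_cannot_carry_confidence(self):
        with pytest.raises(ValueError):
            ReadSignature("r", hp=None, pc=5.0, vc=0)

    def test_unphased_signature_cannot_carry_phase_set(self):
        with pytest.raises(ValueError):
            ReadSignature("r", hp=None, pc=0.0, vc=0, phase_set=1)
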