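"""SV mark detection, loose clustering into candidates, and per-read signatures.

An *SV mark* is an intra-read (CIGAR I/D operation) or split-read alignment
signature indicating a putative insertion or deletion on one read.  Marks
from many reads are clustered with the loose single-linkage rule used by
long-read SV callers (position distance within a per-type bias, relative
length difference within a per-type ratio), and each surviving cluster
becomes an :class:`SVCandidate`.  Every read spanning the candidate locus
then contributes one :class:`ReadSignature`: its haplotype (HP), phasing
confidence (PC) and the count of its marks in the cluster (VC).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .formats_io import (
    DEFAULT_MIN_SV_SIZE,
    AlignedReadView,
    QUERY_CONSUMING,
)

logger = logging.getLogger("duophase")

#: half-width of the window a read's primary alignment must cover on the left
#: of the candidate start (and, type-dependently, on the right) to count as
#: spanning the locus.
SPAN_WINDOW = 50

DEFAULT_FLANK = 500
DEFAULT_MAX_SPLIT_GAP = 100_000


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SVMark:
    """One putative SV event observed on one read."""

    read_id: str
    chrom: str
    pos: int          # 0-based reference coordinate of the event
    length: int       # bp, > 0
    sv_type: str      # INS | DEL
    source: str = "cigar"  # cigar | split

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("mark length must be positive")
        if self.sv_type not in ("INS", "DEL"):
            raise ValueError(f"sv_type must be INS or DEL, got {self.sv_type!r}")


@dataclass(frozen=True)
class ReadSignature:
    """The (HP, PC, VC) triple of one read at one candidate locus.

    ``hp`` is 1, 2 or ``None`` (unphased).  Unphased reads carry no phasing
    confidence and no phase set by construction.
    """

    read_id: str
    hp: Optional[int]
    pc: float
    vc: int
    phase_set: Optional[int] = None

    def __post_init__(self) -> None:
        if self.hp is not None and self.hp not in (1, 2):
            raise ValueError("hp must be 1, 2 or None")
        if self.hp is None and (self.pc != 0 or self.phase_set is not None):
            raise ValueError("unphased signature must have pc=0 and no phase set")
        if self.pc < 0 or self.vc < 0:
            raise ValueError("pc and vc must be non-negative")


@dataclass(frozen=True)
class SVCandidate:
    """A clustered putative SV with (optionally) its supporting-read signatures.

    ``comp_s``/``comp_L``/``comp_t`` summarise the member marks (medians,
    lower of the two middle values on even counts, for determinism).
    """

    chrom: str
    comp_s: int
    comp_L: int
    comp_t: str
    signatures: tuple[ReadSignature, ...] = ()
    marks: tuple[SVMark, ...] = ()

    @property
    def n_support(self) -> int:
        return sum(1 for s in self.signatures if s.vc > 0)


@dataclass(frozen=True)
class ClusterParams:
    """Loose clustering parameters (per-type bias/ratio, minimum support)."""

    bias_ins: int = 100
    bias_del: int = 200
    diff_ratio_ins: float = 0.3
    diff_ratio_del: float = 0.5
    min_support: int = 2

    def bias(self, sv_type: str) -> int:
        return self.bias_ins if sv_type == "INS" else self.bias_del

    def diff_ratio(self, sv_type: str) -> float:
        return self.diff_ratio_ins if sv_type == "INS" else self.diff_ratio_del


# ---------------------------------------------------------------------------
# mark extraction
# ---------------------------------------------------------------------------


def extract_sv_marks(read: AlignedReadView, min_sv_size: int = DEFAULT_MIN_SV_SIZE) -> list[SVMark]:
    """Detect intra-read SV marks from the CIGAR string.

    One INS mark per insertion operation >= ``min_sv_size`` (at the reference
    coordinate of the insertion point) and one DEL mark per deletion
    operation >= ``min_sv_size`` (at the deletion start).  Marks are returned
    ordered by position.
    """
    marks: list[SVMark] = []
    ref = read.ref_start
    for op, length in read.cigar:
        if op == "I":
            if length >= min_sv_size:
                marks.append(SVMark(read.read_id, read.chrom, ref, length, "INS"))
        elif op in ("D", "N"):
            if op == "D" and length >= min_sv_size:
                marks.append(SVMark(read.read_id, read.chrom, ref, length, "DEL"))
            ref += length
        elif op in ("M", "=", "X"):
            ref += length
    return marks


def _query_interval(seg: AlignedReadView) -> tuple[int, int]:
    """Interval of the original read covered by this alignment segment."""
    ops = seg.cigar
    lead = 0
    for op, ln in ops:
        if op in ("S", "H"):
            lead += ln
        else:
            break
    trail = 0
    for op, ln in reversed(ops):
        if op in ("S", "H"):
            trail += ln
        else:
            break
    aligned = sum(ln for op, ln in ops if op in QUERY_CONSUMING and op != "S")
    start = trail if seg.is_reverse else lead
    return start, start + aligned


def extract_split_marks(
    segments: Sequence[AlignedReadView],
    min_sv_size: int = DEFAULT_MIN_SV_SIZE,
    max_split_gap: int = DEFAULT_MAX_SPLIT_GAP,
) -> list[SVMark]:
    """Detect split-read SV marks from the primary + supplementary segments
    of one read.

    Adjacent segment pairs (ordered along the read) with a reference gap
    exceeding the read gap by >= ``min_sv_size`` yield a DEL mark at the
    inner junction; the converse yields an INS mark.  Pairs on different
    chromosomes/strands, or further apart on the reference than
    ``max_split_gap``, produce no mark.
    """
    if len(segments) < 2:
        return []
    ordered = sorted(segments, key=lambda s: _query_interval(s)[0])
    marks: list[SVMark] = []
    for a, b in zip(ordered, ordered[1:]):
        if a.chrom != b.chrom or a.is_reverse != b.is_reverse:
            continue
        ref_gap = b.ref_start - a.ref_end
        if abs(ref_gap) > max_split_gap:
            continue
        a_q = _query_interval(a)
        b_q = _query_interval(b)
        read_gap = b_q[0] - a_q[1]
        delta = ref_gap - read_gap
        junction = min(a.ref_end, b.ref_start)
        if delta >= min_sv_size:
            marks.append(SVMark(a.read_id, a.chrom, a.ref_end, delta, "DEL", "split"))
        elif -delta >= min_sv_size:
            marks.append(SVMark(a.read_id, a.chrom, junction, -delta, "INS", "split"))
    marks.sort(key=lambda m: m.pos)
    return marks


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def _lower_median(values: Sequence[int]) -> int:
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def marks_link(a: SVMark, b: SVMark, params: ClusterParams) -> bool:
    """The pairwise merge rule: same chrom/type, close positions, similar lengths."""
    if a.chrom != b.chrom or a.sv_type != b.sv_type:
        return False
    if abs(a.pos - b.pos) > params.bias(a.sv_type):
        return False
    ratio = abs(a.length - b.length) / max(a.length, b.length)
    return ratio <= params.diff_ratio(a.sv_type)


def cluster_candidates(
    marks: Sequence[SVMark],
    params: ClusterParams = ClusterParams(),
) -> list[SVCandidate]:
    """Single-linkage clustering of marks into SV candidates.

    Two marks join when their positions differ by at most the per-type bias
    AND their relative length difference is within the per-type ratio.
    Clusters supported by fewer than ``params.min_support`` distinct reads
    are dropped.  Signatures are not yet attached.
    """
    groups: dict[tuple[str, str], list[SVMark]] = defaultdict(list)
    for mark in marks:
        groups[(mark.chrom, mark.sv_type)].append(mark)

    candidates: list[SVCandidate] = []
    for (chrom, sv_type), members in groups.items():
        members.sort(key=lambda m: m.pos)
        bias = params.bias(sv_type)
        uf = _UnionFind(len(members))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if members[j].pos - members[i].pos > bias:
                    break
                if marks_link(members[i], members[j], params):
                    uf.union(i, j)
        clusters: dict[int, list[SVMark]] = defaultdict(list)
        for i, mark in enumerate(members):
            clusters[uf.find(i)].append(mark)
        for cluster in clusters.values():
            reads = {m.read_id for m in cluster}
            if len(reads) < params.min_support:
                continue
            candidates.append(
                SVCandidate(
                    chrom=chrom,
                    comp_s=_lower_median([m.pos for m in cluster]),
                    comp_L=_lower_median([m.length for m in cluster]),
                    comp_t=sv_type,
                    marks=tuple(sorted(cluster, key=lambda m: (m.pos, m.read_id))),
                )
            )
    candidates.sort(key=lambda c: (c.chrom, c.comp_s))
    return candidates


# ---------------------------------------------------------------------------
# signature collection
# ---------------------------------------------------------------------------


def span_window(candidate: SVCandidate) -> tuple[int, int]:
    """Reference points a primary alignment must cover to span the locus."""
    left = candidate.comp_s - SPAN_WINDOW
    if candidate.comp_t == "DEL":
        right = candidate.comp_s + min(candidate.comp_L, SPAN_WINDOW)
    else:
        right = candidate.comp_s + SPAN_WINDOW
    return left, right


def collect_signatures(
    candidate: SVCandidate,
    alignments: Iterable[AlignedReadView],
    flank: int = DEFAULT_FLANK,
) -> Optional[SVCandidate]:
    """Attach one :class:`ReadSignature` per read spanning the candidate locus.

    ``vc`` is the count of the read's marks assigned to this candidate's
    cluster; haplotype/confidence/phase-set come from the read's primary
    alignment tags.  Returns ``None`` (with a log entry) when no spanning
    read supports the candidate, which violates the candidate invariant.
    """
    left, right = span_window(candidate)
    lo = candidate.comp_s - flank
    hi = candidate.comp_s + candidate.comp_L + flank

    vc_by_read: dict[str, int] = defaultdict(int)
    for mark in candidate.marks:
        vc_by_read[mark.read_id] += 1

    signatures: list[ReadSignature] = []
    seen: set[str] = set()
    for view in alignments:
        if view.is_supplementary or view.chrom != candidate.chrom:
            continue
        if view.ref_end <= lo or view.ref_start >= hi:
            continue
        if view.read_id in seen:
            continue
        if not (view.ref_start <= left and view.ref_end > right):
            continue  # does not span both sides of the locus
        seen.add(view.read_id)
        hp = view.hp_tag
        signatures.append(
            ReadSignature(
                read_id=view.read_id,
                hp=hp,
                pc=(view.pc_tag or 0.0) if hp is not None else 0.0,
                vc=vc_by_read.get(view.read_id, 0),
                phase_set=view.ps_tag if hp is not None else None,
            )
        )
    signatures.sort(key=lambda s: s.read_id)
    if not any(s.vc > 0 for s in signatures):
        logger.info(
            "candidate %s:%d %s has no spanning supporting read; discarded",
            candidate.chrom, candidate.comp_s, candidate.comp_t,
        )
        return None
    return replace(candidate, signatures=tuple(signatures))


# ---------------------------------------------------------------------------
# convenience: reads -> candidates with signatures
# ---------------------------------------------------------------------------


class _ReadIndex:
    """Per-chromosome start-sorted read index for windowed spanning queries."""

    def __init__(self, reads: Iterable[AlignedReadView]):
        self._by_chrom: dict[str, list[AlignedReadView]] = defaultdict(list)
        for read in reads:
            self._by_chrom[read.chrom].append(read)
        self._starts: dict[str, list[int]] = {}
        self._max_span: dict[str, int] = {}
        for chrom, views in self._by_chrom.items():
            views.sort(key=lambda v: v.ref_start)
            self._starts[chrom] = [v.ref_start for v in views]
            self._max_span[chrom] = max(v.ref_end - v.ref_start for v in views)

    def overlapping(self, chrom: str, lo: int, hi: int) -> list[AlignedReadView]:
        import bisect

        views = self._by_chrom.get(chrom)
        if not views:
            return []
        starts = self._starts[chrom]
        left = bisect.bisect_left(starts, lo - self._max_span[chrom])
        right = bisect.bisect_right(starts, hi)
        return [v for v in views[left:right] if v.ref_end > lo and v.ref_start < hi]


def generate_candidates(
    reads: Sequence[AlignedReadView],
    *,
    min_sv_size: int = DEFAULT_MIN_SV_SIZE,
    params: ClusterParams = ClusterParams(),
    flank: int = DEFAULT_FLANK,
    max_split_gap: int = DEFAULT_MAX_SPLIT_GAP,
) -> list[SVCandidate]:
    """Full detection pass: marks (CIGAR + split) -> clusters -> signatures."""
    marks: list[SVMark] = []
    by_read: dict[str, list[AlignedReadView]] = defaultdict(list)
    for read in reads:
        marks.extend(extract_sv_marks(read, min_sv_size))
        by_read[read.read_id].append(read)
    for segments in by_read.values():
        if len(segments) > 1:
            marks.extend(extract_split_marks(segments, min_sv_size, max_split_gap))
    marks.sort(key=lambda m: (m.chrom, m.pos))

    index = _ReadIndex(reads) if reads else None
    out: list[SVCandidate] = []
    for candidate in cluster_candidates(marks, params):
        window = index.overlapping(
            candidate.chrom,
            candidate.comp_s - flank,
            candidate.comp_s + candidate.comp_L + flank,
        )
        filled = collect_signatures(candidate, window, flank)
        if filled is not None:
            out.append(filled)
    return out


def candidates_to_bed(candidates: Sequence[SVCandidate], path) -> None:
    """Export candidate loci as 0-based half-open BED for inspection."""
    with open(path, "w") as fh:
        for cand in candidates:
            end = cand.comp_s + (cand.comp_L if cand.comp_t == "DEL" else 1)
            fh.write(
                f"{cand.chrom}\t{cand.comp_s}\t{end}\t{cand.comp_t}"
                f"\t{cand.comp_L}\t{cand.n_support}\n"
            )
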