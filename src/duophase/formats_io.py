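"""Alignment and VCF I/O for haplotagged long-read SV phasing.

This module is the boundary between the on-disk formats (coordinate-sorted
BAM/SAM with per-read haplotype tags, SV VCFs) and the in-memory types the
rest of the pipeline works with.

Conventions
-----------
* Internal coordinates are 0-based half-open; VCF I/O converts to/from
  1-based starts at this boundary.
* A read's haplotype is carried in the standard ``HP`` tag (1 or 2) with its
  phase-set block in ``PS``.  The per-read phasing confidence -- a score
  positively related to the number of accurately phased heterozygous SNPs the
  read covers -- is not a standard SAM field; it is read from a configurable
  numeric tag (default ``PC``) or from a sidecar haplotag table
  (``read_id  hp  ps  pc``), so output of external haplotaggers can be
  adapted without retagging the BAM.
* Tag sanity is enforced here: ``HP`` without ``PS`` is dropped with a
  warning, ``PC`` without ``HP`` is dropped, and ``HP`` without ``PC`` gets a
  conservative confidence of 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import pysam

logger = logging.getLogger("duophase")

DEFAULT_MIN_MAPQ = 20
DEFAULT_MIN_SV_SIZE = 30
DEFAULT_PC_TAG = "PC"

#: CIGAR operation classes (character codes as stored in AlignedReadView).
REF_CONSUMING = frozenset("MDN=X")
QUERY_CONSUMING = frozenset("MIS=X")
_CIGAR_CODES = "MIDNSHP=XB"

PathLike = Union[str, Path]


def setup_logging(level: str = "INFO") -> None:
    """Configure package logging (used by the CLI; library callers may skip)."""
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignedReadView:
    """A minimal, validated view of one alignment record.

    ``cigar`` is a tuple of ``(op, length)`` pairs with ``op`` a CIGAR
    character.  Reference-consuming lengths must sum to
    ``ref_end - ref_start``.  Tag invariants: ``hp_tag`` implies ``ps_tag``;
    ``pc_tag`` implies ``hp_tag``.
    """

    read_id: str
    chrom: str
    ref_start: int
    ref_end: int
    cigar: tuple[tuple[str, int], ...] = ()
    is_supplementary: bool = False
    is_reverse: bool = False
    mapq: int = 60
    hp_tag: Optional[int] = None
    ps_tag: Optional[int] = None
    pc_tag: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ref_start >= self.ref_end:
            raise ValueError(
                f"{self.read_id}: ref_start {self.ref_start} >= ref_end {self.ref_end}"
            )
        if self.cigar:
            ref_len = sum(ln for op, ln in self.cigar if op in REF_CONSUMING)
            if ref_len != self.ref_end - self.ref_start:
                raise ValueError(
                    f"{self.read_id}: CIGAR reference length {ref_len} != "
                    f"{self.ref_end - self.ref_start}"
                )
        if self.hp_tag is not None and self.hp_tag not in (1, 2):
            raise ValueError(f"{self.read_id}: hp_tag must be 1 or 2")
        if self.hp_tag is not None and self.ps_tag is None:
            raise ValueError(f"{self.read_id}: hp_tag requires ps_tag")
        if self.pc_tag is not None and self.hp_tag is None:
            raise ValueError(f"{self.read_id}: pc_tag requires hp_tag")
        if self.pc_tag is not None and self.pc_tag < 0:
            raise ValueError(f"{self.read_id}: pc_tag must be non-negative")


@dataclass(frozen=True)
class TruthRecord:
    """One SV record (truth-set entry or parsed call).

    ``base_s`` is the 1-based start, ``base_L`` the length in bp and
    ``base_t`` the class (INS/DEL).  ``genotype`` uses VCF notation:
    ``0/1`` unphased het, ``1|0``/``0|1`` phased het, ``1|1``/``1/1``
    homozygous, ``0/0`` filtered.
    """

    chrom: str
    base_s: int
    base_L: int
    base_t: str
    genotype: str = "1/1"
    phase_set: Optional[int] = None

    def __post_init__(self) -> None:
        if self.base_L <= 0:
            raise ValueError(f"SV length must be positive, got {self.base_L}")
        if self.base_t not in ("INS", "DEL"):
            raise ValueError(f"SV class must be INS or DEL, got {self.base_t!r}")

    @property
    def is_phased(self) -> bool:
        return "|" in self.genotype

    @property
    def gt_class(self) -> str:
        """Collapse the genotype to ``ref``, ``het`` or ``hom``."""
        alleles = {a for a in self.genotype.replace("|", "/").split("/") if a != "."}
        if alleles == {"0", "1"}:
            return "het"
        if alleles == {"1"}:
            return "hom"
        return "ref"


# ---------------------------------------------------------------------------
# alignment reading
# ---------------------------------------------------------------------------


def load_haplotag_table(path: PathLike) -> dict[str, tuple[Optional[int], Optional[int], float]]:
    """Parse a sidecar haplotag table: ``read_id  hp  ps  pc`` (tab-separated).

    ``hp`` accepts 1/2, H1/H2 or ``none``; missing fields are tolerated.
    Returns ``{read_id: (hp, ps, pc)}``.
    """
    table: dict[str, tuple[Optional[int], Optional[int], float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            read_id = parts[0]
            hp: Optional[int] = None
            ps: Optional[int] = None
            pc = 0.0
            if len(parts) > 1 and parts[1] not in ("", "none", "NA", "."):
                raw = parts[1].upper().lstrip("H")
                if raw in ("1", "2"):
                    hp = int(raw)
            if len(parts) > 2 and parts[2] not in ("", "none", "NA", "."):
                try:
                    ps = int(parts[2])
                except ValueError:
                    ps = None
            if len(parts) > 3 and parts[3] not in ("", "none", "NA", "."):
                try:
                    pc = float(parts[3])
                except ValueError:
                    pc = 0.0
            table[read_id] = (hp, ps, pc)
    return table


def _decode_tag(aln: pysam.AlignedSegment, tag: str, caster):
    try:
        value = aln.get_tag(tag)
    except KeyError:
        return None
    try:
        return caster(value)
    except (TypeError, ValueError):
        logger.warning(
            "read %s: malformed %s tag %r; treating as absent", aln.query_name, tag, value
        )
        return None


def _parse_region(region: Union[str, tuple, None]):
    if region is None:
        return None
    if isinstance(region, str):
        if ":" not in region:
            return (region, None, None)
        chrom, _, span = region.partition(":")
        start, _, end = span.partition("-")
        return (chrom, int(start.replace(",", "")) - 1, int(end.replace(",", "")))
    return tuple(region)


def read_alignments(
    path: PathLike,
    region: Union[str, tuple, None] = None,
    *,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    pc_tag: str = DEFAULT_PC_TAG,
    sidecar: Union[PathLike, Mapping, None] = None,
) -> Iterator[AlignedReadView]:
    """Stream validated alignment views from a BAM/SAM file.

    Secondary alignments, unmapped reads and reads below ``min_mapq`` are
    skipped.  Supplementary alignments missing haplotype tags inherit HP/PS
    from their primary (confidence 0), so split-read SV marks keep their
    haplotype context.  ``region`` is ``"chrom:start-end"`` (1-based,
    inclusive) and requires an index.
    """
    if sidecar is not None and not isinstance(sidecar, Mapping):
        sidecar = load_haplotag_table(sidecar)

    reg = _parse_region(region)
    afile = pysam.AlignmentFile(str(path))
    try:
        if reg is None:
            segments = [s for s in afile]
        else:
            try:
                segments = list(afile.fetch(*reg))
            except ValueError as exc:
                raise ValueError(
                    f"region query on {path} requires a coordinate-sorted, indexed "
                    f"file; run 'samtools index' first ({exc})"
                ) from exc
    finally:
        afile.close()

    kept: list[tuple[pysam.AlignedSegment, dict]] = []
    primary_tags: dict[str, tuple[Optional[int], Optional[int]]] = {}
    for seg in segments:
        if seg.is_unmapped or seg.is_secondary:
            continue
        if seg.mapping_quality < min_mapq:
            continue
        hp = _decode_tag(seg, "HP", int)
        ps = _decode_tag(seg, "PS", int)
        pc = _decode_tag(seg, pc_tag, float)
        if sidecar is not None and seg.query_name in sidecar:
            s_hp, s_ps, s_pc = sidecar[seg.query_name]
            if s_hp is not None:
                hp, ps, pc = s_hp, s_ps, s_pc
        if hp is not None and hp not in (1, 2):
            logger.warning("read %s: HP=%s outside {1,2}; treated as unphased", seg.query_name, hp)
            hp = None
        if hp is not None and ps is None:
            logger.warning("read %s: HP without PS; haplotype tag rejected", seg.query_name)
            hp = None
        if pc is not None and hp is None:
            logger.warning("read %s: PC without HP; confidence dropped", seg.query_name)
            pc = None
        if hp is None:
            ps = None
            pc = None
        elif pc is None:
            pc = 0.0  # phased but unscored: conservative zero weight
        kept.append((seg, {"hp": hp, "ps": ps, "pc": pc}))
        if not seg.is_supplementary and hp is not None:
            primary_tags[seg.query_name] = (hp, ps)

    for seg, tags in kept:
        hp, ps, pc = tags["hp"], tags["ps"], tags["pc"]
        if seg.is_supplementary and hp is None and seg.query_name in primary_tags:
            hp, ps = primary_tags[seg.query_name]
            pc = 0.0
        cigar = tuple(
            (_CIGAR_CODES[op], ln) for op, ln in (seg.cigartuples or ())
        )
        yield AlignedReadView(
            read_id=seg.query_name,
            chrom=seg.reference_name,
            ref_start=seg.reference_start,
            ref_end=seg.reference_end,
            cigar=cigar,
            is_supplementary=seg.is_supplementary,
            is_reverse=seg.is_reverse,
            mapq=seg.mapping_quality,
            hp_tag=hp,
            ps_tag=ps,
            pc_tag=pc,
        )


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------


def _scalar(value):
    if isinstance(value, (tuple, list)):
        return value[0]
    return value


def read_sv_vcf(path: PathLike, *, min_sv_size: int = 1) -> list[TruthRecord]:
    """Parse INS/DEL records from an SV VCF into :class:`TruthRecord` rows.

    Length is ``|SVLEN|`` when present, otherwise ``END - POS`` for
    deletions.  Records of other SV classes, or lacking both SVLEN and END,
    are skipped (counts logged).  Phased ``a|b`` genotypes keep their PS;
    ``a/b`` is recorded unphased.
    """
    records: list[TruthRecord] = []
    skipped_class = 0
    skipped_len = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            svtype = _scalar(rec.info.get("SVTYPE"))
            if svtype not in ("INS", "DEL"):
                skipped_class += 1
                continue
            svlen = rec.info.get("SVLEN")
            if svlen is not None:
                length = abs(int(_scalar(svlen)))
            elif svtype == "DEL" and rec.stop is not None and rec.stop > rec.pos:
                length = rec.stop - rec.pos
            else:
                logger.warning(
                    "%s:%d: record lacks both SVLEN and END; skipped", rec.chrom, rec.pos
                )
                skipped_len += 1
                continue
            if length < min_sv_size:
                skipped_len += 1
                continue
            genotype = "1/1"
            phase_set: Optional[int] = None
            if len(rec.samples) > 0:
                sample = rec.samples[0]
                gt = sample.get("GT")
                if gt is not None and None not in gt:
                    sep = "|" if sample.phased else "/"
                    genotype = sep.join(str(a) for a in gt)
                ps = sample.get("PS")
                if ps is not None:
                    phase_set = int(_scalar(ps))
            records.append(
                TruthRecord(
                    chrom=rec.chrom,
                    base_s=rec.pos,
                    base_L=length,
                    base_t=svtype,
                    genotype=genotype,
                    phase_set=phase_set,
                )
            )
    if skipped_class or skipped_len:
        logger.info(
            "read_sv_vcf(%s): skipped %d non-INS/DEL and %d unusable/short records",
            path, skipped_class, skipped_len,
        )
    return records


# ---------------------------------------------------------------------------
# VCF writing
# ---------------------------------------------------------------------------


def _sv_header(
    reference_names: Sequence[str],
    contig_lengths: Optional[Mapping[str, int]],
    with_features: bool,
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name in reference_names:
        if contig_lengths and name in contig_lengths:
            header.contigs.add(name, length=contig_lengths[name])
        else:
            header.contigs.add(name)
    header.add_line('##ALT=<ID=DEL,Description="Deletion">')
    header.add_line('##ALT=<ID=INS,Description="Insertion">')
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV class">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End coordinate">')
    if with_features:
        header.add_line('##INFO=<ID=PSV,Number=1,Type=Float,Description="Fraction of spanning reads with SV marks">')
        header.add_line('##INFO=<ID=PHP,Number=1,Type=Float,Description="Fraction of supporting reads that are phasable">')
        header.add_line('##INFO=<ID=SPC1,Number=1,Type=Float,Description="Total weighted phasing confidence, haplotype 1">')
        header.add_line('##INFO=<ID=SPC2,Number=1,Type=Float,Description="Total weighted phasing confidence, haplotype 2">')
        header.add_line('##INFO=<ID=LAYER,Number=1,Type=Integer,Description="Decision layer that fired">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">')
    header.add_sample("SAMPLE")
    return header


def _gt_tuple(genotype: str) -> tuple[tuple[int, ...], bool]:
    phased = "|" in genotype
    alleles = tuple(int(a) for a in genotype.replace("|", "/").split("/"))
    return alleles, phased


def _emit_record(out: pysam.VariantFile, header, chrom, start0, length, svtype,
                 genotype, phase_set, info_extra=None) -> None:
    stop = start0 + length if svtype == "DEL" else start0 + 1
    rec = out.new_record(
        contig=chrom,
        start=start0,
        stop=stop,
        alleles=("N", f"<{svtype}>"),
    )
    rec.info["SVTYPE"] = svtype
    rec.info["SVLEN"] = -length if svtype == "DEL" else length
    if info_extra:
        for key, value in info_extra.items():
            rec.info[key] = value
    alleles, phased = _gt_tuple(genotype)
    sample = rec.samples["SAMPLE"]
    sample["GT"] = alleles
    sample.phased = phased
    if phased and phase_set is not None:
        sample["PS"] = int(phase_set)
    out.write(rec)


def _check_sorted(rows: Sequence[tuple[str, int]], reference_names: Sequence[str]) -> None:
    order = {name: i for i, name in enumerate(reference_names)}
    keys = []
    for chrom, pos in rows:
        if chrom not in order:
            raise ValueError(f"contig {chrom!r} not in reference_names")
        keys.append((order[chrom], pos))
    if keys != sorted(keys):
        raise ValueError("records must be sorted by (contig order, position)")


def write_truth_vcf(
    records: Sequence[TruthRecord],
    reference_names: Sequence[str],
    path: PathLike,
    *,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    """Write plain SV records (e.g. a simulated truth set) as VCF 4.2."""
    _check_sorted([(r.chrom, r.base_s) for r in records], reference_names)
    header = _sv_header(reference_names, contig_lengths, with_features=False)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            _emit_record(
                out, header, rec.chrom, rec.base_s - 1, rec.base_L, rec.base_t,
                rec.genotype, rec.phase_set,
            )


def write_phased_vcf(
    calls: Sequence,
    reference_names: Sequence[str],
    path: PathLike,
    *,
    contig_lengths: Optional[Mapping[str, int]] = None,
    include_filtered: bool = False,
) -> None:
    """Write classified calls (``PhasedCall``) as a phased SV VCF.

    Filtered (0/0) calls are excluded by default.  Feature values are stored
    in INFO for auditability.  Input must be sorted by coordinate.
    """
    _check_sorted([(c.chrom, c.pos) for c in calls], reference_names)
    header = _sv_header(reference_names, contig_lengths, with_features=True)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in calls:
            if call.classification == "0/0" and not include_filtered:
                continue
            info = {}
            if call.features is not None:
                fv = call.features
                info = {
                    "PSV": round(fv.p_sv, 6),
                    "PHP": round(fv.p_hp, 6),
                    "SPC1": round(fv.sigma_pc_1, 3),
                    "SPC2": round(fv.sigma_pc_2, 3),
                }
            if call.decision_layer is not None:
                info["LAYER"] = call.decision_layer
            _emit_record(
                out, header, call.chrom, call.pos, call.length, call.sv_type,
                call.classification, call.phase_set, info_extra=info,
            )
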