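"""Seed-reproducible synthetic diploid SV data.

The generator emulates the statistical structure the decision path relies
on: a haplotype-resolved diploid truth set (INS/DEL with genotype and
haplotype), per-locus supporting reads at Poisson coverage with an even
haplotype split, haplotag assignment with configurable error, false
candidate loci with one or two supporters, and per-read phasing-confidence
scores drawn from the empirical confidence bins — with different bin weights
for reads at true versus false SV loci, so that excessive confidence is a
false-signal indicator.

``emit_fixture`` materialises a locus set as a coordinate-sorted BAM (reads
whose CIGARs encode the SV marks, HP/PS/PC tags matching the signatures,
sequences omitted), a truth VCF, and a JSON manifest; the files round-trip
through signature collection to reproduce every ReadSignature exactly.
Confidence scores are drawn as integers so the float BAM tag is lossless.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pysam

from .formats_io import TruthRecord, write_truth_vcf
from .sv_signatures import ReadSignature

PC_BINS_DEFAULT = (0.0, 300.0, 900.0, 1500.0, 8100.0, 72600.0, math.inf)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    Defaults describe a well-behaved 20x dataset: 60% of true SVs
    heterozygous, sizes log-uniform in 50-2000 bp, 80% of reads phasable
    with 2% mis-assignment, 5% allele dropout, and confidence weights that
    put true-locus reads mostly in the moderate bins and false-locus reads
    in the extreme (lowest/highest) bins.
    """

    n_true_sv: int = 100
    n_false_candidates: int = 0
    genome_length: int = 50_000_000
    chrom: str = "chr1"
    coverage: float = 20.0
    het_fraction: float = 0.6
    sv_size_range: tuple[int, int] = (50, 2000)
    ins_del_ratio: float = 0.5          # P(type == INS)
    haplotag_rate: float = 0.8
    haplotag_error: float = 0.02
    allele_dropout: float = 0.05
    pc_bins: tuple[float, ...] = PC_BINS_DEFAULT
    pc_true_weights: tuple[float, ...] = (0.10, 0.35, 0.30, 0.22, 0.025, 0.005)
    pc_false_weights: tuple[float, ...] = (0.35, 0.07, 0.05, 0.08, 0.30, 0.15)
    multi_mark_rate: float = 0.1        # extra same-cluster mark on INS supporters
    false_supporters: tuple[int, int] = (1, 2)
    read_length: int = 20_000
    min_sv_size: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("het_fraction", "haplotag_rate", "haplotag_error",
                     "allele_dropout", "ins_del_ratio", "multi_mark_rate"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        for name in ("pc_true_weights", "pc_false_weights"):
            weights = getattr(self, name)
            if len(weights) != len(self.pc_bins) - 1:
                raise ValueError(f"{name} must have one weight per bin")
            if abs(sum(weights) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if self.sv_size_range[0] < self.min_sv_size:
            raise ValueError("minimum SV size below the detection floor")
        if 2 * self.sv_size_range[1] + 4200 > self.read_length:
            raise ValueError("read_length too short to span the largest SV with flanks")

    @classmethod
    def noise_free(cls, **overrides) -> "SimConfig":
        """Every read phasable and correctly tagged, no dropout, no false
        candidates, and no mass in the untrustworthy-confidence bins."""
        base = dict(
            haplotag_rate=1.0,
            haplotag_error=0.0,
            allele_dropout=0.0,
            n_false_candidates=0,
            pc_true_weights=(0.10, 0.40, 0.30, 0.20, 0.0, 0.0),
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def adversarial_low_coverage(cls, **overrides) -> "SimConfig":
        """A low-coverage (8x-like) set where false candidates carry one or
        two supporters drawn from the excessive-confidence bins."""
        base = dict(
            coverage=8.0,
            n_true_sv=200,
            n_false_candidates=200,
            pc_false_weights=(0.0, 0.0, 0.0, 0.0, 0.8, 0.2),
        )
        base.update(overrides)
        return cls(**base)

    @property
    def locus_spacing(self) -> int:
        # loci stay read-disjoint so fixtures round-trip exactly
        return max(2 * self.sv_size_range[1], self.read_length)


@dataclass(frozen=True)
class FalseCandidate:
    """Locus of a false SV signal (no underlying variant)."""

    chrom: str
    pos: int        # 1-based, like TruthRecord.base_s
    length: int
    sv_type: str


@dataclass(frozen=True)
class SimulatedLocus:
    chrom: str
    pos: int        # 1-based start
    length: int
    sv_type: str
    label: str      # true_sv | false_signal
    truth: Optional[TruthRecord]
    signatures: tuple[ReadSignature, ...]

    def __post_init__(self) -> None:
        if (self.label == "true_sv") != (self.truth is not None):
            raise ValueError("label true_sv iff truth record present")


# ---------------------------------------------------------------------------
# truth-set simulation
# ---------------------------------------------------------------------------


def _spaced_positions(rng: np.random.Generator, n: int, config: SimConfig) -> list[int]:
    spacing = config.locus_spacing
    slack = config.genome_length - (n + 1) * spacing
    if n > 0 and slack <= 0:
        raise ValueError(
            f"genome of {config.genome_length} bp too small for {n} loci "
            f"at {spacing} bp spacing"
        )
    offsets = np.sort(rng.uniform(0, slack, size=n))
    return [int(offsets[i]) + (i + 1) * spacing for i in range(n)]


def _sample_size(rng: np.random.Generator, config: SimConfig) -> int:
    lo, hi = config.sv_size_range
    return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


def _sample_locus_shape(rng: np.random.Generator, config: SimConfig) -> tuple[int, str]:
    size = _sample_size(rng, config)
    sv_type = "INS" if rng.random() < config.ins_del_ratio else "DEL"
    return size, sv_type


def simulate_truth_set(config: SimConfig, rng: Optional[np.random.Generator] = None) -> list[TruthRecord]:
    """Draw ``n_true_sv`` haplotype-resolved SV records.

    Positions are uniform with a minimum spacing, sizes log-uniform in
    ``sv_size_range``, genotypes heterozygous with probability
    ``het_fraction`` (haplotype uniform), one phase set per chromosome.
    Deterministic given the seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    positions = _spaced_positions(rng, config.n_true_sv, config)
    records = []
    for pos in positions:
        size, sv_type = _sample_locus_shape(rng, config)
        if rng.random() < config.het_fraction:
            genotype = "1|0" if rng.random() < 0.5 else "0|1"
        else:
            genotype = "1|1"
        records.append(
            TruthRecord(
                chrom=config.chrom, base_s=pos, base_L=size, base_t=sv_type,
                genotype=genotype, phase_set=1,
            )
        )
    return records


# ---------------------------------------------------------------------------
# per-locus signature simulation
# ---------------------------------------------------------------------------


def _draw_pc(rng: np.random.Generator, config: SimConfig, weights: Sequence[float]) -> float:
    idx = int(rng.choice(len(weights), p=np.asarray(weights)))
    lo = config.pc_bins[idx]
    hi = config.pc_bins[idx + 1]
    if math.isinf(hi):
        hi = 2 * lo  # open top bin: bounded uniform above the edge
    return float(rng.integers(int(lo), int(hi)))  # integer scores: lossless tags


def simulate_locus_signatures(
    truth_or_false: Union[TruthRecord, FalseCandidate],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    read_prefix: str = "r",
) -> SimulatedLocus:
    """Simulate the supporting-read signatures of one locus.

    Spanning-read count is Poisson(coverage) with an even haplotype split.
    At a true locus, carrier-haplotype reads carry an SV mark unless dropped
    (``allele_dropout``); INS supporters occasionally carry a second mark
    (``multi_mark_rate``) so VC genuinely varies.  A false locus gets 1-2
    supporters irrespective of haplotype.  Each read is phasable with
    probability ``haplotag_rate`` and mis-tagged with ``haplotag_error``;
    confidences come from the true- or false-locus bin weights.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    truth = truth_or_false if isinstance(truth_or_false, TruthRecord) else None
    is_true = truth is not None

    n_span = int(rng.poisson(config.coverage))
    supporters: set[int] = set()
    if not is_true:
        k = int(rng.integers(config.false_supporters[0], config.false_supporters[1] + 1))
        if n_span < k:
            n_span = k
        supporters = set(rng.choice(n_span, size=k, replace=False).tolist())

    # even split of spanning reads over the two haplotypes
    origins = np.array([1, 2] * ((n_span + 1) // 2))[:n_span]
    rng.shuffle(origins)

    if is_true:
        if truth.gt_class == "hom":
            carriers = {1, 2}
        else:
            carriers = {1} if truth.genotype == "1|0" else {2}

    weights = config.pc_true_weights if is_true else config.pc_false_weights
    signatures = []
    for i in range(n_span):
        origin = int(origins[i])
        vc = 0
        if is_true:
            if origin in carriers and rng.random() >= config.allele_dropout:
                vc = 1
                if (truth.base_t == "INS" and rng.random() < config.multi_mark_rate):
                    vc = 2
        elif i in supporters:
            vc = 1
        if rng.random() < config.haplotag_rate:
            observed = origin if rng.random() >= config.haplotag_error else 3 - origin
            signatures.append(
                ReadSignature(
                    read_id=f"{read_prefix}{i:04d}", hp=observed,
                    pc=_draw_pc(rng, config, weights), vc=vc, phase_set=1,
                )
            )
        else:
            signatures.append(
                ReadSignature(read_id=f"{read_prefix}{i:04d}", hp=None, pc=0.0, vc=vc)
            )

    locus = truth_or_false
    return SimulatedLocus(
        chrom=locus.chrom,
        pos=locus.base_s if is_true else locus.pos,
        length=locus.base_L if is_true else locus.length,
        sv_type=locus.base_t if is_true else locus.sv_type,
        label="true_sv" if is_true else "false_signal",
        truth=truth,
        signatures=tuple(signatures),
    )


def simulate_dataset(config: SimConfig) -> tuple[list[TruthRecord], list[SimulatedLocus]]:
    """Simulate the full locus set: truth records plus false candidates,
    position-interleaved, with per-locus signatures.  Deterministic given
    ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    total = config.n_true_sv + config.n_false_candidates
    positions = _spaced_positions(rng, total, config)
    labels = np.array([True] * config.n_true_sv + [False] * config.n_false_candidates)
    rng.shuffle(labels)

    truth_records: list[TruthRecord] = []
    loci: list[SimulatedLocus] = []
    for idx, (pos, is_true) in enumerate(zip(positions, labels)):
        size, sv_type = _sample_locus_shape(rng, config)
        if is_true:
            if rng.random() < config.het_fraction:
                genotype = "1|0" if rng.random() < 0.5 else "0|1"
            else:
                genotype = "1|1"
            site: Union[TruthRecord, FalseCandidate] = TruthRecord(
                chrom=config.chrom, base_s=pos, base_L=size, base_t=sv_type,
                genotype=genotype, phase_set=1,
            )
            truth_records.append(site)
        else:
            site = FalseCandidate(chrom=config.chrom, pos=pos, length=size, sv_type=sv_type)
        loci.append(
            simulate_locus_signatures(site, config, rng, read_prefix=f"L{idx:05d}_r")
        )
    return truth_records, loci


# ---------------------------------------------------------------------------
# fixture emission
# ---------------------------------------------------------------------------


def _read_cigar_and_start(
    locus: SimulatedLocus, sig: ReadSignature, rng: np.random.Generator, config: SimConfig
) -> tuple[str, int]:
    """CIGAR encoding the read's marks and the read's reference start.

    The read fully spans the locus; the event sits ``before`` bases into the
    alignment.  A VC=2 insertion is emitted as two full-length I operations
    20 bp apart (they merge back into one cluster on re-detection).
    """
    read_len = config.read_length
    length = locus.length
    pos0 = locus.pos - 1
    before = int(rng.integers(2000, read_len - 2 * max(length, 1) - 2100))
    if sig.vc == 0:
        return f"{read_len}M", pos0 - before
    if locus.sv_type == "DEL":
        after = read_len - before
        return f"{before}M{length}D{after}M", pos0 - before
    if sig.vc >= 2:
        after = read_len - before - 2 * length - 20
        return f"{before}M{length}I20M{length}I{after}M", pos0 - before
    after = read_len - before - length
    return f"{before}M{length}I{after}M", pos0 - before


def emit_fixture(
    loci: Sequence[SimulatedLocus],
    config: SimConfig,
    out_dir: Union[str, Path],
) -> dict[str, Path]:
    """Write the locus set as BAM (+index), truth VCF and manifest JSON.

    Re-running signature collection on the emitted BAM recovers every
    simulated (HP, PC, VC) triple exactly.  Byte-identical across replays of
    the same config and seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([config.seed, 0xF1])

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": config.chrom, "LN": config.genome_length}],
    }
    rows = []
    for locus in sorted(loci, key=lambda l: l.pos):
        for sig in locus.signatures:
            cigar, start = _read_cigar_and_start(locus, sig, rng, config)
            rows.append((start, cigar, sig))
    rows.sort(key=lambda r: r[0])

    bam_path = out_dir / "fixture.bam"
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
        for start, cigar, sig in rows:
            seg = pysam.AlignedSegment(bam.header)
            seg.query_name = sig.read_id
            seg.reference_id = 0
            seg.reference_start = start
            seg.mapping_quality = 60
            seg.cigarstring = cigar
            seg.flag = 0
            tags = []
            if sig.hp is not None:
                tags = [("HP", sig.hp, "i"), ("PS", sig.phase_set, "i"), ("PC", float(sig.pc), "f")]
            seg.set_tags(tags)
            bam.write(seg)
    pysam.index(str(bam_path))

    vcf_path = out_dir / "truth.vcf"
    truth = sorted(
        (l.truth for l in loci if l.truth is not None), key=lambda r: r.base_s
    )
    write_truth_vcf(truth, [config.chrom], vcf_path,
                    contig_lengths={config.chrom: config.genome_length})

    manifest_path = out_dir / "manifest.json"
    cfg = dataclasses.asdict(config)
    cfg["pc_bins"] = [b if math.isfinite(b) else None for b in config.pc_bins]
    manifest = {
        "config": cfg,
        "seed": config.seed,
        "n_loci": len(loci),
        "n_true": sum(1 for l in loci if l.label == "true_sv"),
        "files": {"bam": bam_path.name, "truth_vcf": vcf_path.name},
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return {"bam": bam_path, "vcf": vcf_path, "manifest": manifest_path}
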