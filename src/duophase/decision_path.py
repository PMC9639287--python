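"""The three-layer rule-based decision path, the traditional baselines, and
the end-to-end calling pipeline.

Layer 1 distrusts candidates whose supporting reads show untrustworthy
phasing evidence: too small a fraction of phasable supporters (low ``p_HP``)
or an excessively high average phasing confidence (``mu_PC`` above ~8100,
the regime where false SV signals dominate).  The default combines the two
conditions with OR; AND is available via ``layer1_rule`` for a stricter
filter.

Layer 2 falls back to the supporting-read fraction ``p_SV``: below the low
threshold the candidate is a false signal (0/0), above the high threshold it
is homozygous (1|1).

Layer 3 handles the moderate-``p_SV`` band by comparing the total phasing
confidence of the two haplotype groups (``sigma_PC1`` vs ``sigma_PC2``): no
huge difference (ratio within ``t5``) means homozygous, otherwise the call
is heterozygous and assigned to the dominant haplotype (1|0 or 0|1).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from . import formats_io
from .formats_io import DEFAULT_MIN_SV_SIZE, AlignedReadView, TruthRecord
from .haplotype_features import FeatureVector, compute_features, features_as_dict
from .sv_signatures import (
    DEFAULT_FLANK,
    ClusterParams,
    ReadSignature,
    SVCandidate,
    _ReadIndex,
    cluster_candidates,
    collect_signatures,
    extract_split_marks,
    extract_sv_marks,
    marks_link,
)

logger = logging.getLogger("duophase")

FILTERED = "0/0"
HOM = "1|1"
HET_H1 = "1|0"
HET_H2 = "0|1"
HET_UNPHASED = "0/1"


@dataclass(frozen=True)
class Thresholds:
    """Cut-offs T1..T5 of the decision path (all configurable).

    ``t2``/``t3``/``t4`` are anchored to the excessive-confidence bin edge
    (8100) and the traditional p_SV rule (0.2/0.8); ``t1`` and ``t5`` were
    fixed by simulation.
    """

    t1_min_p_hp: float = 0.3
    t2_max_mu_pc: float = 8100.0
    t3_low_p_sv: float = 0.2
    t4_high_p_sv: float = 0.8
    t5_max_ratio: float = 3.0
    layer1_mu_mode: str = "overall"   # overall | max | min
    layer1_rule: str = "or"           # or | and

    def __post_init__(self) -> None:
        if not (0.0 <= self.t3_low_p_sv < self.t4_high_p_sv <= 1.0):
            raise ValueError("need 0 <= t3 < t4 <= 1")
        if self.t5_max_ratio < 1.0:
            raise ValueError("t5_max_ratio must be >= 1")
        if self.layer1_mu_mode not in ("overall", "max", "min"):
            raise ValueError("layer1_mu_mode must be overall/max/min")
        if self.layer1_rule not in ("or", "and"):
            raise ValueError("layer1_rule must be 'or' or 'and'")


@dataclass(frozen=True)
class PhasedCall:
    """A classified SV call (coordinates 0-based half-open internally)."""

    chrom: str
    pos: int
    length: int
    sv_type: str
    classification: str
    phase_set: Optional[int] = None
    features: Optional[FeatureVector] = None
    decision_layer: Optional[int] = None

    def __post_init__(self) -> None:
        if self.classification in (HET_H1, HET_H2) and self.phase_set is None:
            raise ValueError("phased heterozygous call requires a phase set")


def _layer1_mu(features: FeatureVector, mode: str) -> float:
    if mode == "overall":
        return features.mu_pc_all
    per_hap = [
        mu for mu, n in ((features.mu_pc_1, features.n_sv_1), (features.mu_pc_2, features.n_sv_2))
        if n > 0
    ]
    if not per_hap:
        return 0.0
    return max(per_hap) if mode == "max" else min(per_hap)


def classify(features: FeatureVector, thresholds: Thresholds = Thresholds()) -> tuple[str, int]:
    """Run the decision path on one feature vector.

    Returns ``(classification, layer)`` with classification one of
    ``0/0``, ``1|1``, ``1|0``, ``0|1`` and layer the index (1-3) that fired.
    Deterministic and total; exactly one layer fires.
    """
    mu = _layer1_mu(features, thresholds.layer1_mu_mode)
    low_p_hp = features.p_hp < thresholds.t1_min_p_hp
    high_mu = mu > thresholds.t2_max_mu_pc
    fired = (low_p_hp and high_mu) if thresholds.layer1_rule == "and" else (low_p_hp or high_mu)
    if fired:
        return FILTERED, 1
    if features.p_sv < thresholds.t3_low_p_sv:
        return FILTERED, 2
    if features.p_sv > thresholds.t4_high_p_sv:
        return HOM, 2
    if features.p_sigma_pc <= thresholds.t5_max_ratio:
        return HOM, 3
    return (HET_H1 if features.sigma_pc_1 >= features.sigma_pc_2 else HET_H2), 3


# ---------------------------------------------------------------------------
# traditional baselines
# ---------------------------------------------------------------------------


def genotype_by_psv(features: FeatureVector, low: float = 0.2, high: float = 0.8) -> str:
    """p_SV-only genotyping: < low -> false, > high -> homozygous, else het.

    The boundaries themselves classify heterozygous (closed interval).
    """
    if features.p_sv < low:
        return FILTERED
    if features.p_sv > high:
        return "1/1"
    return HET_UNPHASED


def phase_by_nsv(features: FeatureVector, min_nsv: int = 2) -> str:
    """N_SV-only phasing: >= min_nsv on both haplotypes -> 1|1, on exactly one
    -> heterozygous on that haplotype, on neither -> false."""
    h1 = features.n_sv_1 >= min_nsv
    h2 = features.n_sv_2 >= min_nsv
    if h1 and h2:
        return HOM
    if h1:
        return HET_H1
    if h2:
        return HET_H2
    return FILTERED


# ---------------------------------------------------------------------------
# phase-set assignment
# ---------------------------------------------------------------------------


def _het_phase_set(signatures: Sequence[ReadSignature], hap: int) -> Optional[int]:
    """Majority phase set among supporters of the dominant haplotype."""
    sets = [s.phase_set for s in signatures if s.vc > 0 and s.hp == hap and s.phase_set is not None]
    if not sets:
        return None
    counts = Counter(sets)
    if len(counts) > 1:
        logger.warning("mixed phase sets among dominant-haplotype supporters: %s", dict(counts))
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return best[0]


def _classification_to_call(candidate: SVCandidate, features: FeatureVector,
                            classification: str, layer: Optional[int]) -> PhasedCall:
    phase_set = None
    if classification in (HET_H1, HET_H2):
        hap = 1 if classification == HET_H1 else 2
        phase_set = _het_phase_set(candidate.signatures, hap)
        if phase_set is None:
            # cannot anchor the call to a phase block: demote to unphased het
            classification = HET_UNPHASED
    return PhasedCall(
        chrom=candidate.chrom,
        pos=candidate.comp_s,
        length=candidate.comp_L,
        sv_type=candidate.comp_t,
        classification=classification,
        phase_set=phase_set,
        features=features,
        decision_layer=layer,
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


def _candidates_from_vcf(
    records: Sequence[TruthRecord],
    marks,
    params: ClusterParams,
) -> list[SVCandidate]:
    """Build candidate skeletons from an external call set and assign each
    detected mark to the nearest compatible candidate (same merge rule as
    clustering)."""
    skeletons = [
        SVCandidate(chrom=r.chrom, comp_s=r.base_s - 1, comp_L=r.base_L, comp_t=r.base_t)
        for r in records
    ]
    assigned: dict[int, list] = {i: [] for i in range(len(skeletons))}
    for mark in marks:
        best = None
        best_dist = None
        for i, cand in enumerate(skeletons):
            if cand.chrom != mark.chrom or cand.comp_t != mark.sv_type:
                continue
            dist = abs(mark.pos - cand.comp_s)
            if dist > params.bias(mark.sv_type):
                continue
            ratio = abs(mark.length - cand.comp_L) / max(mark.length, cand.comp_L)
            if ratio > params.diff_ratio(mark.sv_type):
                continue
            if best_dist is None or dist < best_dist:
                best, best_dist = i, dist
        if best is not None:
            assigned[best].append(mark)
    out = []
    for i, cand in enumerate(skeletons):
        out.append(
            SVCandidate(
                chrom=cand.chrom, comp_s=cand.comp_s, comp_L=cand.comp_L,
                comp_t=cand.comp_t, marks=tuple(assigned[i]),
            )
        )
    return out


def call_pipeline(
    alignments: Union[str, Path, Iterable[AlignedReadView]],
    candidates: Union[str, Path, Sequence[TruthRecord], None] = None,
    *,
    thresholds: Thresholds = Thresholds(),
    cluster_params: ClusterParams = ClusterParams(),
    min_sv_size: int = DEFAULT_MIN_SV_SIZE,
    flank: int = DEFAULT_FLANK,
    min_mapq: int = formats_io.DEFAULT_MIN_MAPQ,
    pc_tag: str = formats_io.DEFAULT_PC_TAG,
    sidecar=None,
) -> list[PhasedCall]:
    """Alignments -> candidates -> signatures -> features -> classification.

    ``candidates`` may be a VCF path or parsed records, in which case the
    clustering stage is bypassed.  Filtered (0/0) calls are retained in the
    returned list with their deciding layer; the VCF writer excludes them by
    default.
    """
    if isinstance(alignments, (str, Path)):
        reads = list(
            formats_io.read_alignments(alignments, min_mapq=min_mapq, pc_tag=pc_tag, sidecar=sidecar)
        )
    else:
        reads = list(alignments)
    if not reads:
        return []

    from collections import defaultdict

    marks = []
    by_read = defaultdict(list)
    for read in reads:
        marks.extend(extract_sv_marks(read, min_sv_size))
        by_read[read.read_id].append(read)
    for segments in by_read.values():
        if len(segments) > 1:
            marks.extend(extract_split_marks(segments, min_sv_size))
    marks.sort(key=lambda m: (m.chrom, m.pos))

    if candidates is not None:
        if isinstance(candidates, (str, Path)):
            candidates = formats_io.read_sv_vcf(candidates, min_sv_size=min_sv_size)
        skeletons = _candidates_from_vcf(candidates, marks, cluster_params)
    else:
        skeletons = cluster_candidates(marks, cluster_params)

    index = _ReadIndex(reads)
    calls: list[PhasedCall] = []
    for skeleton in skeletons:
        window = index.overlapping(
            skeleton.chrom,
            skeleton.comp_s - flank,
            skeleton.comp_s + skeleton.comp_L + flank,
        )
        candidate = collect_signatures(skeleton, window, flank)
        if candidate is None:
            continue
        features = compute_features(candidate.signatures)
        classification, layer = classify(features, thresholds)
        calls.append(_classification_to_call(candidate, features, classification, layer))
    calls.sort(key=lambda c: (c.chrom, c.pos))
    return calls


# ---------------------------------------------------------------------------
# adapters & reports
# ---------------------------------------------------------------------------


def calls_to_records(calls: Iterable[PhasedCall], include_filtered: bool = False) -> list[TruthRecord]:
    """Convert classified calls to 1-based SV records for evaluation/export."""
    records = []
    for call in calls:
        if call.classification == FILTERED and not include_filtered:
            continue
        if call.classification == FILTERED:
            continue  # 0/0 records are not representable as TruthRecord
        records.append(
            TruthRecord(
                chrom=call.chrom,
                base_s=call.pos + 1,
                base_L=call.length,
                base_t=call.sv_type,
                genotype=call.classification,
                phase_set=call.phase_set,
            )
        )
    return records


def classify_locus_set(loci, method: str = "decision",
                       thresholds: Thresholds = Thresholds()) -> list[TruthRecord]:
    """Classify simulated loci (objects with chrom/pos/length/sv_type/signatures)
    directly from their signatures, returning eval-ready records.

    ``method``: ``decision`` (three-layer path), ``psv`` (p_SV-only
    genotyping, unphased) or ``nsv`` (per-haplotype N_SV rule).  Loci whose
    classification is 0/0 are omitted, mirroring the default VCF output.
    """
    records: list[TruthRecord] = []
    for locus in loci:
        signatures = list(locus.signatures)
        if not signatures or not any(s.vc > 0 for s in signatures):
            continue
        features = compute_features(signatures)
        if method == "decision":
            classification, _layer = classify(features, thresholds)
        elif method == "psv":
            classification = genotype_by_psv(features)
        elif method == "nsv":
            classification = phase_by_nsv(features)
        else:
            raise ValueError(f"unknown method {method!r}")
        if classification == FILTERED:
            continue
        phase_set = None
        if classification in (HET_H1, HET_H2):
            hap = 1 if classification == HET_H1 else 2
            phase_set = _het_phase_set(signatures, hap)
            if phase_set is None:
                classification = HET_UNPHASED
        elif classification == HOM:
            sets = [s.phase_set for s in signatures if s.phase_set is not None]
            phase_set = Counter(sets).most_common(1)[0][0] if sets else None
        records.append(
            TruthRecord(
                chrom=locus.chrom, base_s=locus.pos, base_L=locus.length,
                base_t=locus.sv_type, genotype=classification, phase_set=phase_set,
            )
        )
    records.sort(key=lambda r: (r.chrom, r.base_s))
    return records


def report_frame(calls: Sequence[PhasedCall]) -> pd.DataFrame:
    """One row per candidate: locus, features, classification, deciding layer."""
    rows = []
    for call in calls:
        row = {
            "chrom": call.chrom,
            "pos": call.pos,
            "length": call.length,
            "sv_type": call.sv_type,
            "classification": call.classification,
            "phase_set": call.phase_set,
            "decision_layer": call.decision_layer,
        }
        if call.features is not None:
            row.update(features_as_dict(call.features))
        rows.append(row)
    return pd.DataFrame(rows)
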