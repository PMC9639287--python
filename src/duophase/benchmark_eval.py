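"""Three-level SV benchmarking: calling, genotyping, phasing.

Matching a call against a truth record requires a start distance within
1 kbp, a size ratio ``min(L)/max(L) >= 0.4`` and matching SV class.  A call
is a calling-level TP when it matches at least one truth record (matching is
many-to-one; truth records are not consumed) and a truth record is an FN
when no call matches it.

Genotyping keeps a calling-level TP only when its genotype class (het vs
hom, phase orientation ignored) agrees with its *corresponding* truth record
— the nearest matching one by start distance, ties to the smaller start.

Phasing scores haplotype orientation.  Because haplotype labels within a
phase block are arbitrary, each phase set is evaluated under the original
and the globally-flipped orientation (0|1 <-> 1|0, 0/0 and 1|1 unchanged)
and the version with more TPs is kept (ties keep the original).  Calls that
are heterozygous but unphased, or lack a phase set, count as FP at this
level.

Precision, recall and F1 are TP/(TP+FP), TP/(TP+FN) and their harmonic
mean, each defined as 0 when its denominator is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .formats_io import TruthRecord

HET_CLASSES = ("0|1", "1|0", "0/1")


@dataclass(frozen=True)
class MatchParams:
    max_start_dist: int = 1000
    min_size_ratio: float = 0.4
    require_type_match: bool = True

    def __post_init__(self) -> None:
        if self.max_start_dist <= 0:
            raise ValueError("max_start_dist must be positive")
        if not (0 < self.min_size_ratio <= 1):
            raise ValueError("min_size_ratio must be in (0, 1]")


@dataclass(frozen=True)
class EvalReport:
    level: str
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    flip_choices: Optional[dict] = None

    @classmethod
    def from_counts(cls, level: str, tp: int, fp: int, fn: int,
                    flip_choices: Optional[dict] = None) -> "EvalReport":
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall > 0 else 0.0)
        return cls(level, tp, fp, fn, precision, recall, f1, flip_choices)


def matches(comp: TruthRecord, base: TruthRecord, params: MatchParams = MatchParams()) -> bool:
    """True when a call and a truth record describe the same SV."""
    if comp.base_L <= 0 or base.base_L <= 0:
        raise ValueError("SV lengths must be positive")
    if comp.chrom != base.chrom:
        return False
    if abs(comp.base_s - base.base_s) > params.max_start_dist:
        return False
    if min(comp.base_L, base.base_L) / max(comp.base_L, base.base_L) < params.min_size_ratio:
        return False
    if params.require_type_match and comp.base_t != base.base_t:
        return False
    return True


def _correspondence(calls: Sequence[TruthRecord], truth: Sequence[TruthRecord],
                    params: MatchParams) -> list[Optional[int]]:
    """Per call, the index of its corresponding truth record (nearest match,
    ties to the smaller start), or None when no truth matches."""
    corr: list[Optional[int]] = []
    for call in calls:
        best = None
        best_key = None
        for i, base in enumerate(truth):
            if not matches(call, base, params):
                continue
            key = (abs(call.base_s - base.base_s), base.base_s)
            if best_key is None or key < best_key:
                best, best_key = i, key
        corr.append(best)
    return corr


def evaluate_calling(calls: Sequence[TruthRecord], truth: Sequence[TruthRecord],
                     params: MatchParams = MatchParams()) -> EvalReport:
    """Positional evaluation: a call is TP iff it matches >= 1 truth record."""
    corr = _correspondence(calls, truth, params)
    tp = sum(1 for c in corr if c is not None)
    fp = len(calls) - tp
    # FN is existential: a truth record is missed only when NO call matches
    # it (not merely when it is nobody's nearest match)
    fn = sum(
        1 for base in truth if not any(matches(call, base, params) for call in calls)
    )
    return EvalReport.from_counts("calling", tp, fp, fn)


def evaluate_genotyping(calls: Sequence[TruthRecord], truth: Sequence[TruthRecord],
                        params: MatchParams = MatchParams()) -> EvalReport:
    """Calling-level TPs survive only with the right genotype class (het/hom);
    phase orientation is deliberately ignored at this level."""
    corr = _correspondence(calls, truth, params)
    tp = 0
    tp_truth: set[int] = set()
    for call, c in zip(calls, corr):
        if c is None:
            continue
        if call.gt_class == truth[c].gt_class:
            tp += 1
            tp_truth.add(c)
    fp = len(calls) - tp
    fn = len(truth) - len(tp_truth)
    return EvalReport.from_counts("genotyping", tp, fp, fn)


def _hap_match(call_gt: str, truth_gt: str) -> bool:
    """Haplotype agreement for one orientation.  A phased het matches a
    phased het with the same orientation; truth het lacking phase matches
    either orientation; homozygous matches homozygous."""
    call_het = call_gt in ("0|1", "1|0")
    truth_het = truth_gt in ("0|1", "1|0", "0/1")
    if call_het and truth_het:
        return truth_gt == "0/1" or call_gt == truth_gt
    hom = ("1|1", "1/1")
    return call_gt in hom and truth_gt in hom


def _flip(gt: str) -> str:
    return {"0|1": "1|0", "1|0": "0|1"}.get(gt, gt)


def evaluate_phasing(calls: Sequence[TruthRecord], truth: Sequence[TruthRecord],
                     params: MatchParams = MatchParams()) -> EvalReport:
    """Per-phase-set flip evaluation of haplotype orientation."""
    corr = _correspondence(calls, truth, params)

    status = [False] * len(calls)           # phasing-level TP flags
    groups: dict[tuple, list[int]] = {}
    flip_choices: dict = {}

    for i, (call, c) in enumerate(zip(calls, corr)):
        if c is None:
            continue  # calling-level FP stays FP
        if call.genotype in ("1|1", "1/1"):
            status[i] = _hap_match(call.genotype, truth[c].genotype)
        elif call.genotype in ("0|1", "1|0"):
            if call.phase_set is None:
                continue  # het without a phase block: FP at this level
            groups.setdefault((call.chrom, call.phase_set), []).append(i)
        # unphased het ("0/1") remains FP at the phasing level

    for key, members in sorted(groups.items()):
        original = sum(
            1 for i in members if _hap_match(calls[i].genotype, truth[corr[i]].genotype)
        )
        flipped = sum(
            1 for i in members if _hap_match(_flip(calls[i].genotype), truth[corr[i]].genotype)
        )
        use_flip = flipped > original       # ties keep the original
        flip_choices[key] = "flipped" if use_flip else "original"
        for i in members:
            gt = _flip(calls[i].genotype) if use_flip else calls[i].genotype
            status[i] = _hap_match(gt, truth[corr[i]].genotype)

    tp = sum(status)
    fp = len(calls) - tp
    tp_truth = {corr[i] for i in range(len(calls)) if status[i]}
    fn = len(truth) - len(tp_truth)
    return EvalReport.from_counts("phasing", tp, fp, fn, flip_choices)


def evaluate_all(calls: Sequence[TruthRecord], truth: Sequence[TruthRecord],
                 params: MatchParams = MatchParams()) -> dict[str, EvalReport]:
    return {
        "calling": evaluate_calling(calls, truth, params),
        "genotyping": evaluate_genotyping(calls, truth, params),
        "phasing": evaluate_phasing(calls, truth, params),
    }


def report_frame(reports: dict[str, EvalReport]) -> pd.DataFrame:
    """3-row TSV-ready table (level, tp, fp, fn, precision, recall, f1)."""
    return pd.DataFrame(
        [
            {
                "level": r.level, "tp": r.tp, "fp": r.fp, "fn": r.fn,
                "precision": r.precision, "recall": r.recall, "f1": r.f1,
            }
            for r in reports.values()
        ]
    )
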