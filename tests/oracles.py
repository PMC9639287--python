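"""Independent brute-force reference implementations used as test oracles.

These deliberately re-derive the definitions from first principles
(exhaustive pairwise scans, explicit connected components, per-block
orientation enumeration) instead of calling the package internals they
check.
"""

from __future__ import annotations

import itertools
from collections import defaultdict

import numpy as np

from duophase.formats_io import TruthRecord
from duophase.sv_signatures import SVMark


# ---------------------------------------------------------------------------
# clustering oracle: explicit graph + DFS connected components
# ---------------------------------------------------------------------------


def brute_force_clusters(marks, bias_ins=100, bias_del=200,
                         ratio_ins=0.3, ratio_del=0.5):
    """Connected components under the pairwise merge rule, as frozensets of
    mark indices."""
    n = len(marks)
    adj = defaultdict(set)
    for i, j in itertools.combinations(range(n), 2):
        a, b = marks[i], marks[j]
        if a.chrom != b.chrom or a.sv_type != b.sv_type:
            continue
        bias = bias_ins if a.sv_type == "INS" else bias_del
        ratio = ratio_ins if a.sv_type == "INS" else ratio_del
        if abs(a.pos - b.pos) <= bias and \
                abs(a.length - b.length) / max(a.length, b.length) <= ratio:
            adj[i].add(j)
            adj[j].add(i)
    seen = set()
    components = []
    for start in range(n):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            node = stack.pop()
            if node in comp:
                continue
            comp.add(node)
            stack.extend(adj[node] - comp)
        seen |= comp
        components.append(frozenset(comp))
    return components


# ---------------------------------------------------------------------------
# evaluation oracles: quadratic all-pairs, explicit orientation handling
# ---------------------------------------------------------------------------


def _pair_ok(call, base, max_dist=1000, min_ratio=0.4):
    return (
        call.chrom == base.chrom
        and abs(call.base_s - base.base_s) <= max_dist
        and min(call.base_L, base.base_L) / max(call.base_L, base.base_L) >= min_ratio
        and call.base_t == base.base_t
    )


def _nearest_truth(call, truth):
    hits = [(abs(call.base_s - t.base_s), t.base_s, i)
            for i, t in enumerate(truth) if _pair_ok(call, t)]
    return min(hits)[2] if hits else None


def _cls(gt):
    alleles = sorted(gt.replace("|", "/").split("/"))
    if alleles == ["0", "1"]:
        return "het"
    if alleles == ["1", "1"]:
        return "hom"
    return "ref"


def oracle_calling(calls, truth):
    tp = sum(1 for c in calls if any(_pair_ok(c, t) for t in truth))
    fp = len(calls) - tp
    fn = sum(1 for t in truth if not any(_pair_ok(c, t) for c in calls))
    return tp, fp, fn


def oracle_genotyping(calls, truth):
    tp = 0
    covered = set()
    for call in calls:
        i = _nearest_truth(call, truth)
        if i is not None and _cls(call.genotype) == _cls(truth[i].genotype):
            tp += 1
            covered.add(i)
    return tp, len(calls) - tp, len(truth) - len(covered)


def _orient_match(call_gt, truth_gt, flipped):
    if flipped:
        call_gt = {"0|1": "1|0", "1|0": "0|1"}.get(call_gt, call_gt)
    if call_gt in ("1|1", "1/1"):
        return truth_gt in ("1|1", "1/1")
    if call_gt in ("0|1", "1|0"):
        if truth_gt == "0/1":
            return True
        return call_gt == truth_gt
    return False


def oracle_phasing(calls, truth):
    """Enumerate both orientations of every phase block explicitly."""
    corr = [_nearest_truth(c, truth) for c in calls]
    blocks = sorted({(c.chrom, c.phase_set) for c in calls
                     if c.genotype in ("0|1", "1|0") and c.phase_set is not None})
    best_flip = {}
    for block in blocks:
        scores = {}
        for flipped in (False, True):
            scores[flipped] = sum(
                1 for c, i in zip(calls, corr)
                if i is not None and (c.chrom, c.phase_set) == block
                and c.genotype in ("0|1", "1|0")
                and _orient_match(c.genotype, truth[i].genotype, flipped)
            )
        best_flip[block] = scores[True] > scores[False]  # ties keep original
    tp = 0
    covered = set()
    for call, i in zip(calls, corr):
        if i is None:
            continue
        if call.genotype in ("1|1", "1/1"):
            ok = _orient_match(call.genotype, truth[i].genotype, False)
        elif call.genotype in ("0|1", "1|0") and call.phase_set is not None:
            ok = _orient_match(call.genotype, truth[i].genotype,
                               best_flip[(call.chrom, call.phase_set)])
        else:
            ok = False
        if ok:
            tp += 1
            covered.add(i)
    return tp, len(calls) - tp, len(truth) - len(covered)


# ---------------------------------------------------------------------------
# random instance generator for evaluation tests
# ---------------------------------------------------------------------------

GENOTYPES = ("0/1", "0|1", "1|0", "1|1", "1/1")


def random_eval_instance(rng: np.random.Generator, max_calls=50, max_truth=50):
    """A random (calls, truth) pair with deliberate positional ambiguity."""
    def rand_records(n, phased_only):
        records = []
        for _ in range(n):
            gt = str(rng.choice(GENOTYPES[1:] if phased_only else GENOTYPES))
            records.append(
                TruthRecord(
                    chrom=str(rng.choice(["chr1", "chr2"])),
                    base_s=int(rng.integers(1, 15)) * 400,
                    base_L=int(rng.choice([100, 150, 300, 600, 1200])),
                    base_t=str(rng.choice(["INS", "DEL"])),
                    genotype=gt,
                    phase_set=int(rng.integers(1, 4)),
                )
            )
        return records

    calls = rand_records(int(rng.integers(0, max_calls + 1)), phased_only=False)
    truth = rand_records(int(rng.integers(1, max_truth + 1)), phased_only=True)
    return calls, truth
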