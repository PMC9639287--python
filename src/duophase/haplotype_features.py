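"""The five integrated features computed per SV candidate.

From the supporting-read signatures (HP, PC, VC) the candidate gets:

* ``p_sv``      — fraction of locus-spanning reads carrying SV marks,
* ``p_hp``      — fraction of supporting reads that are phasable,
* ``sigma_pc_h``— Σ VC·PC over reads of haplotype h (h = 1, 2),
* ``mu_pc_h``   — mean VC·PC over supporting reads of haplotype h,
* ``p_sigma_pc``— ratio of the two Σ values, stored symmetrically as
  max/min so the downstream "no huge difference" test is label-invariant.
  One-sided zero support yields ``inf``; no phasable support on either
  haplotype yields 1.0 (no difference).

``mu_pc_all`` (mean VC·PC over all phasable supporting reads) backs the
layer-1 filter, which runs before the per-haplotype comparison is
meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .sv_signatures import ReadSignature


@dataclass(frozen=True)
class FeatureVector:
    p_sv: float
    p_hp: float
    sigma_pc_1: float
    sigma_pc_2: float
    mu_pc_1: float
    mu_pc_2: float
    mu_pc_all: float
    p_sigma_pc: float
    n_sv_1: int
    n_sv_2: int
    n_span: int


def overall_mu_pc(signatures: Sequence[ReadSignature], mode: str = "overall") -> float:
    """Aggregate VC-weighted phasing confidence of the phasable supporters.

    ``overall`` — mean of vc*pc over all phasable supporting reads;
    ``max``/``min`` — extreme of the per-haplotype means (haplotypes with no
    supporter contribute nothing).  Returns 0 when no phasable supporter
    exists.
    """
    weighted = {1: [], 2: []}
    for sig in signatures:
        if sig.vc > 0 and sig.hp in (1, 2):
            weighted[sig.hp].append(sig.vc * sig.pc)
    pooled = weighted[1] + weighted[2]
    if not pooled:
        return 0.0
    if mode == "overall":
        return sum(pooled) / len(pooled)
    per_hap = [sum(v) / len(v) for v in (weighted[1], weighted[2]) if v]
    if mode == "max":
        return max(per_hap)
    if mode == "min":
        return min(per_hap)
    raise ValueError(f"unknown mu mode {mode!r}")


def compute_features(signatures: Sequence[ReadSignature]) -> FeatureVector:
    """Compute the full feature vector for one candidate.

    Raises ``ValueError`` on an empty signature list or when no read
    supports the candidate (both are candidate-invariant violations).
    """
    if not signatures:
        raise ValueError("cannot compute features from an empty signature list")
    n_span = len(signatures)
    supporters = [s for s in signatures if s.vc > 0]
    if not supporters:
        raise ValueError("candidate has no supporting read (vc > 0)")
    p_sv = len(supporters) / n_span
    phased = [s for s in supporters if s.hp in (1, 2)]
    p_hp = len(phased) / len(supporters)

    sigma = {1: 0.0, 2: 0.0}
    count = {1: 0, 2: 0}
    for sig in phased:
        sigma[sig.hp] += sig.vc * sig.pc
        count[sig.hp] += 1
    mu = {h: (sigma[h] / count[h] if count[h] else 0.0) for h in (1, 2)}

    hi, lo = max(sigma[1], sigma[2]), min(sigma[1], sigma[2])
    if hi == 0.0:
        ratio = 1.0
    elif lo == 0.0:
        ratio = math.inf
    else:
        ratio = hi / lo

    return FeatureVector(
        p_sv=p_sv,
        p_hp=p_hp,
        sigma_pc_1=sigma[1],
        sigma_pc_2=sigma[2],
        mu_pc_1=mu[1],
        mu_pc_2=mu[2],
        mu_pc_all=overall_mu_pc(signatures, "overall"),
        p_sigma_pc=ratio,
        n_sv_1=count[1],
        n_sv_2=count[2],
        n_span=n_span,
    )


def features_as_dict(fv: FeatureVector) -> dict:
    """Flat dict view (for TSV/DataFrame export)."""
    return {
        "p_sv": fv.p_sv,
        "p_hp": fv.p_hp,
        "sigma_pc_1": fv.sigma_pc_1,
        "sigma_pc_2": fv.sigma_pc_2,
        "mu_pc_1": fv.mu_pc_1,
        "mu_pc_2": fv.mu_pc_2,
        "mu_pc_all": fv.mu_pc_all,
        "p_sigma_pc": fv.p_sigma_pc,
        "n_sv_1": fv.n_sv_1,
        "n_sv_2": fv.n_sv_2,
        "n_span": fv.n_span,
    }
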