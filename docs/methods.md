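# Methods

## Model and procedure

duophase treats SV genotyping and phasing as a rule-based classification of
candidate loci from supporting-read signatures. The inputs are a
coordinate-sorted long-read alignment file whose reads may carry haplotype
(`HP` ∈ {1,2}), phase-set (`PS`) and phasing-confidence tags, plus optionally
an external candidate VCF. The procedure runs in five stages:

1. **Mark detection.** Each alignment contributes intra-read marks (one per
   insertion/deletion CIGAR operation ≥ `min_sv_size`, default 30 bp) and
   split-read marks (reference-vs-read gap differences between adjacent
   segments of one read, suppressed beyond `max_split_gap` = 100 kbp).
2. **Loose clustering.** Marks of the same class merge by single linkage
   when their positions differ by ≤ bias (INS 100 bp, DEL 200 bp) and their
   relative length difference is ≤ ratio (INS 0.3, DEL 0.5); clusters
   supported by < 2 distinct reads are dropped. These defaults mirror the
   sensitive, loosely-clustered regime long-read SV callers use when a
   downstream filter will remove false positives. Candidate position and
   length are cluster medians (lower middle value on ties, for determinism).
3. **Signature collection.** A read spans a candidate when its primary
   alignment covers `comp_s − 50` and `comp_s + min(comp_L, 50)` (DEL) or
   `comp_s ± 50` (INS); the tight window keeps the p_SV denominator from
   counting distant reads. Each spanning read contributes (HP, PC, VC) with
   VC the count of its marks in the cluster; same-read marks in one cluster
   sum, so VC can exceed 1 and the VC-weighted sums are meaningful.
4. **Features.** p_SV, p_HP, Σ_PC1/Σ_PC2, μ_PC1/μ_PC2 and p_ΣPC as defined
   in the README. p_ΣPC is stored symmetrically as max/min because the
   decision path only asks whether the two sums differ hugely, which is
   label-invariant. Conventions: one-sided zero support → ∞ (always a huge
   difference); zero on both sides → 1 (no difference). The layer-1
   aggregate μ_PC is the mean of VC·PC over all phasable supporters
   (`layer1_mu_mode = overall`; per-haplotype max/min are selectable), since
   layer 1 runs before the haplotype comparison is meaningful.
5. **Decision path.** Layer 1 filters candidates with p_HP < T1 **or**
   μ_PC > T2; layer 2 applies the p_SV rule (strict < T3 → 0/0, strict
   > T4 → 1|1, mirroring the wording of the traditional baseline); layer 3
   compares Σ_PC1 with Σ_PC2 (ratio ≤ T5 → 1|1, otherwise heterozygous on
   the dominant haplotype). Exactly one layer fires. A heterozygous call
   takes the majority PS among its dominant-haplotype supporters; if no
   supporter carries a PS the call is demoted to unphased `0/1`.

### Threshold defaults

| name | default | unit | rationale |
|---|---|---|---|
| T1 (`t1_min_p_hp`) | 0.3 | fraction | below this, too little of the support is phasable to trust the locus; fixed by simulation |
| T2 (`t2_max_mu_pc`) | 8100 | confidence | the bin edge above which false SV signals dominate the confidence distribution |
| T3 (`t3_low_p_sv`) | 0.2 | fraction | traditional false-signal ceiling |
| T4 (`t4_high_p_sv`) | 0.8 | fraction | traditional homozygous floor |
| T5 (`t5_max_ratio`) | 3.0 | ratio | a ≤3-fold Σ_PC imbalance is consistent with both haplotypes carrying the allele; fixed by simulation |

The layer-1 combination rule is a genuinely open design point: "too few
phasable reads with very high confidence" can be read as a conjunction or as
two independent distrust conditions. We default to the disjunction
(`layer1_rule = "or"`): with the one-or-two-supporter candidates the method
targets, p_HP < 0.3 forces *zero* phasable supporters and hence μ_PC = 0, so
a conjunction can essentially never fire and the layer would be dead code at
low coverage. The disjunction directly encodes "distrust candidates whose
supporters have either too little or excessively high phasing confidence".
The conjunction remains available in config.

## Evaluation methodology

Matching uses |Δstart| ≤ 1 kbp, size ratio ≥ 0.4 and class equality.
Matching is many-to-one: a truth record can validate several calls and is a
false negative only when *no* call matches it. Precision and recall follow
TP/(TP+FP) and TP/(TP+FN) with the call-centric TP count; note that with
many-to-one matching this recall can differ from benchmarkers that count
truth-side TPs. The "corresponding" truth record of a TP call — needed at
the genotyping and phasing levels — is its nearest match by start distance,
ties to the smaller coordinate.

Genotyping compares the collapsed het/hom class only. Phasing scores exact
haplotype orientation but, because labels within a phase block are
arbitrary, each phase set is evaluated under the original and the globally
flipped orientation (0|1 ↔ 1|0; 0/0 and 1|1 unchanged) and the orientation
with more TPs is kept, ties preferring the original. Heterozygous calls
without phase information count as FP at this level; truth records are
assumed phased within a chromosome (one block per chromosome when truth PS
is absent). Switch-error rate is deliberately not computed: SVs are sparse
and distant, so per-block orientation accuracy is the meaningful metric.

## The simulator

`synthetic_data` emulates exactly the statistics the decision path consumes:

- diploid truth sets: positions uniform with spacing
  max(2·max SV size, read length) — the second bound keeps every simulated
  read inside one locus so emitted fixtures round-trip exactly; sizes
  log-uniform in 50–2000 bp; 60% heterozygous (haplotype uniform); one phase
  set per chromosome;
- per-locus reads: Poisson(coverage) spanning reads split evenly between
  haplotypes; carrier reads carry a mark unless dropped
  (`allele_dropout` = 0.05); insertion supporters occasionally carry a
  second mark (`multi_mark_rate` = 0.1) so VC genuinely varies (deletion
  marks cannot be duplicated on one read and still co-cluster under the
  200 bp bias, so DEL reads have VC ∈ {0,1});
- haplotagging: each read phasable with probability 0.8, mis-assigned with
  probability 0.02;
- confidence scores: drawn per read from the empirical bins
  [0,300), [300,900), [900,1500), [1500,8100), [8100,72600), [72600,∞),
  integer-valued so the float32 BAM tag is lossless. True-locus reads use
  weights concentrated in the moderate bins (0.10/0.35/0.30/0.22/0.025/0.005);
  false-locus reads use weights concentrated at the extremes
  (0.35/0.07/0.05/0.08/0.30/0.15). The bin *structure* is empirical; the
  weights are free simulator parameters, not measured quantities;
- false candidates: 1–2 supporting reads irrespective of haplotype.

Two presets define the study conditions used by the tests and the acceptance
script. `noise_free()` (20×, perfect tagging, no dropout, no false
candidates, no confidence mass above 8100 — aberrant confidence *is* a noise
mode) is the regime where the pipeline must recover every locus perfectly.
`adversarial_low_coverage()` (8×, 200 true + 200 false loci, false
supporters drawn from the ≥8100 bins) is the regime where the decision path
should beat the single-feature baselines; problem sizes (500 loci noise-free,
20 × 400 loci adversarial) were chosen to make both studies decisive yet
quick on one CPU.

What the simulator does **not** model: base-level sequence and ONT error
profiles, mapping ambiguity and partial spanning, coverage heterogeneity,
multi-chromosome phase-block fragmentation, and SV classes other than INS/DEL.
Passing the noise-free and adversarial studies therefore demonstrates the
correctness and the discriminative logic of the decision path under its own
assumptions, not genome-wide accuracy on real sequencing data.

## Numerical and degenerate-input choices

- Boundary inclusivity at layer 2 is strict (< T3, > T4), so p_SV exactly at
  a boundary falls through to layer 3.
- Σ_PC ties at layer 3 give 1|1 (ratio 1 is "no difference" by definition);
  the dominant-haplotype tie-break (≥) is unreachable because ties never
  exceed T5 ≥ 1.
- Reads with HP but no confidence score get PC = 0 (conservative); unphased
  reads contribute nothing to any confidence sum. Supplementary alignments
  inherit HP/PS from their primary.
- Median ties in clustering take the lower middle value; mark-to-candidate
  assignment in the VCF-bypass mode uses the same merge rule with
  nearest-candidate tie-breaking.
- Candidates whose spanning reads include no supporter are discarded with a
  log entry (they violate the candidate invariant).

## Known limitations

- Thresholds are fixed, not coverage-adaptive; at high coverage the p_SV
  layers dominate and the confidence layers add less.
- The evaluator's many-to-one matching never deduplicates calls; callers
  that emit near-duplicate records are flattered at the calling level.
- The internal candidate generator is a minimal CIGAR + split-read extractor
  intended for haplotagged fixtures and modest datasets; production call
  sets from a dedicated base caller can be supplied via `--candidates` to
  bypass it.
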