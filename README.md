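# duophase

SNP-assisted structural-variant (SV) genotyping and phasing from haplotagged
long-read alignments.

## The problem

Long-read SV callers decide whether a candidate insertion or deletion is real
from the number (N_SV) and fraction (p_SV) of reads carrying SV signatures at
the locus. At low sequencing coverage (~8×) both true SVs and alignment
artifacts are often supported by only one or two reads, so these
single-feature filters lose their discriminative power — and they say nothing
about which parental haplotype carries a heterozygous SV.

duophase adds the read-level SNP-phasing evidence that modern workflows
already produce: after small variants are called, phased and used to haplotag
the reads, each read carries a haplotype label (`HP` 1/2), a phase-set block
(`PS`), and a phasing-confidence score (PC, positively related to the number
of accurately phased SNPs the read covers). Every read spanning a candidate
locus contributes a signature triple **(HP, PC, VC)**, where VC counts the
read's SV marks supporting the candidate. From these, five locus-level
features are integrated:

| feature | definition | meaning |
|---|---|---|
| p_SV | Σ_{VC>0} / Σ_{VC≥0} | fraction of spanning reads with SV marks |
| p_HP | Σ_{VC,HP>0} / Σ_{VC>0} | fraction of supporting reads that are phasable |
| Σ_PC | Σ VC·PC per HP | total weighted confidence per haplotype |
| μ_PC | mean VC·PC per HP | average weighted confidence per haplotype |
| p_ΣPC | Σ_PC1 / Σ_PC2 | haplotype confidence imbalance |

A three-layer decision path with thresholds T1–T5 classifies each candidate:

1. **Signal-quality filter** — distrust candidates whose supporters show
   untrustworthy phasing evidence: too few phasable supporters
   (p_HP < T1) or an excessively high average confidence (μ_PC > T2 = 8100,
   the regime empirically dominated by false SV signals) → `0/0`.
2. **Support fraction** — p_SV < T3 (0.2) → false signal `0/0`;
   p_SV > T4 (0.8) → homozygous `1|1`.
3. **Haplotype imbalance** — in the moderate band, compare Σ_PC1 with Σ_PC2:
   no huge difference (ratio ≤ T5) → `1|1`; otherwise heterozygous, assigned
   to the dominant haplotype (`1|0` or `0|1`) with its phase-set block.

The package also implements the matching three-level benchmark. A call
matches a truth record when |comp_s − base_s| ≤ 1 kbp,
min(L)/max(L) ≥ 0.4 and the SV class agrees; precision = TP/(TP+FP),
recall = TP/(TP+FN), F1 their harmonic mean. Genotyping additionally requires
the right het/hom class, and phasing scores haplotype orientation per phase
set under both the original and the flipped orientation, keeping the better
one (orientation within a block is arbitrary). A seed-reproducible diploid
simulator generates truth sets, per-locus signatures and BAM/VCF fixtures
with the confidence-bin structure the method relies on.

## Worked example

Simulate an adversarial low-coverage dataset (8×, 50 true SVs, 50 false
candidates whose supporters carry excessively high phasing confidence), call
it end to end, and benchmark against the truth:

```python
from duophase import (SimConfig, simulate_dataset, emit_fixture,
                      call_pipeline, calls_to_records, evaluate_all)

cfg = SimConfig.adversarial_low_coverage(n_true_sv=50, n_false_candidates=50, seed=7)
truth, loci = simulate_dataset(cfg)
paths = emit_fixture(loci, cfg, "demo")          # BAM + truth VCF + manifest
calls = call_pipeline(str(paths["bam"]))
reports = evaluate_all(calls_to_records(calls), truth)
```

This prints (via the snippet in the repo):

```
80 candidates -> 44 calls
chr1:625877 INS len=1070 GT=0|1 layer=3 p_SV=0.50 p_HP=1.00 sigma_PC=(0,7725)
chr1:1288945 DEL len=361 GT=1|1 layer=2 p_SV=0.82 p_HP=1.00 sigma_PC=(20198,5390)
calling    TP= 44 FP= 0 FN= 6 P=1.000 R=0.880 F1=0.936
genotyping TP= 41 FP= 3 FN= 9 P=0.932 R=0.820 F1=0.872
phasing    TP= 41 FP= 3 FN= 9 P=0.932 R=0.820 F1=0.872
```

Reading the output: 100 simulated loci yield 80 clustered candidates (false
signals with a single supporting read never reach the candidate stage); the
decision path then filters most remaining false candidates — here with no
false positives at the calling level. The first call is a heterozygous
insertion assigned to haplotype 2 at layer 3 because all of its supporting
confidence sits on one haplotype (Σ_PC = 0 vs 7725); the second is homozygous
at layer 2 from its high support fraction (p_SV = 0.82 > 0.8).

The same workflow is available from the shell:

```bash
duophase simulate --config config.toml --seed 5 --out-dir fx
duophase call --bam fx/fixture.bam --out calls.vcf --report features.tsv
duophase eval --calls calls.vcf --truth fx/truth.vcf --out report.tsv
```

Thresholds, clustering parameters and simulation settings live in the TOML
sections `[thresholds]`, `[clustering]` and `[simulation]`.

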