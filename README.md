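# mpcall

Multi-platform small-variant calling at desk scale: a fully testable
re-implementation of a two-part deep-learning variant-calling workflow that
consumes aligned reads from **two sequencing platforms of the same sample**
(e.g. short accurate Illumina-like reads plus long noisy nanopore-like
reads) and emits a single VCF. It is aimed at method developers and students
who want to study how multi-platform evidence integration works —
candidate extraction, read-backed phasing, read-level tensor encoding, a
multi-task CNN, and genotype-aware benchmarking — on laptop-sized synthetic
data, with every stage unit-testable against a built-in simulator.

## The method

**Part one (per platform).** An mpileup-style recount summarizes per-position
allele evidence; positions passing depth / alt-count / allele-fraction
thresholds become candidates. Each candidate window is encoded as a 33 × 18
integer pileup input (594 integers) and scored by a small two-task network
(21 genotypes + zygosity). The calls are split into variant calls
(0/1, 1/1, 1/2) and reference calls (0/0) and ranked by QUAL; the **top 70 %
of heterozygous SNP calls** seed a read-backed phaser that haplotags the
alignments (HP/PS tags).

**Part two (joint).** Candidates from all platforms are merged; around each
site every platform's haplotagged reads are encoded into an 8-channel
tensor — reference base, alternative base, strand, mapping quality, base
quality, candidate proportion, insertion base, phasing — of shape
(8, 33, 89) per platform, concatenated to (8, 33, 178) = **46,992 integers**
for two platforms (an optional difficult-region stratification channel with
a 50/100 value makes it (9, 33, 178) = **52,866**). An N-to-1 multi-task CNN
(three residual blocks, each topped by a convolution, then spatial pyramid
pooling; four heads: 21 genotypes, zygosity, two indel lengths) genotypes
every candidate; QUAL = −10·log₁₀(1 − p_max).

Training downsamples reads to a grid of coverage pairs (default
{10, 20, 30}× × {10, 20, 30}×), mixes candidate sites at a **1:5
variant:reference** ratio, and holds out **10 %** of examples for
validation. The genotype-aware evaluator reports precision / recall / F1
overall, by SNP vs indel, and per stratification region.

The neural-network core (convolutions, residual blocks, SPP, multi-head
softmax, Adam) is implemented in numpy with hand-written backward passes —
small enough to train in minutes on one CPU and fully deterministic under a
seed.

## Worked example

```bash
mpcall simulate -o fixture --seed 3
mpcall train --fixture fixture -o models
mpcall call --platform-a fixture/illumina.bam --platform-b fixture/ont.bam \
            --ref fixture/ref.fa --model models -o calls.vcf
mpcall evaluate --calls calls.vcf --truth fixture/truth.vcf \
                --strat fixture/difficult.bed -o report
```

`simulate` writes a 100 kb diploid reference, a phased truth VCF
(~120 planted SNPs/indels), a difficult-region BED, and one
coordinate-sorted BAM per platform. `train` prints the coverage pairings it
trained on and the input channel count, e.g.:

```
coverage pairings trained: 10x-10x, 10x-20x, 10x-30x, 20x-10x, 20x-20x,
20x-30x, 30x-10x, 30x-20x, 30x-30x
input channels: 8
models written to models
```

`evaluate` prints the genotype-aware report. `examples/04_full_workflow.py`
runs the same pipeline from Python on a deliberately tiny fixture (30 kb,
one coverage pair, 16 epochs, minutes of CPU) and prints:

```
 region  type  tp  fp  fn  precision   recall       f1
overall   ALL  63  16  15   0.797468 0.807692 0.802548
overall   SNP  62  16  10   0.794872 0.861111 0.826667
overall INDEL   1   0   5   1.000000 0.166667 0.285714
```

(tp/fp/fn are genotype-aware matches against the planted truth; the
SNP/INDEL rows split the same comparison by variant type). At the
package's standard scale — the default 100 kb fixture, multi-pair
coverage grids, more epochs, as run by `scripts/acceptance.py` — the same
pipeline reaches SNP F1 1.00 on zero-error reads and ≈0.96 on the noisy
default profiles. The `examples/` directory holds runnable scripts for
each capability — simulation, candidate extraction, phasing, the full
workflow, and stratified evaluation — as a Python-API tour of the same
pipeline.

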