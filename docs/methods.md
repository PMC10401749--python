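# Methods

`mpcall` re-implements, at desk scale, a two-part multi-platform
small-variant calling workflow for a single diploid sample sequenced on two
platforms (e.g. short accurate reads plus long noisy reads), together with
the synthetic data generator that makes every stage testable without
external downloads. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic fixtures do and do
not establish about real data.

## The calling workflow

**Part one (per platform).** An mpileup-style recount summarizes every
covered reference position into per-strand counts of A/C/G/T, insertion
events and inserted bases (attributed to the anchor position on the left),
deleted positions and deletion anchors, and a low-quality bucket (reads
under the MAPQ floor, bases under the baseQ floor). Positions pass to the
candidate set when depth ≥ `min_depth` (4) and some alt allele has count ≥
`min_alt_count` (2) and allele fraction ≥ its floor — `min_af` (0.12) for
substitutions, `min_indel_af` (0.40 long-read, 0.15 short-read) for indel
alleles. Candidates are encoded as a
33 × 18 integer matrix (33 genome positions × 9 evidence categories × 2
strands, each normalized to 0–100 by column depth; 594 integers) and scored
by a small two-task convolutional model (21-genotype and zygosity heads).
The resulting calls are partitioned into variant calls (0/1, 1/1, 1/2) and
reference calls (0/0), ranked by QUAL; the top 70 % (floor of 0.7·n,
QUAL-descending, position-ascending tie-break) of heterozygous SNP calls
seed a read-backed phaser, and reads are haplotagged (HP/PS tags) by
majority vote over the selected SNPs they cover.

**Part two (joint).** Per-platform candidate sets are merged by (contig,
position) — evidence summed, provenance recorded. Around each merged
candidate, each platform's haplotagged reads are encoded into an 8-channel
integer tensor of shape (8, 33, 89): one row per read overlapping the
33-position window, channels = reference base, alternative base, strand,
mapping quality, base quality, candidate proportion, insertion base, and
phasing information, all coded into 0–100 (code table in
`fullalign.py`, versioned as `fullalign-8ch-v1`). The two platform tensors
are concatenated along read rows into the (8, 33, 178) multi-platform input
of 46,992 integers; an optional ninth stratification channel — constant 100
when the candidate lies in a difficult region, 50 otherwise — grows the
input to 52,866 integers. The N-to-1 network scores every candidate with
four softmax heads (21 genotypes, zygosity, two indel lengths); the argmax
genotype class is decoded to VCF alleles using the site's reference base
and its modal insertion sequence / deletion length, reference calls are
suppressed, and QUAL is −10·log₁₀(1 − p_max) capped at 60.

## The network

The full-alignment model is three standard residual blocks (two same-shape
3×3 convolutions with an identity skip), each followed by a convolution
that widens channels and strides down the read-row axis, after a stem
convolution with a (3, 9) kernel and (1, 8) row stride — every read row
falls inside some stem kernel footprint while the row axis, which carries
most of the CPU cost, is cut 8× immediately. After the third block a
spatial pyramid pooling layer pools the (positions × rows) plane at grids
(1×1), (2×2), (4×4), (33×1) and (33×2) with both max and mean pooling.
The (33×1) level keeps per-position structure (the candidate column is
always index 16); the (33×2) level pools each half of the row axis
separately, which in a two-platform input is exactly a per-platform
summary per position — without it the heads cannot separate short-read
evidence from long-read homopolymer noise and the noisy-fixture SNP F1
plateaus well below its final value. Every level is invariant to the
absolute number of read rows, so the same dense heads serve 1- and
2-platform inputs. Default widths are (12, 16, 24)
filters with a 96-unit shared hidden layer — deliberately small so training
runs in minutes on one CPU core; all widths are `NetworkSpec` parameters.

Training minimizes the unweighted sum of per-head cross-entropies with
Adam (lr 2·10⁻³, step-decayed ×0.3 for the final third of the epochs),
batch 64, float32, with 10 % of examples held out for validation and the
best-validation weights kept. All randomness flows from caller-supplied
seeds; repeated runs are bit-identical.

Training examples are generated by read-level downsampling to a grid of
coverage pairs (default: the nine pairs over {10, 20, 30}× per platform)
and the candidate sites are mixed at a 1:5 variant:reference ratio —
reference-call windows otherwise swamp the loss. Training alignments are
haplotagged by exactly the call-time machinery: the freshly trained pileup
model's calls are QUAL-ranked, the top 70 % of het SNP calls phase the
reads. Two alternatives that look equivalent are not. Tagging reads
directly with their true haplotype gives the phasing channel a globally
consistent gauge and an unrealistically clean tag distribution; a model
trained that way loses measurable recall at call time, where tags come
from imperfect preliminary calls with an arbitrary per-block,
per-platform gauge. Seeding the phaser with the true het SNVs fixes the
gauge statistics but still overstates tag quality on noisy reads. Using
the deployment path end to end removes the mismatch. On top of that,
each training example flips each platform's haplotype labels with
probability ½ (gauge augmentation): within a phase block the two labels
are only defined up to a global flip, and augmenting forces the network
to respect that symmetry instead of memorizing the particular labeling
the training phaser produced. On zero-error fixtures these two choices
together close the gap between held-out-example accuracy and call-time
recall (SNP recovery 0.95 → 1.00).

## The simulator

The generator plants SNPs (rate 10⁻³/base) and short indels (2·10⁻⁴/base,
lengths mostly 1–3, max 10) into a random diploid genome (default 100 kb
over 4 contigs), 60 % heterozygous with the alt on a random haplotype,
with a minimum spacing of `max_indel_len`+1 so every allele is
unambiguous. Low-complexity tracts (homopolymers of 8–20 bp, tandem
repeats of 2–4 bp units) are planted to cover ~15 % of each contig and
their padded spans become the difficult-region BED; one 400 bp segment per
contig is duplicated elsewhere and reads overlapping either copy can
receive MAPQ 0 (2 % of reads by default) to emulate ambiguous mapping.

Reads are drawn from the two haplotype sequences with start offsets that
may fall before the contig and extend past its end (truncating the read),
so coverage is uniform across each contig rather than ramping over a
read length at every contig end — on multi-kb reads and desk-sized
contigs those ramps would otherwise put a third of the genome at a
fraction of the nominal depth. Reads are emitted pre-aligned:
the simulator knows each read's haplotype interval, converts it to a
reference-anchored alignment through the planted-variant coordinate map,
injects platform errors, and writes the exact CIGAR. Default profiles:
`illumina` fixed 151 bp, 0.3 % substitutions, 0.01 % indels, MAPQ 60;
`ont` lognormal ~8 kb, 2 % substitutions, 2 % insertions, 3 % deletions
with a 5× multiplier inside read homopolymer runs (≥3 identical bases),
MAPQ 50; `hifi` fixed 12 kb, 0.2 % substitutions, 0.2 % indels, MAPQ 60 —
order-of-magnitude matches to the platforms' published error structure,
all overridable. The simulator also returns a per-read ledger (haplotype
of origin, injected edit counts) that tests use as ground truth.

What the simulator does **not** emulate: base-caller-specific error motifs
beyond homopolymer enrichment, quality-score calibration (base qualities
are constant per platform), GC/coverage bias, chimeric or supplementary
alignments, true mapping ambiguity (alignments are by construction
correct; MAPQ 0 is assigned, not earned), and structural variants. Passing
the recovery suites therefore shows that the pipeline's mechanics — 
candidate extraction, phasing, tensor encoding, the network, decoding and
evaluation — are correct and learnable end to end, not that the trained
desk-scale models transfer to real sequencing data.

## Thresholds and numerical choices

- Candidate floors: `min_af` 0.12 (both platform classes) applies to
  substitution alleles; indel alleles use a separate, higher
  `min_indel_af` (0.40 long-read, 0.15 short-read). With the ONT-like
  profile's error rates, lower floors mark large fractions of the genome
  as candidates (homopolymer-amplified deletions alone would flag roughly
  a quarter of it at a 0.08 floor); a separate indel floor is how
  production long-read callers handle exactly this error mode. True
  heterozygous alleles sit near allele fraction 0.5 and clear both floors
  at usable depth; on two-platform runs the short-read side also proposes
  indel candidates cleanly, and the merge unions them.
- Base-quality floor 13 for short reads, 0 for long reads (whose constant
  desk-scale base qualities carry no information); MAPQ floor 5 for the
  pileup counts, but MAPQ-0 reads are retained in full-alignment encoding
  — ambiguously mapped reads reaching the network is intentional.
- The 21-genotype task enumerates unordered pairs over {A, C, G, T, Ins,
  Del} in fixed lexicographic order; zygosity is {hom-ref, het, hom-alt};
  indel-length heads classify signed lengths into −15…+15 plus two
  overflow bins (33 classes each).
- The 70 % phasing cut uses floor(0.7·n) genome-wide (not per contig);
  both choices are exposed as parameters.
- Ties: QUAL ties in ranking break by ascending position; the phaser
  processes edges by descending vote margin and leaves tied reads
  unassigned; row overflow beyond the 89-row capacity keeps reads by
  (center overlap, MAPQ, start) before re-sorting by start.
- Degenerate inputs: empty windows encode to all-zero tensors; an empty
  phasing selection leaves every read untagged; empty call sets produce
  header-only VCFs; metrics with zero denominators report 0.

## Problem sizes used by the test and acceptance runs

The recovery runs train on the simulator's default 100 kb / 4-contig
genome at 30× per platform: the zero-error run with a four-pair coverage
grid — (30,30), (20,30), (30,20), (20,20) — and 22 full-alignment epochs,
the noisy run with the first three pairs and 14 epochs. The
multi-platform-benefit runs use the same genome with the fourth contig
held out for evaluation, 10× short reads plus 30× long reads (grids
varying the long-read fold), and 14 epochs. All runs use the 1:5 site
mix. These sizes were chosen as the smallest at which per-genotype-class
example counts support generalization rather than memorization; within-
fixture recovery is near-perfect, while F1 on held-out contigs — a
stricter test of cross-site generalization at this training-set size — is
substantially lower for both single- and two-platform models, and only
their ordering is treated as meaningful. The structural and oracle suites
are size-independent.

## Known limitations

- Exact-match, genotype-aware evaluation (no local realignment): correct
  because the synthetic truth and the caller share one left-anchored
  representation; it would under-credit equivalent representations on
  real data.
- The phaser is a greedy majority spanning assignment, not an exact
  minimum-error-correction solver; externally haplotagged BAMs (HP tags)
  are honoured as a drop-in replacement.
- Multi-allelic sites are limited to two alt alleles; only the modal
  insertion sequence / deletion length is materialized.
- Single sample, one or two platforms; no three-platform model.
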