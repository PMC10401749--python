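"""Select phasing SNPs and haplotag long reads.

Runs the first part of the workflow on a long-read set: pileup calling,
QUAL-ranked partitioning, the top-70% het-SNP selection, read-backed
phasing, and haplotagging — then checks the tags against the simulator's
haplotype-of-origin ledger.
"""

from mpcall import SimConfig, make_diploid_genome, simulate_reads
from mpcall.phasing import (partition_calls, phase_and_haplotag,
                            select_phasing_snps)
from mpcall.pileup_caller import (build_pileup_network, make_pileup_labels,
                                  pileup_call, train_pileup)
from mpcall.pipeline import encode_pileup_sites, run_pileup_stage
from mpcall.simdata import PlatformErrorProfile

genome = make_diploid_genome(SimConfig(genome_length=40_000, n_contigs=1,
                                       snp_rate=0.002, seed=9))
profile = PlatformErrorProfile(label="hifi", read_length_mean=4000)
reads, ledger = simulate_reads(genome, profile, 25, seed=3)

stage = run_pileup_stage(reads, genome.reference, "hifi")
train_sites = stage.variant_sites + stage.reference_sites[:200]
model = build_pileup_network(seed=0)
train_pileup(model, encode_pileup_sites(stage, train_sites),
             make_pileup_labels(train_sites, genome.truth), epochs=12, seed=0)

calls = pileup_call(model, encode_pileup_sites(stage, stage.variant_sites),
                    stage.variant_sites)
variants, refs = partition_calls(calls)
selection = select_phasing_snps(variants)          # top 70% het SNPs
print(f"{len(selection.ranked)} het SNP calls, "
      f"{len(selection.retained)} retained for phasing")

assignment = phase_and_haplotag(reads, selection)
tagged = [r for r in reads if r.hp is not None]
# within a phase block the two haplotype labels are only defined up to a
# flip, so concordance with the planted haplotypes is counted per block
by_block = {}
for r in tagged:
    by_block.setdefault((r.contig, r.phase_set), []).append(
        r.hp == ledger[r.read_id].haplotype)
total = ok = 0
for matches in by_block.values():
    ok += max(sum(matches), len(matches) - sum(matches))
    total += len(matches)
print(f"{len(tagged)}/{len(reads)} reads haplotagged in "
      f"{len(by_block)} phase blocks; {ok / total:.1%} concordant with "
      f"the planted haplotypes (up to a flip per block)")
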