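"""Pileup evidence summarization and candidate extraction.

Runs the mpileup-style recount over simulated reads, extracts variant
candidates with per-platform thresholds, and shows the evidence at one
planted heterozygous SNP.
"""

from mpcall import (DEFAULT_PROFILES, SimConfig, make_diploid_genome,
                    simulate_reads)
from mpcall.candidates import pileup
from mpcall.pipeline import run_pileup_stage

genome = make_diploid_genome(SimConfig(genome_length=30_000, n_contigs=1,
                                       seed=7))
reads, _ = simulate_reads(genome, DEFAULT_PROFILES["illumina"], 30, seed=2)

stage = run_pileup_stage(reads, genome.reference, "illumina")
print(f"{len(stage.variant_sites)} variant candidates, "
      f"{len(stage.reference_sites)} reference-call sites")

het = next(v for v in genome.truth if v.gt == "0/1" and v.is_snp)
col = pileup([r for r in reads if r.contig == het.contig],
             het.contig, het.pos, het.pos + 1)[0]
print(f"planted het SNP {het.ref}->{het.alts[0]} at {het.contig}:{het.pos}")
print(f"  depth {col.depth}: " +
      ", ".join(f"{b}={col.count(b)}" for b in "ACGT"))
# At a true het site roughly half the reads support the alternative base;
# the candidate passes the depth / alt-count / allele-fraction thresholds.
site = next(s for s in stage.variant_sites if s.position == het.pos)
print(f"  candidate allele fraction {site.allele_fraction:.2f} "
      f"(variant candidate: {site.is_variant_candidate})")
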