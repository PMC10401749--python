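"""Simulator contracts: determinism, planted-variant statistics, error profiles."""

import numpy as np
import pytest
from scipy import stats

from mpcall.align_io import write_bed, write_fasta, write_vcf
from mpcall.simdata import (DEFAULT_PROFILES, PlatformErrorProfile, SimConfig,
                            make_diploid_genome, simulate_reads,
                            truth_to_vcf_records)


def test_no_variants_when_rates_zero():
    cfg = SimConfig(genome_length=5000, n_contigs=1, snp_rate=0.0,
                    indel_rate=0.0, seed=3)
    genome = make_diploid_genome(cfg)
    assert len(genome.truth) == 0


def test_snp_count_within_binomial_bounds():
    L, rate = 100_000, 0.001
    cfg = SimConfig(genome_length=L, n_contigs=1, snp_rate=rate,
                    indel_rate=0.0, seed=21)
    genome = make_diploid_genome(cfg)
    n = len(genome.truth)
    lo, hi = stats.binom.ppf([1e-5, 1 - 1e-5], L, rate)
    assert lo <= n <= hi


def test_same_seed_byte_identical_outputs(tmp_path):
    cfg = SimConfig(genome_length=10_000, n_contigs=1, seed=9)
    files = []
    for run in ("a", "b"):
        genome = make_diploid_genome(cfg)
        reads, _ = simulate_reads(genome, DEFAULT_PROFILES["illumina"], 10,
                                  seed=5)
        d = tmp_path / run
        d.mkdir()
        write_fasta(genome.reference, d / "ref.fa")
        write_vcf(truth_to_vcf_records(genome.truth), genome.reference,
                  d / "truth.vcf")
        write_bed(genome.difficult, d / "difficult.bed")
        files.append(d)
    for name in ("ref.fa", "truth.vcf", "difficult.bed"):
        assert (files[0] / name).read_bytes() == (files[1] / name).read_bytes()


def test_unsatisfiable_variant_spacing_raises():
    cfg = SimConfig(genome_length=1000, n_contigs=1, snp_rate=0.4,
                    indel_rate=0.0, max_indel_len=10, seed=0)
    with pytest.raises(ValueError, match="spacing"):
        make_diploid_genome(cfg)


def test_ont_profile_requires_indel_dominated_error():
    with pytest.raises(ValueError, match="indel"):
        PlatformErrorProfile(label="ont", read_length_mean=5000,
                             sub_rate=0.05, ins_rate=0.01, del_rate=0.01)


def test_zero_coverage_raises(small_genome):
    with pytest.raises(ValueError):
        simulate_reads(small_genome, DEFAULT_PROFILES["illumina"], 0, seed=1)


def test_total_bases_match_requested_coverage(small_genome,
                                              clean_reads_30x):
    reads, _ = clean_reads_30x
    genome_len = sum(len(s) for s in small_genome.reference.values())
    total = sum(len(r.sequence) for r in reads)
    assert abs(total / genome_len - 30) / 30 < 0.10


def test_zero_noise_reads_match_reference_except_planted_variants(
        small_genome, clean_reads_30x):
    """With zero error rates, every mismatch/indel in a read is a planted
    variant of its haplotype of origin."""
    reads, ledger = clean_reads_30x
    truth_pos = {}
    for v in small_genome.truth:
        for hap in (1, 2):
            if v.gt == "1/1" or (v.gt == "0/1" and v.hap == hap):
                truth_pos.setdefault((v.contig, hap), set()).add(v.pos)
    checked_mismatches = 0
    for r in reads[:300]:
        assert ledger[r.read_id].n_sub == ledger[r.read_id].n_ins == \
            ledger[r.read_id].n_del == 0
        hap = ledger[r.read_id].haplotype
        allowed = truth_pos.get((r.contig, hap), set())
        ref = small_genome.reference[r.contig]
        for ref_pos, read_idx, op in r.walk():
            if op == "M" and r.sequence[read_idx] != ref[ref_pos]:
                assert ref_pos in allowed
                checked_mismatches += 1
            elif op == "D":
                # deleted positions follow a planted deletion anchor
                assert any(p in allowed for p in range(ref_pos - 11, ref_pos))
    assert checked_mismatches > 0


def test_long_noisy_profile_has_more_indel_edits_than_short_accurate(
        small_genome):
    _, led_ont = simulate_reads(small_genome, DEFAULT_PROFILES["ont"], 10,
                                seed=13)
    _, led_ilmn = simulate_reads(small_genome, DEFAULT_PROFILES["illumina"],
                                 10, seed=14)
    per_base_ont = (sum(e.n_ins + e.n_del for e in led_ont.values())
                    / max(1, sum(1 for _ in led_ont)))
    # normalize per read length
    mean_indels_ont = np.mean([e.n_ins + e.n_del for e in led_ont.values()])
    mean_indels_ilmn = np.mean([e.n_ins + e.n_del for e in led_ilmn.values()])
    assert mean_indels_ont > mean_indels_ilmn


def test_homopolymer_indel_enrichment(small_genome):
    """The ONT-like profile concentrates indels in homopolymer runs."""
    profile = PlatformErrorProfile(
        label="ont", read_length_mean=2000, sub_rate=0.0, ins_rate=0.01,
        del_rate=0.01, homopolymer_indel_multiplier=5.0)
    reads, ledger = simulate_reads(small_genome, profile, 15, seed=17)
    n_edits = sum(e.n_ins + e.n_del for e in ledger.values())
    flat = PlatformErrorProfile(
        label="ont", read_length_mean=2000, sub_rate=0.0, ins_rate=0.01,
        del_rate=0.01, homopolymer_indel_multiplier=1.0)
    _, ledger_flat = simulate_reads(small_genome, flat, 15, seed=17)
    n_flat = sum(e.n_ins + e.n_del for e in ledger_flat.values())
    assert n_edits > n_flat


def test_het_allele_balance_is_binomial(small_genome, clean_reads_30x):
    """At het sites with zero error, alt fraction ~ Binomial(depth, 0.5)."""
    from mpcall.candidates import pileup
    reads, _ = clean_reads_30x
    fractions = []
    for v in small_genome.truth:
        if v.gt != "0/1" or not v.is_snp:
            continue
        contig_reads = [r for r in reads if r.contig == v.contig]
        cols = pileup(contig_reads, v.contig, v.pos, v.pos + 1)
        if not cols:
            continue
        c = cols[0]
        if c.depth >= 15:
            fractions.append(c.count(v.alts[0]) / c.depth)
    assert len(fractions) > 5
    # pooled check: mean allele fraction close to 0.5
    assert abs(np.mean(fractions) - 0.5) < 0.1


def test_truth_coverage_at_10x(small_genome):
    """Nearly every truth site is covered by at least one read at 10x."""
    from mpcall.align_io import ReadIndex
    reads, _ = simulate_reads(small_genome, DEFAULT_PROFILES["illumina"], 10,
                              seed=23)
    idx = ReadIndex(reads)
    covered = sum(
        1 for v in small_genome.truth
        if idx.query(v.contig, v.pos, v.pos + 1))
    assert covered / len(small_genome.truth) >= 0.95


def test_mapq0_fraction_near_default(small_genome, clean_reads_30x):
    reads, _ = clean_reads_30x
    frac = np.mean([r.mapq == 0 for r in reads])
    assert 0.0 < frac <= 0.03
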