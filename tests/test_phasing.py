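"""Call partitioning, the top-70% het-SNP cut, and read-backed haplotagging."""

import math

import numpy as np
import pytest

from mpcall.align_io import GenomicWindow
from mpcall.candidates import CandidateSite
from mpcall.phasing import (partition_calls, phase_and_haplotag,
                            select_phasing_snps)
from mpcall.pileup_caller import PileupCall
from conftest import make_read


def _call(pos, gt, qual, ref="A", alts=("C",), contig="c"):
    site = CandidateSite(window=GenomicWindow(contig, pos), ref=ref,
                         alts={a: 5 for a in alts}, depth=20,
                         platforms={"p"}, is_variant_candidate=gt != "0/0")
    return PileupCall(site=site, gt=gt, ref=ref,
                      alts=alts if gt != "0/0" else (), qual=qual,
                      gt21_probs=np.full(21, 1 / 21),
                      zygosity_probs=np.full(3, 1 / 3))


def test_partition_by_genotype_groups():
    calls = [_call(10, "0/1", 30), _call(20, "1/1", 40),
             _call(30, "0/0", 50), _call(40, "1/2", 20, alts=("C", "G"))]
    variants, refs = partition_calls(calls)
    assert sorted(c.gt for c in variants) == ["0/1", "1/1", "1/2"]
    assert [c.gt for c in refs] == ["0/0"]
    # each group is QUAL-descending
    assert [c.qual for c in variants] == sorted(
        (c.qual for c in variants), reverse=True)


def test_partition_empty_and_missing_gt():
    assert partition_calls([]) == ([], [])
    bad = _call(10, "0/1", 30)
    bad.gt = ""
    with pytest.raises(ValueError, match="GT"):
        partition_calls([bad])


def test_partition_matches_predicate_oracle():
    rng = np.random.default_rng(2)
    gts = ["0/0", "0/1", "1/1", "1/2"]
    calls = [_call(int(p), gts[rng.integers(4)], float(rng.integers(1, 60)))
             for p in range(0, 1000, 10)]
    variants, refs = partition_calls(calls)
    assert {c.position for c in variants} == \
        {c.position for c in calls if c.gt != "0/0"}
    assert {c.position for c in refs} == \
        {c.position for c in calls if c.gt == "0/0"}


def test_top70_retains_seven_of_ten():
    calls = [_call(10 * i, "0/1", qual=10 + i) for i in range(10)]
    sel = select_phasing_snps(calls)
    assert len(sel.retained) == 7
    assert min(c.qual for c in sel.retained) == 13  # the 7 highest QUALs


def test_top70_empty_and_indel_exclusion():
    assert select_phasing_snps([]).retained == []
    calls = ([_call(10 * i, "0/1", 30 + i) for i in range(7)]
             + [_call(500 + 10 * i, "0/1", 50 + i, ref="A", alts=("ATT",))
                for i in range(3)])
    sel = select_phasing_snps(calls)
    # indels never enter the ranking: floor(0.7 * 7) = 4
    assert len(sel.ranked) == 7
    assert len(sel.retained) == 4
    assert all(len(c.alts[0]) == 1 for c in sel.retained)


def test_top70_floor_exhaustive():
    for n in range(101):
        calls = [_call(10 * i, "0/1", qual=float(i % 60)) for i in range(n)]
        sel = select_phasing_snps(calls)
        assert len(sel.retained) == math.floor(0.7 * n)


def _two_snp_reads(n_per_hap=5):
    """10 reads spanning two het SNPs at 105 and 115; hap1 = alt at both."""
    reads = []
    for i in range(n_per_hap):
        seq = list("A" * 20)
        seq[5] = "C"; seq[15] = "G"                  # alt alleles
        reads.append(make_read(f"h1_{i}", "c", 100, "".join(seq)))
    for i in range(n_per_hap):
        seq = list("A" * 20)                         # reference alleles
        reads.append(make_read(f"h2_{i}", "c", 100, "".join(seq)))
    return reads


def test_two_snp_block_tags_all_reads_up_to_global_flip():
    reads = _two_snp_reads()
    calls = [_call(105, "0/1", 30, ref="A", alts=("C",)),
             _call(115, "0/1", 40, ref="A", alts=("G",))]
    sel = select_phasing_snps(calls, retain_fraction=1.0)
    assignment = phase_and_haplotag(reads, sel)
    # one phase block
    assert len(set(assignment.phase_set.values())) == 1
    haps = {r.read_id: r.hp for r in reads}
    h1 = {haps[f"h1_{i}"] for i in range(5)}
    h2 = {haps[f"h2_{i}"] for i in range(5)}
    assert len(h1) == 1 and len(h2) == 1 and h1 != h2
    assert None not in (h1 | h2)


def test_read_covering_no_selected_snp_stays_unassigned():
    reads = _two_snp_reads() + [make_read("far", "c", 500, "A" * 20)]
    calls = [_call(105, "0/1", 30), _call(115, "0/1", 40, alts=("G",))]
    sel = select_phasing_snps(calls, retain_fraction=1.0)
    phase_and_haplotag(reads, sel)
    assert next(r for r in reads if r.read_id == "far").hp is None


def test_single_snp_splits_ref_and_alt_reads():
    reads = []
    for i in range(5):
        seq = list("A" * 20); seq[5] = "C"
        reads.append(make_read(f"alt{i}", "c", 100, "".join(seq)))
    for i in range(5):
        reads.append(make_read(f"ref{i}", "c", 100, "A" * 20))
    sel = select_phasing_snps([_call(105, "0/1", 30)], retain_fraction=1.0)
    phase_and_haplotag(reads, sel)
    alt_tags = {r.hp for r in reads if r.read_id.startswith("alt")}
    ref_tags = {r.hp for r in reads if r.read_id.startswith("ref")}
    assert alt_tags.isdisjoint(ref_tags)
    assert len(alt_tags) == 1 and len(ref_tags) == 1


def test_phasing_recovers_planted_haplotypes(small_genome,
                                             clean_long_reads_30x):
    """>= 95% of reads covering >= 2 selected SNPs are tagged concordantly
    with their haplotype of origin, up to a global flip per phase block."""
    reads, ledger = clean_long_reads_30x
    reads = [r for r in reads]  # session fixture: do not mutate order
    calls = [_call(v.pos, "0/1", 40.0, ref=v.ref, alts=v.alts,
                   contig=v.contig)
             for v in small_genome.truth if v.gt == "0/1" and v.is_snp]
    calls.sort(key=lambda c: (c.contig, c.position))
    sel = select_phasing_snps(calls, retain_fraction=1.0)
    snp_pos = {(c.contig, c.position) for c in sel.retained}
    try:
        assignment = phase_and_haplotag(reads, sel)
        concordant = discordant = 0
        by_block = {}
        for r in reads:
            covered = [k for k in snp_pos
                       if k[0] == r.contig and r.start <= k[1] < r.end]
            if len(covered) < 2 or r.hp is None:
                continue
            block = assignment.phase_set[covered[0]]
            true_hap = ledger[r.read_id].haplotype
            by_block.setdefault((r.contig, block), []).append(
                r.hp == true_hap)
        total = ok = 0
        for matches in by_block.values():
            # a global flip per block is allowed
            agree = sum(matches)
            ok += max(agree, len(matches) - agree)
            total += len(matches)
        assert total > 20
        assert ok / total >= 0.95
    finally:
        for r in reads:
            r.hp = None
            r.phase_set = None
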