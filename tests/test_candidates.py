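"""Pileup recount, candidate thresholds, platform merge, training subsample."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mpcall.align_io import GenomicWindow
from mpcall.candidates import (CandidateSite, extract_candidates,
                               merge_platform_candidates, pileup,
                               subsample_training_sites)
from conftest import make_read


def test_base_counts_at_single_position():
    reads = [make_read(f"r{i}", "c", 50, b * 10)
             for i, b in enumerate("AAACC")]
    cols = pileup(reads, "c", 55, 56)
    c = cols[0]
    assert c.depth == 5
    assert c.count("A") == 3
    assert c.count("C") == 2


def test_insertion_anchored_left_of_inserted_bases():
    # 10M2I10M: the insertion is attributed to the 10th aligned position
    read = make_read("r", "c", 100, "A" * 22, cigar=[("M", 10), ("I", 2),
                                                     ("M", 10)])
    cols = pileup([read], "c", 100, 130)
    by_pos = {c.position: c for c in cols}
    assert by_pos[109].count("ins") == 1
    assert by_pos[109].dominant_insertion == "AA"
    assert all(by_pos[p].count("ins") == 0 for p in by_pos if p != 109)
    # reference span: 100..119 (insertion consumes no reference)
    assert sorted(by_pos) == list(range(100, 120))


def test_deletion_counted_at_every_deleted_position():
    read = make_read("r", "c", 100, "A" * 20, cigar=[("M", 10), ("D", 3),
                                                     ("M", 10)])
    cols = pileup([read], "c", 100, 130)
    by_pos = {c.position: c for c in cols}
    for p in (110, 111, 112):
        assert by_pos[p].count("del") == 1
    assert by_pos[109].count("del_anchor") == 1
    assert by_pos[109].dominant_deletion == 3


def test_low_quality_reads_counted_in_lowq_bucket():
    good = make_read("g", "c", 0, "AAAA", mapq=60)
    bad = make_read("b", "c", 0, "CCCC", mapq=0)
    cols = pileup([good, bad], "c", 1, 2, min_mapq=5)
    c = cols[0]
    assert c.depth == 2
    assert c.count("A") == 1
    assert c.count("C") == 0
    assert c.count("lowq") == 1


def test_unsorted_reads_rejected():
    reads = [make_read("a", "c", 100, "AAAA"), make_read("b", "c", 50, "AAAA")]
    with pytest.raises(ValueError, match="sorted"):
        pileup(reads, "c", 0, 200)


def test_pileup_matches_naive_recount(small_genome, clean_reads_30x):
    """Columns equal a brute-force per-read per-position recount."""
    reads, _ = clean_reads_30x
    contig = "ctg1"
    lo, hi = 4000, 4200
    contig_reads = [r for r in reads if r.contig == contig]
    cols = {c.position: c for c in pileup(contig_reads, contig, lo, hi)}
    for pos in range(lo, hi):
        depth = 0
        counts = {}
        for r in contig_reads:
            if not (r.start <= pos < r.end):
                continue
            b = r.base_at(pos)
            if b is None:
                continue
            depth += 1
            if b == "*":
                counts["del"] = counts.get("del", 0) + 1
            else:
                counts[b] = counts.get(b, 0) + 1
        if depth == 0:
            assert pos not in cols
            continue
        c = cols[pos]
        assert c.depth == depth
        for b in "ACGT":
            assert c.count(b) == counts.get(b, 0), (pos, b)
        assert c.count("del") == counts.get("del", 0)


# ---------------------------------------------------------------------------
# candidate extraction rule
# ---------------------------------------------------------------------------

def _site_from(depth, alt_count, min_af=0.08, min_alt_count=2, min_depth=4):
    from mpcall.candidates import PileupColumn
    col = PileupColumn("c", 50, depth=depth)
    col.counts[("A", "+")] = depth - alt_count
    col.counts[("C", "+")] = alt_count
    ref = {"c": "A" * 100}
    sites = extract_candidates([col], ref, "p", min_af=min_af,
                               min_alt_count=min_alt_count,
                               min_depth=min_depth)
    return sites[0] if sites else None


def test_candidate_rule_examples():
    s = _site_from(depth=10, alt_count=3)
    assert s.is_variant_candidate and s.allele_fraction == pytest.approx(0.3)
    s = _site_from(depth=10, alt_count=0)
    assert s is not None and not s.is_variant_candidate
    assert _site_from(depth=3, alt_count=3) is None  # below depth floor


def test_candidate_rule_exhaustive_enumeration():
    """All (depth <= 20, alt <= depth) pairs agree with the stated rule."""
    min_af, min_alt, min_depth = 0.08, 2, 4
    for depth in range(1, 21):
        for alt in range(0, depth + 1):
            s = _site_from(depth, alt, min_af, min_alt, min_depth)
            expected_variant = (depth >= min_depth and alt >= min_alt
                                and alt / depth >= min_af)
            if depth < min_depth:
                assert s is None
            else:
                assert s.is_variant_candidate == expected_variant, (depth, alt)


@given(st.integers(4, 30), st.integers(0, 30),
       st.floats(0.01, 0.5), st.floats(0.01, 0.5))
@settings(deadline=None, max_examples=60)
def test_candidate_rule_monotone_in_min_af(depth, alt, af_lo, af_hi):
    """Raising the allele-fraction floor never adds a variant candidate."""
    alt = min(alt, depth)
    lo, hi = sorted((af_lo, af_hi))
    s_lo = _site_from(depth, alt, min_af=lo)
    s_hi = _site_from(depth, alt, min_af=hi)
    if s_hi is not None and s_hi.is_variant_candidate:
        assert s_lo.is_variant_candidate


# ---------------------------------------------------------------------------
# merge + subsample
# ---------------------------------------------------------------------------

def _candidate(contig, pos, ref="A", alts=None, depth=20, platform="p",
               variant=True):
    return CandidateSite(window=GenomicWindow(contig, pos), ref=ref,
                         alts=alts or {"C": 5}, depth=depth,
                         platforms={platform},
                         is_variant_candidate=variant)


def test_merge_is_keyed_union_with_provenance():
    ont = [_candidate("c", 100, platform="ont"),
           _candidate("c", 200, platform="ont")]
    ilmn = [_candidate("c", 200, platform="illumina"),
            _candidate("c", 300, platform="illumina")]
    merged = merge_platform_candidates([ont, ilmn])
    assert [s.position for s in merged] == [100, 200, 300]
    at200 = merged[1]
    assert at200.platforms == {"ont", "illumina"}
    assert at200.depth == 40
    assert at200.alts["C"] == 10


def test_merge_disjoint_lists_is_sorted_concatenation():
    a = [_candidate("c", p) for p in (10, 30)]
    b = [_candidate("c", p) for p in (20, 40)]
    merged = merge_platform_candidates([a, b])
    assert [s.position for s in merged] == [10, 20, 30, 40]


def test_merge_reference_mismatch_fails():
    with pytest.raises(ValueError, match="mismatch"):
        merge_platform_candidates([[_candidate("c", 100, ref="A")],
                                   [_candidate("c", 100, ref="G")]])


def test_merge_matches_set_union_oracle():
    rng = np.random.default_rng(3)
    pos_a = rng.choice(5000, size=500, replace=False)
    pos_b = rng.choice(5000, size=500, replace=False)
    a = [_candidate("c", int(p), platform="a") for p in sorted(pos_a)]
    b = [_candidate("c", int(p), platform="b") for p in sorted(pos_b)]
    merged = merge_platform_candidates([a, b])
    assert [s.position for s in merged] == sorted(set(pos_a) | set(pos_b))


def test_subsample_ratio_one_to_five():
    var = [_candidate("c", p) for p in range(100)]
    ref = [_candidate("c", 1000 + p, variant=False) for p in range(1000)]
    kept = subsample_training_sites(var, ref, ratio_ref_per_var=5, seed=1)
    assert len(kept) == 600
    assert sum(s.is_variant_candidate for s in kept) == 100


def test_subsample_keeps_all_when_supply_short():
    var = [_candidate("c", p) for p in range(100)]
    ref = [_candidate("c", 1000 + p, variant=False) for p in range(200)]
    assert len(subsample_training_sites(var, ref, 5, seed=1)) == 300


def test_subsample_zero_variants_keeps_nothing():
    ref = [_candidate("c", p, variant=False) for p in range(50)]
    assert subsample_training_sites([], ref, 5, seed=1) == []


@given(st.integers(0, 50), st.integers(0, 400))
@settings(deadline=None, max_examples=40)
def test_subsample_ratio_never_exceeds_five(n_var, n_ref):
    var = [_candidate("c", p) for p in range(n_var)]
    ref = [_candidate("c", 1000 + p, variant=False) for p in range(n_ref)]
    kept = subsample_training_sites(var, ref, 5, seed=0)
    n_kept_ref = len(kept) - n_var
    assert n_kept_ref <= 5 * n_var
    if n_ref >= 5 * n_var:
        assert n_kept_ref == 5 * n_var
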