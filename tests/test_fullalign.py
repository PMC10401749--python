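"""Full-alignment tensor shapes, channel semantics, and the N-to-1 network."""

import numpy as np
import pytest

from mpcall.align_io import GenomicWindow, StratificationIndex
from mpcall.candidates import CandidateSite
from mpcall.fullalign import (CoverageGrid, NetworkSpec, assemble_mp_input,
                              build_network, downsample_reads,
                              encode_platform, make_training_examples,
                              stratification_value)
from conftest import make_read


def _site(contig="c", pos=116, ref="A", af_alts=None, depth=20):
    s = CandidateSite(window=GenomicWindow(contig, pos), ref=ref,
                      alts=af_alts or {"C": 10}, depth=depth,
                      platforms={"p"}, is_variant_candidate=True)
    s.ref_context = "A" * 33
    return s


def _reads(n=10, contig="c", start=100, hp=None):
    return [make_read(f"r{i}", contig, start + i, "A" * 40, hp=hp)
            for i in range(n)]


# ---------------------------------------------------------------------------
# shape law
# ---------------------------------------------------------------------------

def test_per_platform_tensor_is_23496_elements():
    t = encode_platform(_reads(), _site().window, _site())
    assert t.shape == (8, 33, 89)
    assert t.size == 23_496


def test_two_platform_input_is_46992_elements():
    a = encode_platform(_reads(), _site().window, _site())
    b = encode_platform(_reads(), _site().window, _site())
    full = assemble_mp_input(a, b)
    assert full.shape == (8, 33, 178)
    assert full.size == 46_992


def test_stratification_channel_grows_input_to_52866():
    a = encode_platform(_reads(), _site().window, _site())
    b = encode_platform(_reads(), _site().window, _site())
    full = assemble_mp_input(a, b, strat_value=100)
    assert full.shape == (9, 33, 178)
    assert full.size == 52_866
    assert (full[8] == 100).all()


def test_assemble_rejects_wrong_shapes():
    a = encode_platform(_reads(), _site().window, _site())
    with pytest.raises(ValueError, match="shape"):
        assemble_mp_input(a, a[:, :, :50])


def test_empty_window_encodes_to_zero_tensor():
    t = encode_platform([], _site().window, _site())
    assert not t.any()
    z = assemble_mp_input(t, t)
    assert not z.any() and z.shape == (8, 33, 178)


# ---------------------------------------------------------------------------
# channel semantics
# ---------------------------------------------------------------------------

def test_haplotype_tag_changes_only_phasing_channel():
    site = _site()
    tagged = encode_platform(_reads(hp=1), site.window, site)
    untagged = encode_platform(_reads(hp=None), site.window, site)
    diff_channels = {c for c in range(8)
                     if not np.array_equal(tagged[c], untagged[c])}
    assert diff_channels == {7}


def test_alt_channel_marks_mismatches_only():
    site = _site(ref="A")
    # read matches the all-A reference except one C at window position 16
    seq = list("A" * 40)
    seq[16] = "C"
    read = make_read("r", "c", 100, "".join(seq))
    t = encode_platform([read], site.window, site)
    alt = t[1, :, 0]
    assert alt[16] != 0
    assert (alt[:16] == 0).all() and (alt[17:] == 0).all()


def test_row_overflow_downsample_is_deterministic():
    site = _site()
    reads = [make_read(f"r{i}", "c", 90 + (i % 30), "A" * 40)
             for i in range(200)]
    t1 = encode_platform(sorted(reads, key=lambda r: r.read_id), site.window,
                         site)
    t2 = encode_platform(list(reversed(reads)), site.window, site)
    np.testing.assert_array_equal(t1, t2)


def test_read_order_permutation_invariance():
    site = _site()
    reads = _reads(12)
    rng = np.random.default_rng(0)
    perm = list(reads)
    rng.shuffle(perm)
    np.testing.assert_array_equal(
        encode_platform(reads, site.window, site),
        encode_platform(perm, site.window, site))


def test_stratification_value_50_100():
    idx = StratificationIndex([("c", 100, 200)])
    assert stratification_value(idx, GenomicWindow("c", 150)) == 100
    assert stratification_value(idx, GenomicWindow("c", 250)) == 50
    empty = StratificationIndex([])
    assert stratification_value(empty, GenomicWindow("c", 150)) == 50


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def test_forward_produces_four_probability_heads():
    spec = NetworkSpec()
    net = build_network(spec, seed=0)
    x = np.random.default_rng(0).random((3, 8, 33, 178)).astype(np.float32)
    probs = net.predict_proba(x)
    assert set(probs) == {"gt21", "zygosity", "indel_len_1", "indel_len_2"}
    assert probs["gt21"].shape == (3, 21)
    assert probs["zygosity"].shape == (3, 3)
    assert probs["indel_len_1"].shape == (3, 33)
    for p in probs.values():
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-5)


def test_single_platform_spec_accepts_89_rows():
    spec = NetworkSpec(n_platforms=1)
    net = build_network(spec, seed=0)
    x = np.zeros((2, 8, 33, 89), dtype=np.float32)
    probs = net.predict_proba(x)
    assert probs["gt21"].shape == (2, 21)


def test_same_seed_identical_initial_weights():
    a = build_network(NetworkSpec(), seed=5)
    b = build_network(NetworkSpec(), seed=5)
    for p1, p2 in zip(a.params(), b.params()):
        np.testing.assert_array_equal(p1, p2)


def test_channel_mismatch_fails_at_forward():
    net = build_network(NetworkSpec(stratification=False), seed=0)
    x = np.zeros((1, 9, 33, 178), dtype=np.float32)
    with pytest.raises(Exception):
        net.forward(x)


# ---------------------------------------------------------------------------
# training examples
# ---------------------------------------------------------------------------

def test_default_grid_is_nine_pairs_over_10_20_30():
    grid = CoverageGrid()
    assert len(grid) == 9
    assert set(grid) == {(a, b) for a in (10.0, 20.0, 30.0)
                         for b in (10.0, 20.0, 30.0)}


def test_examples_cover_every_grid_pair(small_genome):
    sites = [_site("ctg1", 200), _site("ctg1", 400)]
    reads = {"p1": _reads(8, "ctg1", 180), "p2": _reads(8, "ctg1", 180)}
    grid = CoverageGrid()
    examples = make_training_examples(
        sites, reads, ["p1", "p2"], {"p1": 30.0, "p2": 30.0},
        small_genome.truth, grid, seed=0)
    assert len(examples) == 18
    assert {e.coverage_pair for e in examples} == set(grid)
    assert all(e.x.shape == (8, 33, 178) for e in examples)


def test_downsample_is_deterministic_and_proportional():
    reads = _reads(1000)
    a = downsample_reads(reads, 1 / 3, seed=4)
    b = downsample_reads(reads, 1 / 3, seed=4)
    assert [r.read_id for r in a] == [r.read_id for r in b]
    assert 0.25 < len(a) / 1000 < 0.42
    assert downsample_reads(reads, 1.0, seed=4) == reads
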