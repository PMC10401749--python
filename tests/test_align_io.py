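"""Format round-trips and coordinate conventions (0-based internal, 1-based VCF)."""

import numpy as np
import pysam
import pytest

from mpcall.align_io import (GenomicWindow, ReadIndex, StratificationIndex,
                             VcfRecord, in_difficult_region, load_alignments,
                             read_bed, read_fasta, read_vcf, write_alignments,
                             write_bed, write_fasta, write_vcf)
from conftest import make_read


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def test_vcf_het_snp_coordinate_convention(tmp_path):
    """A het SNP at 0-based 999 is written as POS=1000."""
    ref = {"ctg1": "A" * 2000}
    rec = VcfRecord("ctg1", 999, "A", ("C",), "0/1", qual=30.0)
    path = tmp_path / "x.vcf"
    write_vcf([rec], ref, path)
    line = [l for l in path.read_text().splitlines()
            if not l.startswith("#")][0]
    fields = line.split("\t")
    assert fields[:5] == ["ctg1", "1000", ".", "A", "C"]
    assert fields[9].startswith("0/1")


def test_vcf_header_only_is_parseable(tmp_path):
    ref = {"ctg1": "ACGT" * 100}
    path = tmp_path / "empty.vcf"
    write_vcf([], ref, path)
    with pysam.VariantFile(str(path)) as vf:
        assert list(vf) == []


def test_vcf_roundtrip_preserves_fields(tmp_path):
    rng = np.random.default_rng(4)
    bases = "ACGT"
    ref_seq = "".join(rng.choice(list(bases), size=5000))
    ref = {"ctg1": ref_seq}
    records = []
    pos = 10
    for i in range(50):
        pos += int(rng.integers(20, 60))
        r = ref_seq[pos]
        alt = bases[(bases.index(r) + 1) % 4]
        gt = ["0/1", "1/1"][i % 2]
        records.append(VcfRecord("ctg1", pos, r, (alt,), gt, qual=25.0,
                                 gq=25, dp=30, af=0.5))
    path = tmp_path / "rt.vcf"
    write_vcf(records, ref, path)
    back = read_vcf(str(path))
    assert len(back) == 50
    for a, b in zip(records, back):
        assert (a.contig, a.pos, a.ref, a.alts, a.gt) == \
            (b.contig, b.pos, b.ref, b.alts, b.gt)


def test_vcf_ref_mismatch_rejected(tmp_path):
    ref = {"ctg1": "AAAA"}
    rec = VcfRecord("ctg1", 1, "C", ("G",), "0/1")
    with pytest.raises(ValueError, match="REF mismatch"):
        write_vcf([rec], ref, tmp_path / "bad.vcf")


def test_vcf_unsorted_rejected(tmp_path):
    ref = {"ctg1": "AAAA"}
    recs = [VcfRecord("ctg1", 2, "A", ("C",), "0/1"),
            VcfRecord("ctg1", 1, "A", ("C",), "0/1")]
    with pytest.raises(ValueError, match="sorted"):
        write_vcf(recs, ref, tmp_path / "bad.vcf")


# ---------------------------------------------------------------------------
# BAM
# ---------------------------------------------------------------------------

def test_bam_roundtrip_with_hp_tags(tmp_path):
    reads = [
        make_read("r1", "ctg1", 100, "ACGTACGTAC", hp=1),
        make_read("r2", "ctg1", 150, "TTTTACGTAC", hp=2, strand="-"),
        make_read("r3", "ctg1", 300, "ACGTACGTAC"),
    ]
    path = str(tmp_path / "x.bam")
    write_alignments(reads, {"ctg1": 1000}, path)
    back = load_alignments(path)
    assert [r.read_id for r in back] == ["r1", "r2", "r3"]
    assert [r.hp for r in back] == [1, 2, None]
    assert [r.strand for r in back] == ["+", "-", "+"]
    assert back[0].sequence == "ACGTACGTAC"
    assert back[0].cigar == [("M", 10)]


def test_bam_region_query_interval_semantics(tmp_path, small_genome,
                                             clean_reads_30x):
    reads, _ = clean_reads_30x
    ref_lengths = {c: len(s) for c, s in small_genome.reference.items()}
    path = str(tmp_path / "r.bam")
    write_alignments(reads, ref_lengths, path)
    # whole-contig query returns every primary read of that contig
    whole = load_alignments(path, region=("ctg1", 0, ref_lengths["ctg1"]))
    expected = sorted(r.read_id for r in reads if r.contig == "ctg1")
    assert sorted(r.read_id for r in whole) == expected
    # [100, 200) returns exactly the reads whose span intersects it
    window = load_alignments(path, region=("ctg1", 100, 200))
    oracle = sorted(r.read_id for r in reads
                    if r.contig == "ctg1" and r.start < 200 and r.end > 100)
    assert sorted(r.read_id for r in window) == oracle
    # empty region -> empty stream
    assert load_alignments(path, region=("ctg1", 0, 0)) == []


def test_read_index_matches_linear_scan(clean_reads_30x):
    reads, _ = clean_reads_30x
    idx = ReadIndex(reads)
    rng = np.random.default_rng(0)
    for _ in range(50):
        s = int(rng.integers(0, 10_000))
        e = s + int(rng.integers(1, 500))
        got = {r.read_id for r in idx.query("ctg1", s, e)}
        want = {r.read_id for r in reads
                if r.contig == "ctg1" and r.start < e and r.end > s}
        assert got == want


# ---------------------------------------------------------------------------
# FASTA / BED / stratification
# ---------------------------------------------------------------------------

def test_fasta_roundtrip(tmp_path, small_genome):
    path = tmp_path / "ref.fa"
    write_fasta(small_genome.reference, path)
    back = read_fasta(path)
    assert back == small_genome.reference


def test_bed_roundtrip_and_gzip(tmp_path):
    import gzip
    ivs = [("ctg1", 100, 200), ("ctg1", 500, 800), ("ctg2", 0, 50)]
    path = tmp_path / "x.bed"
    write_bed(ivs, path)
    assert read_bed(str(path)) == ivs
    gz = tmp_path / "x.bed.gz"
    with gzip.open(gz, "wt") as fh:
        fh.write(path.read_text())
    assert read_bed(str(gz)) == ivs


def test_stratification_boundary_semantics():
    index = StratificationIndex([("ctg1", 100, 200)])
    assert in_difficult_region(index, GenomicWindow("ctg1", 100))
    assert not in_difficult_region(index, GenomicWindow("ctg1", 200))
    assert not in_difficult_region(index, GenomicWindow("ctg1", 99))
    assert in_difficult_region(index, GenomicWindow("ctg1", 199))
    # unknown contig is simply outside
    assert not in_difficult_region(index, GenomicWindow("ctgX", 100))


def test_stratification_matches_linear_scan():
    rng = np.random.default_rng(8)
    ivs = []
    pos = 0
    for _ in range(30):
        pos += int(rng.integers(10, 100))
        end = pos + int(rng.integers(1, 50))
        ivs.append(("ctg1", pos, end))
        pos = end
    index = StratificationIndex(ivs)
    for center in rng.integers(0, pos + 100, size=1000):
        center = int(center)
        want = any(s <= center < e for _, s, e in ivs)
        assert index.contains("ctg1", center) == want
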