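"""Alignment, reference, VCF and BED input/output plus coordinate conventions.

Every module in the package works in 0-based, half-open coordinates. The only
places 1-based coordinates appear are the VCF reader/writer boundaries in this
module. Alignments round-trip through coordinate-sorted BAM via pysam;
haplotype assignments travel on the conventional ``HP`` (and ``PS``) auxiliary
tags so externally haplotagged files interoperate.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pysam
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

_REF_CONSUMING = set("MDN=X")
_READ_CONSUMING = set("MIS=X")


@dataclass
class AlignedRead:
    """One primary alignment record.

    ``start`` is the 0-based leftmost reference position; ``cigar`` is a list
    of ``(op, length)`` with the standard SAM operator letters. ``hp`` is the
    haplotype tag (1, 2, or None for unassigned) and is filled in by the
    phasing stage.
    """

    read_id: str
    contig: str
    start: int
    cigar: List[Tuple[str, int]]
    sequence: str
    baseq: List[int]
    mapq: int
    strand: str = "+"
    hp: Optional[int] = None
    phase_set: Optional[int] = None
    platform: str = "unknown"

    @property
    def end(self) -> int:
        """0-based exclusive end of the reference span."""
        return self.start + sum(n for op, n in self.cigar if op in _REF_CONSUMING)

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and self.end > start

    def walk(self) -> Iterator[Tuple[int, Optional[int], str]]:
        """Yield (ref_pos, read_index, op) for every M/D/I event.

        For M: one tuple per aligned base. For D: one tuple per deleted
        reference position with read_index None. For I: a single tuple at the
        anchor (the reference position to the left), read_index pointing at
        the first inserted base.
        """
        rpos = self.start
        qpos = 0
        for op, n in self.cigar:
            if op in "M=X":
                for k in range(n):
                    yield rpos + k, qpos + k, "M"
                rpos += n
                qpos += n
            elif op == "I":
                yield rpos - 1, qpos, "I%d" % n
                qpos += n
            elif op in "DN":
                for k in range(n):
                    yield rpos + k, None, "D"
                rpos += n
            elif op == "S":
                qpos += n
            # H/P consume nothing we track

    def walk_window(self, w0: int, w1: int) -> Iterator[Tuple[int, Optional[int], str]]:
        """Like :meth:`walk` but restricted to ref positions in [w0, w1).

        Skips CIGAR blocks outside the window in O(1) per block, so the cost
        is proportional to the window size, not the read length.
        """
        rpos = self.start
        qpos = 0
        for op, n in self.cigar:
            if rpos >= w1 and op in _REF_CONSUMING:
                break
            if op in "M=X":
                lo = max(rpos, w0)
                hi = min(rpos + n, w1)
                for p in range(lo, hi):
                    yield p, qpos + (p - rpos), "M"
                rpos += n
                qpos += n
            elif op == "I":
                if w0 <= rpos - 1 < w1:
                    yield rpos - 1, qpos, "I%d" % n
                qpos += n
            elif op in "DN":
                lo = max(rpos, w0)
                hi = min(rpos + n, w1)
                for p in range(lo, hi):
                    yield p, None, "D"
                rpos += n
            elif op == "S":
                qpos += n

    def base_at(self, ref_pos: int) -> Optional[str]:
        """Read base aligned at ref_pos, '*' if deleted, None if not covered."""
        if not (self.start <= ref_pos < self.end):
            return None
        rpos = self.start
        qpos = 0
        for op, n in self.cigar:
            if op in "M=X":
                if rpos <= ref_pos < rpos + n:
                    return self.sequence[qpos + (ref_pos - rpos)]
                rpos += n
                qpos += n
            elif op == "I":
                qpos += n
            elif op in "DN":
                if rpos <= ref_pos < rpos + n:
                    return "*"
                rpos += n
            elif op == "S":
                qpos += n
        return None


@dataclass(frozen=True)
class GenomicWindow:
    """A symmetric window around a candidate position (default 33 bp wide)."""

    contig: str
    center: int
    half_width: int = 16

    @property
    def start(self) -> int:
        return self.center - self.half_width

    @property
    def end(self) -> int:
        return self.center + self.half_width + 1

    @property
    def size(self) -> int:
        return 2 * self.half_width + 1


class StratificationIndex:
    """Interval membership index over 0-based half-open regions per contig."""

    def __init__(self, intervals: Optional[Iterable[Tuple[str, int, int]]] = None):
        self._trees: Dict[str, IntervalTree] = {}
        self._warned: set = set()
        for contig, start, end in intervals or []:
            if end > start:
                self._trees.setdefault(contig, IntervalTree()).addi(start, end)

    @classmethod
    def from_bed(cls, path: str) -> "StratificationIndex":
        return cls(read_bed(path))

    def contains(self, contig: str, pos: int) -> bool:
        tree = self._trees.get(contig)
        if tree is None:
            if contig not in self._warned:
                self._warned.add(contig)
                log.info("contig %s absent from stratification index", contig)
            return False
        return bool(tree.overlap(pos, pos + 1))

    def intervals(self) -> List[Tuple[str, int, int]]:
        out = []
        for contig, tree in self._trees.items():
            out.extend((contig, iv.begin, iv.end) for iv in sorted(tree))
        return sorted(out)


class ReadIndex:
    """Fast interval queries over a fixed, start-sorted read collection."""

    def __init__(self, reads: Iterable[AlignedRead]):
        self._by_contig: Dict[str, List[AlignedRead]] = {}
        self._starts: Dict[str, List[int]] = {}
        self._max_span: Dict[str, int] = {}
        for r in sorted(reads, key=lambda r: (r.contig, r.start)):
            self._by_contig.setdefault(r.contig, []).append(r)
        for contig, rs in self._by_contig.items():
            self._starts[contig] = [r.start for r in rs]
            self._max_span[contig] = max(r.end - r.start for r in rs)

    def query(self, contig: str, start: int, end: int) -> List[AlignedRead]:
        """Reads whose alignment span intersects [start, end)."""
        import bisect
        rs = self._by_contig.get(contig)
        if not rs:
            return []
        starts = self._starts[contig]
        hi = bisect.bisect_left(starts, end)
        lo = bisect.bisect_left(starts, start - self._max_span[contig])
        return [r for r in rs[lo:hi] if r.end > start]


def in_difficult_region(index: StratificationIndex, window: GenomicWindow) -> bool:
    """True iff the window's center position falls inside any interval."""
    return index.contains(window.contig, window.center)


# ---------------------------------------------------------------------------
# BAM / SAM
# ---------------------------------------------------------------------------

def _cigar_tuples_to_pysam(cigar: List[Tuple[str, int]]) -> List[Tuple[int, int]]:
    order = "MIDNSHP=X"
    return [(order.index(op), n) for op, n in cigar]


def _cigar_tuples_from_pysam(cigartuples) -> List[Tuple[str, int]]:
    order = "MIDNSHP=X"
    return [(order[code], n) for code, n in cigartuples]


def write_alignments(reads: Sequence[AlignedRead], ref_lengths: Dict[str, int],
                     path: str, write_index: bool = True) -> None:
    """Write coordinate-sorted BAM (or SAM if the path ends in .sam)."""
    contigs = list(ref_lengths)
    platforms = sorted({r.platform for r in reads}) or ["unknown"]
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": ref_lengths[c]} for c in contigs],
        "RG": [{"ID": p, "PL": p, "SM": "sim"} for p in platforms],
    }
    mode = "w" if str(path).endswith(".sam") else "wb"
    ordered = sorted(reads, key=lambda r: (contigs.index(r.contig), r.start))
    with pysam.AlignmentFile(path, mode, header=header) as out:
        for r in ordered:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.query_sequence = r.sequence
            a.reference_id = contigs.index(r.contig)
            a.reference_start = r.start
            a.mapping_quality = r.mapq
            a.cigartuples = _cigar_tuples_to_pysam(r.cigar)
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(min(q, 93) + 33) for q in r.baseq))
            a.flag = 16 if r.strand == "-" else 0
            tags = [("RG", r.platform)]
            if r.hp is not None:
                tags.append(("HP", int(r.hp)))
            if r.phase_set is not None:
                tags.append(("PS", int(r.phase_set)))
            a.set_tags(tags)
            out.write(a)
    if write_index and mode == "wb":
        pysam.index(str(path))


def load_alignments(path: str, region: Optional[Tuple[str, int, int]] = None
                    ) -> List[AlignedRead]:
    """Load primary alignments, sorted by start, as AlignedRead records.

    ``region`` is (contig, start, end) 0-based half-open; requires an index.
    Unmapped, secondary and supplementary records are excluded.
    """
    out: List[AlignedRead] = []
    with pysam.AlignmentFile(path) as af:
        if region is not None:
            if not af.has_index():
                raise FileNotFoundError(
                    f"region query on {path} requires a .bai index")
            it = af.fetch(region[0], region[1], region[2])
        else:
            it = af.fetch() if af.has_index() else af
        for a in it:
            if a.is_unmapped or a.is_secondary or a.is_supplementary:
                continue
            if a.cigartuples is None:
                raise ValueError(f"malformed record (no CIGAR): {a.query_name}")
            tags = dict(a.get_tags())
            out.append(AlignedRead(
                read_id=a.query_name,
                contig=a.reference_name,
                start=a.reference_start,
                cigar=_cigar_tuples_from_pysam(a.cigartuples),
                sequence=a.query_sequence,
                baseq=(np.array(a.query_qualities, dtype=np.uint8)
                       if a.query_qualities is not None
                       else np.full(len(a.query_sequence), 30, np.uint8)),
                mapq=a.mapping_quality,
                strand="-" if a.is_reverse else "+",
                hp=tags.get("HP"),
                phase_set=tags.get("PS"),
                platform=tags.get("RG", "unknown"),
            ))
    out.sort(key=lambda r: (r.contig, r.start))
    return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: Dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str) -> Dict[str, str]:
    seqs: Dict[str, str] = {}
    name = None
    chunks: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable[Tuple[str, int, int]], path: str) -> None:
    with open(path, "w") as fh:
        for contig, start, end in intervals:
            fh.write(f"{contig}\t{start}\t{end}\n")


def read_bed(path: str) -> List[Tuple[str, int, int]]:
    """Read BED (0-based half-open); transparently handles gzip."""
    opener = gzip.open if str(path).endswith(".gz") else open
    out = []
    with opener(path, "rt") as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##FILTER=<ID=PASS,Description="All filters passed">
##INFO=<ID=P,Number=.,Type=String,Description="Platform support">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AF,Number=1,Type=Float,Description="Allele fraction">
##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">
"""


@dataclass
class VcfRecord:
    """A minimal single-sample VCF record with 0-based ``pos``."""

    contig: str
    pos: int
    ref: str
    alts: Tuple[str, ...]
    gt: str                       # e.g. "0/1", "1|0"
    qual: float = 0.0
    gq: Optional[int] = None
    dp: Optional[int] = None
    af: Optional[float] = None
    phase_set: Optional[int] = None
    info: str = "."


def write_vcf(records: Sequence[VcfRecord], reference: Dict[str, str],
              path: str, sample: str = "SAMPLE") -> None:
    """Write a single-sample VCF 4.2. Records must be sorted; ref checked."""
    order = {c: i for i, c in enumerate(reference)}
    prev = None
    for rec in records:
        key = (order.get(rec.contig, 1 << 30), rec.pos)
        if prev is not None and key < prev:
            raise ValueError("VCF records must be sorted by contig, position")
        prev = key
        refseq = reference.get(rec.contig)
        if refseq is not None:
            actual = refseq[rec.pos:rec.pos + len(rec.ref)]
            if actual.upper() != rec.ref.upper():
                raise ValueError(
                    f"REF mismatch at {rec.contig}:{rec.pos + 1}: "
                    f"record says {rec.ref!r}, reference has {actual!r}")
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for contig, seq in reference.items():
            fh.write(f"##contig=<ID={contig},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample}\n")
        for rec in records:
            fmt_keys, fmt_vals = ["GT"], [rec.gt]
            if rec.gq is not None:
                fmt_keys.append("GQ"); fmt_vals.append(str(int(rec.gq)))
            if rec.dp is not None:
                fmt_keys.append("DP"); fmt_vals.append(str(int(rec.dp)))
            if rec.af is not None:
                fmt_keys.append("AF"); fmt_vals.append(f"{rec.af:.4f}")
            if rec.phase_set is not None:
                fmt_keys.append("PS"); fmt_vals.append(str(int(rec.phase_set)))
            fh.write("\t".join([
                rec.contig, str(rec.pos + 1), ".", rec.ref,
                ",".join(rec.alts) if rec.alts else ".",
                f"{rec.qual:.2f}", "PASS", rec.info,
                ":".join(fmt_keys), ":".join(fmt_vals),
            ]) + "\n")


def read_vcf(path: str) -> List[VcfRecord]:
    """Read a single-sample VCF into records with 0-based positions."""
    out: List[VcfRecord] = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            sample = rec.samples[list(rec.samples)[0]]
            gt_idx = sample.get("GT")
            phased = getattr(sample, "phased", False)
            sep = "|" if phased else "/"
            gt = sep.join("." if a is None else str(a) for a in gt_idx) \
                if gt_idx is not None else "./."
            out.append(VcfRecord(
                contig=rec.contig,
                pos=rec.start,
                ref=rec.ref,
                alts=tuple(rec.alts or ()),
                gt=gt,
                qual=rec.qual or 0.0,
                gq=sample.get("GQ"),
                dp=sample.get("DP"),
                af=sample.get("AF"),
                phase_set=sample.get("PS"),
            ))
    return out
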