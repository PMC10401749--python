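"""Synthetic diploid genomes and pre-aligned multi-platform reads.

The simulator plants SNPs and short indels (het and hom) into a random
reference, builds the two haplotype sequences, and draws reads from the
haplotypes with platform-specific error profiles:

* a short accurate platform ("illumina": fixed 151 bp, ~0.3% substitutions),
* a long noisy platform ("ont": lognormal multi-kb reads, indel error above
  substitution error and further concentrated in homopolymer runs),
* a long accurate platform ("hifi": fixed 12 kb, ~0.2% errors).

Reads are emitted pre-aligned: the simulator knows each read's haplotype of
origin and its true reference interval, so it writes the exact CIGAR implied
by the planted variants plus the injected sequencing errors. No aligner is
involved, which keeps every downstream stage exactly testable. Low-complexity
tracts (homopolymers and tandem repeats) are planted together with the
"difficult region" intervals so that difficulty is biologically meaningful,
and reads over planted duplications receive mapping quality 0 to emulate
ambiguous mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .align_io import AlignedRead

BASES = "ACGT"


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Genome-level simulation parameters.

    Rates are per base; ``het_fraction`` is the fraction of planted variants
    that are heterozygous; ``difficult_fraction`` is the approximate fraction
    of the genome covered by difficult-region intervals.
    """

    genome_length: int = 100_000
    n_contigs: int = 4
    snp_rate: float = 1e-3
    indel_rate: float = 2e-4
    max_indel_len: int = 10
    het_fraction: float = 0.6
    difficult_fraction: float = 0.15
    mapq0_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for name in ("snp_rate", "indel_rate", "het_fraction",
                     "difficult_fraction", "mapq0_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1000")
        if self.max_indel_len < 1:
            raise ValueError("max_indel_len must be >= 1")
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be >= 1")


@dataclass(frozen=True)
class PlatformErrorProfile:
    """Read length and error model for one sequencing platform."""

    label: str
    read_length_mean: float
    read_length_lognormal_sigma: float = 0.0   # 0 => fixed length
    paired: bool = False
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    homopolymer_indel_multiplier: float = 1.0
    baseq_mean: int = 30
    mapq_assigned: int = 60

    def __post_init__(self):
        if self.sub_rate + self.ins_rate + self.del_rate >= 0.5:
            raise ValueError("total error rate must be < 0.5")
        if self.read_length_mean < 20:
            raise ValueError("read lengths must be >= 20 bases")
        if self.homopolymer_indel_multiplier < 1.0:
            raise ValueError("homopolymer_indel_multiplier must be >= 1")
        if self.label == "ont" and not (self.ins_rate + self.del_rate > self.sub_rate):
            raise ValueError("ont profile requires indel error above "
                             "substitution error")


DEFAULT_PROFILES: Dict[str, PlatformErrorProfile] = {
    "illumina": PlatformErrorProfile(
        label="illumina", read_length_mean=151, sub_rate=0.003,
        ins_rate=0.0001, del_rate=0.0001, baseq_mean=35, mapq_assigned=60),
    "ont": PlatformErrorProfile(
        label="ont", read_length_mean=8000, read_length_lognormal_sigma=0.35,
        sub_rate=0.02, ins_rate=0.02, del_rate=0.03,
        homopolymer_indel_multiplier=5.0, baseq_mean=15, mapq_assigned=50),
    "hifi": PlatformErrorProfile(
        label="hifi", read_length_mean=12000, sub_rate=0.002,
        ins_rate=0.001, del_rate=0.001, baseq_mean=35, mapq_assigned=60),
}


# ---------------------------------------------------------------------------
# Truth variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthVariant:
    """One planted variant. ``pos`` is 0-based; alleles are left-anchored."""

    contig: str
    pos: int
    ref: str
    alts: Tuple[str, ...]
    gt: str                      # "0/1", "1/1" or "1/2"
    hap: Optional[int] = None    # haplotype carrying the alt for 0/1

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)


@dataclass
class TruthSet:
    records: List[TruthVariant]

    def __post_init__(self):
        prev: Dict[str, int] = {}
        for r in self.records:
            if r.contig in prev and r.pos <= prev[r.contig]:
                raise ValueError("truth positions must be strictly increasing "
                                 f"per contig (at {r.contig}:{r.pos})")
            prev[r.contig] = r.pos
            if r.gt == "1/2" and len(set(r.alts)) != 2:
                raise ValueError("1/2 genotype requires two distinct alts")

    def by_contig(self, contig: str) -> List[TruthVariant]:
        return [r for r in self.records if r.contig == contig]

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


# ---------------------------------------------------------------------------
# Haplotype sequence + coordinate map
# ---------------------------------------------------------------------------

class HaplotypeMap:
    """One haplotype of one contig plus a haplotype<->reference alignment.

    Stores the haplotype sequence and a segment list of ``(op, ref0, hap0,
    length)`` with op in M (match block, may carry planted SNPs), I (hap-only
    insertion) and D (reference-only deletion), from which any haplotype
    interval can be converted to (reference start, alignment token list).
    """

    def __init__(self, ref_seq: str, variants: Sequence[TruthVariant], hap: int):
        seq: List[str] = []
        segs: List[Tuple[str, int, int, int]] = []
        rpos = 0
        hpos = 0

        def emit_match(length: int, block: str):
            nonlocal rpos, hpos
            if length > 0:
                segs.append(("M", rpos, hpos, length))
                seq.append(block)
                rpos += length
                hpos += length

        for v in variants:
            applies = v.gt == "1/1" or (v.gt == "0/1" and v.hap == hap)
            if not applies:
                continue
            emit_match(v.pos - rpos, ref_seq[rpos:v.pos])
            alt = v.alts[0]
            if len(v.ref) == 1 and len(alt) == 1:            # SNP
                segs.append(("M", rpos, hpos, 1))
                seq.append(alt)
                rpos += 1
                hpos += 1
            elif len(alt) > len(v.ref):                       # insertion
                emit_match(1, ref_seq[v.pos])
                ins = alt[1:]
                segs.append(("I", rpos, hpos, len(ins)))
                seq.append(ins)
                hpos += len(ins)
            else:                                             # deletion
                emit_match(1, ref_seq[v.pos])
                dlen = len(v.ref) - 1
                segs.append(("D", rpos, hpos, dlen))
                rpos += dlen
        emit_match(len(ref_seq) - rpos, ref_seq[rpos:])
        self.seq = "".join(seq)
        self.segs = segs
        self._hap_starts = np.array([s[2] for s in segs])

    def __len__(self):
        return len(self.seq)

    def slice(self, hs: int, he: int) -> Tuple[int, List]:
        """Alignment of haplotype interval [hs, he) against the reference.

        Returns (ref_start, tokens) where tokens are ('M', base), ('I', base)
        or ('D', length). Leading/trailing D/I are trimmed so the alignment
        starts and ends on an M.
        """
        i = int(np.searchsorted(self._hap_starts, hs, side="right")) - 1
        i = max(i, 0)
        tokens: List = []
        ref_start = None
        while i < len(self.segs):
            op, ref0, hap0, length = self.segs[i]
            if op == "M":
                lo = max(hs, hap0)
                hi = min(he, hap0 + length)
                if lo < hi:
                    if ref_start is None:
                        ref_start = ref0 + (lo - hap0)
                    for p in range(lo, hi):
                        tokens.append(("M", self.seq[p]))
                if hap0 >= he:
                    break
            elif op == "I":
                lo = max(hs, hap0)
                hi = min(he, hap0 + length)
                for p in range(lo, hi):
                    tokens.append(("I", self.seq[p]))
                if hap0 >= he:
                    break
            else:  # D consumes no haplotype; include when inside the window
                if hs < hap0 < he or (hap0 == hs and tokens):
                    tokens.append(("D", length))
                if hap0 >= he:
                    break
            i += 1
        # trim to first/last M
        while tokens and tokens[0][0] != "M":
            t = tokens.pop(0)
            if ref_start is not None and t[0] == "D":
                ref_start += t[1]
        while tokens and tokens[-1][0] != "M":
            tokens.pop()
        if ref_start is None:
            ref_start = 0
        return ref_start, tokens


@dataclass
class DiploidGenome:
    """Reference plus both haplotypes, truth set and difficult intervals."""

    reference: Dict[str, str]
    truth: TruthSet
    difficult: List[Tuple[str, int, int]]
    duplications: List[Tuple[str, int, int]]
    haplotypes: Dict[Tuple[str, int], HaplotypeMap] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

def _plant_tracts(seq: np.ndarray, target_bases: int,
                  rng: np.random.Generator) -> List[Tuple[int, int]]:
    """Overwrite random spots with homopolymer / tandem tracts; return spans."""
    L = len(seq)
    spans: List[Tuple[int, int]] = []
    covered = 0
    attempts = 0
    occupied = np.zeros(L, dtype=bool)
    while covered < target_bases and attempts < 10_000:
        attempts += 1
        if rng.random() < 0.5:                       # homopolymer
            tlen = int(rng.integers(8, 21))
            unit = BASES[rng.integers(4)]
            tract = unit * tlen
        else:                                        # tandem repeat
            ulen = int(rng.integers(2, 5))
            unit = "".join(BASES[rng.integers(4)] for _ in range(ulen))
            tract = unit * int(rng.integers(4, 11))
            tlen = len(tract)
        start = int(rng.integers(0, max(1, L - tlen)))
        if occupied[max(0, start - 25):start + tlen + 25].any():
            continue
        seq[start:start + tlen] = np.frombuffer(tract.encode(), dtype="S1")
        occupied[start:start + tlen] = True
        spans.append((start, start + tlen))
        covered += tlen + 20                          # tract plus padding
    return spans


def _merge_intervals(ivs: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    out: List[Tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def make_diploid_genome(config: SimConfig) -> DiploidGenome:
    """Build a diploid genome with planted variants and difficult regions.

    Variants are spaced at least ``max_indel_len + 1`` bases apart so every
    planted allele is unambiguous; raises if the requested rates make that
    spacing unsatisfiable.
    """
    rng = np.random.default_rng(config.seed)
    per_contig = config.genome_length // config.n_contigs
    reference: Dict[str, str] = {}
    difficult: List[Tuple[str, int, int]] = []
    duplications: List[Tuple[str, int, int]] = []
    records: List[TruthVariant] = []

    for ci in range(config.n_contigs):
        contig = f"ctg{ci + 1}"
        L = per_contig
        seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=L)

        tract_spans = _plant_tracts(seq, int(config.difficult_fraction * L), rng)
        ivs = [(max(0, s - 10), min(L, e + 10)) for s, e in tract_spans]

        # one duplicated segment per contig to emulate ambiguous mapping
        if L >= 5000:
            dlen = 400
            src = int(rng.integers(0, L // 2 - dlen))
            dst = int(rng.integers(L // 2, L - dlen))
            seq[dst:dst + dlen] = seq[src:src + dlen]
            duplications.append((contig, src, src + dlen))
            duplications.append((contig, dst, dst + dlen))
            ivs.extend([(src, src + dlen), (dst, dst + dlen)])

        ref_seq = seq.tobytes().decode()
        reference[contig] = ref_seq
        difficult.extend((contig, s, e) for s, e in _merge_intervals(ivs))

        # ---- plant variants with minimum spacing ----
        spacing = config.max_indel_len + 1
        n_snp = int(rng.binomial(L, config.snp_rate))
        n_indel = int(rng.binomial(L, config.indel_rate))
        n_total = n_snp + n_indel
        order = rng.permutation(L - 2 * spacing) + spacing
        chosen: List[int] = []
        taken = np.zeros(L, dtype=bool)
        for p in order:
            if len(chosen) == n_total:
                break
            if not taken[max(0, p - spacing):p + spacing + 1].any():
                chosen.append(int(p))
                taken[p] = True
        if len(chosen) < n_total:
            raise ValueError(
                f"variant rate too high: cannot place {n_total} variants on "
                f"{L} bp with minimum spacing {spacing}")
        kinds = ["snp"] * n_snp + ["indel"] * n_indel
        rng.shuffle(kinds)
        for p, kind in sorted(zip(chosen, kinds)):
            ref_base = ref_seq[p]
            if kind == "snp":
                alt = BASES[(BASES.index(ref_base) + int(rng.integers(1, 4))) % 4]
                ref_allele, alt_allele = ref_base, alt
            else:
                ilen = 1 + int(rng.binomial(config.max_indel_len - 1, 0.15)) \
                    if config.max_indel_len > 1 else 1
                if rng.random() < 0.5:               # insertion
                    ins = "".join(BASES[rng.integers(4)] for _ in range(ilen))
                    ref_allele, alt_allele = ref_base, ref_base + ins
                else:                                # deletion
                    ref_allele = ref_seq[p:p + 1 + ilen]
                    alt_allele = ref_base
            het = rng.random() < config.het_fraction
            gt = "0/1" if het else "1/1"
            hap = int(rng.integers(1, 3)) if het else None
            records.append(TruthVariant(contig, p, ref_allele,
                                        (alt_allele,), gt, hap))

    truth = TruthSet(records)
    genome = DiploidGenome(reference, truth, sorted(difficult), duplications)
    for contig, ref_seq in reference.items():
        variants = truth.by_contig(contig)
        for hap in (1, 2):
            genome.haplotypes[(contig, hap)] = HaplotypeMap(ref_seq, variants, hap)
    return genome


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadLedgerEntry:
    """Simulator-side record of a read's origin and injected errors."""

    haplotype: int
    n_sub: int
    n_ins: int
    n_del: int


def _homopolymer_mask(bases: List[str], min_run: int = 3) -> np.ndarray:
    n = len(bases)
    mask = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        j = i
        while j < n and bases[j] == bases[i]:
            j += 1
        if j - i >= min_run:
            mask[i:j] = True
        i = j
    return mask


def _tokens_to_read(tokens: List, ref_start: int, baseq: int
                    ) -> Tuple[int, List[Tuple[str, int]], str, List[int]]:
    """Compress alignment tokens into (start, CIGAR, sequence, qualities)."""
    while tokens and tokens[0][0] != "M":
        t = tokens.pop(0)
        if t[0] == "D":
            ref_start += t[1]
    while tokens and tokens[-1][0] != "M":
        tokens.pop()
    cigar: List[Tuple[str, int]] = []
    seq: List[str] = []
    for t in tokens:
        op = t[0]
        if op == "D":
            length = t[1]
        else:
            length = 1
            seq.append(t[1])
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + length)
        else:
            cigar.append((op, length))
    s = "".join(seq)
    return ref_start, cigar, s, np.full(len(s), baseq, dtype=np.uint8)


def _inject_errors(tokens: List, profile: PlatformErrorProfile,
                   rng: np.random.Generator) -> Tuple[List, int, int, int]:
    """Apply substitution/indel errors to alignment tokens.

    Insertion and deletion rates are multiplied by the profile's homopolymer
    multiplier at positions inside runs of >= 3 identical read bases.
    """
    if profile.sub_rate == profile.ins_rate == profile.del_rate == 0:
        return tokens, 0, 0, 0
    bases = [t[1] for t in tokens if t[0] != "D"]
    base_idx = [i for i, t in enumerate(tokens) if t[0] != "D"]
    hp = _homopolymer_mask(bases)
    n = len(bases)
    mult = np.where(hp, profile.homopolymer_indel_multiplier, 1.0)
    sub_hits = rng.random(n) < profile.sub_rate
    ins_hits = rng.random(n) < np.minimum(profile.ins_rate * mult, 0.45)
    del_hits = rng.random(n) < np.minimum(profile.del_rate * mult, 0.45)
    out: List = []
    n_sub = n_ins = n_del = 0
    bi = 0
    for i, t in enumerate(tokens):
        if t[0] == "D":
            out.append(t)
            continue
        op, base = t
        if del_hits[bi]:
            n_del += 1
            if op == "M":                      # ref base lost from the read
                out.append(("D", 1))
            # deleted inserted base vanishes entirely
        else:
            if sub_hits[bi]:
                n_sub += 1
                base = BASES[(BASES.index(base) + int(rng.integers(1, 4))) % 4]
            out.append((op, base))
        if ins_hits[bi]:
            n_ins += 1
            ilen = 1 + int(rng.geometric(0.7)) - 1
            for _ in range(max(1, min(ilen, 3))):
                out.append(("I", BASES[rng.integers(4)]))
        bi += 1
    # merge adjacent D tokens
    merged: List = []
    for t in out:
        if t[0] == "D" and merged and merged[-1][0] == "D":
            merged[-1] = ("D", merged[-1][1] + t[1])
        else:
            merged.append(list(t) if t[0] == "D" else t)
    return [tuple(t) if isinstance(t, list) else t for t in merged], n_sub, n_ins, n_del


def simulate_reads(genome: DiploidGenome, profile: PlatformErrorProfile,
                   coverage: float, seed: int,
                   mapq0_fraction: Optional[float] = None
                   ) -> Tuple[List[AlignedRead], Dict[str, ReadLedgerEntry]]:
    """Draw pre-aligned reads from the two haplotypes at the given coverage.

    Returns the coordinate-sorted reads and a ledger mapping read id to its
    haplotype of origin and injected error counts.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = np.random.default_rng(seed)
    reads: List[AlignedRead] = []
    ledger: Dict[str, ReadLedgerEntry] = {}
    for contig, ref_seq in genome.reference.items():
        L = len(ref_seq)
        mean_len = min(profile.read_length_mean, L)
        # reads may start before / run past the contig and are truncated, so
        # coverage is uniform across the contig instead of ramping at the
        # ends; n is scaled for the truncation loss
        margin = int(min(50, mean_len // 3))
        n_reads = int(round(coverage * (L + mean_len - 2 * margin)
                            / mean_len))
        if n_reads == 0:
            raise ValueError(
                f"coverage {coverage} yields zero reads on {contig}")
        for i in range(n_reads):
            hap = int(rng.integers(1, 3))
            hmap = genome.haplotypes[(contig, hap)]
            hlen = len(hmap)
            if profile.read_length_lognormal_sigma > 0:
                sigma = profile.read_length_lognormal_sigma
                mu = np.log(mean_len) - sigma ** 2 / 2
                rlen = int(rng.lognormal(mu, sigma))
            else:
                rlen = int(mean_len)
            rlen = max(20, min(rlen, hlen))
            m = int(min(margin, rlen // 2))
            offset = int(rng.integers(-(rlen - m), hlen - m))
            hs = max(0, offset)
            he = min(hlen, offset + rlen)
            if he - hs < 20:
                continue
            ref_start, tokens = hmap.slice(hs, he)
            tokens, n_sub, n_ins, n_del = _inject_errors(tokens, profile, rng)
            start, cigar, seq, quals = _tokens_to_read(
                tokens, ref_start, profile.baseq_mean)
            if not seq:
                continue
            rid = f"{profile.label}_{contig}_{i:06d}"
            reads.append(AlignedRead(
                read_id=rid, contig=contig, start=start, cigar=cigar,
                sequence=seq, baseq=quals, mapq=profile.mapq_assigned,
                strand="+" if rng.random() < 0.5 else "-",
                platform=profile.label))
            ledger[rid] = ReadLedgerEntry(hap, n_sub, n_ins, n_del)

    # ambiguous-mapping emulation: MAPQ 0 over planted duplications
    frac = mapq0_fraction
    if frac is None:
        frac = 0.02
    if genome.duplications and frac > 0:
        dup_by_contig: Dict[str, List[Tuple[int, int]]] = {}
        for contig, s, e in genome.duplications:
            dup_by_contig.setdefault(contig, []).append((s, e))
        candidates = [r for r in reads
                      if any(r.overlaps(s, e)
                             for s, e in dup_by_contig.get(r.contig, []))]
        n_target = min(len(candidates), int(round(frac * len(reads))))
        if n_target > 0:
            for idx in rng.choice(len(candidates), size=n_target, replace=False):
                candidates[idx].mapq = 0

    reads.sort(key=lambda r: (r.contig, r.start))
    return reads, ledger


def truth_to_vcf_records(truth: TruthSet):
    """Truth variants as phased VCF records (alt on its haplotype for hets)."""
    from .align_io import VcfRecord
    out = []
    for v in truth:
        if v.gt == "0/1":
            gt = "1|0" if v.hap == 1 else "0|1"
        elif v.gt == "1/1":
            gt = "1|1"
        else:
            gt = v.gt
        out.append(VcfRecord(contig=v.contig, pos=v.pos, ref=v.ref,
                             alts=v.alts, gt=gt, qual=60.0))
    return out
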