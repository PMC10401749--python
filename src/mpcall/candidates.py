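"""Per-position evidence summarization and candidate-site extraction.

Re-implements the mpileup-style recount used to seed the neural callers: for
every covered reference position, per-strand counts of matching bases,
insertions (attributed to the anchor position on their left), deletions
(counted at every deleted position, anchored at the left flank), and a
low-quality bucket for reads/bases failing the MAPQ/baseQ floors. Candidate
sites are extracted by depth / alt-count / allele-fraction thresholds, merged
across platforms by position, and subsampled for training at a fixed
variant:reference ratio.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .align_io import AlignedRead, GenomicWindow

STRANDS = ("+", "-")
# per-strand evidence categories tracked in a pileup column
CATEGORIES = ("A", "C", "G", "T", "ins", "ins_bases", "del", "del_anchor", "lowq")


@dataclass
class PileupColumn:
    """Evidence summary at one reference position (0-based)."""

    contig: str
    position: int
    depth: int = 0
    counts: Dict[Tuple[str, str], int] = field(default_factory=Counter)
    ins_seqs: Counter = field(default_factory=Counter)
    del_lens: Counter = field(default_factory=Counter)

    def count(self, category: str, strand: Optional[str] = None) -> int:
        if strand is not None:
            return self.counts.get((category, strand), 0)
        return sum(self.counts.get((category, s), 0) for s in STRANDS)

    @property
    def dominant_insertion(self) -> Optional[str]:
        if not self.ins_seqs:
            return None
        return max(sorted(self.ins_seqs), key=lambda s: self.ins_seqs[s])

    @property
    def dominant_deletion(self) -> Optional[int]:
        if not self.del_lens:
            return None
        return max(sorted(self.del_lens), key=lambda d: self.del_lens[d])


@dataclass
class CandidateSite:
    """A position forwarded to tensor encoding, with its allele evidence."""

    window: GenomicWindow
    ref: str
    alts: Dict[str, int]          # allele -> supporting read count
    depth: int
    platforms: Set[str] = field(default_factory=set)
    is_variant_candidate: bool = False

    @property
    def contig(self) -> str:
        return self.window.contig

    @property
    def position(self) -> int:
        return self.window.center

    @property
    def allele_fraction(self) -> float:
        if self.depth == 0 or not self.alts:
            return 0.0
        return max(self.alts.values()) / self.depth

    def top_alts(self, n: int = 2) -> List[str]:
        return sorted(self.alts, key=lambda a: (-self.alts[a], a))[:n]


def pileup(reads: Sequence[AlignedRead], contig: str, start: int, end: int,
           min_mapq: int = 5, min_baseq: int = 0) -> List[PileupColumn]:
    """Summarize per-position evidence over [start, end) from sorted reads.

    Reads with MAPQ below ``min_mapq`` and bases below ``min_baseq`` are
    tallied in the low-quality bucket rather than the allele counts; they
    still contribute to depth.
    """
    last = -1
    for r in reads:
        if r.contig == contig:
            if r.start < last:
                raise ValueError("pileup requires start-sorted reads")
            last = r.start
    cols: Dict[int, PileupColumn] = {}

    def col(pos: int) -> PileupColumn:
        c = cols.get(pos)
        if c is None:
            c = cols[pos] = PileupColumn(contig, pos)
        return c

    for r in reads:
        if r.contig != contig or not r.overlaps(start, end):
            continue
        s = r.strand
        low_read = r.mapq < min_mapq
        covered: Set[int] = set()
        for ref_pos, read_idx, op in r.walk():
            if not (start <= ref_pos < end):
                continue
            if op == "M":
                c = col(ref_pos)
                covered.add(ref_pos)
                base = r.sequence[read_idx].upper()
                if low_read or r.baseq[read_idx] < min_baseq or base not in "ACGT":
                    c.counts[("lowq", s)] += 1
                else:
                    c.counts[(base, s)] += 1
            elif op.startswith("I"):
                ilen = int(op[1:])
                c = col(ref_pos)
                if low_read:
                    c.counts[("lowq", s)] += 1
                else:
                    c.counts[("ins", s)] += 1
                    c.counts[("ins_bases", s)] += ilen
                    c.ins_seqs[r.sequence[read_idx:read_idx + ilen].upper()] += 1
            elif op == "D":
                c = col(ref_pos)
                covered.add(ref_pos)
                if low_read:
                    c.counts[("lowq", s)] += 1
                else:
                    c.counts[("del", s)] += 1
        # anchor full deletion events at the left flank
        rpos = r.start
        for cop, n in r.cigar:
            if cop in "M=X":
                rpos += n
            elif cop in "DN":
                if start <= rpos - 1 < end and not low_read:
                    c = col(rpos - 1)
                    c.counts[("del_anchor", s)] += 1
                    c.del_lens[n] += 1
                rpos += n
        for pos in covered:
            cols[pos].depth += 1
    return [cols[p] for p in sorted(cols)]


def extract_candidates(columns: Iterable[PileupColumn],
                       reference: Dict[str, str],
                       platform: str,
                       min_af: float = 0.08,
                       min_alt_count: int = 2,
                       min_depth: int = 4,
                       min_indel_af: Optional[float] = None,
                       half_width: int = 16) -> List[CandidateSite]:
    """Classify covered positions into variant / reference-call candidates.

    A site is a variant candidate iff depth >= min_depth AND some alt allele
    has count >= min_alt_count AND allele fraction >= its floor: ``min_af``
    for substitutions, ``min_indel_af`` (defaults to ``min_af``) for
    insertion/deletion alleles — indel evidence on noisy long reads needs a
    higher floor because systematic homopolymer indel error otherwise floods
    the candidate set. Sites meeting the depth floor but failing the allele
    test are kept as reference-call candidates for the training path to
    subsample.
    """
    if min_indel_af is None:
        min_indel_af = min_af
    out: List[CandidateSite] = []
    for c in columns:
        if c.depth < min_depth:
            continue
        ref_base = reference[c.contig][c.position].upper()
        alts: Dict[str, int] = {}
        for b in "ACGT":
            if b != ref_base:
                n = c.count(b)
                if n > 0:
                    alts[b] = n
        n_ins = c.count("ins")
        if n_ins > 0 and c.dominant_insertion:
            alts[ref_base + c.dominant_insertion] = n_ins
        n_del = c.count("del_anchor")
        if n_del > 0 and c.dominant_deletion:
            dlen = c.dominant_deletion
            ref_allele = reference[c.contig][c.position:c.position + 1 + dlen]
            # deletion candidate keyed by its left-anchored allele pair
            alts["-" + ref_allele] = n_del
        is_var = False
        for allele, n in alts.items():
            floor = min_af if len(allele) == 1 else min_indel_af
            if n >= min_alt_count and n / c.depth >= floor:
                is_var = True
                break
        out.append(CandidateSite(
            window=GenomicWindow(c.contig, c.position, half_width),
            ref=ref_base, alts=alts, depth=c.depth,
            platforms={platform}, is_variant_candidate=is_var))
    return out


def merge_platform_candidates(per_platform: Sequence[List[CandidateSite]]
                              ) -> List[CandidateSite]:
    """Union candidate lists by (contig, position), merging evidence.

    Alt-allele supporting counts and depths are summed across platforms;
    provenance records every platform that proposed the site; a site is a
    variant candidate if any platform called it one.
    """
    merged: Dict[Tuple[str, int], CandidateSite] = {}
    for plat_list in per_platform:
        for site in plat_list:
            key = (site.contig, site.position)
            cur = merged.get(key)
            if cur is None:
                merged[key] = CandidateSite(
                    window=site.window, ref=site.ref, alts=dict(site.alts),
                    depth=site.depth, platforms=set(site.platforms),
                    is_variant_candidate=site.is_variant_candidate)
            else:
                if cur.ref != site.ref:
                    raise ValueError(
                        f"reference mismatch at {key[0]}:{key[1]}: "
                        f"{cur.ref!r} vs {site.ref!r}")
                for a, n in site.alts.items():
                    cur.alts[a] = cur.alts.get(a, 0) + n
                cur.depth += site.depth
                cur.platforms |= site.platforms
                cur.is_variant_candidate |= site.is_variant_candidate
    return [merged[k] for k in sorted(merged)]


def subsample_training_sites(variant_sites: Sequence[CandidateSite],
                             reference_sites: Sequence[CandidateSite],
                             ratio_ref_per_var: int = 5,
                             seed: int = 0) -> List[CandidateSite]:
    """Keep all variant sites plus up to ratio x |variants| reference sites.

    Training uses a 1:5 variant:reference mix so reference calls do not swamp
    the loss; if fewer reference sites exist they are all kept.
    """
    if ratio_ref_per_var < 0:
        raise ValueError("ratio must be >= 0")
    rng = np.random.default_rng(seed)
    n_ref = min(len(reference_sites), ratio_ref_per_var * len(variant_sites))
    keep = list(variant_sites)
    if n_ref > 0:
        idx = rng.choice(len(reference_sites), size=n_ref, replace=False)
        keep.extend(reference_sites[i] for i in sorted(idx))
    return keep


def write_candidates_tsv(sites: Sequence[CandidateSite], path: str) -> None:
    """Dump candidates as TSV for inspection."""
    with open(path, "w") as fh:
        fh.write("contig\tpos\tref\talts\tcounts\tdepth\taf\tplatforms\t"
                 "variant\n")
        for s in sites:
            alts = sorted(s.alts, key=lambda a: -s.alts[a])
            fh.write("\t".join([
                s.contig, str(s.position), s.ref,
                ",".join(alts) or ".",
                ",".join(str(s.alts[a]) for a in alts) or ".",
                str(s.depth), f"{s.allele_fraction:.3f}",
                ",".join(sorted(s.platforms)),
                "1" if s.is_variant_candidate else "0",
            ]) + "\n")
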