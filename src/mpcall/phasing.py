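"""Read-backed phasing and haplotagging from preliminary pileup calls.

Pileup calls are partitioned into variant calls (genotypes 0/1, 1/1, 1/2)
and reference calls (0/0), ranked by QUAL. The top 70% of heterozygous SNP
calls (floor of 0.7*n, QUAL-descending, ties broken by position) seed a
read-backed phaser: heterozygous SNPs become graph nodes, reads covering SNP
pairs vote for same/opposite haplotype orientation, and a greedy spanning
assignment over edges sorted by vote margin fixes each SNP's orientation.
Each read is then tagged with the haplotype matching the majority of its
covered selected-SNP alleles (HP tag; PS tag identifies the phase block),
or left unassigned on ties. Within a block the assignment is only defined
up to a global flip of both haplotypes — the standard phasing gauge.

Phasing is run per platform, independently; externally haplotagged
alignments (HP tags from another phaser) are honoured by downstream stages.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from math import floor
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .align_io import AlignedRead
from .pileup_caller import PileupCall

VARIANT_GTS = {"0/1", "1/1", "1/2"}


@dataclass
class PhasingSelection:
    """Het-SNP calls retained for phasing (highest-QUAL floor(0.7n))."""

    ranked: List[PileupCall]
    retained: List[PileupCall]
    retain_fraction: float = 0.70


@dataclass
class HaplotypeAssignment:
    """Per-SNP orientation and per-read haplotype tags for one platform."""

    # (contig,pos) -> 1 if the alt allele sits on haplotype 1, else 2
    variant_phase: Dict[Tuple[str, int], int] = field(default_factory=dict)
    # (contig,pos) -> phase-set id (leftmost SNP position of the block)
    phase_set: Dict[Tuple[str, int], int] = field(default_factory=dict)
    read_haplotype: Dict[str, Optional[int]] = field(default_factory=dict)
    read_phase_set: Dict[str, Optional[int]] = field(default_factory=dict)


def partition_calls(calls: Sequence[PileupCall]
                    ) -> Tuple[List[PileupCall], List[PileupCall]]:
    """Split calls into (variant, reference) groups, QUAL-descending."""
    variants: List[PileupCall] = []
    refs: List[PileupCall] = []
    for c in calls:
        if not c.gt or c.gt == "./.":
            raise ValueError(f"call at {c.contig}:{c.position} carries no GT")
        (variants if c.gt in VARIANT_GTS else refs).append(c)
    key = lambda c: (-c.qual, c.contig, c.position)
    return sorted(variants, key=key), sorted(refs, key=key)


def select_phasing_snps(variant_calls: Sequence[PileupCall],
                        retain_fraction: float = 0.70) -> PhasingSelection:
    """Keep the floor(fraction*n) highest-QUAL heterozygous SNP calls.

    Indels never qualify; ties in QUAL are broken by ascending position so
    the selection is deterministic.
    """
    if not 0.0 < retain_fraction <= 1.0:
        raise ValueError("retain_fraction must be in (0, 1]")
    het_snps = [c for c in variant_calls if c.gt == "0/1" and c.is_snp]
    ranked = sorted(het_snps, key=lambda c: (-c.qual, c.contig, c.position))
    n_keep = floor(retain_fraction * len(ranked))
    return PhasingSelection(ranked=ranked, retained=ranked[:n_keep],
                            retain_fraction=retain_fraction)


class _UnionFind:
    """Union-find carrying each node's orientation relative to its root."""

    def __init__(self):
        self.parent: Dict = {}
        self.flip: Dict = {}      # parity of the path to the root

    def find(self, x) -> Tuple[object, int]:
        if x not in self.parent:
            self.parent[x] = x
            self.flip[x] = 0
            return x, 0
        path = []
        while self.parent[x] != x:
            path.append(x)
            x = self.parent[x]
        parity = 0
        for node in reversed(path):
            parity ^= self.flip[node]
            self.parent[node] = x
            self.flip[node] = parity
        return x, self.flip[path[0]] if path else 0

    def orientation(self, x) -> int:
        self.find(x)
        return self.flip[x]

    def union(self, a, b, relative_flip: int) -> bool:
        ra, fa = self.find(a)
        rb, fb = self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        self.flip[rb] = fa ^ fb ^ relative_flip
        return True


def _read_allele(read: AlignedRead, pos: int, ref: str, alt: str
                 ) -> Optional[int]:
    """0 if the read carries ref at pos, 1 for alt, None otherwise."""
    base = read.base_at(pos)
    if base == ref:
        return 0
    if base == alt:
        return 1
    return None


def phase_and_haplotag(reads: Sequence[AlignedRead],
                       selection: PhasingSelection
                       ) -> HaplotypeAssignment:
    """Phase the selected het SNPs from read co-occurrence and tag the reads.

    Sets ``read.hp``/``read.phase_set`` in place and returns the assignment.
    Reads covering no selected SNP, or splitting their votes evenly, stay
    unassigned. Degenerate inputs (empty selection) simply leave every read
    untagged.
    """
    assignment = HaplotypeAssignment()
    snps = {(c.contig, c.position): c for c in selection.retained}
    for r in reads:
        assignment.read_haplotype[r.read_id] = None
        assignment.read_phase_set[r.read_id] = None
    if not snps:
        return assignment

    by_contig: Dict[str, List[Tuple[int, str, str]]] = defaultdict(list)
    for (contig, pos), call in snps.items():
        by_contig[contig].append((pos, call.ref, call.alts[0]))
    for contig in by_contig:
        by_contig[contig].sort()

    # read -> observed allele per covered selected SNP
    read_obs: Dict[str, List[Tuple[Tuple[str, int], int]]] = {}
    edge_votes: Dict[Tuple, List[int]] = defaultdict(lambda: [0, 0])
    for r in reads:
        obs: List[Tuple[Tuple[str, int], int]] = []
        for pos, ref, alt in by_contig.get(r.contig, []):
            if pos < r.start:
                continue
            if pos >= r.end:
                break
            a = _read_allele(r, pos, ref, alt)
            if a is not None:
                obs.append(((r.contig, pos), a))
        if obs:
            read_obs[r.read_id] = obs
        for i in range(len(obs) - 1):
            (ka, aa), (kb, ab) = obs[i], obs[i + 1]
            edge_votes[(ka, kb)][aa ^ ab] += 1

    uf = _UnionFind()
    for key in snps:
        uf.find(key)
    edges = sorted(edge_votes.items(),
                   key=lambda kv: (-abs(kv[1][0] - kv[1][1]), kv[0]))
    for (ka, kb), (same, diff) in edges:
        if same == diff:
            continue
        uf.union(ka, kb, 0 if same > diff else 1)

    # orientation 0 => alt allele on haplotype 1
    blocks: Dict[object, List[Tuple[str, int]]] = defaultdict(list)
    for key in snps:
        root, _ = uf.find(key)
        blocks[root].append(key)
    for root, members in blocks.items():
        ps = min(pos for _, pos in members)
        for key in members:
            assignment.variant_phase[key] = 1 if uf.orientation(key) == 0 else 2
            assignment.phase_set[key] = ps

    for r in reads:
        obs = read_obs.get(r.read_id)
        if not obs:
            continue
        votes = [0, 0, 0]  # index 1 / 2
        ps_seen: Set[int] = set()
        for key, allele in obs:
            alt_hap = assignment.variant_phase[key]
            hap = alt_hap if allele == 1 else (3 - alt_hap)
            votes[hap] += 1
            ps_seen.add(assignment.phase_set[key])
        if votes[1] == votes[2]:
            continue
        hap = 1 if votes[1] > votes[2] else 2
        r.hp = hap
        r.phase_set = min(ps_seen)
        assignment.read_haplotype[r.read_id] = hap
        assignment.read_phase_set[r.read_id] = r.phase_set
    return assignment
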