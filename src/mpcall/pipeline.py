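"""End-to-end orchestration: simulate -> train -> call -> evaluate.

This module wires the stages together in the order the two-part workflow
prescribes: per-platform pileup candidate extraction and preliminary pileup
calling; QUAL-ranked partitioning and top-70% het-SNP selection; per-platform
phasing and haplotagging; candidate merging; and full-alignment calling with
the N-to-1 model. Training runs the same first part — pileup calling,
top-70% het-SNP selection, per-platform phasing and haplotagging — then
downsamples reads to the coverage grid, subsamples candidate sites at 1:5
variant:reference, and trains one pileup model per platform plus one
multi-platform full-alignment model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import candidates as cand
from . import fullalign as fa
from . import phasing as ph
from . import pileup_caller as pc
from .align_io import AlignedRead, GenomicWindow, StratificationIndex
from .simdata import DiploidGenome, TruthSet

log = logging.getLogger(__name__)

LONG_READ_PLATFORMS = {"ont", "hifi"}


@dataclass(frozen=True)
class Thresholds:
    """Candidate-extraction thresholds for one platform.

    Long-read platforms get no base-quality floor (their desk-scale base
    qualities carry no information) but a higher indel allele-fraction
    floor, because systematic homopolymer indel error otherwise floods the
    candidate set; substitution floors are sized so that random sequencing
    error at 30x rarely reaches candidate status while true heterozygous
    alleles (allele fraction ~0.5) always do.
    """

    min_af: float = 0.08
    min_indel_af: float = 0.08
    min_alt_count: int = 2
    min_depth: int = 4
    min_mapq: int = 5
    min_baseq: int = 0


def default_thresholds(platform: str) -> Thresholds:
    if platform in LONG_READ_PLATFORMS:
        return Thresholds(min_af=0.12, min_indel_af=0.40, min_baseq=0)
    return Thresholds(min_af=0.12, min_indel_af=0.15, min_baseq=13)


@dataclass
class PlatformCandidates:
    """Per-platform pileup products for one read set."""

    platform: str
    columns: Dict[Tuple[str, int], cand.PileupColumn]
    variant_sites: List[cand.CandidateSite]
    reference_sites: List[cand.CandidateSite]


def run_pileup_stage(reads: Sequence[AlignedRead],
                     reference: Dict[str, str],
                     platform: str,
                     thresholds: Optional[Thresholds] = None
                     ) -> PlatformCandidates:
    """mpileup-style recount and candidate extraction over every contig."""
    th = thresholds or default_thresholds(platform)
    columns: Dict[Tuple[str, int], cand.PileupColumn] = {}
    variant_sites: List[cand.CandidateSite] = []
    reference_sites: List[cand.CandidateSite] = []
    for contig, seq in reference.items():
        contig_reads = [r for r in reads if r.contig == contig]
        cols = cand.pileup(contig_reads, contig, 0, len(seq),
                           min_mapq=th.min_mapq, min_baseq=th.min_baseq)
        for c in cols:
            columns[(contig, c.position)] = c
        sites = cand.extract_candidates(
            cols, reference, platform, min_af=th.min_af,
            min_alt_count=th.min_alt_count, min_depth=th.min_depth,
            min_indel_af=th.min_indel_af)
        for s in sites:
            fa.attach_ref_context(s, reference)
            (variant_sites if s.is_variant_candidate
             else reference_sites).append(s)
    log.info("%s: %d variant candidates, %d reference sites",
             platform, len(variant_sites), len(reference_sites))
    return PlatformCandidates(platform, columns, variant_sites,
                              reference_sites)


def encode_pileup_sites(pcand: PlatformCandidates,
                        sites: Sequence[cand.CandidateSite]) -> List[np.ndarray]:
    """Gather each site's window columns and encode the 33x18 input."""
    encoded = []
    for s in sites:
        w = s.window
        cols = [pcand.columns[(w.contig, p)]
                for p in range(w.start, w.end)
                if (w.contig, p) in pcand.columns]
        encoded.append(pc.encode_pileup(cols, w))
    return encoded


def phase_reads_from_truth(reads: Sequence[AlignedRead],
                           truth: TruthSet) -> int:
    """Training-time haplotagging: read-backed phasing seeded by the truth.

    The known het SNVs play the role of the selected phasing SNPs and the
    reads are tagged with the same per-platform machinery used at call time
    (including its arbitrary per-block gauge), so the phasing channel has
    the same statistics during training and calling. Returns the number of
    reads tagged.
    """
    from .candidates import CandidateSite
    calls = []
    for v in truth:
        if v.gt != "0/1" or not v.is_snp:
            continue
        site = CandidateSite(
            window=GenomicWindow(v.contig, v.pos), ref=v.ref,
            alts={v.alts[0]: 1}, depth=1, platforms={"truth"},
            is_variant_candidate=True)
        calls.append(pc.PileupCall(
            site=site, gt="0/1", ref=v.ref, alts=v.alts, qual=60.0,
            gt21_probs=np.full(21, 1 / 21), zygosity_probs=np.full(3, 1 / 3)))
    selection = ph.select_phasing_snps(calls, retain_fraction=1.0)
    assignment = ph.phase_and_haplotag(reads, selection)
    return sum(1 for h in assignment.read_haplotype.values() if h is not None)


def truth_haplotag(reads: Sequence[AlignedRead], truth: TruthSet) -> int:
    """Training-time haplotagging straight from the phased truth set.

    Each read votes over the het SNVs it covers (alt base -> the variant's
    haplotype, ref base -> the other); majority wins, ties stay unassigned.
    Returns the number of reads tagged.
    """
    by_contig: Dict[str, List] = {}
    for v in truth:
        if v.gt == "0/1" and v.is_snp and v.hap is not None:
            by_contig.setdefault(v.contig, []).append(
                (v.pos, v.ref, v.alts[0], v.hap))
    for contig in by_contig:
        by_contig[contig].sort()
    n_tagged = 0
    for r in reads:
        votes = [0, 0, 0]
        for pos, ref, alt, hap in by_contig.get(r.contig, []):
            if pos < r.start:
                continue
            if pos >= r.end:
                break
            base = r.base_at(pos)
            if base == alt:
                votes[hap] += 1
            elif base == ref:
                votes[3 - hap] += 1
        if votes[1] != votes[2]:
            r.hp = 1 if votes[1] > votes[2] else 2
            n_tagged += 1
    return n_tagged


@dataclass
class TrainedModels:
    """Checkpoint bundle produced by the training pipeline."""

    pileup: Dict[str, object]            # platform -> MultiTaskNet
    fullalign: object                    # MultiTaskNet
    spec: fa.NetworkSpec
    platform_order: List[str]
    history: List[dict] = field(default_factory=list)
    pileup_history: Dict[str, List[dict]] = field(default_factory=dict)
    coverage_pairs_seen: List[Tuple[float, float]] = field(default_factory=list)


def train_pipeline(genome: DiploidGenome,
                   reads_by_platform: Dict[str, List[AlignedRead]],
                   max_coverage: Dict[str, float],
                   platform_order: Optional[Sequence[str]] = None,
                   grid: Optional[fa.CoverageGrid] = None,
                   strat_index: Optional[StratificationIndex] = None,
                   thresholds: Optional[Dict[str, Thresholds]] = None,
                   ratio_ref_per_var: int = 5,
                   val_fraction: float = 0.10,
                   retain_fraction: float = 0.70,
                   pileup_epochs: int = 30,
                   fullalign_epochs: int = 25,
                   spec: Optional[fa.NetworkSpec] = None,
                   seed: int = 0) -> TrainedModels:
    """Train per-platform pileup models and the full-alignment model.

    Training alignments are haplotagged by the same machinery the caller
    uses — the freshly trained pileup model's calls are QUAL-ranked, the
    top ``retain_fraction`` of het SNP calls phase the reads — so the
    phasing channel carries the same statistics during training and
    calling.
    """
    platform_order = list(platform_order or reads_by_platform)
    grid = grid or fa.CoverageGrid()
    truth = genome.truth

    # 1. per-platform candidates, pileup model training, phasing/haplotagging
    pileup_models: Dict[str, object] = {}
    pileup_history: Dict[str, List[dict]] = {}
    per_platform_sites: List[List[cand.CandidateSite]] = []
    for pi, plat in enumerate(platform_order):
        pcand = run_pileup_stage(reads_by_platform[plat], genome.reference,
                                 plat, (thresholds or {}).get(plat))
        train_sites = cand.subsample_training_sites(
            pcand.variant_sites, pcand.reference_sites,
            ratio_ref_per_var=ratio_ref_per_var, seed=seed + 17 * pi)
        encoded = encode_pileup_sites(pcand, train_sites)
        labels = pc.make_pileup_labels(train_sites, truth)
        model = pc.build_pileup_network(seed=seed + pi)
        hist = pc.train_pileup(model, encoded, labels, epochs=pileup_epochs,
                               seed=seed + pi, val_fraction=val_fraction)
        pileup_models[plat] = model
        pileup_history[plat] = hist
        per_platform_sites.append(pcand.variant_sites + pcand.reference_sites)

        # phase and haplotag this platform's alignments from its own
        # preliminary calls, exactly as at call time
        if pcand.variant_sites:
            var_encoded = encode_pileup_sites(pcand, pcand.variant_sites)
            prelim = pc.pileup_call(model, var_encoded, pcand.variant_sites)
            variants, _refs = ph.partition_calls(prelim)
            selection = ph.select_phasing_snps(
                variants, retain_fraction=retain_fraction)
            ph.phase_and_haplotag(reads_by_platform[plat], selection)
            n = sum(1 for r in reads_by_platform[plat] if r.hp is not None)
            log.info("haplotagged %d/%d %s reads from %d selected het SNPs",
                     n, len(reads_by_platform[plat]), plat,
                     len(selection.retained))

    # 2. merged candidate set, 1:5 subsample, grid encoding, CNN training
    merged = cand.merge_platform_candidates(per_platform_sites)
    for s in merged:
        fa.attach_ref_context(s, genome.reference)
    var = [s for s in merged if s.is_variant_candidate]
    ref = [s for s in merged if not s.is_variant_candidate]
    train_sites = cand.subsample_training_sites(
        var, ref, ratio_ref_per_var=ratio_ref_per_var, seed=seed + 101)
    train_sites.sort(key=lambda s: (s.contig, s.position))

    examples = fa.make_training_examples(
        train_sites, reads_by_platform, platform_order, max_coverage,
        truth, grid, strat_index=strat_index, seed=seed)
    pairs_seen = sorted({e.coverage_pair for e in examples})
    log.info("%d training examples over %d coverage pairs",
             len(examples), len(pairs_seen))

    spec = spec or fa.NetworkSpec(n_platforms=len(platform_order),
                                  stratification=strat_index is not None)
    model = fa.build_network(spec, seed=seed)
    history = fa.train_fullalign(model, examples, val_fraction=val_fraction,
                                 epochs=fullalign_epochs, seed=seed)
    return TrainedModels(pileup=pileup_models, fullalign=model, spec=spec,
                         platform_order=platform_order, history=history,
                         pileup_history=pileup_history,
                         coverage_pairs_seen=list(pairs_seen))


def call_pipeline(models: TrainedModels,
                  reads_by_platform: Dict[str, List[AlignedRead]],
                  reference: Dict[str, str],
                  strat_index: Optional[StratificationIndex] = None,
                  thresholds: Optional[Dict[str, Thresholds]] = None,
                  retain_fraction: float = 0.70,
                  keep_refcalls: bool = False) -> List[fa.VariantCall]:
    """The two-part calling workflow on (possibly pre-haplotagged) reads.

    Reads that already carry HP tags (e.g. from an external phaser) keep
    them; untagged platforms are phased here from their own pileup calls.
    """
    per_platform_sites: List[List[cand.CandidateSite]] = []
    for plat in models.platform_order:
        reads = reads_by_platform[plat]
        pcand = run_pileup_stage(reads, reference, plat,
                                 (thresholds or {}).get(plat))
        sites = pcand.variant_sites
        per_platform_sites.append(sites)
        if any(r.hp is not None for r in reads):
            log.info("%s reads already haplotagged; skipping phasing", plat)
            continue
        if not sites:
            continue
        encoded = encode_pileup_sites(pcand, sites)
        calls = pc.pileup_call(models.pileup[plat], encoded, sites)
        variants, _refs = ph.partition_calls(calls)
        selection = ph.select_phasing_snps(variants,
                                           retain_fraction=retain_fraction)
        ph.phase_and_haplotag(reads, selection)
        log.info("%s: %d het SNPs selected for phasing", plat,
                 len(selection.retained))

    merged = cand.merge_platform_candidates(per_platform_sites)
    for s in merged:
        fa.attach_ref_context(s, reference)
    return fa.call_variants(
        models.fullalign, models.spec, merged, reads_by_platform,
        models.platform_order, strat_index=strat_index,
        keep_refcalls=keep_refcalls)
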