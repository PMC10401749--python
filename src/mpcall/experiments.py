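"""Self-contained benchmark experiments on simulated fixtures.

Each function builds its inputs with the synthetic-data module, runs the
pipeline, and measures the result; they are shared by the test suite and
the acceptance script. Problem sizes (genome length, coverages, grids and
epochs) are the package's standard desk-scale settings documented in
docs/methods.md.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np

from . import candidates as cand
from . import fullalign as fa
from . import nn
from .align_io import GenomicWindow, VcfRecord
from .evaluate import match_calls, prf
from .phasing import phase_and_haplotag, select_phasing_snps
from .pileup_caller import PileupCall, encode_pileup
from .pipeline import call_pipeline, train_pipeline
from .simdata import (DEFAULT_PROFILES, DiploidGenome, PlatformErrorProfile,
                      SimConfig, TruthSet, make_diploid_genome,
                      simulate_reads, truth_to_vcf_records)

RECOVERY_GRID = fa.CoverageGrid(
    ((30.0, 30.0), (20.0, 30.0), (30.0, 20.0), (20.0, 20.0)))
NOISY_GRID = fa.CoverageGrid(((30.0, 30.0), (20.0, 30.0), (30.0, 20.0)))


def _zero_error_profiles() -> Dict[str, PlatformErrorProfile]:
    return {
        "illumina": PlatformErrorProfile(label="illumina",
                                         read_length_mean=151),
        "ont": PlatformErrorProfile(label="ont", read_length_mean=8000,
                                    read_length_lognormal_sigma=0.35,
                                    ins_rate=1e-9, del_rate=1e-9),
    }


def _split_snps(records: List[VcfRecord]) -> List[VcfRecord]:
    return [r for r in records
            if len(r.ref) == 1 and all(len(a) == 1 for a in r.alts)]


def _snp_metrics(calls, truth) -> Dict[str, float]:
    crecs = fa.calls_to_vcf_records(calls)
    trecs = truth_to_vcf_records(truth)
    m = match_calls(_split_snps(crecs), _split_snps(trecs))
    p, r, f1 = prf(m)
    m_all = match_calls(crecs, trecs)
    _, _, f1_all = prf(m_all)
    return {"snp_recovery": r, "snp_precision": p, "snp_f1": f1,
            "overall_f1": f1_all, "n_truth_snps": m.tp + m.fn}


def _train_and_call(genome: DiploidGenome,
                    reads: Dict[str, List],
                    max_coverage: Dict[str, float],
                    platform_order: List[str],
                    grid: fa.CoverageGrid,
                    epochs: int,
                    seed: int,
                    call_reads: Optional[Dict[str, List]] = None,
                    call_genome: Optional[DiploidGenome] = None):
    models = train_pipeline(genome, reads, max_coverage, platform_order,
                            grid=grid, pileup_epochs=15,
                            fullalign_epochs=epochs, seed=seed)
    target_reads = call_reads if call_reads is not None else reads
    target_genome = call_genome if call_genome is not None else genome
    for rs in target_reads.values():
        for r in rs:
            r.hp = None
            r.phase_set = None
    calls = call_pipeline(models, target_reads, target_genome.reference)
    return models, calls


def recovery_run(seed: int, noisy: bool, epochs: Optional[int] = None
                 ) -> Dict[str, float]:
    """Parameter recovery on the default 100 kb fixture at 30x + 30x.

    With ``noisy=False`` the platforms are error-free (the zero-noise
    limit); with ``noisy=True`` the default error profiles apply.
    """
    rng = np.random.SeedSequence(seed)
    s = [int(x) for x in rng.generate_state(4) % (2 ** 31)]
    genome = make_diploid_genome(SimConfig(seed=s[0]))
    profiles = (dict(DEFAULT_PROFILES) if noisy else _zero_error_profiles())
    reads = {}
    for i, plat in enumerate(("illumina", "ont")):
        reads[plat], _ = simulate_reads(genome, profiles[plat], 30,
                                        seed=s[1] + i)
    grid = NOISY_GRID if noisy else RECOVERY_GRID
    if epochs is None:
        epochs = 14 if noisy else 22
    _, calls = _train_and_call(genome, reads, {"illumina": 30, "ont": 30},
                               ["illumina", "ont"], grid, epochs, s[2])
    out = _snp_metrics(calls, genome.truth)
    out["n_truth"] = len(genome.truth)
    return out


def _subset_genome(genome: DiploidGenome, contigs: List[str]) -> DiploidGenome:
    sub = DiploidGenome(
        reference={c: genome.reference[c] for c in contigs},
        truth=TruthSet([v for v in genome.truth if v.contig in contigs]),
        difficult=[iv for iv in genome.difficult if iv[0] in contigs],
        duplications=[d for d in genome.duplications if d[0] in contigs])
    sub.haplotypes = {k: v for k, v in genome.haplotypes.items()
                      if k[0] in contigs}
    return sub


def multiplatform_benefit(seed: int, epochs: int = 14) -> Dict[str, float]:
    """Low-coverage short reads with and without 30x long-read support.

    Trains a two-platform model (10x short + 30x long) and a single-platform
    model (10x short) on three contigs of the default noisy fixture and
    compares their SNP F1 on the held-out fourth contig.
    """
    rng = np.random.SeedSequence(seed + 1)
    s = [int(x) for x in rng.generate_state(4) % (2 ** 31)]
    genome = make_diploid_genome(SimConfig(seed=s[0]))
    contigs = list(genome.reference)
    train_contigs, eval_contigs = contigs[:-1], contigs[-1:]
    ilmn, _ = simulate_reads(genome, DEFAULT_PROFILES["illumina"], 10,
                             seed=s[1])
    ont, _ = simulate_reads(genome, DEFAULT_PROFILES["ont"], 30, seed=s[1] + 1)

    def split(reads, keep):
        return [r for r in reads if r.contig in keep]

    train_genome = _subset_genome(genome, train_contigs)
    eval_genome = _subset_genome(genome, eval_contigs)

    # two-platform model: 10x short + 30x long
    _, mp_calls = _train_and_call(
        train_genome,
        {"illumina": split(ilmn, train_contigs),
         "ont": split(ont, train_contigs)},
        {"illumina": 10, "ont": 30}, ["illumina", "ont"],
        fa.CoverageGrid(((10.0, 30.0), (10.0, 20.0), (10.0, 10.0))),
        epochs, s[2],
        call_reads={"illumina": split(ilmn, eval_contigs),
                    "ont": split(ont, eval_contigs)},
        call_genome=eval_genome)
    mp = _snp_metrics(mp_calls, eval_genome.truth)

    # single-platform model: the same 10x short reads alone
    _, single_calls = _train_and_call(
        train_genome, {"illumina": split(ilmn, train_contigs)},
        {"illumina": 10}, ["illumina"],
        fa.CoverageGrid(((10.0, 10.0), (8.0, 8.0), (6.0, 6.0))),
        epochs, s[3],
        call_reads={"illumina": split(ilmn, eval_contigs)},
        call_genome=eval_genome)
    single = _snp_metrics(single_calls, eval_genome.truth)

    return {"mp_snp_f1": mp["snp_f1"], "single_snp_f1": single["snp_f1"],
            "benefit": mp["snp_f1"] - single["snp_f1"],
            "n_heldout_snps": mp["n_truth_snps"]}


def phasing_concordance(seed: int) -> Dict[str, float]:
    """Fraction of multi-SNP reads tagged to their true haplotype (zero
    error, allowing a global flip per phase block)."""
    rng = np.random.SeedSequence(seed + 2)
    s = [int(x) for x in rng.generate_state(2) % (2 ** 31)]
    genome = make_diploid_genome(
        SimConfig(genome_length=40_000, n_contigs=2, snp_rate=0.002,
                  seed=s[0]))
    profile = PlatformErrorProfile(label="hifi", read_length_mean=3000)
    reads, ledger = simulate_reads(genome, profile, 30, seed=s[1])
    calls = []
    for v in genome.truth:
        if v.gt != "0/1" or not v.is_snp:
            continue
        site = cand.CandidateSite(
            window=GenomicWindow(v.contig, v.pos), ref=v.ref,
            alts={v.alts[0]: 10}, depth=20, platforms={"hifi"},
            is_variant_candidate=True)
        calls.append(PileupCall(site=site, gt="0/1", ref=v.ref, alts=v.alts,
                                qual=60.0, gt21_probs=np.full(21, 1 / 21),
                                zygosity_probs=np.full(3, 1 / 3)))
    selection = select_phasing_snps(calls, retain_fraction=1.0)
    assignment = phase_and_haplotag(reads, selection)
    snp_keys = {(c.contig, c.position) for c in selection.retained}
    by_block: Dict[Tuple[str, int], List[bool]] = {}
    for r in reads:
        covered = [k for k in snp_keys
                   if k[0] == r.contig and r.start <= k[1] < r.end]
        if len(covered) < 2 or r.hp is None:
            continue
        block = assignment.phase_set[covered[0]]
        by_block.setdefault((r.contig, block), []).append(
            r.hp == ledger[r.read_id].haplotype)
    total = ok = 0
    for matches in by_block.values():
        agree = sum(matches)
        ok += max(agree, len(matches) - agree)
        total += len(matches)
    return {"concordance": ok / total if total else 0.0, "n_reads": total}


def tensor_shape_counts(seed: int) -> Dict[str, int]:
    """Element counts of the encodings, measured on freshly simulated data."""
    genome = make_diploid_genome(
        SimConfig(genome_length=5_000, n_contigs=1, seed=seed % (2 ** 31)))
    reads, _ = simulate_reads(
        genome, PlatformErrorProfile(label="illumina", read_length_mean=151),
        20, seed=(seed + 1) % (2 ** 31))
    contig = next(iter(genome.reference))
    cols = cand.pileup(reads, contig, 0, len(genome.reference[contig]))
    window = GenomicWindow(contig, 2_500)
    pileup_mat = encode_pileup(cols, window)
    site = cand.extract_candidates(cols, genome.reference, "illumina")[0]
    fa.attach_ref_context(site, genome.reference)
    t = fa.encode_platform(reads, site.window, site)
    two = fa.assemble_mp_input(t, t)
    strat = fa.assemble_mp_input(t, t, strat_value=100)
    return {
        "pileup_elements": int(pileup_mat.size),
        "fullalign_two_platform_elements": int(two.size),
        "fullalign_stratified_elements": int(strat.size),
        "fullalign_read_rows": int(two.shape[2]),
    }


def workflow_constants(seed: int) -> Dict[str, float]:
    """The workflow's selection/split/subsampling constants, measured."""
    # top-70% het-SNP retention on 10 ranked calls
    calls = []
    for i in range(10):
        site = cand.CandidateSite(
            window=GenomicWindow("c", 100 + 20 * i), ref="A",
            alts={"C": 10}, depth=20, platforms={"p"},
            is_variant_candidate=True)
        calls.append(PileupCall(site=site, gt="0/1", ref="A", alts=("C",),
                                qual=10.0 + i, gt21_probs=np.full(21, 1 / 21),
                                zygosity_probs=np.full(3, 1 / 3)))
    sel = select_phasing_snps(calls)
    retention = 100.0 * len(sel.retained) / len(sel.ranked)

    # 10% validation split measured from a real fit
    rng = np.random.default_rng(seed % (2 ** 31))
    x = rng.normal(size=(200, 18, 33, 1)).astype(np.float32)
    labels = {"gt21": rng.integers(21, size=200),
              "zygosity": rng.integers(3, size=200)}
    from .pileup_caller import build_pileup_network
    net = build_pileup_network(seed=seed % (2 ** 31))
    hist = nn.fit(net, x, labels, epochs=1, seed=seed % (2 ** 31),
                  val_fraction=0.10)
    val_pct = 100.0 * hist[0]["n_val"] / (hist[0]["n_val"]
                                          + hist[0]["n_train"])

    # 1:5 subsampling measured on 100 variant + 1000 reference sites
    def mk(pos, variant):
        return cand.CandidateSite(window=GenomicWindow("c", pos), ref="A",
                                  alts={"C": 3}, depth=20, platforms={"p"},
                                  is_variant_candidate=variant)
    var = [mk(i, True) for i in range(100)]
    ref = [mk(1000 + i, False) for i in range(1000)]
    kept = cand.subsample_training_sites(var, ref, seed=seed % (2 ** 31))
    ratio = (len(kept) - len(var)) / len(var)

    # nine coverage pairs in the default training grid, measured from
    # generated example metadata
    genome = make_diploid_genome(
        SimConfig(genome_length=5_000, n_contigs=1, seed=seed % (2 ** 31)))
    reads, _ = simulate_reads(
        genome, PlatformErrorProfile(label="illumina", read_length_mean=151),
        30, seed=(seed + 3) % (2 ** 31))
    contig = next(iter(genome.reference))
    cols = cand.pileup(reads, contig, 0, 5000)
    site = cand.extract_candidates(cols, genome.reference, "illumina")[0]
    fa.attach_ref_context(site, genome.reference)
    examples = fa.make_training_examples(
        [site], {"a": reads, "b": reads}, ["a", "b"], {"a": 30, "b": 30},
        genome.truth, fa.CoverageGrid(), seed=seed % (2 ** 31))
    n_pairs = len({e.coverage_pair for e in examples})

    return {"het_snp_retention_pct": retention,
            "validation_split_pct": val_pct,
            "ref_per_variant_ratio": ratio,
            "coverage_pairs_in_default_grid": n_pairs}
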