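"""Full-alignment tensor encoding and the N-to-1 multi-platform caller.

Around every candidate site, each platform's haplotagged reads are encoded
into an 8-channel integer tensor of shape (8, 33, 89): 33 genome positions by
up to 89 read rows, with channels

  reference base, alternative base, strand, mapping quality, base quality,
  candidate proportion, insertion base, phasing information,

all coded into 0-100. Two platform tensors are concatenated along the read
rows into the (8, 33, 178) multi-platform input — 46,992 integers. An
optional ninth stratification channel, constant 100 when the candidate lies
in a difficult region and 50 otherwise, grows the input to 52,866 integers.

The caller is an N-to-1 multi-task CNN: three residual blocks, each followed
by a convolution, then spatial pyramid pooling (so the dense heads are
independent of the read-row count), with four softmax heads — 21 genotypes,
zygosity, and two indel lengths. Training examples mix nine coverage pairs
over {10, 20, 30}x per platform via read-level downsampling, with a 10%
validation split and a 1:5 variant:reference site mix upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .align_io import (AlignedRead, GenomicWindow, StratificationIndex,
                       VcfRecord, in_difficult_region)
from .candidates import CandidateSite
from .genotypes import (N_GT21, N_INDEL_CLASSES, decode_genotype,
                        truth_genotype_labels)
from .pileup_caller import phred_qual

WINDOW_SIZE = 33
ROWS_PER_PLATFORM = 89
CHANNELS = ("reference_base", "alternative_base", "strand",
            "mapping_quality", "base_quality", "candidate_proportion",
            "insertion_base", "phasing")
N_CHANNELS = len(CHANNELS)                     # 8
CHANNEL_LAYOUT_VERSION = "fullalign-8ch-v1"

# --- the versioned 0-100 code table ---------------------------------------
BASE_CODE = {"A": 25, "C": 50, "G": 75, "T": 100, "N": 0}
GAP_CODE = 10                                  # deleted position in a read
STRAND_CODE = {"+": 50, "-": 100}
PHASE_CODE = {None: 33, 1: 67, 2: 100}
QUAL_CAP = 60
STRAT_DIFFICULT = 100
STRAT_NORMAL = 50


def stratification_value(index: StratificationIndex,
                         window: GenomicWindow) -> int:
    """50/100 stratification code: 100 inside a difficult region, else 50."""
    return STRAT_DIFFICULT if in_difficult_region(index, window) else STRAT_NORMAL


def _qual_code(q: int) -> int:
    return int(round(100.0 * min(q, QUAL_CAP) / QUAL_CAP))


def encode_platform(reads: Sequence[AlignedRead], window: GenomicWindow,
                    candidate: CandidateSite,
                    capacity: int = ROWS_PER_PLATFORM) -> np.ndarray:
    """Encode one platform's reads around a candidate as (8, 33, capacity).

    One row per read overlapping the window, ordered by start position. When
    more than ``capacity`` reads overlap, reads are ranked by (overlap with
    the center position desc, MAPQ desc, start asc), truncated, and re-sorted
    by start — a deterministic downsample. Missing rows stay zero.
    """
    if capacity < 1:
        raise ValueError("row capacity must be >= 1")
    if window.size != WINDOW_SIZE:
        raise ValueError(f"window must span {WINDOW_SIZE} positions")
    overlapping = [r for r in reads
                   if r.contig == window.contig
                   and r.overlaps(window.start, window.end)]
    if len(overlapping) > capacity:
        center = window.center
        overlapping.sort(key=lambda r: (
            -(1 if r.start <= center < r.end else 0), -r.mapq, r.start,
            r.read_id))
        overlapping = overlapping[:capacity]
    overlapping.sort(key=lambda r: (r.start, r.read_id))

    af_code = int(round(100.0 * min(candidate.allele_fraction, 1.0)))
    t = np.zeros((N_CHANNELS, WINDOW_SIZE, capacity), dtype=np.int8)
    w0, w1 = window.start, window.end
    for row, r in enumerate(overlapping):
        strand = STRAND_CODE[r.strand]
        mapq = _qual_code(r.mapq)
        phase = PHASE_CODE.get(r.hp, PHASE_CODE[None])
        for ref_pos, read_idx, op in r.walk_window(w0, w1):
            i = ref_pos - w0
            if op == "M":
                base = r.sequence[read_idx].upper()
                ref_base = _ref_base_at(candidate, window, ref_pos)
                t[0, i, row] = BASE_CODE.get(ref_base, 0)
                t[1, i, row] = BASE_CODE.get(base, 0) if base != ref_base else 0
                t[2, i, row] = strand
                t[3, i, row] = mapq
                t[4, i, row] = _qual_code(r.baseq[read_idx])
                t[5, i, row] = af_code
                t[7, i, row] = phase
            elif op == "D":
                t[0, i, row] = BASE_CODE.get(
                    _ref_base_at(candidate, window, ref_pos), 0)
                t[1, i, row] = GAP_CODE
                t[2, i, row] = strand
                t[3, i, row] = mapq
                t[5, i, row] = af_code
                t[7, i, row] = phase
            elif op.startswith("I"):
                t[6, i, row] = BASE_CODE.get(r.sequence[read_idx].upper(), 0)
    return t


def _ref_base_at(candidate: CandidateSite, window: GenomicWindow,
                 ref_pos: int) -> str:
    """Reference base within the window, from the candidate's context."""
    ctx = getattr(candidate, "ref_context", None)
    if ctx is not None:
        return ctx[ref_pos - window.start]
    return candidate.ref if ref_pos == window.center else "N"


def attach_ref_context(candidate: CandidateSite,
                       reference: Dict[str, str]) -> None:
    """Cache the window's reference bases on the candidate for encoding."""
    w = candidate.window
    seq = reference[w.contig]
    lo, hi = max(w.start, 0), min(w.end, len(seq))
    ctx = "N" * (lo - w.start) + seq[lo:hi].upper() + "N" * (w.end - hi)
    candidate.ref_context = ctx  # type: ignore[attr-defined]


def assemble_mp_input(tensor_a: np.ndarray, tensor_b: np.ndarray,
                      strat_value: Optional[int] = None) -> np.ndarray:
    """Concatenate two platform tensors along read rows; optionally append
    the constant stratification channel."""
    expected = (N_CHANNELS, WINDOW_SIZE, ROWS_PER_PLATFORM)
    for t in (tensor_a, tensor_b):
        if t.shape != expected:
            raise ValueError(f"platform tensor shape {t.shape} != {expected}")
    full = np.concatenate([tensor_a, tensor_b], axis=2)
    if strat_value is not None:
        plane = np.full((1,) + full.shape[1:], int(strat_value),
                        dtype=full.dtype)
        full = np.concatenate([full, plane], axis=0)
    return full


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture parameters of the N-to-1 full-alignment model."""

    n_platforms: int = 2
    stratification: bool = False
    widths: Tuple[int, int, int] = (12, 16, 24)
    hidden: int = 96
    # pooling grids (positions x rows): coarse square summaries plus
    # per-position row pools — (33, 1) over all rows and (33, 2) over each
    # half of the row axis, which in a two-platform input is exactly a
    # per-platform summary per position. All levels are invariant to the
    # absolute read-row count.
    spp_levels: Tuple[Tuple[int, int], ...] = ((1, 1), (2, 2), (4, 4),
                                               (33, 1), (33, 2))

    @property
    def in_channels(self) -> int:
        return N_CHANNELS + (1 if self.stratification else 0)

    @property
    def total_rows(self) -> int:
        return self.n_platforms * ROWS_PER_PLATFORM

    @property
    def element_count(self) -> int:
        return self.in_channels * WINDOW_SIZE * self.total_rows


@dataclass(frozen=True)
class CoverageGrid:
    """Training coverage pairs (platform A fold, platform B fold)."""

    pairs: Tuple[Tuple[float, float], ...] = tuple(
        (a, b) for a in (10.0, 20.0, 30.0) for b in (10.0, 20.0, 30.0))

    def __len__(self):
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


HEADS = {"gt21": N_GT21, "zygosity": 3,
         "indel_len_1": N_INDEL_CLASSES, "indel_len_2": N_INDEL_CLASSES}


def build_network(spec: NetworkSpec, seed: int = 0) -> nn.MultiTaskNet:
    """Three ResBlocks each topped by a convolution, then SPP and 4 heads.

    The stem convolution strides over read rows and each per-block
    convolution strides further, keeping the CPU cost small; spatial pyramid
    pooling makes the head input size independent of the read-row count, so
    the same network accepts 1- or 2-platform inputs.
    """
    if spec.n_platforms < 1:
        raise ValueError("need at least one platform")
    rng = np.random.default_rng(seed)
    w1, w2, w3 = spec.widths
    trunk: List[nn.Layer] = [
        # wide-row stem: every read row lands in some kernel footprint while
        # the row axis is cut 8x immediately, which is where the CPU time is
        nn.Conv2d(spec.in_channels, w1, kernel=(3, 9), stride=(1, 8), rng=rng),
        nn.ReLU(),
        nn.ResBlock(w1, rng=rng),
        nn.Conv2d(w1, w2, stride=(1, 2), rng=rng),
        nn.ReLU(),
        nn.ResBlock(w2, rng=rng),
        nn.Conv2d(w2, w3, stride=(1, 2), rng=rng),
        nn.ReLU(),
        nn.ResBlock(w3, rng=rng),
        nn.SpatialPyramidPooling(spec.spp_levels),
    ]
    spp: nn.SpatialPyramidPooling = trunk[-1]  # type: ignore[assignment]
    hidden_in = w3 * spp.bins_per_channel
    return nn.MultiTaskNet(trunk, hidden_in, spec.hidden, dict(HEADS), rng)


# ---------------------------------------------------------------------------
# Training-example generation
# ---------------------------------------------------------------------------

@dataclass
class TrainingExample:
    x: np.ndarray                       # (channels, 33, rows)
    labels: Tuple[int, int, int, int]   # gt21, zygosity, indel1, indel2
    coverage_pair: Tuple[float, float]
    site_key: Tuple[str, int]


def flip_phase_channel(tensor: np.ndarray) -> None:
    """Swap the hap1/hap2 codes in the phasing channel, in place.

    Within a phase block the two haplotype labels are only defined up to a
    global flip; training flips each example's per-platform labels at
    random so the network learns that gauge symmetry instead of the
    particular labeling the training phaser happened to produce.
    """
    ch = tensor[7]
    h1 = ch == PHASE_CODE[1]
    h2 = ch == PHASE_CODE[2]
    ch[h1] = PHASE_CODE[2]
    ch[h2] = PHASE_CODE[1]


def downsample_reads(reads: Sequence[AlignedRead], fraction: float,
                     seed: int) -> List[AlignedRead]:
    """Random read-level downsample keeping each read with prob fraction."""
    if fraction >= 1.0:
        return list(reads)
    rng = np.random.default_rng(seed)
    keep = rng.random(len(reads)) < fraction
    return [r for r, k in zip(reads, keep) if k]


def make_training_examples(sites: Sequence[CandidateSite],
                           reads_by_platform: Dict[str, List[AlignedRead]],
                           platform_order: Sequence[str],
                           max_coverage: Dict[str, float],
                           truth,
                           grid: CoverageGrid,
                           strat_index: Optional[StratificationIndex] = None,
                           seed: int = 0) -> List[TrainingExample]:
    """Encode every site at every coverage pair of the grid.

    Reads are downsampled per platform to approximate each grid coverage from
    the maximum simulated coverage, then encoded; labels come from the truth
    set. With ``strat_index`` given, the 9th channel is appended.
    """
    from .align_io import ReadIndex
    truth_at = {(v.contig, v.pos): v for v in truth}
    examples: List[TrainingExample] = []
    single = len(platform_order) == 1
    flip_rng = np.random.default_rng((seed + 12345) % (2 ** 31))
    for gi, (cov_a, cov_b) in enumerate(grid):
        subs: Dict[str, ReadIndex] = {}
        for pi, plat in enumerate(platform_order):
            want = (cov_a, cov_b)[pi]
            frac = min(1.0, want / max_coverage[plat])
            subs[plat] = ReadIndex(downsample_reads(
                reads_by_platform[plat], frac,
                seed=(seed * 1009 + gi * 31 + pi) % (2 ** 31)))
        for site in sites:
            w = site.window
            tensors = [encode_platform(subs[p].query(w.contig, w.start, w.end),
                                       w, site)
                       for p in platform_order]
            for t in tensors:
                # phasing gauge augmentation: each platform's haplotype
                # labels flip with probability 1/2
                if flip_rng.random() < 0.5:
                    flip_phase_channel(t)
            sv = (stratification_value(strat_index, site.window)
                  if strat_index is not None else None)
            if single:
                x = tensors[0]
                if sv is not None:
                    plane = np.full((1,) + x.shape[1:], sv, dtype=x.dtype)
                    x = np.concatenate([x, plane], axis=0)
            else:
                x = assemble_mp_input(tensors[0], tensors[1], sv)
            v = truth_at.get((site.contig, site.position))
            labels = truth_genotype_labels(site.ref, v)
            examples.append(TrainingExample(
                x=x, labels=labels, coverage_pair=(cov_a, cov_b),
                site_key=(site.contig, site.position)))
    return examples


def _examples_to_arrays(examples: Sequence[TrainingExample]
                        ) -> Tuple[np.ndarray, Dict[str, np.ndarray]]:
    # kept int8 until batch time; nn.fit rescales each batch by 1/100
    x = np.stack([e.x for e in examples])
    lab = np.array([e.labels for e in examples], dtype=np.int64)
    labels = {"gt21": lab[:, 0], "zygosity": lab[:, 1],
              "indel_len_1": lab[:, 2], "indel_len_2": lab[:, 3]}
    return x, labels


def train_fullalign(model: nn.MultiTaskNet,
                    examples: Sequence[TrainingExample],
                    val_fraction: float = 0.10,
                    epochs: int = 30, seed: int = 0,
                    lr: float = 2e-3, batch_size: int = 64) -> List[dict]:
    """Train on encoded examples; 10% random validation split, best-val
    checkpointing. Returns the epoch history."""
    if len(examples) == 0:
        raise ValueError("empty full-alignment training set")
    x, labels = _examples_to_arrays(examples)
    return nn.fit(model, x, labels, epochs=epochs, seed=seed,
                  batch_size=batch_size, lr=lr, val_fraction=val_fraction,
                  input_scale=100.0)


def save_fullalign_model(model: nn.MultiTaskNet, path: str,
                         spec: NetworkSpec,
                         platform_order: Sequence[str],
                         history: Optional[List[dict]] = None) -> None:
    meta = {"kind": "fullalign", "spec": asdict(spec),
            "platforms": list(platform_order),
            "channel_layout": CHANNEL_LAYOUT_VERSION,
            "in_channels": spec.in_channels}
    if history:
        meta["final_val_loss"] = history[-1].get("val_loss")
    model.save(path, metadata=meta)


def load_fullalign_model(path: str) -> Tuple[nn.MultiTaskNet, NetworkSpec, dict]:
    meta = nn.load_checkpoint_metadata(path)
    if meta.get("kind") != "fullalign":
        raise ValueError(f"{path} is not a full-alignment checkpoint")
    sd = dict(meta["spec"])
    sd["widths"] = tuple(sd["widths"])
    sd["spp_levels"] = tuple(
        tuple(l) if isinstance(l, (list, tuple)) else l
        for l in sd["spp_levels"])
    spec = NetworkSpec(**sd)
    model = build_network(spec, seed=0)
    model.load_weights(path)
    return model, spec, meta


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

@dataclass
class VariantCall:
    """A final genotyped site with per-task probabilities."""

    contig: str
    position: int                       # 0-based
    ref: str
    alts: Tuple[str, ...]
    gt: str
    qual: float
    depth: int
    allele_fraction: float
    probs: Dict[str, np.ndarray]
    indel_lengths: Tuple[int, int] = (0, 0)

    @property
    def is_refcall(self) -> bool:
        return self.gt == "0/0"


def call_variants(model: nn.MultiTaskNet, spec: NetworkSpec,
                  candidates: Sequence[CandidateSite],
                  reads_by_platform: Dict[str, List[AlignedRead]],
                  platform_order: Sequence[str],
                  strat_index: Optional[StratificationIndex] = None,
                  batch_size: int = 64,
                  keep_refcalls: bool = False) -> List[VariantCall]:
    """Encode and score every candidate; decode genotypes to VCF alleles.

    Reference calls (0/0) are suppressed unless ``keep_refcalls``. A model
    built with the stratification channel requires ``strat_index``.
    """
    if spec.stratification and strat_index is None:
        raise ValueError("model expects a stratification channel; no "
                         "stratification index given")
    if len(platform_order) != spec.n_platforms:
        raise ValueError(f"model is {spec.n_platforms}-platform, got "
                         f"{len(platform_order)}")
    from .align_io import ReadIndex
    from .genotypes import indel_length_from_class
    indexes = {p: ReadIndex(reads_by_platform[p]) for p in platform_order}

    calls: List[VariantCall] = []
    batch: List[np.ndarray] = []
    batch_sites: List[CandidateSite] = []

    def flush():
        if not batch:
            return
        x = np.stack(batch).astype(float) / 100.0
        probs = model.predict_proba(x)
        for j, site in enumerate(batch_sites):
            g = probs["gt21"][j]
            cls = int(g.argmax())
            modal_ins = None
            modal_del_ref = None
            for a in site.alts:
                if a.startswith("-"):
                    modal_del_ref = a[1:]
                elif len(a) > 1:
                    modal_ins = a[1:]
            decoded = decode_genotype(cls, site.ref, modal_ins, modal_del_ref)
            if decoded is None:
                decoded = (site.ref, (), "0/0")
            ref, alts, gt = decoded
            lens = (indel_length_from_class(int(probs["indel_len_1"][j].argmax())),
                    indel_length_from_class(int(probs["indel_len_2"][j].argmax())))
            calls.append(VariantCall(
                contig=site.contig, position=site.position, ref=ref,
                alts=alts, gt=gt, qual=phred_qual(float(g[cls])),
                depth=site.depth, allele_fraction=site.allele_fraction,
                probs={k: probs[k][j] for k in probs},
                indel_lengths=lens))
        batch.clear()
        batch_sites.clear()

    for site in candidates:
        w = site.window
        tensors = [encode_platform(indexes[p].query(w.contig, w.start, w.end),
                                   w, site)
                   for p in platform_order]
        sv = (stratification_value(strat_index, site.window)
              if spec.stratification else None)
        if spec.n_platforms == 1:
            x = tensors[0]
            if sv is not None:
                plane = np.full((1,) + x.shape[1:], sv, dtype=x.dtype)
                x = np.concatenate([x, plane], axis=0)
        else:
            x = assemble_mp_input(tensors[0], tensors[1], sv)
        batch.append(x)
        batch_sites.append(site)
        if len(batch) >= batch_size:
            flush()
    flush()
    if not keep_refcalls:
        calls = [c for c in calls if not c.is_refcall]
    calls.sort(key=lambda c: (c.contig, c.position))
    return calls


def calls_to_vcf_records(calls: Sequence[VariantCall]) -> List[VcfRecord]:
    out = []
    for c in calls:
        if c.is_refcall:
            continue
        out.append(VcfRecord(
            contig=c.contig, pos=c.position, ref=c.ref, alts=c.alts,
            gt=c.gt, qual=c.qual, gq=int(round(c.qual)), dp=c.depth,
            af=c.allele_fraction))
    return out
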