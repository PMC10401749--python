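"""The 33x18 pileup tensor encoder and the per-platform pileup caller.

The pileup input summarizes a 33-position window as 18 integer features per
position: 9 evidence categories (A, C, G, T, insertion events, inserted
bases, deleted positions, deletion anchors, low-quality/other) split by
strand, each normalized to 0-100 by the column depth — 594 integers in
total. The pileup model is a small two-task convolutional network (21
genotypes + zygosity) whose calls drive phasing-SNP selection; its QUAL is
the Phred-scaled confidence of the argmax genotype, capped at 60.

The exact 18-feature semantics are a documented, versioned layout
(``FEATURE_LAYOUT_VERSION``) isolated behind this encoder so alternative
layouts can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .align_io import GenomicWindow
from .candidates import CATEGORIES, STRANDS, CandidateSite, PileupColumn
from .genotypes import (N_GT21, decode_genotype, truth_genotype_labels)

WINDOW_SIZE = 33
N_FEATURES = len(CATEGORIES) * len(STRANDS)          # 18
PILEUP_ELEMENTS = WINDOW_SIZE * N_FEATURES           # 594
FEATURE_LAYOUT_VERSION = "pileup-9cat-2strand-v1"
QUAL_CAP = 60.0


@dataclass
class PileupCall:
    """A preliminary per-platform call at a candidate site."""

    site: CandidateSite
    gt: str                               # "0/0", "0/1", "1/1", "1/2"
    ref: str
    alts: Tuple[str, ...]
    qual: float
    gt21_probs: np.ndarray
    zygosity_probs: np.ndarray

    @property
    def contig(self) -> str:
        return self.site.contig

    @property
    def position(self) -> int:
        return self.site.position

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)


def encode_pileup(columns: Sequence[PileupColumn], window: GenomicWindow
                  ) -> np.ndarray:
    """Encode a 33-position window as the (33, 18) integer pileup input.

    Counts are normalized per column to 0-100 by depth (so duplicating every
    read leaves the encoding unchanged); uncovered positions are all-zero.
    """
    if window.size != WINDOW_SIZE:
        raise ValueError(f"pileup window must span {WINDOW_SIZE} positions, "
                         f"got {window.size}")
    by_pos = {c.position: c for c in columns if c.contig == window.contig}
    out = np.zeros((WINDOW_SIZE, N_FEATURES), dtype=np.int64)
    for i, pos in enumerate(range(window.start, window.end)):
        c = by_pos.get(pos)
        if c is None or c.depth == 0:
            continue
        f = 0
        for cat in CATEGORIES:
            for s in STRANDS:
                val = 100.0 * c.counts.get((cat, s), 0) / c.depth
                out[i, f] = int(round(min(val, 100.0)))
                f += 1
    return out


def phred_qual(p_max: float, cap: float = QUAL_CAP) -> float:
    """Phred-scaled confidence -10*log10(1 - p_max), capped."""
    err = max(1.0 - p_max, 1e-300)
    return float(min(-10.0 * np.log10(err), cap))


def build_pileup_network(seed: int = 0) -> nn.MultiTaskNet:
    """Two 1-D convolutions over the 33 positions plus two softmax heads."""
    rng = np.random.default_rng(seed)
    trunk: List[nn.Layer] = [
        nn.Conv2d(N_FEATURES, 24, kernel=(3, 1), rng=rng),
        nn.ReLU(),
        nn.Conv2d(24, 32, kernel=(3, 1), stride=(2, 1), rng=rng),
        nn.ReLU(),
        nn.Flatten(),
    ]
    hidden_in = 32 * ((WINDOW_SIZE - 1) // 2 + 1)    # stride-2 over 33 -> 17
    return nn.MultiTaskNet(trunk, hidden_in, 64,
                           {"gt21": N_GT21, "zygosity": 3}, rng)


def _to_net_input(mats: Sequence[np.ndarray]) -> np.ndarray:
    """Stack (33,18) matrices to (B, 18, 33, 1) network input in [0,1]."""
    x = np.stack(mats).astype(float) / 100.0
    return x.transpose(0, 2, 1)[:, :, :, None]


def make_pileup_labels(sites: Sequence[CandidateSite], truth
                       ) -> Dict[str, np.ndarray]:
    """gt21/zygosity labels for candidate sites from the truth set."""
    truth_at = {(v.contig, v.pos): v for v in truth}
    gt21 = np.empty(len(sites), dtype=np.int64)
    zyg = np.empty(len(sites), dtype=np.int64)
    for i, s in enumerate(sites):
        v = truth_at.get((s.contig, s.position))
        g, z, _, _ = truth_genotype_labels(s.ref, v)
        gt21[i] = g
        zyg[i] = z
    return {"gt21": gt21, "zygosity": zyg}


def train_pileup(model: nn.MultiTaskNet, encoded: Sequence[np.ndarray],
                 labels: Dict[str, np.ndarray], epochs: int = 30,
                 seed: int = 0, lr: float = 2e-3,
                 val_fraction: float = 0.10) -> List[dict]:
    """Train the pileup model; returns the epoch history."""
    if len(encoded) == 0:
        raise ValueError("empty pileup training set")
    return nn.fit(model, _to_net_input(encoded), labels, epochs=epochs,
                  seed=seed, lr=lr, val_fraction=val_fraction)


def save_pileup_model(model: nn.MultiTaskNet, path: str, platform: str) -> None:
    model.save(path, metadata={
        "kind": "pileup", "platform": platform,
        "feature_layout": FEATURE_LAYOUT_VERSION,
    })


def load_pileup_model(path: str) -> Tuple[nn.MultiTaskNet, dict]:
    model = build_pileup_network(seed=0)
    meta = model.load_weights(path)
    if meta.get("kind") != "pileup":
        raise ValueError(f"{path} is not a pileup checkpoint")
    return model, meta


def pileup_call(model: nn.MultiTaskNet, encoded: Sequence[np.ndarray],
                sites: Sequence[CandidateSite],
                model_platform: Optional[str] = None,
                batch_size: int = 256) -> List[PileupCall]:
    """Score encoded candidate windows and decode preliminary genotypes."""
    if model_platform is not None:
        for s in sites:
            if s.platforms and model_platform not in s.platforms:
                raise ValueError(
                    f"model trained for {model_platform} got a site from "
                    f"{sorted(s.platforms)}")
    calls: List[PileupCall] = []
    x = _to_net_input(encoded)
    for i in range(0, len(sites), batch_size):
        probs = model.predict_proba(x[i:i + batch_size])
        for j, site in enumerate(sites[i:i + batch_size]):
            g = probs["gt21"][j]
            z = probs["zygosity"][j]
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
            calls.append(PileupCall(
                site=site, gt=gt, ref=ref, alts=alts,
                qual=phred_qual(float(g[cls])),
                gt21_probs=g, zygosity_probs=z))
    return calls
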