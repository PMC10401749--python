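"""Genotype-aware benchmarking of a call set against a truth set.

A lightweight, exact-matching analogue of haplotype-comparison benchmarking:
a call is a true positive iff a truth record exists with the same (contig,
position, REF, ALT set, genotype); a genotype mismatch at an otherwise
matched site counts one false positive and one false negative. Metrics are
reported overall, split by SNP vs indel, and per labeled stratification
region (membership decided by the POS anchor base). Both inputs must be
position-sorted with left-anchored indel alleles; the synthetic truth the
package generates is already normalized that way, so representation
differences cannot arise — a documented divergence from realignment-based
matchers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .align_io import StratificationIndex, VcfRecord


@dataclass
class MatchResult:
    """TP/FP/FN counts plus per-record labels from genotype-aware matching."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    call_labels: List[Tuple[Tuple[str, int], str]] = field(default_factory=list)
    truth_labels: List[Tuple[Tuple[str, int], str]] = field(default_factory=list)


def _gt_multiset(gt: str, alts: Sequence[str]) -> Optional[frozenset]:
    """Genotype as a multiset of allele strings (phase-insensitive)."""
    sep = "|" if "|" in gt else "/"
    try:
        idx = [int(a) for a in gt.split(sep)]
    except ValueError:
        return None
    alleles = []
    for i in idx:
        alleles.append("REF" if i == 0 else alts[i - 1])
    return frozenset((a, alleles.count(a)) for a in alleles)


def _is_indel(ref: str, alts: Sequence[str]) -> bool:
    longest = max([len(ref)] + [len(a) for a in alts]) if alts else len(ref)
    return longest > 1


def _check_sorted_normalized(records: Sequence[VcfRecord], name: str) -> None:
    prev: Dict[str, int] = {}
    for r in records:
        if r.contig in prev and r.pos < prev[r.contig]:
            raise ValueError(f"{name} records are not position-sorted")
        prev[r.contig] = r.pos
        for a in r.alts:
            # length-changing alleles must share the anchor base; equal
            # lengths (SNP/MNP-style) carry no anchor requirement
            if (len(r.ref) != len(a) and min(len(r.ref), len(a)) > 1
                    and r.ref[0] != a[0]):
                raise ValueError(
                    f"{name} record at {r.contig}:{r.pos + 1} is not "
                    "left-anchored")


def match_calls(calls: Sequence[VcfRecord], truth: Sequence[VcfRecord],
                regions: Optional[StratificationIndex] = None) -> MatchResult:
    """Genotype-aware exact matching of calls against truth.

    With ``regions`` given, both sets are first restricted to records whose
    POS anchor falls inside the region set.
    """
    _check_sorted_normalized(calls, "call")
    _check_sorted_normalized(truth, "truth")
    if regions is not None:
        calls = [c for c in calls if regions.contains(c.contig, c.pos)]
        truth = [t for t in truth if regions.contains(t.contig, t.pos)]
    truth_by_pos: Dict[Tuple[str, int], VcfRecord] = {
        (t.contig, t.pos): t for t in truth}
    res = MatchResult()
    matched: set = set()
    for c in calls:
        key = (c.contig, c.pos)
        t = truth_by_pos.get(key)
        ok = (t is not None
              and c.ref.upper() == t.ref.upper()
              and set(a.upper() for a in c.alts) == set(a.upper() for a in t.alts)
              and _gt_multiset(c.gt, [a.upper() for a in c.alts])
                  == _gt_multiset(t.gt, [a.upper() for a in t.alts]))
        if ok and key not in matched:
            matched.add(key)
            res.tp += 1
            res.call_labels.append((key, "TP"))
        else:
            res.fp += 1
            res.call_labels.append((key, "FP"))
    for t in truth:
        key = (t.contig, t.pos)
        if key in matched:
            res.truth_labels.append((key, "TP"))
        else:
            res.fn += 1
            res.truth_labels.append((key, "FN"))
    return res


def prf(match: MatchResult) -> Tuple[float, float, float]:
    """(precision, recall, F1); zero denominators yield zero metrics."""
    p = match.tp / (match.tp + match.fp) if match.tp + match.fp else 0.0
    r = match.tp / (match.tp + match.fn) if match.tp + match.fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def _split_by_type(records: Sequence[VcfRecord]
                   ) -> Tuple[List[VcfRecord], List[VcfRecord]]:
    snps = [r for r in records if not _is_indel(r.ref, r.alts)]
    indels = [r for r in records if _is_indel(r.ref, r.alts)]
    return snps, indels


def stratified_report(calls: Sequence[VcfRecord], truth: Sequence[VcfRecord],
                      strat: Optional[Dict[str, StratificationIndex]] = None
                      ) -> pd.DataFrame:
    """Precision/recall/F1 rows per (region label x variant type).

    Always includes an "overall" region with rows ALL / SNP / INDEL; each
    labeled region contributes SNP and INDEL rows restricted to it.
    """
    rows = []

    def add(region: str, vtype: str, c, t, index):
        m = match_calls(c, t, index)
        p, r, f1 = prf(m)
        rows.append({"region": region, "type": vtype, "tp": m.tp,
                     "fp": m.fp, "fn": m.fn, "precision": p, "recall": r,
                     "f1": f1})

    call_snp, call_indel = _split_by_type(calls)
    truth_snp, truth_indel = _split_by_type(truth)
    add("overall", "ALL", calls, truth, None)
    add("overall", "SNP", call_snp, truth_snp, None)
    add("overall", "INDEL", call_indel, truth_indel, None)
    for label, index in (strat or {}).items():
        add(label, "SNP", call_snp, truth_snp, index)
        add(label, "INDEL", call_indel, truth_indel, index)
    return pd.DataFrame(rows)
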