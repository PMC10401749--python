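"""The 21-class genotype task shared by the pileup and full-alignment models.

Genotypes are unordered pairs with repetition over the six allele symbols
{A, C, G, T, Ins, Del}: 6 homotypic + 15 heterotypic = 21 classes, in fixed
lexicographic order over the symbol list below. The zygosity task has three
classes (hom-ref, het, hom-alt). The two indel-length tasks classify a signed
length into 33 bins: -15..+15 plus one overflow bin at each end.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

ALLELE_SYMBOLS = ("A", "C", "G", "T", "I", "D")   # I=insertion, D=deletion

# fixed lexicographic enumeration of unordered pairs (i <= j)
GT21_PAIRS: List[Tuple[str, str]] = [
    (ALLELE_SYMBOLS[i], ALLELE_SYMBOLS[j])
    for i in range(len(ALLELE_SYMBOLS))
    for j in range(i, len(ALLELE_SYMBOLS))
]
GT21_INDEX: Dict[Tuple[str, str], int] = {p: k for k, p in enumerate(GT21_PAIRS)}
N_GT21 = len(GT21_PAIRS)          # == 21

ZYGOSITY_CLASSES = ("hom_ref", "het", "hom_alt")

INDEL_LEN_SPAN = 15               # classes cover -15..+15
N_INDEL_CLASSES = 2 * INDEL_LEN_SPAN + 3   # + two overflow bins == 33


def genotype21_index(a: str, b: str) -> int:
    """Class index of the unordered pair (a, b) of allele symbols."""
    pair = tuple(sorted((a, b), key=ALLELE_SYMBOLS.index))
    return GT21_INDEX[pair]


def allele_symbol(ref: str, allele: str) -> str:
    """Map a left-anchored allele string to its genotype symbol."""
    if len(allele) == len(ref) == 1:
        return allele.upper()
    if len(allele) > len(ref):
        return "I"
    return "D"


def indel_length_class(length: int) -> int:
    """Bin a signed indel length (ins > 0, del < 0, SNP/ref 0) into 0..32."""
    if length < -INDEL_LEN_SPAN:
        return 0
    if length > INDEL_LEN_SPAN:
        return N_INDEL_CLASSES - 1
    return length + INDEL_LEN_SPAN + 1


def indel_length_from_class(cls: int) -> int:
    """Representative signed length of an indel-length class."""
    if cls == 0:
        return -(INDEL_LEN_SPAN + 1)
    if cls == N_INDEL_CLASSES - 1:
        return INDEL_LEN_SPAN + 1
    return cls - INDEL_LEN_SPAN - 1


def truth_genotype_labels(ref_base: str, truth_variant) -> Tuple[int, int, int, int]:
    """(gt21, zygosity, indel1_cls, indel2_cls) labels for a truth variant.

    ``truth_variant`` may be None for a reference (0/0) site.
    """
    r = ref_base.upper()
    if truth_variant is None:
        return genotype21_index(r, r), 0, indel_length_class(0), indel_length_class(0)
    v = truth_variant
    syms = [allele_symbol(v.ref, a) for a in v.alts]
    lens = [len(a) - len(v.ref) for a in v.alts]
    if v.gt == "0/1":
        gt21 = genotype21_index(r, syms[0])
        zyg = 1
        l1, l2 = sorted((0, lens[0]))
    elif v.gt == "1/1":
        gt21 = genotype21_index(syms[0], syms[0])
        zyg = 2
        l1 = l2 = lens[0]
    elif v.gt == "1/2":
        gt21 = genotype21_index(syms[0], syms[1])
        zyg = 1
        l1, l2 = sorted(lens[:2])
    else:
        raise ValueError(f"unsupported truth genotype {v.gt}")
    return gt21, zyg, indel_length_class(l1), indel_length_class(l2)


def decode_genotype(gt21_class: int, ref_base: str,
                    modal_ins: Optional[str], modal_del_ref: Optional[str]
                    ) -> Optional[Tuple[str, Tuple[str, ...], str]]:
    """Decode a 21-genotype class into (REF, ALTs, GT) at a site.

    ``modal_ins`` is the dominant inserted sequence (without the anchor
    base); ``modal_del_ref`` is the left-anchored reference allele of the
    dominant deletion. Returns None when the class needs indel evidence the
    site does not have (the caller then falls back to hom-ref).
    """
    a, b = GT21_PAIRS[gt21_class]
    r = ref_base.upper()

    def materialize(sym: str) -> Optional[Tuple[str, str]]:
        """-> (ref allele, this allele) in left-anchored representation."""
        if sym == "I":
            if not modal_ins:
                return None
            return r, r + modal_ins
        if sym == "D":
            if not modal_del_ref or len(modal_del_ref) < 2:
                return None
            return modal_del_ref, r
        return r, sym

    if a == b:
        if a == r:
            return r, (), "0/0"
        m = materialize(a)
        if m is None:
            return None
        return m[0], (m[1],), "1/1"
    # heterotypic pair
    if r in (a, b) and a not in "ID" and b not in "ID":
        alt = b if a == r else a
        return r, (alt,), "0/1"
    ma, mb = materialize(a), materialize(b)
    if a not in "ID" and a == r:
        if mb is None:
            return None
        return mb[0], (mb[1],), "0/1"
    if b not in "ID" and b == r:
        if ma is None:
            return None
        return ma[0], (ma[1],), "0/1"
    # 1/2: two non-ref alleles; unify to a common left-anchored REF
    if ma is None or mb is None:
        return None
    ref_a, alt_a = ma
    ref_b, alt_b = mb
    ref = ref_a if len(ref_a) >= len(ref_b) else ref_b
    def pad(alt: str, own_ref: str) -> str:
        return alt + ref[len(own_ref):]
    alts = (pad(alt_a, ref_a), pad(alt_b, ref_b))
    if alts[0] == alts[1]:
        return None
    return ref, alts, "1/2"
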