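"""Focal-cultivar unique-SV calling from a pan-genome multi-sample VCF.

The panel VCF comes from decomposing a pan-genome graph against the focal
cultivar's genome, so the REF allele is the focal sequence and each sample
column is one non-focal haplotype.  A record is a *unique SV* of the focal
cultivar when (a) the allele-length delta reaches the SV threshold (50 bp),
and (b) every haplotype sample is homozygous for alternate allele 1
("1|1"/"1/1"): every other haplotype carries the same alternative, i.e. the
REF-side sequence is private to the focal cultivar.

Direction convention (deliberately inverted relative to naive VCF reading,
and focal-centric): REF longer than the query allele means the focal genome
carries extra sequence, an *insertion*; REF shorter means the focal genome
lacks sequence all others have, a *deletion*.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .records import PanVariantRecord

__all__ = [
    "VariantClass",
    "UniqueSV",
    "classify_variant",
    "summarize_variant_classes",
    "find_unique_svs",
    "classify_sv_direction",
    "unique_sv_table",
]


class VariantClass(str, Enum):
    SNP = "SNP"
    MNP = "MNP"
    INDEL = "INDEL"
    SV = "SV"


@dataclass(frozen=True)
class UniqueSV:
    """A focal-cultivar-private SV record with its direction and size."""

    record: PanVariantRecord
    direction: str  # "insertion" | "deletion"
    allele_length_delta: int


def _max_delta(rec: PanVariantRecord) -> int:
    return max(abs(len(rec.ref) - len(alt)) for alt in rec.alts)


def classify_variant(rec: PanVariantRecord, sv_min_len: int = 50) -> VariantClass:
    """Classify a panel record as SNP, MNP, INDEL or SV.

    Let d be the largest REF-vs-ALT length difference over all ALT alleles:
    d = 0 gives SNP (1-bp REF) or MNP; 0 < d < ``sv_min_len`` gives INDEL;
    d >= ``sv_min_len`` gives SV.
    """
    if not rec.alts:
        raise ValueError(f"record {rec.id!r}: empty ALT list")
    d = _max_delta(rec)
    if d == 0:
        return VariantClass.SNP if len(rec.ref) == 1 else VariantClass.MNP
    if d < sv_min_len:
        return VariantClass.INDEL
    return VariantClass.SV


def summarize_variant_classes(
    recs: Iterable[PanVariantRecord], sv_min_len: int = 50
) -> dict[VariantClass, int]:
    counts = Counter(classify_variant(r, sv_min_len) for r in recs)
    return {cls: counts.get(cls, 0) for cls in VariantClass}


def _is_all_hom_alt1(rec: PanVariantRecord) -> bool:
    """True iff no genotype allele is '0' or missing and all are '1'."""
    alleles = rec.genotype_alleles()
    if not alleles:
        return False
    for tok in alleles:
        if any(a in ("0", ".") for a in tok):
            return False  # shared with focal, or missing call
    for tok in alleles:
        if any(a != "1" for a in tok):
            return False  # e.g. 2|2: a different alternative allele
    return True


def classify_sv_direction(rec: PanVariantRecord) -> str:
    """Focal-centric direction of a unique SV.

    The query allele is the ALT with the largest length delta.  REF longer
    => focal-specific *insertion*; REF shorter => *deletion*.  Equal lengths
    have no PAV direction and raise.
    """
    alt = max(rec.alts, key=lambda a: abs(len(rec.ref) - len(a)))
    if len(rec.ref) > len(alt):
        return "insertion"
    if len(rec.ref) < len(alt):
        return "deletion"
    raise ValueError(
        f"record {rec.id!r}: REF and query allele have equal length; "
        "insertion/deletion direction is undefined"
    )


def find_unique_svs(
    recs: Sequence[PanVariantRecord], sv_min_len: int = 50
) -> list[UniqueSV]:
    """Call focal-cultivar unique SVs, preserving input order.

    A record qualifies iff it classifies as SV, no genotype token carries a
    '0' allele or a missing call, and every token is exactly 1|1 (or 1/1).
    QUAL and FILTER are ignored: uniqueness is a genotype-pattern property.
    """
    out: list[UniqueSV] = []
    for rec in recs:
        if classify_variant(rec, sv_min_len) is not VariantClass.SV:
            continue
        if not _is_all_hom_alt1(rec):
            continue
        out.append(
            UniqueSV(
                record=rec,
                direction=classify_sv_direction(rec),
                allele_length_delta=_max_delta(rec),
            )
        )
    return out


def unique_sv_table(svs: Sequence[UniqueSV]) -> pd.DataFrame:
    """Flat table (chrom, pos, end, direction, delta, record id) for export.

    ``end`` is the last reference base touched by the REF allele, so the
    interval is usable directly for proximity linking.
    """
    rows = [
        {
            "chrom": u.record.chrom,
            "pos": u.record.pos,
            "end": u.record.pos + len(u.record.ref) - 1,
            "direction": u.direction,
            "delta": u.allele_length_delta,
            "id": u.record.id,
        }
        for u in svs
    ]
    return pd.DataFrame(rows, columns=["chrom", "pos", "end", "direction", "delta", "id"])
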