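"""Hemizygous-gene calling from long-read SV deletion calls.

A hemizygous gene is present on only one haplotype of the diploid; it shows
up as a heterozygous deletion call that spans the whole gene body.  The
caller filters deletion calls by the published thresholds (DEL type, END
present, precise breakpoints, length >= 50 bp, QUAL >= 60, read support
>= 4 — all bounds inclusive) and then classifies genes by containment.

Containment direction: the default ``gene_in_deletion`` requires the
deletion interval to fully contain the gene body, which is what a
whole-gene hemizygote means biologically.  The literal alternative
(``deletion_in_gene``) is available via ``mode``.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .records import GeneModel, SVCall

__all__ = [
    "filter_deletion_calls",
    "call_hemizygous_genes",
    "hemizygosity_rate",
]


def passes_deletion_filter(
    call: SVCall,
    min_len: int = 50,
    min_qual: float = 60.0,
    min_support: int = 4,
) -> bool:
    """Record-level predicate behind :func:`filter_deletion_calls`."""
    if not call.svtype:
        raise ValueError(f"SV call {call.id!r}: missing SVTYPE")
    return (
        call.svtype == "DEL"
        and call.end is not None
        and call.precise
        and call.svlen is not None
        and abs(call.svlen) >= min_len
        and call.qual is not None
        and call.qual >= min_qual
        and call.support >= min_support
    )


def filter_deletion_calls(
    calls: Iterable[SVCall],
    min_len: int = 50,
    min_qual: float = 60.0,
    min_support: int = 4,
) -> list[SVCall]:
    return [c for c in calls if passes_deletion_filter(c, min_len, min_qual, min_support)]


def call_hemizygous_genes(
    dels: Sequence[SVCall],
    genes: Sequence[GeneModel],
    mode: str = "gene_in_deletion",
) -> set[str]:
    """Genes fully contained in (or, alternatively, fully containing) a deletion.

    ``dels`` should already have passed :func:`filter_deletion_calls`.
    Each gene id is reported at most once.
    """
    if mode not in ("gene_in_deletion", "deletion_in_gene"):
        raise ValueError(f"unknown containment mode {mode!r}")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for d in dels:
        s, e = d.interval0()
        if e > s:
            trees[d.chrom].addi(s, e, d)
    hemi: set[str] = set()
    for g in genes:
        gs, ge = g.interval0()
        for iv in trees.get(g.chrom, IntervalTree()).overlap(gs, ge):
            if mode == "gene_in_deletion":
                if iv.begin <= gs and ge <= iv.end:
                    hemi.add(g.id)
                    break
            else:
                if gs <= iv.begin and iv.end <= ge:
                    hemi.add(g.id)
                    break
    return hemi


def hemizygosity_rate(n_hemi: int, n_genes: int) -> float:
    """Fraction of the annotated gene complement that is hemizygous."""
    if n_genes <= 0:
        raise ValueError("total gene count must be positive")
    if n_hemi > n_genes:
        raise ValueError("hemizygous gene count exceeds total gene count")
    return n_hemi / n_genes
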