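"""SV-gene proximity linking and term-enrichment testing.

Genes within 5 kb of a focal-unique SV are the candidate neighbourhood the
integration stage intersects with DEGs.  "Within 5 kb" is measured as the
end-to-end gap between the two intervals (bedtools-window semantics),
inclusive at exactly 5000 bp; overlap gives distance 0.  Enrichment of a
gene set against a background uses the upper-tail hypergeometric test with
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .records import GeneModel

__all__ = [
    "SVInterval",
    "SVGeneLink",
    "EnrichmentResult",
    "link_genes_to_svs",
    "links_table",
    "hypergeometric_enrichment",
]


@dataclass(frozen=True)
class SVInterval:
    """A named 1-based inclusive genomic interval (one unique SV)."""

    id: str
    chrom: str
    start: int
    end: int

    def interval0(self) -> tuple[int, int]:
        return self.start - 1, self.end


@dataclass(frozen=True)
class SVGeneLink:
    sv_id: str
    gene_id: str
    distance: int  # bp gap; 0 when overlapping (or book-ended)
    relation: str  # "overlapping" | "upstream" | "downstream" (gene-strand relative)


def _as_intervals(svs) -> list[SVInterval]:
    if isinstance(svs, pd.DataFrame):
        return [
            SVInterval(str(r.id), str(r.chrom), int(r.pos), int(r.end))
            for r in svs.itertuples()
        ]
    out = []
    for sv in svs:
        if isinstance(sv, SVInterval):
            out.append(sv)
        else:  # (id, chrom, start, end) tuple
            out.append(SVInterval(str(sv[0]), str(sv[1]), int(sv[2]), int(sv[3])))
    return out


def _gap0(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Intervening bases between two 0-based half-open intervals (0 if overlapping)."""
    if a_start < b_end and b_start < a_end:
        return 0
    return max(a_start - b_end, b_start - a_end)


def link_genes_to_svs(
    svs: Union[pd.DataFrame, Iterable],
    genes: Sequence[GeneModel],
    window: int = 5000,
) -> list[SVGeneLink]:
    """Emit one link per (SV, gene) pair whose interval gap is <= ``window``.

    The relation annotation uses the gene's strand: an SV 5' of the gene is
    "upstream".  Strand never affects eligibility.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    intervals = _as_intervals(svs)
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for sv in intervals:
        s, e = sv.interval0()
        # pad by window+1 so a tree query finds every candidate pair,
        # including pairs at exactly the window gap; the explicit gap
        # check below decides eligibility
        trees[sv.chrom].addi(s - window - 1, e + window + 1, sv)
    links: list[SVGeneLink] = []
    for g in genes:
        gs, ge = g.interval0()
        seen = set()
        for iv in trees.get(g.chrom, IntervalTree()).overlap(gs, ge):
            sv = iv.data
            if sv.id in seen:
                continue
            ss, se = sv.interval0()
            gap = _gap0(gs, ge, ss, se)
            if gap > window:
                continue
            seen.add(sv.id)
            if ss < ge and gs < se:
                relation = "overlapping"
            else:
                before_gene = se <= gs  # SV left of gene in genome coordinates
                if g.strand == "-":
                    relation = "downstream" if before_gene else "upstream"
                else:
                    relation = "upstream" if before_gene else "downstream"
            links.append(SVGeneLink(sv.id, g.id, gap, relation))
    links.sort(key=lambda l: (l.sv_id, l.gene_id))
    return links


def links_table(links: Sequence[SVGeneLink]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"sv_id": l.sv_id, "gene_id": l.gene_id, "distance": l.distance,
          "relation": l.relation} for l in links],
        columns=["sv_id", "gene_id", "distance", "relation"],
    )


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    study_hits: int        # k
    study_size: int        # n
    population_hits: int   # K
    population_size: int   # N
    p_value: float         # upper-tail hypergeometric P(X >= k)
    adjusted_p: float      # Benjamini-Hochberg


def hypergeometric_enrichment(
    study: set[str],
    population: set[str],
    term_map: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Over-representation test of ``study`` within ``population`` per term.

    ``term_map`` maps gene id -> iterable of term ids (a flat annotation
    table, no ontology propagation).  p = P(X >= k) for a hypergeometric
    draw of n = |study| from N = |population| with K term-annotated genes;
    BH adjustment across the tested terms; results sorted by adjusted p.
    """
    study = set(study)
    population = set(population)
    if not study <= population:
        raise ValueError("study gene set must be a subset of the population")
    term_genes: dict[str, set[str]] = defaultdict(set)
    for gene, terms in term_map.items():
        if gene not in population:
            raise ValueError(f"term map gene {gene!r} not in population")
        for t in terms:
            term_genes[t].add(gene)
    N, n = len(population), len(study)
    rows = []
    for term in sorted(term_genes):
        K = len(term_genes[term])
        k = len(term_genes[term] & study)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, min(1.0, p)))
    if not rows:
        return []
    adj = multipletests([r[3] for r in rows], alpha=alpha, method="fdr_bh")[1]
    results = [
        EnrichmentResult(term, k, n, K, N, p, float(a))
        for (term, k, K, p), a in zip(rows, adj)
    ]
    results.sort(key=lambda r: (r.adjusted_p, r.p_value, r.term))
    return results
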