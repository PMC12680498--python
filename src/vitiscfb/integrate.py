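"""Final integration: SV-proximal genes x DEGs, TPM, Spearman co-expression.

The candidate set is the deduplicated intersection of genes near
focal-unique SVs with the cross-cultivar DEG set, annotated with both
evidence tracks.  Bulk counts over developmental stages are TPM-normalized
(gene span as effective length), zero-containing rows are excluded, and
pairwise Spearman correlation with average-linkage leaf ordering gives the
co-expression structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

__all__ = [
    "CandidateGene",
    "intersect_candidates",
    "tpm_normalize",
    "filter_zero_rows",
    "spearman_matrix",
    "hierarchical_order",
]


@dataclass
class CandidateGene:
    """A gene supported by both SV proximity and differential expression."""

    gene_id: str
    sv_ids: list[str] = field(default_factory=list)
    sv_distances: list[int] = field(default_factory=list)
    deg_clusters: list = field(default_factory=list)
    deg_directions: list[str] = field(default_factory=list)
    deg_log2fcs: list[float] = field(default_factory=list)


def intersect_candidates(
    sv_genes: Iterable[str],
    degs: Iterable[str],
    links: Optional[pd.DataFrame] = None,
    deg_table: Optional[pd.DataFrame] = None,
) -> list[CandidateGene]:
    """Deduplicated intersection of the two evidence tracks, sorted by id.

    ``links`` (columns sv_id/gene_id/distance) and ``deg_table`` (columns
    gene/cluster/direction/avg_log2FC) are optional annotation sources.
    """
    candidates = sorted(set(sv_genes) & set(degs))
    out = []
    for gid in candidates:
        cand = CandidateGene(gene_id=gid)
        if links is not None:
            sub = links[links["gene_id"] == gid]
            cand.sv_ids = sub["sv_id"].tolist()
            cand.sv_distances = sub["distance"].tolist()
        if deg_table is not None:
            sub = deg_table[deg_table["gene"] == gid]
            cand.deg_clusters = sub["cluster"].tolist()
            cand.deg_directions = sub["direction"].tolist()
            cand.deg_log2fcs = sub["avg_log2FC"].tolist()
        out.append(cand)
    return out


def tpm_normalize(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from raw counts and per-gene lengths (bp).

    Per sample: rpk = count / (length/1000); TPM = rpk / sum(rpk) * 1e6,
    so every column sums to one million.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()[:5]
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rpk = counts.div(lengths / 1000.0, axis=0)
    totals = rpk.sum(axis=0)
    if (totals == 0).any():
        bad = totals[totals == 0].index.tolist()
        raise ValueError(f"sample(s) with zero total count: {bad}")
    return rpk.div(totals, axis=1) * 1e6


def filter_zero_rows(table: pd.DataFrame, policy: str = "any_zero") -> pd.DataFrame:
    """Drop genes with zero values before correlation.

    ``any_zero`` (default, the stricter reading) removes a gene if any
    sample is zero; ``all_zero`` removes only never-expressed genes.
    """
    if policy == "any_zero":
        keep = (table > 0).all(axis=1)
    elif policy == "all_zero":
        keep = (table > 0).any(axis=1)
    else:
        raise ValueError(f"unknown zero-row policy {policy!r}")
    if not keep.any():
        raise ValueError("zero-row filtering removed every gene")
    return table[keep]


def spearman_matrix(
    table: pd.DataFrame, genes: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Pairwise Spearman correlation of gene expression profiles.

    Average ranks handle ties; the result is symmetric with a unit
    diagonal.  Constant profiles have undefined correlation and yield NaN
    with a warning.
    """
    if genes is not None:
        missing = [g for g in genes if g not in table.index]
        if missing:
            raise KeyError(f"genes absent from the table: {missing[:5]}")
        table = table.loc[list(genes)]
    if table.shape[1] < 3:
        raise ValueError("need at least 3 samples for rank correlation")
    values = table.to_numpy(dtype=float)
    constant = values.std(axis=1) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant profile(s); correlations reported as NaN"
        )
    with warnings.catch_warnings():
        # constant rows are reported once, above, on our own terms
        warnings.simplefilter("ignore")
        if table.shape[0] == 1:
            corr = np.ones((1, 1))
        elif table.shape[0] == 2:
            rho, _ = spearmanr(values[0], values[1])
            corr = np.array([[1.0, rho], [rho, 1.0]])
        else:
            corr, _ = spearmanr(values, axis=1)
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=table.index, columns=table.index)


def hierarchical_order(corr: pd.DataFrame) -> list[str]:
    """Display ordering of genes by average-linkage clustering on 1 - rho.

    Missing correlations are imputed as 0 (with a warning) before
    clustering; the dendrogram leaf order is returned and is deterministic.
    """
    genes = list(corr.index)
    if len(genes) <= 1:
        return genes
    mat = corr.to_numpy(dtype=float).copy()
    if np.isnan(mat).any():
        warnings.warn("missing correlations imputed as 0 for ordering")
        mat = np.nan_to_num(mat, nan=0.0)
    dist = 1.0 - mat
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # guard against asymmetric float noise
    z = linkage(squareform(dist, checks=False), method="average")
    leaves = dendrogram(z, no_plot=True)["leaves"]
    return [genes[i] for i in leaves]
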