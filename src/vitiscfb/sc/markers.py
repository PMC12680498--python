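"""Cluster marker genes and per-cluster cross-cultivar DEGs.

Both callers share one differential-expression engine: genes are screened
by expression fraction (min.pct on the larger of the two groups), effect
size is the base-2 log fold change of back-transformed mean expression
with a pseudocount of 1, the p-value comes from the Wilcoxon rank-sum test
on log-normalized values, and the adjusted p is Bonferroni over the genes
tested in that comparison.

Markers are one-vs-rest per cluster and positive-only by default
(min.pct 0.25, logfc 0.25); DEGs compare the two cultivars within each
cluster two-sidedly (min.pct 0.1, logfc 0.25) and are consolidated across
clusters with a deduplicated gene-level summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .preprocess import NormalizedMatrix
from .stats import wilcoxon_rank_sum

__all__ = [
    "find_markers",
    "find_group_degs",
    "rank_top_markers",
    "DEGResult",
]

_DE_COLUMNS = ["gene", "cluster", "avg_log2FC", "pct_1", "pct_2", "p", "p_adj"]


def _de_table(
    values: sp.csr_matrix,
    expm1_values: sp.csr_matrix,
    gene_ids: list[str],
    idx1: np.ndarray,
    idx2: np.ndarray,
    min_pct: float,
) -> pd.DataFrame:
    """Test every screened gene between two cell index sets.

    Returns one row per *tested* gene (max of the two expression fractions
    >= ``min_pct``); effect-size filtering is the caller's job.
    """
    n1, n2 = len(idx1), len(idx2)
    pct1 = np.asarray((values[:, idx1] > 0).sum(axis=1)).ravel() / n1
    pct2 = np.asarray((values[:, idx2] > 0).sum(axis=1)).ravel() / n2
    mean1 = np.asarray(expm1_values[:, idx1].mean(axis=1)).ravel()
    mean2 = np.asarray(expm1_values[:, idx2].mean(axis=1)).ravel()
    logfc = np.log2((mean1 + 1.0) / (mean2 + 1.0))
    tested = np.flatnonzero(np.maximum(pct1, pct2) >= min_pct)
    dense = values[tested].toarray() if len(tested) else np.empty((0, values.shape[1]))
    rows = []
    for row, g in zip(dense, tested):
        _, p = wilcoxon_rank_sum(row[idx1], row[idx2])
        rows.append((gene_ids[g], logfc[g], pct1[g], pct2[g], p))
    df = pd.DataFrame(rows, columns=["gene", "avg_log2FC", "pct_1", "pct_2", "p"])
    df["p_adj"] = np.minimum(1.0, df["p"] * max(len(tested), 1))
    return df


def _expm1(values: sp.csr_matrix) -> sp.csr_matrix:
    out = values.copy()
    out.data = np.expm1(out.data)
    return out


def find_markers(
    norm: NormalizedMatrix,
    labels,
    only_positive: bool = True,
    min_pct: float = 0.25,
    logfc_min: float = 0.25,
) -> pd.DataFrame:
    """One-vs-rest marker genes for every cluster.

    Clusters with fewer than 3 cells are skipped with a warning.  Retained
    rows satisfy the fold-change threshold (one-sided when
    ``only_positive``); columns follow the MarkerRecord layout.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("marker calling needs at least two clusters")
    exp = _expm1(norm.values)
    frames = []
    for cluster in np.unique(labels):
        idx1 = np.flatnonzero(labels == cluster)
        idx2 = np.flatnonzero(labels != cluster)
        if len(idx1) < 3:
            warnings.warn(f"cluster {cluster} has {len(idx1)} cells; skipped")
            continue
        df = _de_table(norm.values, exp, norm.gene_ids, idx1, idx2, min_pct)
        keep = df["avg_log2FC"] >= logfc_min if only_positive else df["avg_log2FC"].abs() >= logfc_min
        df = df[keep].copy()
        df.insert(1, "cluster", cluster)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=_DE_COLUMNS)
    return pd.concat(frames, ignore_index=True)[_DE_COLUMNS]


@dataclass
class DEGResult:
    """Consolidated per-cluster DEG table plus a deduplicated gene summary."""

    consolidated: pd.DataFrame  # one row per (gene, cluster)
    gene_summary: pd.DataFrame  # one row per gene (largest-|logFC| cluster)


def find_group_degs(
    norm: NormalizedMatrix,
    labels,
    sample_of_cell=None,
    min_pct: float = 0.1,
    logfc_min: float = 0.25,
    return_all: bool = False,
) -> DEGResult:
    """Cross-sample DEGs within each cluster, consolidated across clusters.

    The first sample name (sorted order) is the reference: positive
    avg_log2FC means higher expression there, and ``direction`` records
    ``up_in_<sample>``.  Clusters lacking cells from both samples are
    skipped with a warning.  With ``return_all`` the consolidated table
    keeps every tested gene and flags threshold passage in
    ``passes_logfc`` (useful for calibration studies); the gene summary
    always uses only threshold-passing rows.
    """
    labels = np.asarray(labels)
    samples = np.asarray(
        norm.sample_of_cell if sample_of_cell is None else sample_of_cell
    )
    names = sorted(set(samples.tolist()))
    if len(names) < 2:
        raise ValueError("cross-sample DEG analysis needs two samples")
    if len(names) > 2:
        raise ValueError(f"expected two samples, got {names}")
    a, b = names
    exp = _expm1(norm.values)
    frames = []
    for cluster in np.unique(labels):
        in_cluster = labels == cluster
        idx1 = np.flatnonzero(in_cluster & (samples == a))
        idx2 = np.flatnonzero(in_cluster & (samples == b))
        if len(idx1) == 0 or len(idx2) == 0:
            warnings.warn(f"cluster {cluster} lacks cells from both samples; skipped")
            continue
        df = _de_table(norm.values, exp, norm.gene_ids, idx1, idx2, min_pct)
        df["passes_logfc"] = df["avg_log2FC"].abs() >= logfc_min
        if not return_all:
            df = df[df["passes_logfc"]].copy()
        df.insert(1, "cluster", cluster)
        df["direction"] = np.where(df["avg_log2FC"] > 0, f"up_in_{a}", f"up_in_{b}")
        frames.append(df)
    if not frames:
        cols = _DE_COLUMNS + ["direction", "passes_logfc"]
        empty = pd.DataFrame(columns=cols)
        return DEGResult(empty, empty)
    consolidated = pd.concat(frames, ignore_index=True)
    passing = consolidated[consolidated["passes_logfc"]]
    summary = (
        passing.loc[passing["avg_log2FC"].abs().groupby(passing["gene"]).idxmax()]
        .sort_values("gene")
        .reset_index(drop=True)
    )
    return DEGResult(consolidated, summary)


def rank_top_markers(records: pd.DataFrame, n: int = 50) -> pd.DataFrame:
    """Per-cluster top-n markers by decreasing avg_log2FC.

    Ties break by ascending raw p, then gene id; the sort is stable.
    """
    if n not in (10, 20, 50):
        warnings.warn(f"top-n of {n} is outside the reported 10/20/50 presets")
    if records.empty:
        return records.copy()
    out = (
        records.sort_values(
            ["cluster", "avg_log2FC", "p", "gene"],
            ascending=[True, False, True, True],
            kind="mergesort",
        )
        .groupby("cluster", group_keys=False)
        .head(n)
        .reset_index(drop=True)
    )
    return out
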