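"""End-to-end single-nucleus stage for two cultivars.

QC per sample -> shared gene space -> log-normalization -> per-sample
variable genes combined by best rank -> per-sample scaling + joint PCA
(the integration substitute) -> PC cutoff -> SNN/Leiden clustering ->
cluster markers -> per-cluster cross-cultivar DEGs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from ..config import PipelineConfig
from ..records import CellMatrix
from .cluster import cluster_cells
from .markers import DEGResult, find_group_degs, find_markers, rank_top_markers
from .preprocess import (
    NormalizedMatrix,
    log_normalize,
    qc_filter,
    run_pca,
    select_pc_cutoff,
    select_variable_genes,
)

__all__ = ["ScStageResult", "run_sc_stage"]


@dataclass
class ScStageResult:
    norm: NormalizedMatrix
    variable_genes: list[str]
    scores: np.ndarray
    variance_fractions: np.ndarray
    pc_cutoff: int        # k suggested by the variance-spectrum criteria
    n_dims_used: int      # embedding dimensionality actually clustered on
    labels: np.ndarray
    markers: pd.DataFrame
    top_markers: dict[int, pd.DataFrame] = field(default_factory=dict)
    degs: DEGResult | None = None


def run_sc_stage(
    cm_a: CellMatrix,
    cm_b: CellMatrix,
    config: PipelineConfig | None = None,
    embedding: np.ndarray | None = None,
) -> ScStageResult:
    """Run the full single-nucleus pipeline on two cultivars' matrices.

    ``embedding`` accepts an externally integrated cell embedding (cells in
    concatenation order) and then skips the internal PCA.

    The neighbor graph is built on the first ``config.n_dims`` components
    (the study clustered on dimensions 1:13); with ``n_dims=None`` the
    variance-spectrum cutoff decides.  The cutoff is computed and reported
    either way.
    """
    cfg = config or PipelineConfig()
    qa = qc_filter(cm_a, cfg.qc_min_genes, cfg.qc_max_genes, cfg.qc_max_umi)
    qb = qc_filter(cm_b, cfg.qc_min_genes, cfg.qc_max_genes, cfg.qc_max_umi)
    shared = [g for g in qa.gene_ids if g in set(qb.gene_ids)]
    ga = np.isin(qa.gene_ids, shared)
    gb = np.isin(qb.gene_ids, shared)
    combined = qa.subset(gene_mask=ga).concat(qb.subset(gene_mask=gb))

    norm = log_normalize(combined, cfg.norm_scale)
    hvgs = select_variable_genes(combined, n=cfg.n_variable_genes)

    if embedding is None:
        n_comp = min(cfg.n_pcs, len(hvgs), combined.n_cells - 1)
        scores, fractions = run_pca(
            norm, hvgs, n_components=n_comp, random_state=cfg.seed
        )
        cutoff = select_pc_cutoff(
            fractions,
            cfg.cum_var_threshold,
            cfg.indiv_var_threshold,
            cfg.delta_var_threshold,
        )
        n_dims = cutoff if cfg.n_dims is None else min(cfg.n_dims, scores.shape[1])
        scores_used = scores[:, :n_dims]
    else:
        scores, fractions = embedding, np.array([])
        cutoff = n_dims = embedding.shape[1]
        scores_used = embedding

    labels = cluster_cells(
        scores_used, cfg.k_neighbors, cfg.resolution, seed=cfg.seed
    )
    if len(np.unique(labels)) >= 2:
        markers = find_markers(
            norm, labels, only_positive=True,
            min_pct=cfg.marker_min_pct, logfc_min=cfg.marker_logfc,
        )
    else:
        warnings.warn("a single cluster was found; no markers to call")
        markers = pd.DataFrame(
            columns=["gene", "cluster", "avg_log2FC", "pct_1", "pct_2", "p", "p_adj"]
        )
    top = {n: rank_top_markers(markers, n) for n in (10, 20, 50)}
    degs = find_group_degs(
        norm, labels, min_pct=cfg.deg_min_pct, logfc_min=cfg.deg_logfc
    )
    return ScStageResult(
        norm=norm,
        variable_genes=hvgs,
        scores=scores,
        variance_fractions=np.asarray(fractions),
        pc_cutoff=cutoff,
        n_dims_used=n_dims,
        labels=labels,
        markers=markers,
        top_markers=top,
        degs=degs,
    )
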