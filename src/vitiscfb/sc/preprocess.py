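"""Single-nucleus preprocessing: QC, log-normalization, variable genes, PCA.

Estimators follow sklearn conventions (``fit``/``transform``, fitted
attributes with trailing underscores) and operate on cells x genes
matrices; the module-level functions are thin wrappers speaking the
pipeline's genes x cells :class:`~vitiscfb.records.CellMatrix` dialect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from statsmodels.nonparametric.smoothers_lowess import lowess

from ..records import CellMatrix

__all__ = [
    "QCFilter",
    "LogNormalizer",
    "VariableGeneSelector",
    "ScaledPCA",
    "NormalizedMatrix",
    "qc_filter",
    "log_normalize",
    "select_variable_genes",
    "run_pca",
    "select_pc_cutoff",
]


class EmptyResultError(RuntimeError):
    """Raised when a filtering step removes every cell."""


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

class QCFilter(TransformerMixin, BaseEstimator):
    """Nucleus-level quality control.

    Keeps cells with ``min_genes <= detected genes <= max_genes`` (bounds
    inclusive) and total UMIs strictly below ``max_umi``; genes with zero
    total count over the retained cells are dropped.  Idempotent.
    """

    def __init__(self, min_genes: int = 200, max_genes: int = 7500, max_umi: int = 15000):
        self.min_genes = min_genes
        self.max_genes = max_genes
        self.max_umi = max_umi

    def fit(self, X, y=None):
        X = sp.csr_matrix(X)  # cells x genes
        genes_per_cell = np.asarray((X > 0).sum(axis=1)).ravel()
        umis_per_cell = np.asarray(X.sum(axis=1)).ravel()
        self.cell_mask_ = (
            (genes_per_cell >= self.min_genes)
            & (genes_per_cell <= self.max_genes)
            & (umis_per_cell < self.max_umi)
        )
        if not self.cell_mask_.any():
            raise EmptyResultError("QC removed every cell")
        kept = X[self.cell_mask_]
        self.gene_mask_ = np.asarray(kept.sum(axis=0)).ravel() > 0
        return self

    def transform(self, X):
        X = sp.csr_matrix(X)
        return X[self.cell_mask_][:, self.gene_mask_]


def qc_filter(
    cm: CellMatrix,
    min_genes: int = 200,
    max_genes: int = 7500,
    max_umi: int = 15000,
) -> CellMatrix:
    est = QCFilter(min_genes, max_genes, max_umi).fit(cm.counts.T)
    return cm.subset(gene_mask=est.gene_mask_, cell_mask=est.cell_mask_)


# ---------------------------------------------------------------------------
# Log-normalization
# ---------------------------------------------------------------------------

class LogNormalizer(TransformerMixin, BaseEstimator):
    """Per-cell depth normalization: value = ln(1 + count * scale / cell_total)."""

    def __init__(self, scale: float = 10000.0):
        self.scale = scale

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = sp.csr_matrix(X, dtype=float)  # cells x genes
        totals = np.asarray(X.sum(axis=1)).ravel()
        if (totals <= 0).any():
            raise ValueError("cell with zero total count; apply QC first")
        out = X.copy()
        # scale each row, then log1p on the stored entries (zeros stay zero)
        row_factor = self.scale / totals
        out = sp.diags(row_factor) @ out
        out = sp.csr_matrix(out)
        out.data = np.log1p(out.data)
        return out


@dataclass
class NormalizedMatrix:
    """Log-normalized expression (genes x cells) with its labels."""

    values: sp.csr_matrix
    gene_ids: list[str]
    barcodes: list[str]
    sample_of_cell: np.ndarray

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids: Sequence[str]) -> "NormalizedMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return NormalizedMatrix(
            self.values[rows], list(gene_ids), self.barcodes, self.sample_of_cell
        )


def log_normalize(cm: CellMatrix, scale: float = 10000.0) -> NormalizedMatrix:
    norm = LogNormalizer(scale).transform(cm.counts.T).T.tocsr()
    return NormalizedMatrix(norm, cm.gene_ids, cm.barcodes, cm.sample_of_cell.copy())


# ---------------------------------------------------------------------------
# Variable genes
# ---------------------------------------------------------------------------

def _standardized_variance(counts: sp.csr_matrix, span: float = 0.3) -> np.ndarray:
    """Per-gene variance of trend-standardized counts (vst-style).

    ``counts`` is cells x genes raw counts.  A lowess trend of log10
    variance against log10 mean predicts each gene's expected variance;
    counts are standardized by the predicted sd (clipped at sqrt(n_cells))
    and the variance of the standardized values is returned.  Genes with
    zero variance score 0.
    """
    counts = sp.csc_matrix(counts, dtype=float)
    n = counts.shape[0]
    mean = np.asarray(counts.mean(axis=0)).ravel()
    sq = counts.copy()
    sq.data **= 2
    ex2 = np.asarray(sq.mean(axis=0)).ravel()
    var = (ex2 - mean**2) * n / max(n - 1, 1)
    out = np.zeros(counts.shape[1])
    fit_mask = (var > 0) & (mean > 0)
    if fit_mask.sum() < 2:
        return out
    lx = np.log10(mean[fit_mask])
    ly = np.log10(var[fit_mask])
    smoothed = lowess(ly, lx, frac=span, return_sorted=False)
    expected_sd = np.sqrt(10.0**smoothed)
    clip = np.sqrt(n)
    indptr, data = counts.indptr, counts.data
    for col, mu, esd in zip(np.flatnonzero(fit_mask), mean[fit_mask], expected_sd):
        nz = data[indptr[col]:indptr[col + 1]]
        z_nz = np.clip((nz - mu) / esd, -clip, clip)
        z_zero = float(np.clip(-mu / esd, -clip, clip))
        n_zero = n - len(nz)
        s1 = z_nz.sum() + z_zero * n_zero
        s2 = (z_nz**2).sum() + z_zero**2 * n_zero
        out[col] = (s2 - s1**2 / n) / max(n - 1, 1)
    return out


class VariableGeneSelector(TransformerMixin, BaseEstimator):
    """Top-n highly variable genes, combined across samples by best rank.

    Per sample, genes are ranked by decreasing standardized variance; the
    combined rank of a gene is its best (minimum) per-sample rank, with the
    rank sum and then the gene index as tie-breaks.  This is the
    integration-free substitute for anchor-based feature selection: it
    keeps genes that are highly variable in either cultivar.
    """

    def __init__(self, n_top: int = 3000, span: float = 0.3):
        self.n_top = n_top
        self.span = span

    def fit(self, X, y=None, sample_labels: Optional[Sequence[str]] = None):
        X = sp.csr_matrix(X)  # cells x genes, raw counts
        n_genes = X.shape[1]
        if sample_labels is None:
            sample_labels = np.zeros(X.shape[0])
        sample_labels = np.asarray(sample_labels)
        ranks = []
        for s in np.unique(sample_labels):
            sv = _standardized_variance(X[sample_labels == s], self.span)
            order = np.argsort(-sv, kind="stable")
            r = np.empty(n_genes, dtype=int)
            r[order] = np.arange(n_genes)
            ranks.append(r)
        ranks = np.vstack(ranks)
        best = ranks.min(axis=0)
        total = ranks.sum(axis=0)
        order = np.lexsort((np.arange(n_genes), total, best))
        n = self.n_top
        if n > n_genes:
            warnings.warn(
                f"requested {n} variable genes but only {n_genes} present; returning all"
            )
            n = n_genes
        self.ranks_ = best
        self.selected_indices_ = np.sort(order[:n])
        return self

    def transform(self, X):
        return sp.csr_matrix(X)[:, self.selected_indices_]


def select_variable_genes(
    cm: CellMatrix, n: int = 3000, span: float = 0.3
) -> list[str]:
    """Gene ids of the top-n variable genes (per-sample ranks combined)."""
    est = VariableGeneSelector(n_top=n, span=span).fit(
        cm.counts.T, sample_labels=cm.sample_of_cell
    )
    return [cm.gene_ids[i] for i in est.selected_indices_]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class ScaledPCA(TransformerMixin, BaseEstimator):
    """PCA on gene-standardized expression.

    Each gene is centred and scaled to unit variance before the
    decomposition; with ``sample_labels`` the standardization happens
    within each sample separately (the joint-embedding substitute for
    anchor-based integration).  ``explained_variance_ratio_`` is the
    per-component variance fraction over the retained components
    (non-increasing, summing to <= 1) — the spectrum the PC-cutoff
    criteria read.
    """

    def __init__(self, n_components: int = 50, random_state: int = 0):
        self.n_components = n_components
        self.random_state = random_state

    def _scale(self, X, sample_labels):
        X = np.asarray(X.todense() if sp.issparse(X) else X, dtype=float)
        out = np.empty_like(X)
        groups = (
            [np.ones(X.shape[0], bool)]
            if sample_labels is None
            else [np.asarray(sample_labels) == s for s in np.unique(sample_labels)]
        )
        for mask in groups:
            block = X[mask]
            mu = block.mean(axis=0)
            sd = block.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            out[mask] = (block - mu) / sd
        return out

    def fit(self, X, y=None, sample_labels=None):
        self.fit_transform(X, sample_labels=sample_labels)
        return self

    def fit_transform(self, X, y=None, sample_labels=None):
        scaled = self._scale(X, sample_labels)
        n_comp = self.n_components
        if n_comp > min(scaled.shape):
            raise ValueError(
                f"n_components={n_comp} exceeds min(n_cells, n_genes)={min(scaled.shape)}"
            )
        self._pca = PCA(
            n_components=n_comp, svd_solver="full", random_state=self.random_state
        )
        scores = self._pca.fit_transform(scaled)
        ev = self._pca.explained_variance_
        self.explained_variance_ratio_ = ev / ev.sum() if ev.sum() > 0 else ev
        self.components_ = self._pca.components_
        self.scores_ = scores
        return scores


def run_pca(
    norm: NormalizedMatrix,
    genes: Sequence[str],
    n_components: int = 50,
    per_sample_scaling: bool = True,
    random_state: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """PCA scores and variance fractions on the selected genes.

    Returns ``(scores, fractions)`` with scores cells x components.
    """
    sub = norm.subset_genes(genes)
    est = ScaledPCA(n_components=n_components, random_state=random_state)
    scores = est.fit_transform(
        sub.values.T, sample_labels=sub.sample_of_cell if per_sample_scaling else None
    )
    return scores, est.explained_variance_ratio_


def select_pc_cutoff(
    fractions,
    cum_threshold: float = 0.90,
    indiv_threshold: float = 0.05,
    delta_threshold: float = 0.001,
) -> int:
    """Optimal PC count from a variance-explained spectrum.

    Primary rule: the smallest j whose cumulative variance exceeds
    ``cum_threshold`` while the next component explains less than
    ``indiv_threshold`` (the component after the last counts as 0).
    Fallback when no j qualifies: the smallest j where the drop between
    consecutive fractions falls below ``delta_threshold`` (the point where
    the variance decrease stabilizes); otherwise all components.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.size == 0:
        raise ValueError("empty variance spectrum")
    n = len(fractions)
    cum = np.cumsum(fractions)
    for j in range(1, n + 1):
        nxt = fractions[j] if j < n else 0.0
        if cum[j - 1] > cum_threshold and nxt < indiv_threshold:
            return j
    for j in range(1, n):
        if fractions[j - 1] - fractions[j] < delta_threshold:
            return j
    return n
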