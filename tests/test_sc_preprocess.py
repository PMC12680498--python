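import warnings

import numpy as np
import pytest
import scipy.sparse as sp

from vitiscfb.records import CellMatrix
from vitiscfb.sc.preprocess import (
    EmptyResultError,
    log_normalize,
    qc_filter,
    run_pca,
    select_pc_cutoff,
    select_variable_genes,
)


def make_cm(counts, samples=None):
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    return CellMatrix(
        sp.csr_matrix(counts),
        [f"g{i}" for i in range(n_genes)],
        [f"c{i}" for i in range(n_cells)],
        samples or ["A"] * n_cells,
    )


class TestQC:
    def test_boundary_cells(self):
        n_genes = 300
        cols = []
        # 200 detected genes, 14 999 UMIs -> kept
        keep = np.zeros(n_genes, int); keep[:200] = 1; keep[0] = 14_800
        # 15 000 UMIs -> removed (strict "fewer than")
        umi = keep.copy(); umi[0] = 14_801
        # 199 detected genes -> removed
        few = np.zeros(n_genes, int); few[:199] = 1
        cm = make_cm(np.column_stack([keep, umi, few]))
        out = qc_filter(cm, min_genes=200, max_genes=7500, max_umi=15_000)
        assert out.barcodes == ["c0"]

    def test_zero_total_genes_dropped(self):
        counts = np.zeros((4, 2), int)
        counts[:3] = 5
        cm = make_cm(counts)
        out = qc_filter(cm, min_genes=1, max_genes=10, max_umi=100)
        assert out.gene_ids == ["g0", "g1", "g2"]

    def test_idempotent(self, sc_data):
        cm, _, _ = sc_data
        once = qc_filter(cm)
        twice = qc_filter(once)
        assert once.barcodes == twice.barcodes and once.gene_ids == twice.gene_ids

    def test_planted_failures_removed_others_kept(self, sc_data):
        cm_a, cm_b, truth = sc_data
        for cm in (cm_a, cm_b):
            kept = set(qc_filter(cm).barcodes)
            planted = {b for b, _ in truth.low_quality_cells if b in set(cm.barcodes)}
            assert kept == set(cm.barcodes) - planted

    def test_empty_result_error(self):
        cm = make_cm(np.ones((5, 3), int))
        with pytest.raises(EmptyResultError):
            qc_filter(cm, min_genes=100, max_genes=200, max_umi=10)


class TestLogNormalize:
    def test_formula(self):
        counts = np.zeros((100, 1), int)
        counts[:99, 0] = 1
        counts[99, 0] = 10
        counts[0, 0] = 9_892  # total exactly 10 000
        cm = make_cm(counts)
        norm = log_normalize(cm, scale=10_000)
        assert norm.values[99, 0] == pytest.approx(np.log(1 + 10), rel=1e-12)

    def test_zeros_stay_zero(self):
        cm = make_cm([[5, 0], [0, 3]])
        norm = log_normalize(cm)
        assert norm.values[0, 1] == 0 and norm.values[1, 0] == 0

    def test_monotone_within_cell(self, rng):
        counts = rng.integers(0, 20, size=(50, 5))
        counts[0] += 1  # avoid zero-total cells
        norm = log_normalize(make_cm(counts)).values.toarray()
        for c in range(5):
            order = np.argsort(counts[:, c], kind="stable")
            assert np.all(np.diff(norm[order, c]) >= -1e-12)

    def test_depth_invariance(self):
        """Doubling a cell's counts leaves normalized values unchanged."""
        base = np.array([[4, 8], [6, 12], [2, 4]])
        norm = log_normalize(make_cm(base)).values.toarray()
        assert np.allclose(norm[:, 0], norm[:, 1])


class TestVariableGenes:
    def test_identity_when_n_equals_gene_count(self, rng):
        counts = rng.poisson(2, size=(30, 40))
        cm = make_cm(counts)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert set(select_variable_genes(cm, n=30)) == set(cm.gene_ids)

    def test_constant_gene_never_beats_varying(self, rng):
        counts = rng.poisson(3, size=(20, 60))
        counts[0, :] = 5  # constant across cells
        got = select_variable_genes(make_cm(counts), n=10)
        assert "g0" not in got

    def test_planted_structure_enriched(self, sc_data):
        cm_a, cm_b, truth = sc_data
        cm = qc_filter(cm_a.concat(cm_b))
        n_sel = 150
        selected = set(select_variable_genes(cm, n=n_sel))
        special = truth.marker_genes | truth.deg_genes
        frac_selected = len(selected & special) / len(special)
        background_rate = n_sel / cm.n_genes
        assert frac_selected > 2 * background_rate


class TestPCA:
    def test_rank_one_data(self, rng):
        u = rng.normal(size=(80, 1))
        v = rng.normal(size=(1, 20))
        X = sp.csr_matrix(np.abs(u @ v))
        cm_vals = X.T.tocsr()  # genes x cells

        from vitiscfb.sc.preprocess import NormalizedMatrix

        norm = NormalizedMatrix(cm_vals, [f"g{i}" for i in range(20)],
                                [f"c{i}" for i in range(80)],
                                np.array(["A"] * 80))
        scores, fr = run_pca(norm, norm.gene_ids, n_components=5,
                             per_sample_scaling=False)
        assert fr[0] > 0.95

    def test_fractions_non_increasing_and_sum_bounded(self, rng):
        from vitiscfb.sc.preprocess import NormalizedMatrix

        vals = sp.csr_matrix(rng.normal(size=(30, 100)))
        norm = NormalizedMatrix(vals, [f"g{i}" for i in range(30)],
                                [f"c{i}" for i in range(100)],
                                np.array(["A"] * 100))
        scores, fr = run_pca(norm, norm.gene_ids, n_components=10,
                             per_sample_scaling=False)
        assert np.all(np.diff(fr) <= 1e-12)
        assert fr.sum() <= 1 + 1e-9

    def test_scores_orthogonal(self, rng):
        from vitiscfb.sc.preprocess import NormalizedMatrix

        vals = sp.csr_matrix(np.abs(rng.normal(size=(40, 120))))
        norm = NormalizedMatrix(vals, [f"g{i}" for i in range(40)],
                                [f"c{i}" for i in range(120)],
                                np.array(["A"] * 120))
        scores, _ = run_pca(norm, norm.gene_ids, n_components=8,
                            per_sample_scaling=False)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()

    def test_too_many_components_error(self, rng):
        from vitiscfb.sc.preprocess import NormalizedMatrix

        vals = sp.csr_matrix(rng.normal(size=(5, 10)))
        norm = NormalizedMatrix(vals, [f"g{i}" for i in range(5)],
                                [f"c{i}" for i in range(10)],
                                np.array(["A"] * 10))
        with pytest.raises(ValueError):
            run_pca(norm, norm.gene_ids, n_components=50)


class TestPCCutoff:
    def test_worked_spectrum(self):
        assert select_pc_cutoff([0.50, 0.25, 0.16, 0.04, 0.03, 0.02]) == 3

    def test_flat_spectrum_takes_all(self):
        assert select_pc_cutoff([0.10] * 10) == 10

    def test_single_component(self):
        assert select_pc_cutoff([1.0]) == 1

    def test_empty_error(self):
        with pytest.raises(ValueError):
            select_pc_cutoff([])

    def test_exhaustive_scan_oracle(self, rng):
        """The closed-form rule matches a literal scan of the criteria."""

        def oracle(fr, cum_t=0.90, ind_t=0.05, d_t=0.001):
            n = len(fr)
            for j in range(1, n + 1):
                cum = sum(fr[:j])
                nxt = fr[j] if j < n else 0.0
                if cum > cum_t and nxt < ind_t:
                    return j
            for j in range(1, n):
                if fr[j - 1] - fr[j] < d_t:
                    return j
            return n

        for _ in range(100):
            n = int(rng.integers(1, 60))
            raw = np.sort(rng.random(n))[::-1]
            fr = raw / raw.sum() * rng.uniform(0.3, 1.0)
            assert select_pc_cutoff(fr) == oracle(list(fr))
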