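import warnings

import numpy as np
import pytest

from vitiscfb.integrate import spearman_matrix, tpm_normalize
from vitiscfb.pangenome import find_unique_svs
from vitiscfb.simulate import (
    simulate_bulk_stages,
    simulate_pangenome_vcf,
    simulate_reference,
    simulate_single_cell,
    simulate_sv_calls,
)


class TestReference:
    def test_forced_dimensions(self, reference):
        assert len(reference.sequences) == 2
        assert all(len(s) == 100_000 for s in reference.sequences.values())
        assert len(reference.genes) == 50
        assert len({g.id for g in reference.genes}) == 50

    def test_same_seed_identical(self, tmp_path):
        a = simulate_reference(seed=5, out_dir=tmp_path / "a")
        b = simulate_reference(seed=5, out_dir=tmp_path / "b")
        assert a.sequences == b.sequences and a.genes == b.genes
        assert (tmp_path / "a" / "reference.fa").read_text() == (
            tmp_path / "b" / "reference.fa").read_text()

    def test_genes_pairwise_non_overlapping(self, reference):
        for chrom in reference.sequences:
            genes = [g for g in reference.genes if g.chrom == chrom]
            for i, a in enumerate(genes):
                for b in genes[i + 1:]:
                    assert a.end < b.start or b.end < a.start

    def test_infeasible_packing_error(self):
        with pytest.raises(ValueError):
            simulate_reference(n_chroms=1, chrom_len=5000, n_genes=50, seed=0)


class TestPanel:
    def test_truth_structure(self, panel):
        records, truth = panel
        assert len(truth.planted) == 8
        assert all(len(v) == 5 for v in truth.decoys.values())
        decoy_ids = {i for ids in truth.decoys.values() for i in ids}
        assert truth.planted_ids.isdisjoint(decoy_ids)
        ids_in_file = {r.id for r in records}
        assert truth.planted_ids <= ids_in_file and decoy_ids <= ids_in_file

    def test_records_position_sorted(self, panel):
        records, _ = panel
        keys = [(r.chrom, r.pos) for r in records]
        by_chrom = {}
        for c, p in keys:
            by_chrom.setdefault(c, []).append(p)
        for pos_list in by_chrom.values():
            assert pos_list == sorted(pos_list)

    def test_planted_records_satisfy_uniqueness_invariants(self, panel):
        records, truth = panel
        by_id = {r.id: r for r in records}
        for rid, direction in truth.planted:
            r = by_id[rid]
            assert set(r.genotypes) == {"1|1"}
            delta = max(abs(len(r.ref) - len(a)) for a in r.alts)
            assert delta >= 50
            if direction == "insertion":
                assert len(r.ref) > max(len(a) for a in r.alts)

    def test_forced_direction_split(self, reference):
        directions = ["insertion"] * 5 + ["deletion"] * 3
        _, truth = simulate_pangenome_vcf(
            reference, n_haplotype_samples=4, n_planted_unique=8,
            n_decoys_per_category=2, seed=3, planted_directions=directions,
        )
        assert [d for _, d in truth.planted] == directions

    def test_no_planted_means_no_unique_calls(self, reference):
        records, _ = simulate_pangenome_vcf(
            reference, n_haplotype_samples=4, n_planted_unique=0,
            n_decoys_per_category=3, seed=2,
        )
        assert find_unique_svs(records) == []

    def test_caller_recovers_exactly_the_planted_set(self, panel):
        records, truth = panel
        svs = find_unique_svs(records)
        assert {u.record.id for u in svs} == truth.planted_ids
        directions = dict(truth.planted)
        assert all(u.direction == directions[u.record.id] for u in svs)


class TestSVCalls:
    def test_forced_counts(self, sv_calls):
        calls, truth = sv_calls
        assert len(calls) == 16 and len(truth) == 10
        assert all(c.svtype == "DEL" for c in calls)

    def test_each_decoy_category_present(self, sv_calls):
        calls, _ = sv_calls
        cats = {c.id.split("_")[1] for c in calls if c.id.startswith("decoy")}
        assert cats == {"qual", "support", "imprecise", "length", "no", "partial"}


class TestSingleCell:
    def test_truth_and_matrix_consistent(self, sc_data):
        cm_a, cm_b, truth = sc_data
        assert cm_a.gene_ids == cm_b.gene_ids
        barcodes = set(cm_a.barcodes) | set(cm_b.barcodes)
        assert set(truth.cell_type_of_cell) <= barcodes
        assert {b for b, _ in truth.low_quality_cells} <= barcodes
        assert truth.deg_genes.isdisjoint(truth.marker_genes)
        assert truth.deg_genes <= set(cm_a.gene_ids)

    def test_deterministic_under_seed(self):
        kw = dict(n_genes=200, cells_per_sample=40, n_types=2, seed=9)
        a1, b1, _ = simulate_single_cell(**kw)
        a2, b2, _ = simulate_single_cell(**kw)
        assert (a1.counts != a2.counts).nnz == 0
        assert (b1.counts != b2.counts).nnz == 0

    def test_bad_cells_break_exactly_one_bound(self, sc_data):
        cm_a, cm_b, truth = sc_data
        both = cm_a.concat(cm_b)
        genes = dict(zip(both.barcodes, both.genes_per_cell()))
        umis = dict(zip(both.barcodes, both.umis_per_cell()))
        for bc, kind in truth.low_quality_cells:
            violations = {
                "min_genes": genes[bc] < 200,
                "max_genes": genes[bc] > 7500,
                "max_umi": umis[bc] >= 15_000,
            }
            assert violations.pop(kind)
            assert not any(violations.values())

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            simulate_single_cell(n_types=1)
        with pytest.raises(ValueError):
            simulate_single_cell(n_genes=50, n_degs=60)
        with pytest.raises(ValueError):
            simulate_single_cell(effect_log2fc=0)


class TestBulk:
    def test_noise_free_pair_correlates_exactly_after_tpm(self, reference):
        counts, lengths, truth = simulate_bulk_stages(
            reference.genes, n_stages=8, n_corr_pairs=4, noise_sd=0.0, seed=3)
        tpm = tpm_normalize(counts, lengths)
        for a, b in truth.correlated_pairs:
            rho = spearman_matrix(tpm.loc[[a, b]]).iloc[0, 1]
            assert rho == pytest.approx(1.0, abs=1e-12)

    def test_independent_genes_weakly_correlated(self, reference, rng):
        counts, lengths, truth = simulate_bulk_stages(
            reference.genes, n_stages=8, n_corr_pairs=0, noise_sd=0.1, seed=4)
        tpm = tpm_normalize(counts, lengths)
        genes = list(tpm.index)
        rhos = []
        for _ in range(60):
            a, b = rng.choice(len(genes), size=2, replace=False)
            rhos.append(abs(spearman_matrix(tpm.iloc[[a, b]]).iloc[0, 1]))
        assert np.mean(rhos) < 0.5

    def test_stage_labels_and_reproducibility(self, reference):
        c1, l1, t1 = simulate_bulk_stages(reference.genes, seed=5)
        c2, _, _ = simulate_bulk_stages(reference.genes, seed=5)
        assert t1.stage_labels == ["F1", "F2", "F3", "F4", "F5", "F6", "L", "B"]
        assert c1.equals(c2)

    def test_min_stage_validation(self, reference):
        with pytest.raises(ValueError):
            simulate_bulk_stages(reference.genes, n_stages=3)
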