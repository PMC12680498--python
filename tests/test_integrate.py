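import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata

from vitiscfb.integrate import (
    filter_zero_rows,
    hierarchical_order,
    intersect_candidates,
    spearman_matrix,
    tpm_normalize,
)


class TestIntersect:
    def test_disjoint_empty(self):
        assert intersect_candidates({"a"}, {"b"}) == []

    def test_basic_overlap_sorted(self):
        cands = intersect_candidates({"a", "b", "c"}, {"b", "c", "d"})
        assert [c.gene_id for c in cands] == ["b", "c"]

    def test_commutative(self):
        a, b = {"x", "y", "z"}, {"y", "q"}
        ab = {c.gene_id for c in intersect_candidates(a, b)}
        ba = {c.gene_id for c in intersect_candidates(b, a)}
        assert ab == ba

    def test_annotation_tracks_attached(self):
        links = pd.DataFrame({"sv_id": ["s1", "s2"], "gene_id": ["b", "b"],
                              "distance": [0, 1200], "relation": ["overlapping", "upstream"]})
        degs = pd.DataFrame({"gene": ["b"], "cluster": [3],
                             "direction": ["up_in_JA"], "avg_log2FC": [1.5]})
        (cand,) = intersect_candidates({"a", "b"}, {"b"}, links=links, deg_table=degs)
        assert cand.sv_ids == ["s1", "s2"] and cand.sv_distances == [0, 1200]
        assert cand.deg_clusters == [3] and cand.deg_directions == ["up_in_JA"]


class TestTPM:
    def test_equal_counts_equal_lengths(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["a", "b"])
        lengths = pd.Series([500, 500], index=["a", "b"])
        tpm = tpm_normalize(counts, lengths)
        assert np.allclose(tpm["s1"], [500_000, 500_000])

    def test_length_scaling(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["a", "b"])
        tpm1 = tpm_normalize(counts, pd.Series([1000, 1000], index=["a", "b"]))
        tpm2 = tpm_normalize(counts, pd.Series([2000, 1000], index=["a", "b"]))
        # doubling a's length halves its rpk share: 1/3 vs 2/3
        assert tpm2.loc["a", "s1"] == pytest.approx(tpm1.loc["a", "s1"] * (1 / 3) / 0.5)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_columns_sum_to_one_million(self, seed):
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(20, 5)),
            index=[f"g{i}" for i in range(20)],
        )
        counts.iloc[0] += 1  # keep every sample non-empty
        lengths = pd.Series(rng.integers(200, 5000, size=20),
                            index=counts.index)
        tpm = tpm_normalize(counts, lengths)
        assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-9)

    def test_scale_invariance_per_sample(self, rng):
        counts = pd.DataFrame(rng.integers(1, 100, size=(15, 3)),
                              index=[f"g{i}" for i in range(15)])
        lengths = pd.Series(rng.integers(300, 3000, size=15), index=counts.index)
        scaled = counts.copy()
        scaled.iloc[:, 1] *= 7
        assert np.allclose(tpm_normalize(counts, lengths),
                           tpm_normalize(scaled, lengths))

    def test_zero_sample_error(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            tpm_normalize(counts, pd.Series([100, 100], index=["a", "b"]))


class TestZeroRows:
    def test_policies(self):
        table = pd.DataFrame([[0, 5, 7], [1, 2, 3], [0, 0, 0]],
                             index=["mixed", "pos", "allzero"])
        assert list(filter_zero_rows(table, "any_zero").index) == ["pos"]
        assert list(filter_zero_rows(table, "all_zero").index) == ["mixed", "pos"]

    def test_matches_brute_force_count(self, rng):
        table = pd.DataFrame(rng.integers(0, 3, size=(50, 6)),
                             index=[f"g{i}" for i in range(50)]).astype(float)
        table.iloc[0] = 1.0  # guarantee a survivor
        kept = filter_zero_rows(table, "any_zero")
        expected = sum(1 for _, row in table.iterrows() if (row > 0).all())
        assert len(kept) == expected

    def test_everything_removed_error(self):
        table = pd.DataFrame([[0, 1], [1, 0]], index=["a", "b"])
        with pytest.raises(ValueError):
            filter_zero_rows(table, "any_zero")


class TestSpearman:
    def test_monotone_pairs(self):
        table = pd.DataFrame(
            [[1, 2, 3, 4], [10, 20, 30, 40], [8, 6, 4, 2]],
            index=["up1", "up2", "down"], dtype=float)
        corr = spearman_matrix(table)
        assert corr.loc["up1", "up2"] == pytest.approx(1.0)
        assert corr.loc["up1", "down"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T)

    def test_monotone_transform_invariance(self, rng):
        x = rng.random(8) * 10
        y = rng.random(8) * 10
        table = pd.DataFrame([x, y], index=["a", "b"])
        transformed = pd.DataFrame([np.exp(x / 3), y], index=["a", "b"])
        assert spearman_matrix(table).loc["a", "b"] == pytest.approx(
            spearman_matrix(transformed).loc["a", "b"])

    def test_tie_handling_matches_rank_then_pearson_oracle(self, rng):
        for _ in range(50):
            table = pd.DataFrame(rng.integers(0, 5, size=(2, 8)),
                                 index=["a", "b"], dtype=float)
            if table.std(axis=1).min() == 0:
                continue
            got = spearman_matrix(table).loc["a", "b"]
            ra, rb = rankdata(table.loc["a"]), rankdata(table.loc["b"])
            oracle = np.corrcoef(ra, rb)[0, 1]
            assert got == pytest.approx(oracle, abs=1e-12)

    def test_constant_profile_is_nan_with_warning(self):
        table = pd.DataFrame([[1, 1, 1, 1], [1, 2, 3, 4]], index=["flat", "up"],
                             dtype=float)
        with pytest.warns(UserWarning, match="constant"):
            corr = spearman_matrix(table)
        assert np.isnan(corr.loc["flat", "up"])
        assert corr.loc["flat", "flat"] == 1.0

    def test_positive_semidefinite(self, rng):
        table = pd.DataFrame(rng.random((8, 10)),
                             index=[f"g{i}" for i in range(8)])
        corr = spearman_matrix(table)
        eigvals = np.linalg.eigvalsh(corr.to_numpy())
        assert eigvals.min() > -1e-10

    def test_too_few_samples_error(self):
        table = pd.DataFrame([[1, 2], [2, 1]], index=["a", "b"])
        with pytest.raises(ValueError):
            spearman_matrix(table)


class TestHierarchicalOrder:
    def test_correlated_pairs_adjacent(self):
        s = np.arange(6, dtype=float)
        table = pd.DataFrame(
            [s, s * 2 + 0.1, -s, -s * 3 + 0.2, np.array([3, 1, 4, 1, 5, 9.0])],
            index=["a1", "a2", "b1", "b2", "lone"])
        corr = spearman_matrix(table)
        order = hierarchical_order(corr)
        pos = {g: i for i, g in enumerate(order)}
        assert abs(pos["a1"] - pos["a2"]) == 1
        assert abs(pos["b1"] - pos["b2"]) == 1

    def test_single_gene_identity(self):
        corr = pd.DataFrame([[1.0]], index=["a"], columns=["a"])
        assert hierarchical_order(corr) == ["a"]

    def test_input_order_invariance_of_adjacency(self, rng):
        s = np.arange(8, dtype=float)
        profiles = {"a1": s, "a2": s * 1.5, "b1": -s, "b2": -s * 2,
                    "n1": rng.random(8), "n2": rng.random(8)}
        names = list(profiles)
        corr1 = spearman_matrix(pd.DataFrame([profiles[n] for n in names], index=names))
        shuffled = names[::-1]
        corr2 = spearman_matrix(pd.DataFrame([profiles[n] for n in shuffled],
                                             index=shuffled))
        o1, o2 = hierarchical_order(corr1), hierarchical_order(corr2)

        def adjacent_pairs(order):
            return {frozenset(p) for p in zip(order, order[1:])}

        # the planted pairs sit together regardless of input ordering
        for pair in ({"a1", "a2"}, {"b1", "b2"}):
            assert frozenset(pair) in adjacent_pairs(o1)
            assert frozenset(pair) in adjacent_pairs(o2)
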