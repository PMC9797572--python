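"""Matrix assembly, clustering, imputation, NODF and Barber modularity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from oracles import nodf_oracle

from phagecoev import infection_network as net


class TestAssemble:
    def test_full_cross_entry_count(self):
        scores = pd.DataFrame(
            [(f"P{i}", f"B{j}", 0.5) for i in range(116) for j in range(97)],
            columns=["phage_id", "bacterium_id", "infectivity"],
        )
        M = net.assemble_matrix(scores)
        assert M.shape == (116, 97)
        assert M.size == 11_252
        assert M.notna().all().all()

    def test_unmeasured_pair_missing(self):
        scores = pd.DataFrame(
            {"phage_id": ["P1", "P1", "P2"], "bacterium_id": ["B1", "B2", "B1"],
             "infectivity": [0.1, 0.2, 0.3]}
        )
        M = net.assemble_matrix(scores)
        assert np.isnan(M.loc["P2", "B2"])

    def test_duplicates_averaged_across_plates(self):
        scores = pd.DataFrame(
            {"phage_id": ["P1", "P1"], "bacterium_id": ["B1", "B1"],
             "infectivity": [0.2, 0.4], "plate_id": ["a", "b"]}
        )
        assert net.assemble_matrix(scores).loc["P1", "B1"] == pytest.approx(0.3)

    def test_same_plate_duplicate_rejected(self):
        scores = pd.DataFrame(
            {"phage_id": ["P1", "P1"], "bacterium_id": ["B1", "B1"],
             "infectivity": [0.2, 0.4], "plate_id": ["a", "a"]}
        )
        with pytest.raises(ValueError):
            net.assemble_matrix(scores)


class TestConcordance:
    def test_identical_and_affine_profiles(self):
        base = np.array([0.1, 0.5, 0.9, 0.3, 0.7])
        M = pd.DataFrame([base, base, 0.5 * base + 0.2],
                         index=["wt1", "wt2", "wt3"],
                         columns=list("abcde"))
        r2 = net.concordance_r2(M, ["wt1", "wt2", "wt3"])
        assert np.allclose(r2["r2"], 1.0)

    def test_zero_covariance_profiles(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        M = pd.DataFrame([a, b], index=["wt1", "wt2"], columns=list("abcd"))
        r2 = net.concordance_r2(M, ["wt1", "wt2"])
        assert r2["r2"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_shared_observations(self):
        M = pd.DataFrame([[0.1, np.nan, 0.2], [0.3, 0.4, np.nan]],
                         index=["wt1", "wt2"], columns=list("abc"))
        with pytest.raises(ValueError):
            net.concordance_r2(M, ["wt1", "wt2"])


class TestClustering:
    def test_identical_profiles_one_class(self):
        M = pd.DataFrame(np.ones((4, 3)), index=list("wxyz"))
        ca = net.cluster_isolates(M)
        assert ca.labels.nunique() == 1

    def test_two_tight_blocks_two_classes(self):
        rng = np.random.default_rng(0)
        block1 = rng.uniform(0, 0.05, size=(4, 6))
        block2 = block1 + 10.0
        M = pd.DataFrame(np.vstack([block1, block2]),
                         index=[f"i{k}" for k in range(8)])
        ca = net.cluster_isolates(M)
        assert ca.labels.nunique() == 2
        assert ca.labels.iloc[:4].nunique() == 1
        assert ca.labels.iloc[4:].nunique() == 1

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        M = pd.DataFrame(rng.uniform(0, 1, size=(10, 6)),
                         index=[f"i{k}" for k in range(10)])
        ca1 = net.cluster_isolates(M)
        perm = rng.permutation(10)
        ca2 = net.cluster_isolates(M.iloc[perm])
        # same partition: co-membership must agree for every pair
        for a in M.index:
            for b in M.index:
                assert (ca1.labels[a] == ca1.labels[b]) == (
                    ca2.labels[a] == ca2.labels[b]
                )

    def test_newick_export_parses(self):
        from io import StringIO

        from Bio import Phylo

        M = pd.DataFrame(np.random.default_rng(2).uniform(size=(5, 4)),
                         index=list("abcde"))
        ca = net.cluster_isolates(M)
        tree = Phylo.read(StringIO(net.linkage_to_newick(ca.linkage, list(M.index))),
                          "newick")
        assert sorted(t.name for t in tree.get_terminals()) == list("abcde")


class TestImputation:
    def test_uniform_neighbourhood(self):
        X = np.full((5, 5), 0.5)
        X[2, 2] = np.nan
        out = net.impute_missing(pd.DataFrame(X))
        assert out.iloc[2, 2] == 0.5

    def test_corner_truncated_window(self):
        X = np.full((6, 6), np.nan)
        X[:3, :3] = 0.25
        X[3:, :] = 0.9
        X[:3, 3:] = 0.9
        X[0, 0] = np.nan  # corner cell: 8 in-bounds neighbours, mean 0.25
        out = net.impute_missing(pd.DataFrame(X))
        assert out.iloc[0, 0] == pytest.approx(0.25)

    def test_present_values_untouched(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, size=(8, 8))
        mask = rng.random((8, 8)) < 0.15
        Xm = X.copy()
        Xm[mask] = np.nan
        out = net.impute_missing(pd.DataFrame(Xm)).to_numpy()
        assert np.allclose(out[~mask], X[~mask])
        assert ((out >= 0) & (out <= 1)).all()

    def test_empty_neighbourhood_rejected(self):
        X = np.full((9, 9), np.nan)
        X[0, 0] = 0.5
        with pytest.raises(ValueError):
            net.impute_missing(pd.DataFrame(X))

    def test_complete_matrix_unchanged(self):
        X = np.random.default_rng(4).uniform(size=(4, 4))
        out = net.impute_missing(pd.DataFrame(X))
        assert np.array_equal(out.to_numpy(), X)


class TestBinarize:
    def test_strict_threshold(self):
        M = np.array([[0.0, 0.3], [0.5, 1.0]])
        assert np.array_equal(net.binarize(M), [[0, 1], [1, 1]])
        assert np.array_equal(net.binarize(M, 0.5), [[0, 0], [0, 1]])


class TestNodf:
    def test_perfectly_nested_triangle(self):
        assert net.nodf([[1, 1, 1], [1, 1, 0], [1, 0, 0]]) == 1.0

    def test_equal_marginals_contribute_zero(self):
        assert net.nodf(np.ones((3, 3))) == 0.0
        assert net.nodf([[1, 0], [0, 1]]) == 0.0

    def test_degenerate_after_removal_rejected(self):
        with pytest.raises(ValueError):
            net.nodf([[1, 0], [0, 0]])

    @given(
        A=hnp.arrays(np.int8, (5, 6), elements=st.integers(0, 1)),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=60, deadline=None)
    def test_permutation_invariance_and_oracle(self, A, seed):
        A = np.asarray(A, int)
        B = A[A.sum(1) > 0][:, A.sum(0) > 0]
        if B.shape[0] < 2 or B.shape[1] < 2:
            return
        assert net.nodf(A) == pytest.approx(nodf_oracle(A))
        rng = np.random.default_rng(seed)
        P = A[rng.permutation(A.shape[0])][:, rng.permutation(A.shape[1])]
        assert net.nodf(P) == pytest.approx(net.nodf(A))


class TestModularity:
    def test_two_block_matrix(self):
        A = np.zeros((4, 4), int)
        A[:2, :2] = 1
        A[2:, 2:] = 1
        res = net.modularity(A, seed=0)
        assert res.q == pytest.approx(0.5)
        assert res.row_labels[0] == res.row_labels[1] == res.col_labels[0]
        assert res.row_labels[2] == res.row_labels[3] == res.col_labels[2]
        assert res.row_labels[0] != res.row_labels[2]

    def test_complete_bipartite_is_unstructured(self):
        assert net.modularity(np.ones((3, 3), int)).q == pytest.approx(0.0)

    def test_never_below_single_module_value(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            A = (rng.random((5, 7)) < 0.4).astype(int)
            if A.sum() == 0:
                continue
            assert net.modularity(A, seed=1).q >= 0.0

    def test_no_edges_rejected(self):
        with pytest.raises(ValueError):
            net.modularity(np.zeros((3, 3), int))

    def test_seed_determinism(self):
        A = (np.random.default_rng(6).random((6, 6)) < 0.5).astype(int)
        a = net.modularity(A, seed=3)
        b = net.modularity(A, seed=3)
        assert a.q == b.q
        assert np.array_equal(a.row_labels, b.row_labels)


class TestEquiprobableNull:
    def test_low_statistic_gives_high_p(self):
        # checkerboard has NODF 0: no null draw scores below it
        A = np.array([[1, 0], [0, 1]] * 3)
        res = net.equiprobable_null(A, "nodf", n=200, seed=0)
        assert res.p_value > 0.9

    def test_nested_matrix_significant(self):
        A = np.tril(np.ones((8, 8), int))
        res = net.equiprobable_null(A, "nodf", n=500, seed=0)
        assert res.p_value < 0.05

    def test_seed_determinism(self):
        A = (np.random.default_rng(7).random((8, 8)) < 0.4).astype(int)
        a = net.equiprobable_null(A, "nodf", n=300, seed=9)
        b = net.equiprobable_null(A, "nodf", n=300, seed=9)
        assert a.p_value == b.p_value

    def test_degenerate_fill_rejected(self):
        with pytest.raises(ValueError):
            net.equiprobable_null(np.ones((3, 3), int), "nodf")

    def test_modularity_statistic_runs(self):
        A = np.zeros((4, 4), int)
        A[:2, :2] = 1
        A[2:, 2:] = 1
        res = net.equiprobable_null(A, "modularity", n=100, seed=1)
        assert res.observed == pytest.approx(0.5)
        assert 0 < res.p_value <= 1
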