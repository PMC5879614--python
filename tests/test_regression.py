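import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from curategap.errors import ConfigurationError, CurategapError
from curategap.regression import (
    NUMERIC_FEATURES,
    EncodingSpec,
    compute_metrics,
    encode,
    fit_ridge,
    permutation_importance,
    predict,
    stratified_split,
)

from conftest import make_gene


class TestEncode:
    def test_column_layout(self):
        table = [make_gene(i, symbol=f"s{i}") for i in range(1, 4)]
        X, y, spec = encode(table)
        # 4 numeric + 3 symbol indicators + 1 unknown bucket
        assert X.shape == (3, 8)
        assert spec.numeric_features == NUMERIC_FEATURES
        assert list(y) == [g.y for g in table]
        dense = X.toarray()
        # each row sets exactly one indicator, none in the unknown bucket
        assert dense[:, 4:].sum(axis=1).tolist() == [1, 1, 1]
        assert dense[:, -1].sum() == 0

    def test_unknown_symbol_maps_to_bucket(self):
        train = [make_gene(1, symbol="a"), make_gene(2, symbol="b")]
        _, _, spec = encode(train)
        X, _, _ = encode([make_gene(3, symbol="zzz")], spec)
        dense = X.toarray()
        assert dense[0, spec.unknown_column] == 1.0

    def test_row_permutation_equivariance(self):
        table = [make_gene(i, symbol=f"s{i}") for i in range(1, 6)]
        _, _, spec = encode(table)
        X1, y1, _ = encode(table, spec)
        perm = [3, 1, 4, 0, 2]
        X2, y2, _ = encode([table[i] for i in perm], spec)
        assert np.array_equal(X1.toarray()[perm], X2.toarray())
        assert np.array_equal(y1[perm], y2)

    def test_empty_table_rejected(self):
        with pytest.raises(CurategapError):
            encode([])

    def test_numeric_values_in_order(self):
        gene = make_gene(1, expr_pub_count=3, total_journal_pub_count=6,
                         percent_expr_pubs=0.5, construct_count=2)
        X, _, _ = encode([gene])
        assert X.toarray()[0, :4].tolist() == [3.0, 6.0, 0.5, 2.0]


class TestStratifiedSplit:
    def make_table(self, n):
        return [make_gene(i, y=i % 17) for i in range(1, n + 1)]

    def test_disjoint_exhaustive_and_sized(self):
        table = self.make_table(100)
        split = stratified_split(table, train_fraction=0.25, n_bins=10, seed=3)
        train, test = set(split.train_gene_ids), set(split.test_gene_ids)
        assert not train & test
        assert train | test == {g.gene_id for g in table}
        # brute-force recount: per-bin rounding keeps the total near 25
        assert abs(len(train) - 25) <= 10  # at most 1 gene per bin of slack

    def test_per_bin_proportions(self):
        table = self.make_table(200)
        split = stratified_split(table, train_fraction=0.25, n_bins=5, seed=0)
        y_by_id = {g.gene_id: g.y for g in table}
        # recompute the bins exactly as documented and recount
        y = np.array([g.y for g in table], dtype=float)
        edges = np.unique(np.quantile(y, np.linspace(0, 1, 6)[1:-1]))
        def bin_of(value):
            return int(np.searchsorted(edges, value, side="right"))
        from collections import Counter
        totals = Counter(bin_of(g.y) for g in table)
        trains = Counter(bin_of(y_by_id[g]) for g in split.train_gene_ids)
        for b, total in totals.items():
            assert abs(trains[b] - 0.25 * total) <= 0.5 + 1e-9

    def test_determinism(self):
        table = self.make_table(60)
        first = stratified_split(table, 0.3, 4, seed=9)
        second = stratified_split(table, 0.3, 4, seed=9)
        assert first == second
        third = stratified_split(table, 0.3, 4, seed=10)
        assert third != first

    def test_single_bin_is_simple_random_split(self):
        table = self.make_table(40)
        split = stratified_split(table, 0.5, 1, seed=1)
        assert len(split.train_gene_ids) == 20

    def test_fewer_genes_than_bins_warns_and_collapses(self):
        table = self.make_table(3)
        with pytest.warns(UserWarning, match="collapsing"):
            split = stratified_split(table, 0.5, 10, seed=1)
        assert len(split.train_gene_ids) + len(split.test_gene_ids) == 3

    def test_bad_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            stratified_split(self.make_table(10), train_fraction=1.0)


class TestFitRidge:
    def test_hand_computed_single_feature(self):
        # w = sum(xy) / (sum(x^2) + lambda) = 5 / (5 + 5)
        X = np.array([[1.0], [2.0]])
        y = np.array([1.0, 2.0])
        model = fit_ridge(X, y, l2_weight=5.0)
        assert model.weights[0] == pytest.approx(0.5)

    def test_noiseless_proportionality_at_zero_penalty(self):
        X = np.array([[1.0], [2.0], [3.0]])
        model = fit_ridge(X, 2.0 * X.ravel(), l2_weight=0.0)
        assert model.weights[0] == pytest.approx(2.0)

    def test_matches_reference_solver(self):
        # independent oracle: scikit-learn's ridge with the same
        # unscaled-penalty convention
        from sklearn.linear_model import Ridge

        rng = np.random.default_rng(42)
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        model = fit_ridge(X, y, l2_weight=10.0)
        reference = Ridge(alpha=10.0, fit_intercept=False).fit(X, y)
        np.testing.assert_allclose(model.weights, reference.coef_, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_random_systems(self, seed):
        from sklearn.linear_model import Ridge

        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 51))
        p = int(rng.integers(1, 11))
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        lam = float(rng.uniform(0.1, 20))
        model = fit_ridge(X, y, l2_weight=lam)
        reference = Ridge(alpha=lam, fit_intercept=False, solver="cholesky")
        reference.fit(X, y)
        np.testing.assert_allclose(model.weights, reference.coef_, atol=1e-8)

    def test_sparse_and_dense_agree(self):
        import scipy.sparse as sp

        rng = np.random.default_rng(0)
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        dense = fit_ridge(X, y, l2_weight=3.0)
        sparse = fit_ridge(sp.csr_matrix(X), y, l2_weight=3.0)
        np.testing.assert_allclose(dense.weights, sparse.weights, atol=1e-10)

    def test_zero_penalty_limit_equals_ols(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        model = fit_ridge(X, y, l2_weight=1e-10)
        np.testing.assert_allclose(model.weights, ols, atol=1e-6)

    def test_monotone_shrinkage(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 4))
        y = rng.normal(size=25)
        norms = [
            np.linalg.norm(fit_ridge(X, y, l2_weight=lam).weights)
            for lam in (0.0, 1.0, 10.0, 100.0)
        ]
        assert norms == sorted(norms, reverse=True)

    def test_singular_zero_penalty_raises_helpfully(self):
        X = np.array([[1.0, 1.0], [2.0, 2.0]])  # rank 1
        with pytest.raises(CurategapError, match="l2_weight > 0"):
            fit_ridge(X, np.array([1.0, 2.0]), l2_weight=0.0)

    def test_intercept_not_penalized(self):
        # y = x + 100: huge unpenalized intercept must be recovered
        X = np.arange(1.0, 21.0)[:, None]
        y = X.ravel() + 100.0
        model = fit_ridge(X, y, l2_weight=1e-8, include_intercept=True)
        assert model.intercept == pytest.approx(100.0, abs=1e-4)
        assert model.weights[0] == pytest.approx(1.0, abs=1e-6)


class TestPredict:
    def test_zero_weights_give_zero(self):
        model = fit_ridge(np.eye(3), np.zeros(3), l2_weight=1.0)
        np.testing.assert_array_equal(predict(model, np.eye(3)), np.zeros(3))

    def test_from_fit_example(self):
        model = fit_ridge(np.array([[1.0], [2.0]]), np.array([1.0, 2.0]),
                          l2_weight=5.0)
        np.testing.assert_allclose(
            predict(model, np.array([[1.0], [2.0]])), [0.5, 1.0]
        )

    def test_interpolation_at_zero_penalty(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        y = rng.normal(size=4)
        model = fit_ridge(X, y, l2_weight=0.0)
        np.testing.assert_allclose(predict(model, X), y, atol=1e-8)

    def test_width_mismatch_rejected(self):
        model = fit_ridge(np.eye(3), np.ones(3), l2_weight=1.0)
        with pytest.raises(CurategapError, match="columns"):
            predict(model, np.ones((2, 2)))


class TestComputeMetrics:
    def test_hand_computed_example(self):
        m = compute_metrics([1, 2, 3], [1, 3, 5])
        assert m.mae == pytest.approx(1.0)
        assert m.rmse == pytest.approx(np.sqrt(5 / 3))
        assert m.rae == pytest.approx(1.5)
        assert m.rse == pytest.approx(2.5)
        assert m.r2 == pytest.approx(-1.5)

    def test_perfect_fit(self):
        m = compute_metrics([1, 2, 3], [1, 2, 3])
        assert (m.mae, m.rmse, m.rae, m.rse) == (0, 0, 0, 0)
        assert m.r2 == 1.0

    def test_constant_label_rejected(self):
        with pytest.raises(CurategapError, match="constant"):
            compute_metrics([2, 2, 2], [1, 2, 3])

    @given(
        arrays(np.float64, st.integers(2, 40),
               elements=st.floats(-100, 100, allow_nan=False)),
        arrays(np.float64, st.integers(2, 40),
               elements=st.floats(-100, 100, allow_nan=False)),
    )
    @settings(max_examples=100, deadline=None)
    def test_identities_on_random_vectors(self, y, y_hat):
        n = min(len(y), len(y_hat))
        y, y_hat = y[:n], y_hat[:n]
        if np.ptp(y) < 1e-6:
            y = y + np.arange(n)  # avoid the (near-)constant undefined case
        m = compute_metrics(y, y_hat)
        assert m.r2 + m.rse == pytest.approx(1.0)
        assert m.rmse + 1e-12 >= m.mae
        assert m.rae >= 0 and m.rse >= 0


class TestPermutationImportance:
    def make_fitted(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        table = [
            make_gene(
                i,
                symbol=f"s{i % 7}",
                y=int(rng.integers(0, 30)),
                expr_pub_count=int(rng.integers(0, 10)),
                total_journal_pub_count=int(rng.integers(10, 20)),
                percent_expr_pubs=float(rng.random()),
                construct_count=int(rng.integers(0, 4)),
            )
            for i in range(1, n + 1)
        ]
        X, y, spec = encode(table)
        model = fit_ridge(X, y, l2_weight=5.0, encoding=spec)
        return model, X, y

    def test_unused_feature_scores_zero(self):
        model, X, y = self.make_fitted()
        model.weights[3] = 0.0  # kill construct_count
        importance = permutation_importance(model, X, y, n_repeats=3, seed=1)
        assert importance.scores["construct_count"] == 0.0

    def test_single_feature_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        table = [
            make_gene(i, symbol="common", y=2 * i, expr_pub_count=i,
                      total_journal_pub_count=0, percent_expr_pubs=0.0,
                      construct_count=0)
            for i in range(1, 21)
        ]
        X, y, spec = encode(table)
        model = fit_ridge(X, y, l2_weight=0.001, encoding=spec)
        importance = permutation_importance(
            model, X, y, metric="rmse", n_repeats=1, seed=7
        )
        # brute-force re-evaluation with the same permutation stream
        baseline = compute_metrics(y, predict(model, X)).rmse
        perm = np.random.default_rng(7).permutation(len(y))
        X_dense = X.toarray()
        X_perm = X_dense.copy()
        X_perm[:, 0] = X_dense[perm, 0]
        expected = compute_metrics(y, predict(model, X_perm)).rmse - baseline
        assert importance.scores["expr_pub_count"] == pytest.approx(expected)

    def test_seeded_reproducibility(self):
        model, X, y = self.make_fitted()
        a = permutation_importance(model, X, y, n_repeats=4, seed=11)
        b = permutation_importance(model, X, y, n_repeats=4, seed=11)
        assert a.scores == b.scores

    def test_symbol_block_permuted_jointly(self):
        # permuting indicator columns jointly keeps one indicator per row
        model, X, y = self.make_fitted()
        importance = permutation_importance(model, X, y, n_repeats=2, seed=3)
        assert "symbol" in importance.scores
        assert set(importance.scores) == set(NUMERIC_FEATURES) | {"symbol"}

    def test_r2_metric_sign_convention(self):
        model, X, y = self.make_fitted()
        rmse_scores = permutation_importance(
            model, X, y, metric="rmse", n_repeats=3, seed=2
        ).scores
        r2_scores = permutation_importance(
            model, X, y, metric="r2", n_repeats=3, seed=2
        ).scores
        # informative features degrade both; signs agree for the dominant one
        top = max(rmse_scores, key=rmse_scores.get)
        assert r2_scores[top] > 0

    def test_invalid_repeats_rejected(self):
        model, X, y = self.make_fitted()
        with pytest.raises(ConfigurationError):
            permutation_importance(model, X, y, n_repeats=0)
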