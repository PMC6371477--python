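import numpy as np
import pytest
import scipy.linalg

from cellhash.io import ExpressionMatrix
from cellhash.preprocessing import (
    CellPreprocessor,
    PreprocessorConfig,
    fit_preprocessor,
    normalize_cells,
    select_features,
    transform_counts,
)


def _matrix(counts):
    counts = np.asarray(counts)
    return ExpressionMatrix(
        counts,
        [f"g{i}" for i in range(counts.shape[0])],
        [f"c{j}" for j in range(counts.shape[1])],
    )


class TestSelectFeatures:
    def test_adaptive_threshold_example(self):
        # per-gene maxima 0, 0, 5, 9; keeping half the genes forces t = 5
        X = _matrix(np.diag([0, 0, 5, 9]))
        got = select_features(X, PreprocessorConfig(min_features_fraction=0.5, n_dims=1))
        assert got == ["g2", "g3"]

    def test_matches_threshold_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 12, size=(40, 6))
        X = _matrix(counts)
        maxima = counts.max(axis=1)
        for frac in (0.1, 0.25, 0.5, 0.9):
            floor = int(np.ceil(frac * 40))
            # oracle: enumerate integer thresholds, keep the largest feasible
            best_t = max(
                t for t in range(int(maxima.max()) + 2) if (maxima >= t).sum() >= floor
            )
            expect = [f"g{i}" for i in range(40) if maxima[i] >= best_t]
            got = select_features(X, PreprocessorConfig(min_features_fraction=frac, n_dims=1))
            assert got == expect

    def test_fraction_one_retains_everything(self):
        X = _matrix(np.diag([0, 3, 7]))
        got = select_features(X, PreprocessorConfig(min_features_fraction=1.0, n_dims=1))
        assert got == ["g0", "g1", "g2"]

    def test_keep_and_drop_overrides(self):
        X = _matrix(np.diag([0, 0, 5, 9]))
        config = PreprocessorConfig(
            min_features_fraction=0.5, n_dims=1, keep_genes=["g0"], drop_genes=["g3"]
        )
        assert select_features(X, config) == ["g0", "g2"]


class TestNormalizeTransform:
    def test_normalization_ratios(self):
        X = np.array([[4.0, 10.0], [6.0, 10.0]])  # totals 10, 20
        out = normalize_cells(X, scale_factor=10)
        np.testing.assert_allclose(out, [[4.0, 5.0], [6.0, 5.0]])

    def test_column_sums_equal_scale_factor(self):
        rng = np.random.default_rng(0)
        X = rng.integers(1, 20, size=(20, 8))
        out = normalize_cells(X, scale_factor=1e4)
        np.testing.assert_allclose(out.sum(axis=0), 1e4, rtol=1e-9)

    def test_zero_total_cell_errors(self):
        with pytest.raises(ValueError, match="column 1"):
            normalize_cells(np.array([[1, 0], [2, 0]]))

    def test_transform_values(self):
        assert transform_counts(np.array([0.0]), "log1p")[0] == 0.0
        assert transform_counts(np.array([0.0]), "ftt")[0] == 1.0
        np.testing.assert_allclose(
            transform_counts(np.array([3.0]), "ftt")[0], np.sqrt(3) + 2.0
        )

    def test_transform_rejects_negative(self):
        with pytest.raises(ValueError, match="negative"):
            transform_counts(np.array([-1.0]))


class TestFitApply:
    def test_standardized_features_have_zero_mean_unit_variance(self):
        rng = np.random.default_rng(1)
        X = _matrix(rng.integers(0, 30, size=(60, 40)))
        prep = CellPreprocessor(n_dims=5, min_features_fraction=0.5, random_state=0)
        prep.fit(X)
        # re-run the deterministic pipeline up to standardization
        sub = X.to_frame().loc[prep.selected_genes_].to_numpy()
        norm = normalize_cells(sub, prep.scale_factor)
        trans = transform_counts(norm, prep.count_transform)
        z = (trans - prep.feature_means_[:, None]) / prep.feature_sds_[:, None]
        assert np.abs(z.mean(axis=1)).max() < 1e-8
        np.testing.assert_allclose(z.var(axis=1, ddof=1), 1.0, atol=1e-6)

    def test_low_rank_input_preserves_cosines(self):
        # build counts whose standardized matrix has numerical rank ~3
        rng = np.random.default_rng(5)
        base = rng.integers(1, 40, size=(30, 3))
        counts = base[:, rng.integers(0, 3, size=25)]
        X = _matrix(counts)
        prep = CellPreprocessor(n_dims=3, min_features_fraction=1.0, random_state=0)
        reduced = prep.fit_transform(X)
        sub = X.to_frame().loc[prep.selected_genes_].to_numpy()
        z = transform_counts(normalize_cells(sub, 1e4), "log1p")
        z = (z - prep.feature_means_[:, None]) / prep.feature_sds_[:, None]

        def cosines(M):
            nrm = np.linalg.norm(M, axis=0)
            return (M.T @ M) / np.outer(nrm, nrm)

        np.testing.assert_allclose(cosines(reduced), cosines(z), atol=1e-6)

    def test_single_cell_errors(self):
        X = _matrix(np.array([[1], [2]]))
        with pytest.raises(ValueError, match="two reference cells"):
            CellPreprocessor(n_dims=1).fit(X)

    def test_determinism(self):
        rng = np.random.default_rng(2)
        X = _matrix(rng.integers(0, 20, size=(40, 15)))
        a = CellPreprocessor(n_dims=4, random_state=9).fit(X)
        b = CellPreprocessor(n_dims=4, random_state=9).fit(X)
        np.testing.assert_array_equal(a.projection_, b.projection_)

    def test_zero_variance_feature_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(1, 20, size=(20, 10))
        # a constant row combined with equal library sizes stays constant
        # through normalization and transform, i.e. has zero variance
        counts[3] = 5
        lib = counts.sum(axis=0)
        counts[0] += lib.max() - lib  # pad gene 0 to equalize library sizes
        X = _matrix(counts)
        with pytest.warns(UserWarning, match="zero-variance"):
            prep = CellPreprocessor(
                n_dims=3, min_features_fraction=1.0, random_state=0
            ).fit(X)
        assert "g3" not in prep.selected_genes_

    def test_too_few_features_errors(self):
        rng = np.random.default_rng(6)
        X = _matrix(rng.integers(1, 10, size=(5, 8)))
        with pytest.raises(ValueError, match="n_dims"):
            CellPreprocessor(n_dims=6, min_features_fraction=1.0).fit(X)

    def test_apply_to_reference_reproduces_fit_output(self):
        rng = np.random.default_rng(7)
        X = _matrix(rng.integers(0, 25, size=(50, 20)))
        prep, reduced = fit_preprocessor(X, PreprocessorConfig(n_dims=5), rng_seed=1)
        again = prep.transform(X)
        np.testing.assert_allclose(again, reduced, atol=1e-10)

    def test_apply_permuted_cells_permutes_output(self):
        rng = np.random.default_rng(8)
        X = _matrix(rng.integers(0, 25, size=(50, 12)))
        prep = CellPreprocessor(n_dims=5, random_state=1).fit(X)
        perm = rng.permutation(12)
        Xp = ExpressionMatrix(
            X.dense()[:, perm], X.gene_names, [X.cell_names[i] for i in perm]
        )
        np.testing.assert_allclose(
            prep.transform(Xp), prep.transform(X)[:, perm], atol=1e-12
        )

    def test_extra_unshared_gene_is_ignored(self):
        rng = np.random.default_rng(9)
        X = _matrix(rng.integers(0, 25, size=(40, 15)))
        prep = CellPreprocessor(n_dims=5, random_state=1).fit(X)
        Q = ExpressionMatrix(
            np.vstack([X.dense(), rng.integers(0, 25, size=(1, 15))]),
            X.gene_names + ["extra"],
            X.cell_names,
        )
        np.testing.assert_allclose(prep.transform(Q), prep.transform(X), atol=1e-12)

    def test_library_size_invariance(self):
        rng = np.random.default_rng(10)
        X = _matrix(rng.integers(0, 25, size=(40, 15)))
        prep = CellPreprocessor(n_dims=5, random_state=1).fit(X)
        scaled = ExpressionMatrix(X.dense() * 3, X.gene_names, X.cell_names)
        np.testing.assert_allclose(prep.transform(scaled), prep.transform(X), atol=1e-9)

    def test_query_stats_mode_differs_from_folding_in(self):
        rng = np.random.default_rng(11)
        X = _matrix(rng.integers(0, 25, size=(40, 15)))
        Q = _matrix(rng.integers(0, 25, size=(40, 10)))
        prep = CellPreprocessor(n_dims=5, random_state=1).fit(X)
        assert not np.allclose(prep.transform(Q), prep.transform(Q, query_stats=True))

    def test_sklearn_params_round_trip(self):
        from sklearn.base import clone

        prep = CellPreprocessor(n_dims=7, count_transform="ftt", random_state=3)
        cloned = clone(prep)
        assert cloned.get_params() == prep.get_params()
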