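import numpy as np
import pytest
import scipy.stats

from cellhash import (
    CellDatabase,
    ExpressionMatrix,
    SynthSpec,
    detect_degs,
    make_deg_pair,
    neighborhood_mean,
    poisson_tails,
)
from cellhash.deg import CompressedCounts


def _pois_pmf_sum(lo, hi, lam):
    return sum(scipy.stats.poisson.pmf(k, lam) for k in range(lo, hi + 1))


class TestCompressedCounts:
    def test_per_cell_round_trip_exact(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(0.5, size=(300, 20))
        X = ExpressionMatrix(
            counts, [f"g{i}" for i in range(300)], [f"c{j}" for j in range(20)]
        )
        store = CompressedCounts.from_matrix(X)
        for j in range(20):
            np.testing.assert_array_equal(store.cell_counts(j), counts[:, j])
        np.testing.assert_array_equal(store.totals, counts.sum(axis=0))


class TestPoissonTails:
    def test_zero_count_closed_form(self):
        lower, upper = poisson_tails(0, 2.0)
        assert lower == pytest.approx(np.exp(-2))
        assert upper == 1.0

    def test_degenerate_zero_mean(self):
        assert poisson_tails(0, 0.0) == (1.0, 1.0)
        lower, upper = poisson_tails(3, 0.0)
        assert lower == 1.0
        assert upper == pytest.approx(0.0)

    def test_upper_tail_matches_pmf_summation(self):
        lower, upper = poisson_tails(7, 2.0)
        assert upper == pytest.approx(1 - _pois_pmf_sum(0, 6, 2.0), abs=1e-12)
        assert lower == pytest.approx(_pois_pmf_sum(0, 7, 2.0), abs=1e-12)

    @pytest.mark.parametrize("lam", [0.3, 1.0, 7.5, 40.0, 100.0])
    def test_gamma_relation_matches_direct_summation(self, lam):
        ys = np.array([0, 1, int(lam), int(lam) + 5, int(3 * lam) + 10])
        lower, upper = poisson_tails(ys, lam)
        for y, lo, up in zip(ys, lower, upper):
            assert lo == pytest.approx(_pois_pmf_sum(0, int(y), lam), abs=1e-10)
            assert up == pytest.approx(
                1 - _pois_pmf_sum(0, int(y) - 1, lam) if y > 0 else 1.0, abs=1e-10
            )

    def test_tails_share_point_mass(self):
        rng = np.random.default_rng(1)
        lam = rng.uniform(0.1, 30, size=50)
        y = rng.poisson(lam)
        lower, upper = poisson_tails(y, lam)
        assert np.all(lower + upper >= 1.0 - 1e-12)

    def test_monotone_in_count(self):
        lam = 5.0
        ys = np.arange(0, 30)
        lower, upper = poisson_tails(ys, lam)
        assert np.all(np.diff(lower) >= 0)
        assert np.all(np.diff(upper) <= 0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            poisson_tails(-1, 2.0)
        with pytest.raises(ValueError):
            poisson_tails(1, -2.0)


class TestNeighborhoodMean:
    def test_k1_identity_at_matching_total(self, small_db):
        store = small_db.raw_store_
        lam, nbrs = neighborhood_mean(small_db, 5, k=1, n_u=float(store.totals[5]))
        assert nbrs == [5]
        np.testing.assert_allclose(lam, store.cell_counts(5))

    def test_identical_normalized_profiles(self):
        # cells proportional to one profile: the scaled mean is that profile
        base = np.array([4, 0, 2, 10, 1, 3, 7, 0, 5, 2, 8, 6])
        rng = np.random.default_rng(0)
        others = rng.integers(1, 40, size=(12, 4))
        counts = np.c_[base, base * 2, base * 3, base * 5, others]
        X = ExpressionMatrix(
            counts, [f"g{i}" for i in range(12)], [f"c{j}" for j in range(8)]
        )
        db = CellDatabase(
            n_bits=64, n_hashes=1, n_dims=2, min_features_fraction=1.0,
            store_counts=True, random_state=0,
        ).fit(X)
        n_u = float(base.sum())
        lam, nbrs = neighborhood_mean(db, 0, k=4, n_u=n_u)
        assert sorted(nbrs) == [0, 1, 2, 3]  # the proportional cells tie at 0
        np.testing.assert_allclose(lam, base)

    def test_matches_hand_computed_mean(self, small_db):
        store = small_db.raw_store_
        n_u = 3000.0
        lam, nbrs = neighborhood_mean(small_db, 10, k=5, n_u=n_u)
        assert len(nbrs) == 5 and 10 in nbrs
        expect = np.mean(
            [store.cell_counts(j) * n_u / store.totals[j] for j in nbrs], axis=0
        )
        np.testing.assert_allclose(lam, expect)

    def test_missing_raw_store_errors(self, small_dataset):
        X, _, _ = small_dataset
        db = CellDatabase(n_bits=64, n_hashes=1, n_dims=10, random_state=0).fit(X)
        with pytest.raises(ValueError, match="store_counts"):
            neighborhood_mean(db, 0, k=3)

    def test_unbiased_under_poisson_capture_model(self):
        # neighbors drawn Pois(beta_j * lam); scaling by n_u/total and
        # averaging should converge to beta_u * lam
        rng = np.random.default_rng(2)
        lam = rng.uniform(1, 20, size=50)
        betas = rng.uniform(0.5, 2.0, size=40)
        n_u_target = lam.sum()  # beta_u = 1
        est = np.zeros(50)
        reps = 300
        for _ in range(reps):
            cells = rng.poisson(np.outer(lam, betas))
            totals = cells.sum(axis=0)
            est += np.mean(cells * (n_u_target / totals), axis=1)
        est /= reps
        np.testing.assert_allclose(est, lam, rtol=0.05)


class TestDetectDegs:
    def test_self_comparison_flags_nothing(self, small_db, small_dataset):
        X, _, _ = small_dataset
        result = detect_degs(
            db=small_db,
            query_counts=ExpressionMatrix(X.dense()[:, [0]], X.gene_names, ["q"]),
            matched_cell=0,
            k=10,
        )
        assert not result.negative.any()
        assert not result.positive.any()

    def test_tenfold_spike_is_flagged_positive(self, small_db, small_dataset):
        X, _, _ = small_dataset
        vec = X.dense()[:, 0].copy()
        lam, _ = neighborhood_mean(small_db, 0, k=10, n_u=float(vec.sum()))
        gene = int(np.argmin(np.abs(lam - 5.0)))
        vec[gene] = int(10 * max(lam[gene], 5.0))
        result = detect_degs(
            db=small_db,
            query_counts=ExpressionMatrix(vec[:, None], X.gene_names, ["q"]),
            matched_cell=0,
            k=10,
        )
        assert result.positive[gene]

    def test_invariant_to_common_library_scaling(self, small_dataset):
        X, labels, _ = small_dataset
        scaled = ExpressionMatrix(X.dense() * 3, X.gene_names, X.cell_names)
        db1 = CellDatabase(
            n_bits=64, n_hashes=2, n_dims=20, store_counts=True, random_state=7
        ).fit(X)
        db2 = CellDatabase(
            n_bits=64, n_hashes=2, n_dims=20, store_counts=True, random_state=7
        ).fit(scaled)
        q = ExpressionMatrix(X.dense()[:, [3]], X.gene_names, ["q"])
        r1 = detect_degs(db1, q, 3, k=5)
        r2 = detect_degs(db2, q, 3, k=5)
        np.testing.assert_allclose(r1.neighborhood_means, r2.neighborhood_means, rtol=1e-9)
        np.testing.assert_array_equal(r1.positive, r2.positive)
        np.testing.assert_array_equal(r1.negative, r2.negative)


class TestSpikeInExperiment:
    def test_recall_and_false_positive_rate(self):
        spec = SynthSpec(n_genes=1000, n_cells=200, seed=5)
        rng = np.random.default_rng(5)
        base = rng.lognormal(0.0, 1.0, size=1000)  # same draw as the generator
        # pick 20 spiked genes among well-expressed ones so lambda >= 5
        strong = np.argsort(base)[::-1][10:60]
        shifted = [f"gene{i}" for i in rng.choice(strong, 20, replace=False)]
        ref, queries, truth = make_deg_pair(spec, shifted_genes=shifted, fold=4.0, n_query=10)
        db = CellDatabase(
            n_bits=128, n_hashes=2, n_dims=20, store_counts=True, random_state=1
        ).fit(ref)
        matched = db.kneighbors(queries, k=1).positions[:, 0]
        qdense = queries.dense()
        hits, total = 0, 0
        false_flags, tested = 0, 0
        shifted_set = set(truth["shifted_genes"])
        for j in range(queries.n_cells):
            res = detect_degs(
                db,
                ExpressionMatrix(qdense[:, [j]], queries.gene_names, ["q"]),
                int(matched[j]),
                k=10,
            )
            flagged = {g for g, d in res.flagged_genes() if d == "positive"}
            strong_lam = res.neighborhood_means >= 5.0
            for g in shifted_set:
                gi = queries.gene_names.index(g)
                if strong_lam[gi]:
                    total += 1
                    hits += g in flagged
            for gi, g in enumerate(queries.gene_names):
                if g not in shifted_set and strong_lam[gi]:
                    tested += 1
                    false_flags += bool(res.positive[gi] or res.negative[gi])
        assert total > 0
        assert hits / total >= 0.9
        assert false_flags / tested <= 0.01
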