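"""kNN boundary imputation, plug-in baselines, and hold-out masking."""

import math

import numpy as np
import pandas as pd
import pytest

from rtimpute.errors import ConfigError, NoSharedFeaturesError
from rtimpute.impute import (
    ImputeConfig,
    knn_impute_quants,
    knn_impute_rt,
    low_value_impute,
    mask_boundary_pairs,
    missforest_impute,
    nan_euclidean_distance,
)
from rtimpute.matrices import PROV_IMPUTED, QuantMatrix, RTBoundaryMatrix

from conftest import make_boundary_matrix
from oracles import brute_knn_impute_quants, brute_knn_impute_table

nan = float("nan")


def _quant(rows, runs=None):
    arr = np.asarray(rows, dtype=float)
    idx = pd.MultiIndex.from_tuples(
        [
            (f"PEPTIDE{chr(65 + i // 20)}{chr(65 + i % 20)}K", 2)
            for i in range(arr.shape[0])
        ],
        names=["sequence", "charge"],
    )
    cols = runs or [f"r{i}" for i in range(arr.shape[1])]
    return QuantMatrix(pd.DataFrame(arr, index=idx, columns=cols))


class TestNanEuclidean:
    def test_identical_complete_vectors(self):
        assert nan_euclidean_distance([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_rescales_for_unshared_coordinates(self):
        d = nan_euclidean_distance([1.0, 2.0, nan], [1.0, 5.0, 7.0])
        assert d == pytest.approx(math.sqrt(13.5), abs=1e-9)

    def test_no_shared_coordinates_is_an_error(self):
        with pytest.raises(NoSharedFeaturesError):
            nan_euclidean_distance([nan, nan], [1.0, 2.0])

    def test_agrees_with_sklearn_reference(self):
        from sklearn.metrics.pairwise import nan_euclidean_distances

        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 9))
        X[rng.random(X.shape) < 0.3] = np.nan
        ref = nan_euclidean_distances(X)
        for i in range(6):
            for j in range(6):
                if i == j or np.isnan(ref[i, j]):
                    continue
                assert nan_euclidean_distance(X[i], X[j]) == pytest.approx(
                    ref[i, j], abs=1e-9
                )


def _rt_from_table(X):
    """runs x (start, end per peptide) table -> RTBoundaryMatrix."""
    n_runs, n_feat = X.shape
    n_pep = n_feat // 2
    idx = pd.MultiIndex.from_tuples(
        [(f"PEPTIDE{chr(65 + i % 26)}{chr(65 + i // 26)}K", 2) for i in range(n_pep)],
        names=["sequence", "charge"],
    )
    cols = [f"r{i}" for i in range(n_runs)]
    return RTBoundaryMatrix(
        pd.DataFrame(X[:, 0::2].T, index=idx, columns=cols),
        pd.DataFrame(X[:, 1::2].T, index=idx, columns=cols),
    )


def _table_from_rt(m):
    X = np.empty((len(m.runs), 2 * len(m.precursors)))
    X[:, 0::2] = m.starts.to_numpy().T
    X[:, 1::2] = m.ends.to_numpy().T
    return X


class TestKnnImputeRt:
    def test_complete_matrix_unchanged(self):
        m = make_boundary_matrix(8, 6, missing_fraction=0.0, seed=1)
        res = knn_impute_rt(m, ImputeConfig(k=3))
        assert res.matrix.equals(m)
        assert res.n_imputed == 0

    def test_zero_distance_donors_average_uniformly(self):
        # r1 matches r2 exactly on every shared coordinate (distance 0) but
        # misses peptide P; r3 is further away. Inverse-distance weights are
        # undefined at d = 0, so with k=2 only the zero-distance donor
        # contributes and P is copied from r2 verbatim.
        X = np.array(
            [
                [nan, nan, 10.0, 20.0],   # r1: P missing, Q = (10, 20)
                [30.0, 40.0, 10.0, 20.0],  # r2: distance 0 to r1 on Q
                [34.0, 44.0, 14.0, 24.0],  # r3: further away
            ]
        )
        m = _rt_from_table(X)
        res = knn_impute_rt(m, ImputeConfig(k=2))
        assert res.matrix.starts.iat[0, 0] == pytest.approx(30.0, abs=1e-12)
        assert res.matrix.ends.iat[0, 0] == pytest.approx(40.0, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for trial in range(10):
            n_runs = int(rng.integers(8, 13))
            m = make_boundary_matrix(8, n_runs, missing_fraction=0.2, seed=trial)
            X = _table_from_rt(m)
            expected = brute_knn_impute_table(X, k=4)
            res = knn_impute_rt(m, ImputeConfig(k=4))
            got = _table_from_rt(res.matrix)
            # canonicalization may swap rare inverted imputed pairs; compare
            # the sorted pair to stay oracle-exact
            exp_pairs = np.sort(expected.reshape(n_runs, -1, 2), axis=2)
            got_pairs = np.sort(got.reshape(n_runs, -1, 2), axis=2)
            mask = ~np.isnan(exp_pairs)
            assert np.allclose(
                exp_pairs[mask], got_pairs[mask], atol=1e-9, equal_nan=True
            )

    def test_agrees_with_sklearn_knnimputer(self):
        from sklearn.impute import KNNImputer

        for seed in range(5):
            m = make_boundary_matrix(10, 9, missing_fraction=0.25, seed=seed)
            X = _table_from_rt(m)
            sk = KNNImputer(n_neighbors=4, weights="distance").fit_transform(X)
            res = knn_impute_rt(m, ImputeConfig(k=4))
            got = _table_from_rt(res.matrix)
            assert np.allclose(got, sk, atol=1e-9)

    def test_observed_cells_never_modified(self):
        m = make_boundary_matrix(10, 8, missing_fraction=0.3, seed=4)
        res = knn_impute_rt(m, ImputeConfig(k=3))
        obs = m.present_mask().to_numpy()
        assert np.array_equal(
            res.matrix.starts.to_numpy()[obs], m.starts.to_numpy()[obs]
        )
        assert np.array_equal(res.matrix.ends.to_numpy()[obs], m.ends.to_numpy()[obs])

    def test_run_permutation_commutes(self):
        m = make_boundary_matrix(8, 7, missing_fraction=0.25, seed=6)
        res = knn_impute_rt(m, ImputeConfig(k=3))
        order = [3, 0, 5, 1, 6, 2, 4]
        perm = [m.runs[i] for i in order]
        m2 = RTBoundaryMatrix(
            m.starts[perm], m.ends[perm], m.provenance[perm]
        )
        res2 = knn_impute_rt(m2, ImputeConfig(k=3))
        assert np.allclose(
            res2.matrix.starts[m.runs].to_numpy(),
            res.matrix.starts.to_numpy(),
            atol=1e-9,
            equal_nan=True,
        )

    def test_completion_when_donors_exist(self):
        m = make_boundary_matrix(10, 8, missing_fraction=0.2, seed=8)
        res = knn_impute_rt(m, ImputeConfig(k=3))
        if not res.unimputable:
            assert res.matrix.n_present == 10 * 8

    def test_imputed_cells_flagged(self):
        m = make_boundary_matrix(6, 6, missing_fraction=0.3, seed=9)
        res = knn_impute_rt(m, ImputeConfig(k=2))
        newly = res.matrix.present_mask().to_numpy() & ~m.present_mask().to_numpy()
        assert (res.matrix.provenance.to_numpy()[newly] == PROV_IMPUTED).all()

    def test_k_must_be_smaller_than_run_count(self):
        m = make_boundary_matrix(4, 5, seed=0)
        with pytest.raises(ConfigError):
            knn_impute_rt(m, ImputeConfig(k=5))
        with pytest.raises(ConfigError):
            knn_impute_rt(make_boundary_matrix(4, 1, seed=0), ImputeConfig(k=1))


class TestMaskBoundaryPairs:
    def test_fraction_zero_masks_nothing(self):
        m = make_boundary_matrix(10, 10, seed=1)
        out, mask = mask_boundary_pairs(m, 0.0, seed=5)
        assert len(mask) == 0
        assert out.equals(m)

    def test_exact_floor_count(self):
        m = make_boundary_matrix(10, 10, missing_fraction=0.0, seed=2)  # 100 cells
        out, mask = mask_boundary_pairs(m, 0.2, seed=5)
        assert len(mask) == 20
        assert out.n_present == 80

    def test_same_seed_same_mask(self):
        m = make_boundary_matrix(10, 10, missing_fraction=0.1, seed=3)
        _, m1 = mask_boundary_pairs(m, 0.2, seed=5)
        _, m2 = mask_boundary_pairs(m, 0.2, seed=5)
        assert m1.cells == m2.cells

    def test_only_observed_cells_masked(self):
        m = make_boundary_matrix(10, 10, missing_fraction=0.4, seed=4)
        _, mask = mask_boundary_pairs(m, 0.3, seed=7)
        present = m.present_mask()
        for pep, run in mask.cells:
            assert present.at[tuple(pep), run]

    def test_fraction_out_of_range(self):
        m = make_boundary_matrix(4, 4, seed=0)
        with pytest.raises(ConfigError):
            mask_boundary_pairs(m, 1.0, seed=0)


class TestLowValue:
    def test_row_minimum_fills_missing(self):
        q = _quant([[5.0, nan, 7.0]])
        out = low_value_impute(q)
        assert out.values.iloc[0].tolist() == [5.0, 5.0, 7.0]

    def test_complete_matrix_unchanged(self):
        q = _quant([[1.0, 2.0], [3.0, 4.0]])
        assert low_value_impute(q).values.equals(q.values)

    def test_all_missing_row_stays_missing(self):
        q = _quant([[nan, nan], [1.0, 2.0]])
        out = low_value_impute(q)
        assert out.values.iloc[0].isna().all()


class TestKnnQuants:
    def test_mean_of_nearest_donors(self):
        # d0 and d1 match the target exactly on the observed peptides while
        # "far" is orders of magnitude off; the target's missing peptide
        # takes the unweighted raw mean of d0 and d1 (10 and 30)
        out = knn_impute_quants(
            _quant(
                [
                    [nan, 10.0, 30.0, 1000.0],
                    [2.0, 2.0, 2.0, 50.0],
                    [4.0, 4.0, 4.0, 90.0],
                ],
                runs=["target", "d0", "d1", "far"],
            ),
            k=2,
        )
        assert out.values.iloc[0, 0] == pytest.approx(20.0)

    def test_complete_matrix_unchanged(self):
        q = _quant([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        assert knn_impute_quants(q, k=2).values.equals(q.values)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        vals = 2.0 ** rng.normal(12, 2, size=(10, 6))
        vals[rng.random(vals.shape) < 0.25] = np.nan
        q = _quant(vals)
        out = knn_impute_quants(q, k=3)
        expected = brute_knn_impute_quants(vals, k=3)
        assert np.allclose(out.values.to_numpy(), expected, atol=1e-9, equal_nan=True)

    def test_k_bound(self):
        with pytest.raises(ConfigError):
            knn_impute_quants(_quant([[1.0, 2.0]]), k=2)


class TestMissForest:
    def test_complete_matrix_unchanged(self):
        q = _quant([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        out = missforest_impute(q, seed=0)
        assert out.values.equals(q.values)

    def test_beats_column_mean_on_low_rank_data(self):
        rng = np.random.default_rng(4)
        u = 2.0 ** rng.normal(10, 1.5, size=50)
        v = rng.uniform(0.5, 2.0, size=10)
        truth = np.outer(u, v) * (1 + 0.05 * rng.normal(size=(50, 10)))
        vals = truth.copy()
        vals[rng.random(vals.shape) < 0.10] = np.nan
        q = _quant(vals)
        out = missforest_impute(q, seed=4)
        miss = np.isnan(vals)
        col_means = np.nanmean(vals, axis=0)
        mse_mf = np.mean((out.values.to_numpy()[miss] - truth[miss]) ** 2)
        mse_cm = np.mean(
            (np.broadcast_to(col_means, vals.shape)[miss] - truth[miss]) ** 2
        )
        assert mse_mf < mse_cm

    def test_same_seed_identical_output(self):
        rng = np.random.default_rng(5)
        vals = 2.0 ** rng.normal(10, 1, size=(20, 6))
        vals[rng.random(vals.shape) < 0.2] = np.nan
        q = _quant(vals)
        a = missforest_impute(q, seed=11, n_trees=20)
        b = missforest_impute(q, seed=11, n_trees=20)
        assert a.values.equals(b.values)

    def test_observed_cells_untouched(self):
        rng = np.random.default_rng(6)
        vals = 2.0 ** rng.normal(10, 1, size=(15, 5))
        vals[rng.random(vals.shape) < 0.2] = np.nan
        q = _quant(vals)
        out = missforest_impute(q, seed=1, n_trees=20)
        obs = ~np.isnan(vals)
        assert np.array_equal(out.values.to_numpy()[obs], vals[obs])
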