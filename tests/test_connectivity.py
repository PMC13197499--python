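"""FC estimators against closed forms, regression oracles and nilearn."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fcbench.connectivity import (ConnectivityMatrix, cov_to_correlation,
                                  devectorize, edge_index_map,
                                  estimate_covariance, expm_sym,
                                  fit_tangent_reference, glasso_fc,
                                  glasso_kkt_residual, glasso_objective,
                                  graphical_lasso_admm, logm_spd, partial_fc,
                                  pearson_fc, powm_spd, tangent_fc, vectorize)


def random_spd(rng, R, T=None):
    A = rng.standard_normal((R, T or 4 * R))
    S = A @ A.T / (T or 4 * R)
    return S + 0.1 * np.eye(R)


class TestCovariance:
    def test_orthonormal_columns_give_identity(self):
        T = 64
        q, _ = np.linalg.qr(np.random.default_rng(0).standard_normal((T, 5)))
        cov = estimate_covariance(q * np.sqrt(T), shrinkage="empirical")
        # columns are orthonormal * sqrt(T): covariance close to identity
        assert np.abs(cov - np.eye(5)).max() < 0.2

    def test_empirical_mode_equals_sample_covariance(self, rng):
        Y = rng.standard_normal((50, 4))
        np.testing.assert_allclose(estimate_covariance(Y, "empirical"),
                                   np.cov(Y, rowvar=False), atol=1e-12)

    def test_shrinkage_keeps_spd_near_t_equals_r(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            Y = rng.standard_normal((12, 10))
            cov = estimate_covariance(Y)
            assert np.linalg.eigvalsh(cov)[0] > 0

    def test_constant_column_names_region(self, rng):
        Y = rng.standard_normal((40, 3))
        Y[:, 1] = 2.0
        with pytest.raises(ValueError, match="1"):
            estimate_covariance(Y)


class TestPearson:
    def test_duplicated_column_has_unit_correlation(self, rng):
        x = rng.standard_normal(100)
        fc = pearson_fc(np.column_stack([x, x, rng.standard_normal(100)]))
        assert fc.values[0, 1] == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(fc.values), 1.0)

    def test_independent_series_near_zero(self, rng):
        T = 4000
        fc = pearson_fc(rng.standard_normal((T, 6)))
        off = vectorize(fc)
        assert np.abs(off).max() < 4 / np.sqrt(T)

    def test_matches_rescaled_empirical_covariance(self, rng):
        Y = rng.standard_normal((80, 5)) @ rng.standard_normal((5, 5))
        fc = pearson_fc(Y)
        np.testing.assert_allclose(
            fc.values, cov_to_correlation(estimate_covariance(Y, "empirical")),
            atol=1e-10)


class TestPartial:
    def test_two_regions_partial_equals_pearson(self, rng):
        Y = rng.standard_normal((200, 2)) @ np.array([[1.0, 0.4], [0.0, 1.0]])
        cov = estimate_covariance(Y, "empirical")
        assert partial_fc(cov).values[0, 1] == pytest.approx(
            pearson_fc(Y).values[0, 1], abs=1e-10)

    def test_chain_graph_nonadjacent_partials_vanish(self):
        # x1 -> x2 -> x3 -> x4 chain: only adjacent pairs conditionally linked
        rng = np.random.default_rng(5)
        T = 200_000
        x1 = rng.standard_normal(T)
        x2 = 0.8 * x1 + rng.standard_normal(T)
        x3 = 0.8 * x2 + rng.standard_normal(T)
        x4 = 0.8 * x3 + rng.standard_normal(T)
        Y = np.column_stack([x1, x2, x3, x4])
        part = partial_fc(np.cov(Y, rowvar=False)).values

        # oracle: correlation of OLS residuals after regressing out the rest
        def partial_oracle(i, j):
            others = [k for k in range(4) if k not in (i, j)]
            X = np.column_stack([np.ones(T), Y[:, others]])
            ri = Y[:, i] - X @ np.linalg.lstsq(X, Y[:, i], rcond=None)[0]
            rj = Y[:, j] - X @ np.linalg.lstsq(X, Y[:, j], rcond=None)[0]
            return np.corrcoef(ri, rj)[0, 1]

        for i in range(4):
            for j in range(i + 1, 4):
                assert part[i, j] == pytest.approx(partial_oracle(i, j),
                                                   abs=1e-8)
        assert abs(part[0, 2]) < 0.02 and abs(part[0, 3]) < 0.02

    def test_diagonal_exactly_zero(self, rng):
        part = partial_fc(random_spd(rng, 6))
        assert (np.diag(part.values) == 0).all()


class TestGlasso:
    def test_zero_penalty_reduces_to_partial_correlation(self, rng):
        S = random_spd(rng, 6)
        np.testing.assert_allclose(glasso_fc(S, alpha=0.0).values,
                                   partial_fc(cov_to_correlation(S)).values,
                                   atol=1e-6)

    def test_large_penalty_zeroes_every_edge(self, rng):
        fc = glasso_fc(random_spd(rng, 8), alpha=5.0)
        assert (vectorize(fc) == 0).all()

    def test_objective_matches_independent_solver(self, rng):
        from sklearn.covariance import graphical_lasso as sk_glasso
        S = cov_to_correlation(random_spd(rng, 5))
        P = graphical_lasso_admm(S, alpha=0.1)
        _, P_sk = sk_glasso(S, alpha=0.1, tol=1e-10, max_iter=2000)
        ours = glasso_objective(S, P, 0.1)
        theirs = glasso_objective(S, P_sk, 0.1)
        assert ours == pytest.approx(theirs, abs=1e-5)
        assert ours <= theirs + 1e-8  # we never do worse on our objective

    def test_stationarity_residual_below_contract(self, rng):
        S = cov_to_correlation(random_spd(rng, 5))
        P = graphical_lasso_admm(S, alpha=0.1)
        assert glasso_kkt_residual(S, P, 0.1) < 1e-4

    def test_negative_penalty_rejected(self, rng):
        with pytest.raises(ValueError):
            glasso_fc(random_spd(rng, 4), alpha=-0.1)


class TestTangent:
    def test_identical_inputs_fix_the_reference(self, rng):
        C = random_spd(rng, 5)
        ref = fit_tangent_reference([C, C, C])
        np.testing.assert_allclose(ref.reference_mean, C, atol=1e-8)

    def test_commuting_diagonal_matrices_give_geometric_mean(self):
        a = np.diag([1.0, 4.0, 9.0])
        b = np.diag([4.0, 1.0, 1.0])
        ref = fit_tangent_reference([a, b])
        np.testing.assert_allclose(ref.reference_mean,
                                   np.diag(np.sqrt(np.diag(a) * np.diag(b))),
                                   atol=1e-8)

    def test_frechet_mean_satisfies_defining_equation(self, rng):
        covs = [random_spd(rng, 4) for _ in range(3)]
        ref = fit_tangent_reference(covs)
        Gih = ref.whitening
        resid = np.mean([logm_spd(Gih @ c @ Gih) for c in covs], axis=0)
        assert np.linalg.norm(resid) < 1e-6

    def test_projection_of_reference_is_zero(self, rng):
        C = random_spd(rng, 5)
        ref = fit_tangent_reference([C, random_spd(rng, 5)])
        zero = tangent_fc(ref.reference_mean, ref)
        assert np.abs(zero.values).max() < 1e-8

    def test_scaled_reference_projects_to_log_scalar_identity(self, rng):
        C = random_spd(rng, 4)
        ref = fit_tangent_reference([C])
        out = tangent_fc(3.0 * C, ref)
        np.testing.assert_allclose(out.values, np.log(3.0) * np.eye(4),
                                   atol=1e-8)

    def test_round_trip_through_matrix_exponential(self, rng):
        covs = [random_spd(rng, 5) for _ in range(4)]
        ref = fit_tangent_reference(covs)
        C = covs[2]
        tang = tangent_fc(C, ref).values
        Gh = powm_spd(ref.reference_mean, 0.5)
        back = Gh @ expm_sym(tang) @ Gh
        np.testing.assert_allclose(back, C, atol=1e-8)

    def test_reference_matches_nilearn_geometric_mean(self, rng):
        nilearn = pytest.importorskip("nilearn")
        from nilearn.connectome import ConnectivityMeasure
        from sklearn.covariance import EmpiricalCovariance
        series = [rng.standard_normal((100, 5)) for _ in range(6)]
        cm = ConnectivityMeasure(kind="tangent",
                                 cov_estimator=EmpiricalCovariance())
        cm.fit(series)
        covs = [np.cov(s, rowvar=False, ddof=0) for s in series]
        ref = fit_tangent_reference(covs)
        np.testing.assert_allclose(ref.reference_mean, cm.mean_, atol=1e-5)

    def test_provenance_records_training_ids(self, rng):
        ref = fit_tangent_reference([random_spd(rng, 4)], ("scan-1",))
        assert ref.train_scan_ids == ("scan-1",)


class TestVectorize:
    def test_four_regions_give_six_edges(self, rng):
        S = random_spd(rng, 4)
        assert vectorize(S).shape == (6,)

    def test_round_trip_identity_off_diagonal(self, rng):
        S = random_spd(rng, 7)
        back = devectorize(vectorize(S))
        off = ~np.eye(7, dtype=bool)
        np.testing.assert_allclose(back[off], S[off])

    def test_documented_row_major_ordering_on_labelled_matrix(self):
        M = np.array([[0.0, 12.0, 13.0], [12.0, 0.0, 23.0], [13.0, 23.0, 0.0]])
        np.testing.assert_array_equal(vectorize(M), [12.0, 13.0, 23.0])
        assert edge_index_map(3) == [(0, 1), (0, 2), (1, 2)]

    def test_asymmetric_matrix_rejected(self, rng):
        M = rng.standard_normal((4, 4))
        with pytest.raises(ValueError):
            vectorize(M)

    @given(st.integers(4, 10))
    def test_devectorize_inverts_vectorize_for_any_size(self, R):
        rng = np.random.default_rng(R)
        S = random_spd(rng, R)
        np.testing.assert_allclose(vectorize(devectorize(vectorize(S))),
                                   vectorize(S))


def test_permutation_equivariance_of_measures(rng):
    """Relabelling regions permutes every FC measure consistently."""
    Y = rng.standard_normal((120, 6)) @ rng.standard_normal((6, 6))
    perm = rng.permutation(6)
    cov = estimate_covariance(Y)
    cov_p = estimate_covariance(Y[:, perm])
    for fn in (lambda c: partial_fc(c).values,
               lambda c: glasso_fc(c, 0.05).values):
        np.testing.assert_allclose(fn(cov)[np.ix_(perm, perm)], fn(cov_p),
                                   atol=1e-6)
    np.testing.assert_allclose(
        pearson_fc(Y).values[np.ix_(perm, perm)], pearson_fc(Y[:, perm]).values,
        atol=1e-10)


def test_asymmetric_connectivity_matrix_rejected(rng):
    with pytest.raises(ValueError):
        ConnectivityMatrix(rng.standard_normal((4, 4)), "pearson")
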