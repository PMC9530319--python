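"""Weight derivation: standardization, eigen-analysis, rate blending."""

import numpy as np
import pytest
import scipy.linalg

import fuzzycomm as fc
from fuzzycomm.exceptions import (
    ComponentSelectionError,
    ConversionError,
    DegenerateIndicatorError,
    WeightDegeneracyError,
)
from fuzzycomm.weighting import (
    coefficients_to_loadings,
    eigen_components,
    standardize,
)

from conftest import random_cohort_matrix


class TestStandardize:
    def test_hand_computed_column(self):
        X = np.column_stack([[10.0, 20.0, 30.0], [1.0, 2.0, 4.0]])
        z = standardize(X)
        np.testing.assert_allclose(z.values[:, 0], [-1.0, 0.0, 1.0])  # sample sd 10
        assert z.sds[0] == pytest.approx(10.0)

    def test_idempotent_on_standardized_data(self, rng):
        X = rng.standard_normal((50, 4))
        z1 = standardize(X)
        z2 = standardize(z1.values)
        np.testing.assert_allclose(z2.values, z1.values, atol=1e-12)

    def test_reference_cohort_postcondition(self, reference_cohort):
        z = standardize(fc.cohort_matrix(reference_cohort))
        np.testing.assert_allclose(z.values.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(z.values.std(axis=0, ddof=1), 1.0, atol=1e-8)

    def test_constant_column_rejected(self):
        X = np.column_stack([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.raises(DegenerateIndicatorError):
            standardize(X)


class TestEigenComponents:
    def test_2x2_closed_form(self, rng):
        # correlated pair: eigenvalues of [[1, rho], [rho, 1]] are 1 +- rho
        x = rng.standard_normal(500)
        y = 0.6 * x + 0.8 * rng.standard_normal(500)
        X = np.column_stack([x, y])
        rho = np.corrcoef(X.T)[0, 1]
        lam, _ = eigen_components(standardize(X))
        np.testing.assert_allclose(lam, [1 + rho, 1 - rho], atol=1e-10)

    def test_identity_correlation(self):
        # exactly uncorrelated columns (orthogonalized noise) -> eigenvalues 1
        rng = np.random.default_rng(1)
        A = rng.standard_normal((50, 3))
        Q, _ = np.linalg.qr(A - A.mean(axis=0))
        lam, _ = eigen_components(standardize(Q))
        np.testing.assert_allclose(lam, np.ones(3), atol=1e-8)

    def test_against_independent_eigen_oracle(self, rng):
        X = random_cohort_matrix(rng, n=6)
        z = standardize(X)
        lam, vec = eigen_components(z)
        C = np.corrcoef(X, rowvar=False)
        lam_ref = np.sort(scipy.linalg.eigvalsh(C))[::-1]
        np.testing.assert_allclose(lam, np.clip(lam_ref, 0, None), atol=1e-8)

    def test_reconstructs_correlation_matrix(self, rng):
        X = random_cohort_matrix(rng, n=30)
        z = standardize(X)
        lam, Q = eigen_components(z)
        C = np.corrcoef(X, rowvar=False)
        np.testing.assert_allclose(Q @ np.diag(lam) @ Q.T, C, atol=1e-8)

    def test_sign_convention(self, rng):
        X = random_cohort_matrix(rng, n=15)
        _, Q = eigen_components(standardize(X))
        for j in range(Q.shape[1]):
            assert Q[np.argmax(np.abs(Q[:, j])), j] > 0


class TestContributionRates:
    def test_equal_eigenvalues(self):
        ind, cum = fc.contribution_rates([1.0, 1.0, 1.0])
        np.testing.assert_allclose(ind, [1 / 3, 1 / 3, 1 / 3])
        np.testing.assert_allclose(cum, [1 / 3, 2 / 3, 1.0])

    def test_two_components_over_nine_variables(self):
        ind, _ = fc.contribution_rates([6.99, 1.28, 0.73])
        assert ind[0] == pytest.approx(6.99 / 9.0, abs=1e-12)
        assert ind[1] == pytest.approx(1.28 / 9.0, abs=1e-12)

    def test_single_component(self):
        ind, cum = fc.contribution_rates([2.5])
        np.testing.assert_allclose(ind, [1.0])
        np.testing.assert_allclose(cum, [1.0])

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateIndicatorError):
            fc.contribution_rates([0.0, 0.0])


class TestSelectComponents:
    def test_two_dominant_components(self):
        lam = [6.99, 1.28, 0.3, 0.2, 0.1, 0.05, 0.04, 0.03, 0.01]
        assert fc.select_components(lam) == 2

    def test_single_carrier(self):
        assert fc.select_components([9.0, 0.0, 0.0]) == 1

    def test_matches_prefix_enumeration(self):
        lam = np.array([2.5, 1.9, 1.5, 1.2, 1.05, 0.4, 0.25, 0.15, 0.05])
        cum = np.cumsum(lam) / lam.sum()
        valid = [
            n
            for n in range(1, len(lam) + 1)
            if np.all(lam[:n] > 1.0) and cum[n - 1] > 0.85
        ]
        assert fc.select_components(lam) == min(valid)

    def test_unsatisfiable_raises_unless_fallback(self):
        lam = [0.9, 0.8, 0.7]
        with pytest.raises(ComponentSelectionError):
            fc.select_components(lam)
        assert fc.select_components(lam, fallback=True) == 1


class TestLoadingConversion:
    def test_unit_eigenvalue_identity(self, rng):
        L = rng.uniform(-1, 1, size=(9, 2))
        np.testing.assert_allclose(fc.loadings_to_coefficients(L, [1.0, 1.0]), L)

    def test_round_trip(self, rng):
        L = rng.uniform(-1, 1, size=(9, 2))
        lam = [6.9, 1.3]
        C = fc.loadings_to_coefficients(L, lam)
        np.testing.assert_allclose(coefficients_to_loadings(C, lam), L, atol=1e-9)

    def test_published_tables_are_consistent(self, factor_model):
        # dividing the published loadings by sqrt(recovered eigenvalue)
        # reproduces the published score coefficients to table precision
        L = np.asarray(factor_model["loadings"])
        C = np.asarray(factor_model["score_coefficients"])
        lam = fc.eigenvalues_from_loading_ratio(L, C)
        recovered = fc.loadings_to_coefficients(L, lam)
        keep = np.abs(C) >= 0.05  # near-zero printed entries are rounding noise
        np.testing.assert_allclose(recovered[keep], C[keep], atol=5e-3)

    def test_nonpositive_eigenvalue_rejected(self):
        with pytest.raises(ConversionError):
            fc.loadings_to_coefficients(np.ones((3, 2)), [1.0, 0.0])


class TestComputeWeights:
    def test_single_component_limit(self, rng):
        C = rng.uniform(0.1, 0.5, size=(9, 2))
        A = fc.compute_weights(C, [0.7, 0.0])
        np.testing.assert_allclose(A, C[:, 0] / C[:, 0].sum(), atol=1e-12)

    def test_symmetric_coefficients(self):
        C = np.full((9, 2), 0.3)
        np.testing.assert_allclose(fc.compute_weights(C, [0.6, 0.2]), np.full(9, 1 / 9))

    def test_scale_invariant_in_rates(self, rng):
        C = rng.uniform(0.0, 0.5, size=(9, 2))
        A1 = fc.compute_weights(C, [0.7, 0.14])
        A2 = fc.compute_weights(C, [7.0, 1.4])
        np.testing.assert_allclose(A1, A2, atol=1e-12)

    def test_degenerate_sum_rejected(self):
        with pytest.raises(WeightDegeneracyError):
            fc.compute_weights(-np.ones((9, 2)), [0.7, 0.2])
        with pytest.raises(WeightDegeneracyError):
            fc.compute_weights(np.ones((9, 2)), [0.0, 0.0])


class TestPrincipalComponentWeights:
    def test_weights_sum_to_one_and_model_roundtrip(self, rng, tmp_path):
        X = random_cohort_matrix(rng, n=25)
        est = fc.PrincipalComponentWeights(fallback=True).fit(X)
        assert est.weights_.sum() == pytest.approx(1.0, abs=1e-9)
        model = est.to_model()
        path = tmp_path / "model.json"
        model.save(path)
        back = fc.WeightModel.load(path)
        np.testing.assert_allclose(back.weights, model.weights, atol=0)
        np.testing.assert_allclose(back.eigenvalues, model.eigenvalues, atol=0)
        assert back.n_selected == model.n_selected
        assert back.metadata == model.metadata

    def test_sign_flips_do_not_change_weights(self, rng):
        # flipping raw eigenvector signs upstream is undone by the
        # largest-entry-positive convention, so the weights are unchanged
        from fuzzycomm.weighting import _fix_signs

        X = random_cohort_matrix(rng, n=20)
        est = fc.PrincipalComponentWeights(fallback=True).fit(X)
        m = est.n_selected_
        Q = est.coefficients_.copy()
        for j in rng.choice(Q.shape[1], size=3, replace=False):
            Q[:, j] = -Q[:, j]
        refixed = _fix_signs(Q)
        A = fc.compute_weights(refixed[:, :m], est.contributions_[:m])
        np.testing.assert_allclose(A, est.weights_, atol=1e-12)

    def test_subject_permutation_invariance(self, rng):
        X = random_cohort_matrix(rng, n=20)
        est1 = fc.PrincipalComponentWeights(fallback=True).fit(X)
        est2 = fc.PrincipalComponentWeights(fallback=True).fit(
            X[rng.permutation(20)]
        )
        np.testing.assert_allclose(est1.weights_, est2.weights_, atol=1e-9)

    def test_indicator_permutation_equivariance(self, rng):
        X = random_cohort_matrix(rng, n=20)
        perm = rng.permutation(9)
        est1 = fc.PrincipalComponentWeights(fallback=True).fit(X)
        est2 = fc.PrincipalComponentWeights(fallback=True).fit(X[:, perm])
        np.testing.assert_allclose(est2.weights_, est1.weights_[perm], atol=1e-8)

    def test_pipeline_agreement_loadings_vs_eigenvectors(self, rng):
        # weights via published-style loading conversion equal weights
        # computed directly from eigenvectors
        X = random_cohort_matrix(rng, n=40)
        est = fc.PrincipalComponentWeights(fallback=True).fit(X)
        m = est.n_selected_
        loadings = coefficients_to_loadings(
            est.coefficients_[:, :m], est.eigenvalues_[:m]
        )
        coeffs = fc.loadings_to_coefficients(loadings, est.eigenvalues_[:m])
        A = fc.compute_weights(coeffs, est.contributions_[:m])
        np.testing.assert_allclose(A, est.weights_, atol=1e-9)
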