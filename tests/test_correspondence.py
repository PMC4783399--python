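"""Correspondence-analysis engine: oracles, invariants, conventions."""
import numpy as np
import pandas as pd
import pytest

from hippocomp.correspondence import (
    axis_contributions,
    correspondence_analysis,
    offset_shift,
)
from hippocomp.transform import CompositionMatrix


def chi_square_inertia_oracle(X):
    """Brute-force cell-by-cell Pearson chi-square over the grand total."""
    X = np.asarray(X, dtype=float)
    n = X.sum()
    chi2 = 0.0
    for i in range(X.shape[0]):
        for j in range(X.shape[1]):
            expected = X[i].sum() * X[:, j].sum() / n
            chi2 += (X[i, j] - expected) ** 2 / expected
    return chi2 / n


class TestInertia:
    def test_rank_one_table_has_zero_inertia(self):
        X = np.outer([1.0, 2.0, 5.0, 0.5], [3.0, 1.0, 4.0])
        result = correspondence_analysis(X)
        assert result.total_inertia == pytest.approx(0.0, abs=1e-12)

    def test_total_inertia_equals_chi_square_over_total(self, rng):
        X = rng.uniform(0.2, 8.0, size=(4, 3))
        result = correspondence_analysis(X)
        assert result.total_inertia == pytest.approx(
            chi_square_inertia_oracle(X), abs=1e-10
        )

    def test_axis_inertias_match_eigen_oracle(self, random_nonneg_matrix):
        """Eigen-decomposition of the chi-square residual cross-product gives
        the same axis inertias as the SVD route."""
        X = random_nonneg_matrix.to_numpy()
        n = X.sum()
        P = X / n
        r, c = P.sum(1), P.sum(0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        eigvals = np.sort(np.linalg.eigvalsh(S.T @ S))[::-1]
        result = correspondence_analysis(random_nonneg_matrix)
        np.testing.assert_allclose(
            result.singular_values**2, eigvals[: result.n_axes], atol=1e-10
        )

    def test_inertia_percentages_sum_to_100(self, random_nonneg_matrix):
        result = correspondence_analysis(random_nonneg_matrix)
        assert result.axis_inertia_pct.sum() == pytest.approx(100.0, abs=1e-9)
        assert np.all(np.diff(result.singular_values) <= 1e-12)

    def test_invariant_to_global_rescaling(self, random_nonneg_matrix):
        a = correspondence_analysis(random_nonneg_matrix)
        b = correspondence_analysis(random_nonneg_matrix * 7.5)
        np.testing.assert_allclose(a.singular_values, b.singular_values, atol=1e-12)
        pd.testing.assert_frame_equal(a.row_coords, b.row_coords)


class TestContributions:
    def test_contributions_sum_to_100_per_axis(self, random_nonneg_matrix):
        result = correspondence_analysis(random_nonneg_matrix)
        for side in ("rows", "cols"):
            for axis in range(result.n_axes):
                assert axis_contributions(result, axis, side).sum() == pytest.approx(
                    100.0, abs=1e-9
                )

    def test_two_column_contributions_match_hand_decomposition(self):
        """With two columns there is one axis; each side's contribution is its
        mass times squared standard coordinate, computed here from scratch."""
        X = np.array([[8.0, 2.0], [3.0, 7.0], [5.0, 5.0]])
        result = correspondence_analysis(X)
        n = X.sum()
        P = X / n
        r, c = P.sum(1), P.sum(0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        U, sv, Vt = np.linalg.svd(S)
        gamma = Vt[0] / np.sqrt(c)  # standard coordinates, axis 1
        expected = 100.0 * c * gamma**2
        np.testing.assert_allclose(
            axis_contributions(result, 0, "cols").to_numpy(), expected, atol=1e-10
        )

    def test_axis_out_of_range(self, random_nonneg_matrix):
        result = correspondence_analysis(random_nonneg_matrix)
        with pytest.raises(IndexError):
            axis_contributions(result, result.n_axes, "rows")


class TestStructuralInvariants:
    def test_transition_formula_duality(self, rng):
        """Row principal coordinates are the row-profile-weighted averages of
        column standard coordinates (the CA transition formula)."""
        X = rng.uniform(0.2, 5.0, size=(5, 4))
        result = correspondence_analysis(X)
        profiles = X / X.sum(axis=1, keepdims=True)
        gamma = result.col_coords.to_numpy() / result.singular_values
        expected = profiles @ gamma  # row barycenters of column standard coords
        np.testing.assert_allclose(result.row_coords.to_numpy(), expected, atol=1e-9)

    def test_row_permutation_equivariance(self, random_nonneg_matrix):
        result = correspondence_analysis(random_nonneg_matrix)
        perm = random_nonneg_matrix.iloc[::-1]
        permuted = correspondence_analysis(perm)
        np.testing.assert_allclose(
            permuted.singular_values, result.singular_values, atol=1e-12
        )
        pd.testing.assert_frame_equal(permuted.col_coords, result.col_coords)
        pd.testing.assert_frame_equal(
            permuted.row_coords, result.row_coords.iloc[::-1]
        )

    def test_sign_convention_leading_column_positive(self, random_nonneg_matrix):
        result = correspondence_analysis(random_nonneg_matrix)
        for axis in range(result.n_axes):
            lead = result.col_contrib_pct.iloc[:, axis].idxmax()
            assert result.col_coords.loc[lead].iloc[axis] >= 0


class TestErrorsAndShift:
    def test_negative_values_point_to_offset_shift(self):
        with pytest.raises(ValueError, match="offset_shift"):
            correspondence_analysis(np.array([[1.0, -0.5], [2.0, 3.0]]))

    def test_zero_row_named(self):
        df = pd.DataFrame(
            [[1.0, 2.0], [0.0, 0.0], [3.0, 1.0]], index=["a", "empty_row", "c"]
        )
        with pytest.raises(ValueError, match="empty_row"):
            correspondence_analysis(df)

    def test_zero_column_named(self):
        df = pd.DataFrame([[1.0, 0.0], [3.0, 0.0], [2.0, 0.0]],
                          columns=["ok", "empty_col"])
        with pytest.raises(ValueError, match="empty_col"):
            correspondence_analysis(df)

    def test_offset_shift_moves_minimum_to_zero(self):
        df = pd.DataFrame([[-1.0, 2.0], [0.5, -0.25]])
        shifted = offset_shift(df)
        assert shifted.meta["shift"] == 1.0
        assert shifted.values.to_numpy().min() == 0.0
        # shifted output is accepted by the CA engine
        correspondence_analysis(shifted)

    def test_offset_shift_identity_on_nonnegative(self):
        df = pd.DataFrame([[0.0, 2.0], [0.5, 1.0]])
        shifted = offset_shift(df)
        assert shifted.meta["shift"] == 0.0
        pd.testing.assert_frame_equal(shifted.values, df.astype(float))

    def test_offset_shift_epsilon(self):
        df = pd.DataFrame([[-2.0, 1.0]])
        shifted = offset_shift(df, epsilon=0.5)
        assert shifted.values.to_numpy().min() == pytest.approx(0.5)


class TestRatioTableOrdination:
    def test_species_level_ratio_table_axis_inertias(self, table4):
        """The 20×4 convergence/divergence table: frozen reference values from
        an independent CA implementation (R vegan::cca on the same table)."""
        result = correspondence_analysis(
            CompositionMatrix(table4, semantics="raw")
        )
        np.testing.assert_allclose(
            result.axis_inertia_pct, [84.8106, 13.2838, 1.9056], atol=5e-4
        )
        assert result.total_inertia == pytest.approx(0.1971258, abs=1e-6)
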