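"""Discrete oracles, Gaussian closed forms, and the sample estimators."""

import numpy as np
import pytest

from tcnet.data import TimeSeriesMatrix, ValidationError
from tcnet.infotheory import (
    DiscreteJoint,
    GaussianModel,
    binned_tc_estimate,
    conditional_total_correlation_discrete,
    copula_tc_estimate,
    entropy_discrete,
    equal_frequency_bins,
    gaussian_total_correlation,
    mutual_information_discrete,
    renyi_matrix_tc,
    tc_decomposition_residual,
    total_correlation_discrete,
    total_correlation_discrete_kl,
)


def brute_entropy(p):
    """Independent oracle: direct -sum p log2 p over a flat table."""
    p = np.asarray(p, float).ravel()
    return float(-sum(pi * np.log2(pi) for pi in p if pi > 0))


def coin(p0=0.5):
    return np.array([p0, 1 - p0])


# --------------------------------------------------------------------- joints
class TestDiscreteJoint:
    def test_rejects_bad_probabilities(self):
        with pytest.raises(ValidationError):
            DiscreteJoint(["a"], np.array([0.5, 0.4]))
        with pytest.raises(ValidationError):
            DiscreteJoint(["a", "b"], np.array([[0.7, 0.5], [-0.1, -0.1]]))

    def test_marginal_is_distribution(self, rng):
        j = DiscreteJoint.random([2, 3, 2], rng)
        for name in j.variable_names:
            m = j.marginal([name]).probabilities
            assert m.sum() == pytest.approx(1.0, abs=1e-12)
            assert (m >= 0).all()

    def test_from_samples_counts(self):
        labels = np.array([[0, 0], [0, 1], [1, 1], [1, 1]])
        j = DiscreteJoint.from_samples(labels)
        assert j.probabilities[1, 1] == pytest.approx(0.5)
        assert j.probabilities[1, 0] == pytest.approx(0.0)


class TestEntropy:
    @pytest.mark.parametrize(
        "table,expected",
        [
            (coin(), 1.0),                                   # uniform coin
            (np.array([1.0, 0.0]), 0.0),                     # deterministic
            (np.array([0.5, 0.25, 0.125, 0.125]), 1.75),     # hand computation
        ],
    )
    def test_single_variable(self, table, expected):
        j = DiscreteJoint(["a"], table)
        assert entropy_discrete(j, ["a"]) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_on_random_marginals(self, rng):
        for _ in range(20):
            j = DiscreteJoint.random([2, 2, 3], rng)
            assert entropy_discrete(j, ["V0", "V2"]) == pytest.approx(
                brute_entropy(j.marginal(["V0", "V2"]).probabilities), abs=1e-12
            )

    def test_empty_axes_rejected(self, rng):
        j = DiscreteJoint.random([2, 2], rng)
        with pytest.raises(ValidationError):
            entropy_discrete(j, [])


class TestMutualInformation:
    def test_independent_coins_zero(self):
        j = DiscreteJoint(["a", "b"], np.outer(coin(), coin()))
        assert mutual_information_discrete(j, ["a"], ["b"]) == pytest.approx(0.0, abs=1e-12)

    def test_copied_bit_one(self):
        j = DiscreteJoint(["a", "b"], np.array([[0.5, 0.0], [0.0, 0.5]]))
        assert mutual_information_discrete(j, ["a"], ["b"]) == pytest.approx(1.0, abs=1e-12)

    def test_noisy_channel_matches_brute_force(self):
        tab = np.array([[0.4, 0.1], [0.1, 0.4]])
        j = DiscreteJoint(["a", "b"], tab)
        expected = (
            brute_entropy(tab.sum(axis=1)) + brute_entropy(tab.sum(axis=0))
            - brute_entropy(tab)
        )
        got = mutual_information_discrete(j, ["a"], ["b"])
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.27807190511263774, abs=1e-12)

    def test_overlapping_groups_rejected(self, rng):
        j = DiscreteJoint.random([2, 2], rng)
        with pytest.raises(ValidationError):
            mutual_information_discrete(j, ["V0"], ["V0", "V1"])


class TestTotalCorrelation:
    def test_product_joint_zero(self, rng):
        tab = np.einsum("i,j,k->ijk", coin(0.3), coin(0.6), coin(0.5))
        j = DiscreteJoint(["a", "b", "c"], tab)
        assert total_correlation_discrete(j) == pytest.approx(0.0, abs=1e-10)

    def test_two_variables_equals_mi(self, rng):
        for _ in range(20):
            j = DiscreteJoint.random([3, 4], rng)
            assert total_correlation_discrete(j) == pytest.approx(
                mutual_information_discrete(j, ["V0"], ["V1"]), abs=1e-12
            )

    def test_three_synchronized_coins(self):
        tab = np.zeros((2, 2, 2))
        tab[0, 0, 0] = tab[1, 1, 1] = 0.5
        j = DiscreteJoint(["a", "b", "c"], tab)
        assert total_correlation_discrete(j) == pytest.approx(2.0, abs=1e-12)

    def test_single_variable_rejected(self):
        with pytest.raises(ValidationError):
            total_correlation_discrete(DiscreteJoint(["a"], coin()))

    def test_sum_of_entropies_equals_kl_form(self, rng):
        for _ in range(100):
            cards = [2, 2, rng.integers(2, 4)]
            j = DiscreteJoint.random(cards, rng)
            assert total_correlation_discrete(j) == pytest.approx(
                total_correlation_discrete_kl(j), abs=1e-10
            )


class TestConditionalTC:
    @staticmethod
    def common_cause_joint():
        # Y fair coin, X1 = X2 = Y
        tab = np.zeros((2, 2, 2))  # axes: X1, X2, Y
        tab[0, 0, 0] = tab[1, 1, 1] = 0.5
        return DiscreteJoint(["X1", "X2", "Y"], tab)

    def test_common_cause_explains_everything(self):
        j = self.common_cause_joint()
        assert conditional_total_correlation_discrete(j, ["X1", "X2"], ["Y"]) == \
            pytest.approx(0.0, abs=1e-12)
        assert total_correlation_discrete(j.marginal(["X1", "X2"])) == \
            pytest.approx(1.0, abs=1e-12)

    def test_empty_conditioner_degenerates_to_tc(self, rng):
        j = DiscreteJoint.random([2, 3, 2], rng)
        assert conditional_total_correlation_discrete(j, ["V0", "V1"], []) == \
            pytest.approx(total_correlation_discrete(j.marginal(["V0", "V1"])), abs=1e-12)

    def test_non_negative_on_random_joints(self, rng):
        for _ in range(50):
            j = DiscreteJoint.random([2, 2, 2], rng)
            assert conditional_total_correlation_discrete(j, ["V0", "V1"], ["V2"]) >= -1e-12


class TestDecompositionIdentity:
    def test_common_cause_residual_zero(self):
        j = TestConditionalTC.common_cause_joint()
        assert tc_decomposition_residual(j, ["X1", "X2"], ["Y"]) < 1e-10

    def test_product_joint_residual_zero(self):
        tab = np.einsum("i,j,k->ijk", coin(), coin(), coin())
        j = DiscreteJoint(["a", "b", "c"], tab)
        assert tc_decomposition_residual(j, ["a", "b"], ["c"]) < 1e-10

    def test_random_joints_residual_zero(self, rng):
        for _ in range(100):
            j = DiscreteJoint.random([2, 2, 2, 2], rng)
            assert tc_decomposition_residual(j, ["V0", "V1", "V2"], ["V3"]) < 1e-10


# ------------------------------------------------------------------- Gaussian
class TestGaussianTC:
    def test_identity_zero(self):
        assert gaussian_total_correlation(np.eye(5)) == pytest.approx(0.0, abs=1e-12)

    def test_bivariate_closed_form(self):
        rho = 0.5
        got = gaussian_total_correlation([[1, rho], [rho, 1]])
        assert got == pytest.approx(-0.5 * np.log2(1 - rho ** 2), abs=1e-12)
        assert got == pytest.approx(0.2075, abs=1e-4)

    def test_equicorrelated_matches_determinant_oracle(self):
        cov = 0.5 * np.ones((3, 3)) + 0.5 * np.eye(3)
        expected = 0.5 * np.log2(1.0 / np.linalg.det(cov))  # det = 0.5
        assert gaussian_total_correlation(cov) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.5, abs=1e-12)

    def test_non_pd_rejected(self):
        with pytest.raises(ValidationError):
            GaussianModel(np.array([[1.0, 2.0], [2.0, 1.0]]))


# ----------------------------------------------------------------- estimators
class TestBinnedEstimator:
    def test_equal_frequency_bins_balanced(self, rng):
        x = rng.standard_normal(1000)
        b = equal_frequency_bins(x, 8)
        assert np.bincount(b, minlength=8).tolist() == [125] * 8

    def test_duplicated_pair_saturates_at_log_bins(self, rng):
        x = rng.standard_normal(5000)
        ts = TimeSeriesMatrix(np.column_stack([x, x]), ["a", "b"])
        assert binned_tc_estimate(ts, 8) == pytest.approx(3.0, abs=1e-6)

    def test_independent_columns_near_zero_large_n(self):
        rng = np.random.default_rng(7)
        ts = TimeSeriesMatrix(rng.standard_normal((10000, 3)), ["a", "b", "c"])
        assert 0 <= binned_tc_estimate(ts, 8) <= 0.15

    def test_two_variables_equals_pairwise_mi(self, rng):
        from tcnet.connectivity import pairwise_mi

        ts = TimeSeriesMatrix(rng.standard_normal((500, 2)), ["a", "b"])
        assert binned_tc_estimate(ts, 6) == pytest.approx(
            pairwise_mi(ts, "binned", 6).values[0, 1], abs=1e-12
        )

    def test_constant_column_rejected(self):
        ts = TimeSeriesMatrix(np.column_stack([np.ones(50), np.arange(50.0)]))
        with pytest.raises(ValidationError):
            binned_tc_estimate(ts, 4)


class TestCopulaEstimator:
    def test_independent_near_zero(self):
        rng = np.random.default_rng(11)
        ts = TimeSeriesMatrix(rng.standard_normal((5000, 3)), ["a", "b", "c"])
        assert abs(copula_tc_estimate(ts)) <= 0.05

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], 800)
        ts = TimeSeriesMatrix(x, ["a", "b"])
        warped = TimeSeriesMatrix(
            np.column_stack([np.exp(x[:, 0]), x[:, 1] ** 3]), ["a", "b"]
        )
        assert copula_tc_estimate(warped) == pytest.approx(
            copula_tc_estimate(ts), abs=1e-12
        )

    def test_bivariate_gaussian_recovers_closed_form(self):
        rng = np.random.default_rng(3)
        rho = 0.8
        x = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], 5000)
        got = copula_tc_estimate(TimeSeriesMatrix(x, ["a", "b"]))
        assert got == pytest.approx(-0.5 * np.log2(1 - rho ** 2), abs=0.05)

    def test_fewer_rows_than_columns_rejected(self, rng):
        ts = TimeSeriesMatrix(rng.standard_normal((3, 3)), ["a", "b", "c"])
        with pytest.raises(ValidationError):
            copula_tc_estimate(ts)


class TestRenyiEstimator:
    def test_independent_triplet_near_zero(self):
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ts = TimeSeriesMatrix(rng.standard_normal((500, 3)), ["a", "b", "c"])
            vals.append(renyi_matrix_tc(ts, alpha=1.01))
        assert abs(np.median(vals)) <= 0.15
        assert all(v >= -1e-8 for v in vals)

    def test_duplicated_columns_strongly_dependent(self, rng):
        x = rng.standard_normal(300)
        dup = renyi_matrix_tc(TimeSeriesMatrix(np.column_stack([x, x]), ["a", "b"]))
        ind = renyi_matrix_tc(
            TimeSeriesMatrix(rng.standard_normal((300, 2)), ["a", "b"])
        )
        assert dup >= 0
        assert dup > ind + 0.5

    def test_alpha_one_rejected(self, rng):
        ts = TimeSeriesMatrix(rng.standard_normal((50, 2)), ["a", "b"])
        with pytest.raises(ValidationError):
            renyi_matrix_tc(ts, alpha=1.0)

    def test_degenerate_column_rejected(self):
        ts = TimeSeriesMatrix(np.column_stack([np.ones(20), np.arange(20.0)]))
        with pytest.raises(ValidationError):
            renyi_matrix_tc(ts)


class TestEstimatorAgreement:
    def test_copula_and_binned_approach_gaussian_oracle(self):
        """Median |error| vs the closed form shrinks as n grows (rho=0.5)."""
        cov = 0.5 * np.ones((3, 3)) + 0.5 * np.eye(3)
        true = gaussian_total_correlation(cov)
        chol = np.linalg.cholesky(cov)
        med_b, med_c = [], []
        for n in (100, 1000):
            eb, ec = [], []
            k = max(2, int((n / 10) ** (1 / 3)))
            for seed in range(10):
                rng = np.random.default_rng(seed)
                ts = TimeSeriesMatrix(rng.standard_normal((n, 3)) @ chol.T,
                                      ["a", "b", "c"])
                eb.append(abs(binned_tc_estimate(ts, k) - true))
                ec.append(abs(copula_tc_estimate(ts) - true))
            med_b.append(np.median(eb))
            med_c.append(np.median(ec))
        assert med_b[1] < med_b[0]
        assert med_c[1] < med_c[0]
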