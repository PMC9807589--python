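"""Monomial dictionary, decomposition recursions, oracle equivalence."""

import numpy as np
import pytest

from canondx import (
    DegenerateBlockError,
    Monomial,
    MomentTable,
    build_canonical_model,
    build_dictionary,
    enumerate_monomials,
    extract_coefficients,
    gram_schmidt_oracle,
    reconstruct_first_component,
    select_decision_coefficients,
)


class TestEnumeration:
    def test_block_one_is_pure_powers(self):
        mons = enumerate_monomials(1, N=4, B=3)
        assert [(m.lags, m.powers) for m in mons] == [((), (1,)), ((), (2,)), ((), (3,))]

    def test_block_two_ends_with_lagged_square(self):
        mons = enumerate_monomials(2, N=4, B=3)
        assert mons[-1] == Monomial(2, (1,), (1, 2))

    def test_block_three_full_census(self):
        mons = enumerate_monomials(3, N=4, B=3)
        assert len(mons) == 10
        assert sum(m.g == 1 for m in mons) == 3
        assert sum(m.g == 2 for m in mons) == 6
        assert mons[-1] == Monomial(3, (1, 2), (1, 1, 1))

    def test_dictionary_sizes(self):
        assert build_dictionary(1, 2, 1).size == 1
        assert build_dictionary(3, 4, 3).size == 19

    def test_block_partition(self):
        order = build_dictionary(6, 4, 3)
        covered = []
        for nu in range(1, 7):
            sl = order.block_slice(nu)
            covered.extend(range(sl.start, sl.stop))
            assert all(m.nu == nu for m in order.monomials[sl])
        assert covered == list(range(order.size))

    @pytest.mark.parametrize("nu", [1, 2, 4, 6])
    def test_monotone_nesting_in_N_and_B(self, nu):
        small_B = set(enumerate_monomials(nu, N=4, B=2))
        big_B = set(enumerate_monomials(nu, N=4, B=3))
        assert small_B <= big_B
        small_N = set(enumerate_monomials(nu, N=3))
        big_N = set(enumerate_monomials(nu, N=4))
        assert small_N <= big_N
        linear = set(enumerate_monomials(nu, N=2, B=1))
        assert linear <= small_N

    def test_invalid_monomial_rejected(self):
        with pytest.raises(Exception):
            Monomial(2, (2,), (1, 1))  # lag exceeds nu - 1


def _linear_two_feature_stats(data):
    """Sample quantities (denominator L) for the closed-form linear model."""
    m = data.mean(axis=0)
    c = data - m
    v1 = (c[:, 0] ** 2).mean()
    v2 = (c[:, 1] ** 2).mean()
    cov = (c[:, 0] * c[:, 1]).mean()
    return m, v1, v2, cov


class TestBuildModel:
    def test_linear_two_feature_closed_form(self, rng):
        data = rng.multivariate_normal([0, 0], [[1.0, 0.6], [0.6, 1.0]], size=400)
        m, v1, v2, cov = _linear_two_feature_stats(data)
        order = build_dictionary(2, N=2, B=1)
        model = build_canonical_model(MomentTable(data), order)
        # one-step regression: omega = cov/v1, D2 = v2 - cov^2/v1
        assert model.omega[0, 1] == pytest.approx(cov / v1, rel=1e-10)
        assert model.variances[0] == pytest.approx(v1, rel=1e-10)
        assert model.variances[1] == pytest.approx(v2 - cov**2 / v1, rel=1e-10)

    def test_self_coordinate_function_is_unity(self, gaussian_table):
        order = build_dictionary(5, N=3)
        model = build_canonical_model(gaussian_table, order)
        for m in model.active:
            assert model.omega[m, m] == 1.0

    def test_constant_training_data_fully_degenerate(self):
        data = np.full((10, 3), 2.5)
        model = build_canonical_model(MomentTable(data), build_dictionary(3, N=3))
        assert model.degenerate.all()
        assert model.active.size == 0
        assert all(v is None for v in model.decision_indices.values())

    def test_variance_decay_of_power_one(self, gaussian_table):
        order = build_dictionary(5, N=4)
        model = build_canonical_model(gaussian_table, order)
        for nu in range(2, 6):
            idx = order.first_power_index(nu)
            spec = order.monomials[idx].spec()
            raw_var = gaussian_table.central_mixed_moment(spec, spec)
            assert model.variances[idx] <= raw_var + 1e-12

    def test_sample_rank_budget_enforced(self, rng):
        # 4 rows -> at most 3 non-degenerate coefficients
        data = rng.standard_normal((4, 5))
        model = build_canonical_model(MomentTable(data), build_dictionary(5, N=4))
        assert model.active.size <= 3


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(6))
    def test_recursion_matches_gram_schmidt(self, seed):
        rng = np.random.default_rng(seed)
        I = int(rng.integers(2, 6))
        N = int(rng.integers(2, 5))
        X = rng.standard_normal((150, I)) * rng.uniform(0.5, 2.0, size=I)
        X += 0.4 * rng.standard_normal((150, 1))
        order = build_dictionary(I, N=N)
        t1, t2 = MomentTable(X), MomentTable(X)
        a = build_canonical_model(t1, order)
        b = gram_schmidt_oracle(t2, order)
        assert (a.degenerate == b.degenerate).all()
        np.testing.assert_allclose(a.variances, b.variances, atol=1e-8)
        np.testing.assert_allclose(a.omega, b.omega, atol=1e-8)

    def test_oracle_coefficient_gram_is_diagonal(self, gaussian_training):
        order = build_dictionary(5, N=3)
        model = gram_schmidt_oracle(MomentTable(gaussian_training), order)
        P = extract_coefficients(model, gaussian_training.values)
        G = P.T @ P / P.shape[0]
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8


class TestCoefficients:
    def test_mean_realization_maps_to_zero_linear(self, rng):
        data = rng.normal(2.0, 1.5, size=(100, 3))
        order = build_dictionary(3, N=2, B=1)
        model = build_canonical_model(MomentTable(data), order)
        p = extract_coefficients(model, data.mean(axis=0))
        np.testing.assert_allclose(p, 0.0, atol=1e-10)

    def test_two_feature_hand_recursion(self, rng):
        data = rng.multivariate_normal([1, -1], [[1, 0.5], [0.5, 2]], size=300)
        m, v1, v2, cov = _linear_two_feature_stats(data)
        order = build_dictionary(2, N=2, B=1)
        model = build_canonical_model(MomentTable(data), order)
        c = np.array([0.7, -0.2])
        p = extract_coefficients(model, c)
        rho = cov / v1
        assert p[0] == pytest.approx(c[0] - m[0], rel=1e-12)
        assert p[1] == pytest.approx((c[1] - m[1]) - rho * p[0], rel=1e-10)
        # hand expansion back
        rec = reconstruct_first_component(model, p)
        assert rec[0] == pytest.approx(m[0] + p[0])
        assert rec[1] == pytest.approx(m[1] + rho * p[0] + p[1])

    def test_training_coefficients_whitened(self, gaussian_training):
        order = build_dictionary(5, N=4)
        model = build_canonical_model(MomentTable(gaussian_training), order)
        P = extract_coefficients(model, gaussian_training.values)
        G = P.T @ P / P.shape[0]
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_reconstruction_round_trip(self, gaussian_training, rng):
        order = build_dictionary(5, N=3)
        model = build_canonical_model(MomentTable(gaussian_training), order)
        probe = rng.standard_normal((20, 5))
        P = extract_coefficients(model, probe)
        rec = reconstruct_first_component(model, P)
        np.testing.assert_allclose(rec, probe, atol=1e-10)

    def test_zero_coefficients_give_mean_function(self, gaussian_training):
        order = build_dictionary(5, N=3)
        model = build_canonical_model(MomentTable(gaussian_training), order)
        rec = reconstruct_first_component(model, np.zeros(order.size))
        np.testing.assert_allclose(rec, model.mean, atol=1e-12)


class TestDecisionSelection:
    def test_order_four_names_match_canonical_rule(self, gaussian_training):
        # blocks 1..3 at N=4: power 3; lag 1 powers (1,2); lags (1,2) powers (1,1,1)
        order = build_dictionary(5, N=4)
        model = build_canonical_model(MomentTable(gaussian_training), order)
        decision = select_decision_coefficients(model)
        assert decision[0] == Monomial(1, (), (3,))
        assert decision[1] == Monomial(2, (1,), (1, 2))
        assert decision[2] == Monomial(3, (1, 2), (1, 1, 1))

    def test_linear_dictionary_selects_power_one(self, gaussian_training):
        order = build_dictionary(5, N=2, B=1)
        model = build_canonical_model(MomentTable(gaussian_training), order)
        decision = select_decision_coefficients(model)
        assert [m.powers for m in decision] == [(1,)] * 5

    def test_fully_degenerate_block_raises_naming_block(self, rng):
        # 3 rows -> rank budget 2: later blocks exhaust and degenerate
        data = rng.standard_normal((3, 4))
        model = build_canonical_model(MomentTable(data), build_dictionary(4, N=4))
        with pytest.raises(DegenerateBlockError, match=r"i=\d"):
            select_decision_coefficients(model)
        # non-strict mode simply omits dead blocks
        partial = select_decision_coefficients(model, strict=False)
        assert len(partial) < 4
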