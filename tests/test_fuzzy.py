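import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fisim.fuzzy import (
    density_grid,
    fisim,
    fuzzy_distance,
    membership_grid,
    row_measure,
    solve_lambda,
    sugeno_row,
)
from fisim.markov import TransitionMatrix
from oracles import (
    lambda_root_oracle,
    random_stochastic_matrix,
    sugeno_subset_oracle,
)


def _tm(rows, step=1):
    return TransitionMatrix(p=np.array(rows, dtype=float), step=step)


ROW_A_FIRST = _tm([[1, 0, 0, 0]] * 4)
ROW_T_FIRST = _tm([[0, 1, 0, 0]] * 4)


class TestGrids:
    def test_membership_of_identical_matrices_is_one(self, random_transition_matrix):
        P = random_transition_matrix()
        assert np.all(membership_grid(P, P).h == 1.0)

    def test_membership_forced_arithmetic(self):
        h = membership_grid(ROW_A_FIRST, ROW_T_FIRST).h
        assert np.allclose(h[0], [0, 0, 1, 1])

    def test_membership_symmetric(self, random_transition_matrix):
        P1, P2 = random_transition_matrix(), random_transition_matrix()
        assert np.array_equal(membership_grid(P1, P2).h,
                              membership_grid(P2, P1).h)

    def test_density_of_identical_matrices_is_matrix(self, random_transition_matrix):
        P = random_transition_matrix()
        mu = density_grid(P, P).mu
        assert np.array_equal(mu, P.p)
        assert np.allclose(mu.sum(axis=1), 1.0)

    def test_density_is_cellwise_max(self, random_transition_matrix):
        P1, P2 = random_transition_matrix(), random_transition_matrix()
        mu = density_grid(P1, P2).mu
        assert np.all(mu >= P1.p) and np.all(mu >= P2.p)
        assert np.allclose(mu, np.maximum(P1.p, P2.p))
        assert np.allclose(density_grid(ROW_A_FIRST, ROW_T_FIRST).mu[0],
                           [1, 1, 0, 0])

    def test_step_mismatch_rejected(self, random_transition_matrix):
        P1 = random_transition_matrix(step=1)
        P2 = random_transition_matrix(step=2)
        with pytest.raises(ValueError, match="step"):
            membership_grid(P1, P2)
        with pytest.raises(ValueError, match="step"):
            density_grid(P1, P2)
        with pytest.raises(ValueError, match="step"):
            fisim(P1, P2)


class TestSolveLambda:
    def test_additive_case(self):
        assert solve_lambda((0.25, 0.25, 0.25, 0.25)) == 0.0

    def test_half_densities_root(self):
        lam = solve_lambda((0.5, 0.5, 0.5, 0.5))
        # independent bracketing: the cubic lam^3/16 + lam^2/2 + 3 lam/2 + 1
        oracle = np.roots([1 / 16, 1 / 2, 3 / 2, 1])
        oracle = [r.real for r in oracle if abs(r.imag) < 1e-12 and -1 < r.real < 0]
        assert lam == pytest.approx(oracle[0], abs=1e-12)
        assert lam == pytest.approx(-0.9127, abs=1e-4)

    def test_degenerate_zero_one_pattern(self):
        # (1+lam)^2 = 1+lam has only the trivial roots; fallback is 0
        assert solve_lambda((1.0, 1.0, 0.0, 0.0)) == 0.0

    def test_residual_and_range(self, rng):
        for _ in range(200):
            mu = np.maximum(rng.dirichlet(np.ones(4)), rng.dirichlet(np.ones(4)))
            lam = solve_lambda(mu)
            assert -1.0 < lam <= 0.0
            residual = np.prod(1.0 + lam * mu) - (1.0 + lam)
            assert abs(residual) < 1e-12

    def test_sum_below_one_gives_positive_lambda(self):
        lam = solve_lambda((0.1, 0.1, 0.1, 0.1))
        assert lam > 0.0
        assert abs(np.prod(1.0 + lam * np.full(4, 0.1)) - (1.0 + lam)) < 1e-12

    def test_out_of_range_density_rejected(self):
        with pytest.raises(ValueError):
            solve_lambda((0.5, 0.5, 0.5, 1.5))
        with pytest.raises(ValueError):
            solve_lambda((-0.1, 0.5, 0.5, 0.5))

    def test_matches_polynomial_oracle(self, rng):
        for _ in range(100):
            mu = np.maximum(random_stochastic_matrix(rng)[0],
                            random_stochastic_matrix(rng)[0])
            assert solve_lambda(mu) == pytest.approx(lambda_root_oracle(mu),
                                                     abs=1e-10)


class TestRowMeasure:
    def test_additive_cumulative(self):
        m = row_measure((1, 1, 1, 1), (0.25, 0.25, 0.25, 0.25))
        assert m.lam == 0.0
        assert m.cumulative == pytest.approx((0.25, 0.5, 0.75, 1.0), abs=1e-12)
        assert m.order == (0, 1, 2, 3)  # stable ties keep A,T,G,C order

    def test_degenerate_row_clamps(self):
        m = row_measure((0, 0, 1, 1), (1, 1, 0, 0))
        assert m.order == (2, 3, 0, 1)
        assert m.lam == 0.0
        assert m.cumulative == (0.0, 0.0, 1.0, 1.0)

    def test_cumulative_non_decreasing(self, rng):
        for _ in range(100):
            h = rng.random(4)
            mu = np.maximum(rng.dirichlet(np.ones(4)), rng.dirichlet(np.ones(4)))
            m = row_measure(h, mu)
            assert all(a <= b + 1e-15 for a, b in
                       zip(m.cumulative, m.cumulative[1:]))
            assert m.cumulative[0] == pytest.approx(m.densities[0])
            assert m.cumulative[3] == pytest.approx(1.0, abs=1e-9)


class TestSugeno:
    def test_full_evidence_gives_one(self, rng):
        mu = np.maximum(rng.dirichlet(np.ones(4)), rng.dirichlet(np.ones(4)))
        assert sugeno_row(row_measure((1, 1, 1, 1), mu)) == pytest.approx(1.0)

    def test_no_evidence_gives_zero(self, rng):
        mu = rng.dirichlet(np.ones(4))
        assert sugeno_row(row_measure((0, 0, 0, 0), mu)) == 0.0

    def test_matches_subset_oracle(self, rng):
        for _ in range(300):
            h = rng.random(4)
            mu = np.maximum(rng.dirichlet(np.ones(4)), rng.dirichlet(np.ones(4)))
            ours = sugeno_row(row_measure(h, mu))
            assert ours == pytest.approx(sugeno_subset_oracle(h, mu), abs=1e-12)


class TestSimilarityDistance:
    def test_self_similarity_is_one(self, random_transition_matrix):
        P = random_transition_matrix()
        assert fisim(P, P) == pytest.approx(1.0, abs=1e-12)
        assert fuzzy_distance(P, P) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_degenerate_matrices(self):
        assert fisim(ROW_A_FIRST, ROW_T_FIRST) == 0.0
        assert fuzzy_distance(ROW_A_FIRST, ROW_T_FIRST) == 1.0

    def test_symmetry_bit_exact(self, rng):
        for _ in range(50):
            P1 = TransitionMatrix(p=random_stochastic_matrix(rng))
            P2 = TransitionMatrix(p=random_stochastic_matrix(rng))
            assert fisim(P1, P2) == fisim(P2, P1)

    def test_distance_bounds(self, rng):
        for _ in range(50):
            P1 = TransitionMatrix(p=random_stochastic_matrix(rng))
            P2 = TransitionMatrix(p=random_stochastic_matrix(rng))
            assert 0.0 <= fuzzy_distance(P1, P2) <= 1.0

    def test_same_chain_closer_than_separated_chains(self):
        """Long sequences from one chain are nearer than from distant chains."""
        from fisim.markov import transition_matrix_from_record
        from fisim.synthetic import ChainSpec, simulate_sequence

        P_a = _tm([[0.7, 0.1, 0.1, 0.1],
                   [0.1, 0.7, 0.1, 0.1],
                   [0.1, 0.1, 0.7, 0.1],
                   [0.1, 0.1, 0.1, 0.7]])
        P_b = _tm([[0.1, 0.3, 0.3, 0.3],
                   [0.3, 0.1, 0.3, 0.3],
                   [0.3, 0.3, 0.1, 0.3],
                   [0.3, 0.3, 0.3, 0.1]])
        init = np.full(4, 0.25)

        def seq_matrix(P, seed):
            spec = ChainSpec(P=P, initial=init, length=50_000, seed=seed)
            return transition_matrix_from_record(simulate_sequence(spec))

        same = fuzzy_distance(seq_matrix(P_a, 1), seq_matrix(P_a, 2))
        apart = fuzzy_distance(seq_matrix(P_a, 3), seq_matrix(P_b, 4))
        assert same < apart


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=4, max_size=4),
       st.lists(st.floats(0.01, 1.0), min_size=8, max_size=8))
def test_sugeno_oracle_equivalence_property(h, raw):
    row1 = np.array(raw[:4]) / sum(raw[:4])
    row2 = np.array(raw[4:]) / sum(raw[4:])
    mu = np.maximum(row1, row2)
    ours = sugeno_row(row_measure(h, mu))
    assert ours == pytest.approx(sugeno_subset_oracle(h, mu), abs=1e-12)
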