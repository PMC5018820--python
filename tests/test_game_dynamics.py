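import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import moran_absorption_oracle
from reciprobots.game_dynamics import (
    DegenerateGameError,
    PayoffMatrix,
    classify_two_strategy_game,
    invasion_threshold,
    load_payoffs,
    load_reference_payoffs,
    moran_fixation_probability,
    occupancy_histogram,
    save_payoffs,
    simulate_strategy_dynamics,
)


def two_by_two(R, T, P, S):
    """Cooperator/defector matrix from the standard payoff letters."""
    return PayoffMatrix(("coop", "defect"), np.array([[R, S], [T, P]], float))


class TestClassification:
    def test_reference_selfish_helper_is_prisoners_dilemma(self):
        m = load_reference_payoffs()
        assert classify_two_strategy_game(m, cooperator="Helper",
                                          defector="Selfish") == "prisoners_dilemma"

    @pytest.mark.parametrize(
        "R,T,P,S,label",
        [
            (3, 5, 1, 0, "prisoners_dilemma"),
            (3, 5, 0, 1, "snowdrift"),
            (5, 3, 1, 0, "stag_hunt"),
            (5, 3, 0, 1, "harmony"),
            (2, 2, 2, 2, "ambiguous"),
            (5, 1, 3, 0, "other"),  # deadlock-like ordering
        ],
    )
    def test_standard_orderings(self, R, T, P, S, label):
        assert classify_two_strategy_game(two_by_two(R, T, P, S),
                                          "coop", "defect") == label


class TestInvasionThreshold:
    def test_reciprocator_barrier_is_5_over_18(self):
        m = load_reference_payoffs()
        x = invasion_threshold(m, "Reciprocator", "Selfish")
        assert x == pytest.approx(5 / 18, abs=1e-15)

    def test_helper_cannot_invade_selfish(self):
        m = load_reference_payoffs()
        assert invasion_threshold(m, "Helper", "Selfish") is None

    def test_dominant_invader_threshold_zero(self):
        m = two_by_two(R=5, T=1, P=0, S=4)  # cooperation dominant
        assert invasion_threshold(m, "coop", "defect") == 0.0

    def test_identical_strategies_degenerate(self):
        m = PayoffMatrix(("a", "b"), np.array([[2.0, 2.0], [2.0, 2.0]]))
        with pytest.raises(DegenerateGameError):
            invasion_threshold(m, "a", "b")

    @given(st.integers(0, 2**32 - 1), st.floats(0.5, 20), st.floats(0, 50))
    @settings(max_examples=40, deadline=None)
    def test_invariance_under_affine_payoff_maps(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1, 10, (2, 2))
        m1 = PayoffMatrix(("i", "r"), p)
        m2 = PayoffMatrix(("i", "r"), p * scale + shift)
        try:
            x1 = invasion_threshold(m1, "i", "r")
        except DegenerateGameError:
            return
        x2 = invasion_threshold(m2, "i", "r")
        if x1 is None:
            assert x2 is None
        else:
            assert x2 == pytest.approx(x1, rel=1e-9)


class TestMoranFixation:
    def test_neutral_is_exactly_one_over_n(self):
        m = PayoffMatrix(("a", "b"), np.full((2, 2), 3.0))
        for n in (2, 5, 100):
            assert moran_fixation_probability(m, "a", "b", n) == pytest.approx(
                1.0 / n, abs=1e-14
            )

    def test_matches_markov_chain_absorption(self):
        rng = np.random.default_rng(71)
        for n in (3, 4, 5, 6):
            for _ in range(5):
                m = PayoffMatrix(("i", "r"), rng.uniform(0.5, 4.0, (2, 2)))
                rho = moran_fixation_probability(m, "i", "r", n)
                oracle = moran_absorption_oracle(m, "i", "r", n, 1.0)
                assert rho == pytest.approx(oracle, abs=1e-10)

    def test_constant_fitness_closed_form(self):
        # frequency-independent relative fitness r: rho = (1-1/r)/(1-1/r^N)
        for r in (0.5, 1.5, 3.0):
            m = PayoffMatrix(("i", "res"), np.array([[2.0 * r, 2.0 * r], [2.0, 2.0]]))
            for n in (4, 25, 100):
                rho = moran_fixation_probability(m, "i", "res", n)
                expected = (1 - 1 / r) / (1 - r ** -n)
                assert rho == pytest.approx(expected, rel=1e-12)

    def test_dominated_invader_fixes_below_neutral(self):
        m = two_by_two(R=2, T=5, P=3, S=1)  # cooperator dominated
        rho = moran_fixation_probability(m, "coop", "defect", 20)
        assert rho < 1 / 20

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_invader_payoffs(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1, 5, (2, 2))
        m = PayoffMatrix(("i", "r"), p)
        bumped = p.copy()
        bumped[0, :] += rng.uniform(0.1, 1.0)
        m2 = PayoffMatrix(("i", "r"), bumped)
        n = int(rng.integers(3, 30))
        assert moran_fixation_probability(m2, "i", "r", n) >= (
            moran_fixation_probability(m, "i", "r", n) - 1e-12
        )

    def test_zero_fitness_rejected(self):
        m = PayoffMatrix(("a", "b"), np.array([[0.0, 0.0], [1.0, 1.0]]))
        with pytest.raises(ValueError):
            moran_fixation_probability(m, "a", "b", 5, intensity=1.0)


class TestStrategyDynamics:
    def test_monomorphic_without_mutation_is_absorbing(self):
        m = load_reference_payoffs()
        tr = simulate_strategy_dynamics(m, 50, 0.0, 200, [50, 0, 0], 3)
        assert (tr.counts[:, 0] == 50).all()

    def test_counts_always_sum_to_n(self):
        m = load_reference_payoffs()
        tr = simulate_strategy_dynamics(m, 77, 5e-2, 500, [30, 30, 17], 4)
        assert (tr.counts.sum(axis=1) == 77).all()
        assert (tr.counts >= 0).all()

    def test_neutral_drift_fixes_at_initial_frequency(self):
        m = PayoffMatrix(("a", "b"), np.full((2, 2), 2.0))
        fixed_a = 0
        reps = 400
        for rep in range(reps):
            tr = simulate_strategy_dynamics(m, 24, 0.0, 3000, [8, 16],
                                            np.random.default_rng(rep))
            fixed_a += tr.counts[-1, 0] == 24
        p = fixed_a / reps
        se = np.sqrt((1 / 3) * (2 / 3) / reps)
        assert abs(p - 1 / 3) < 3 * se

    def test_invalid_init_rejected(self):
        m = load_reference_payoffs()
        with pytest.raises(ValueError):
            simulate_strategy_dynamics(m, 10, 0.0, 5, [5, 5, 5], 0)


class TestOccupancy:
    def test_constant_trajectory_single_bin_and_conservation(self):
        m = load_reference_payoffs()
        tr = simulate_strategy_dynamics(m, 60, 0.0, 150, [60, 0, 0], 5)
        hist = occupancy_histogram(tr, n_bins=20)
        assert hist.sum() == 151
        assert (hist > 0).sum() == 1

    def test_total_counts_conserved_generally(self):
        m = load_reference_payoffs()
        tr = simulate_strategy_dynamics(m, 40, 0.05, 400, [20, 10, 10], 6)
        assert occupancy_histogram(tr, n_bins=13).sum() == 401


class TestPayoffIO:
    def test_tsv_round_trip(self, tmp_path):
        m = load_reference_payoffs()
        p = tmp_path / "payoffs.tsv"
        save_payoffs(p, m)
        back = load_payoffs(p)
        assert back.strategy_names == m.strategy_names
        assert np.array_equal(back.payoffs, m.payoffs)

    def test_restriction_preserves_entries(self):
        m = load_reference_payoffs()
        sub = m.restrict(("Reciprocator", "Selfish"))
        assert sub.payoffs[0, 0] == 173 and sub.payoffs[0, 1] == 147
        assert sub.payoffs[1, 0] == 160 and sub.payoffs[1, 1] == 152
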