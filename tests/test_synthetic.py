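import math

import numpy as np
import pandas as pd
import pytest

from illdyn.prep import prepare_admission
from illdyn.entropy import count_transitions, entropy_matrix, shannon_entropy
from illdyn.synthetic import (
    ChainError,
    ChainSpec,
    CohortConfig,
    draw_chain_specs,
    generate_cohort,
    make_chain,
    simulate_admission,
    simulate_outcomes,
    simulate_states,
    stationary_distribution,
    true_entropy,
)


class TestMakeChain:
    def test_full_stickiness_is_identity(self):
        P = make_chain(ChainSpec(n_states=2, stickiness=1.0))
        np.testing.assert_allclose(P, np.eye(2))

    def test_uniform_row_at_quarter_stickiness(self):
        P = make_chain(ChainSpec(n_states=4, stickiness=0.25, spread="uniform"))
        np.testing.assert_allclose(P, np.full((4, 4), 0.25))

    def test_two_state_sticky(self):
        P = make_chain(ChainSpec(n_states=2, stickiness=0.9, spread="uniform"))
        np.testing.assert_allclose(P, [[0.9, 0.1], [0.1, 0.9]])

    @pytest.mark.parametrize("spread", ["uniform", "decay", "attract"])
    def test_rows_sum_to_one(self, spread):
        P = make_chain(ChainSpec(4, 0.6, spread, seed=3))
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert (P >= 0).all()

    def test_diagonal_equals_stickiness_uniform(self):
        P = make_chain(ChainSpec(5, 0.37, "uniform"))
        np.testing.assert_allclose(np.diag(P), 0.37)

    @pytest.mark.parametrize("bad", [-0.1, 1.1, np.nan])
    def test_invalid_stickiness(self, bad):
        with pytest.raises(ChainError):
            ChainSpec(stickiness=bad)


class TestStationaryDistribution:
    def test_symmetric_chain(self):
        pi = stationary_distribution([[0.9, 0.1], [0.1, 0.9]])
        np.testing.assert_allclose(pi, [0.5, 0.5], atol=1e-12)

    def test_doubly_stochastic(self):
        pi = stationary_distribution(np.full((4, 4), 0.25))
        np.testing.assert_allclose(pi, 0.25, atol=1e-12)

    def test_hand_solved_two_state(self):
        # balance: pi0 = 0.5 pi0 + 0.25 pi1 -> pi0 = pi1 / 2 -> (1/3, 2/3)
        pi = stationary_distribution([[0.5, 0.5], [0.25, 0.75]])
        np.testing.assert_allclose(pi, [1 / 3, 2 / 3], atol=1e-12)

    def test_reducible_chain_errors(self):
        with pytest.raises(ChainError):
            stationary_distribution(np.eye(2))

    def test_agrees_with_power_iteration(self, rng):
        # brute-force oracle: rows of P^1000 converge to the stationary law
        for _ in range(25):
            spec = ChainSpec(4, rng.uniform(0.1, 0.9), "attract",
                             tuple(rng.dirichlet(np.ones(4))))
            P = make_chain(spec)
            pi = stationary_distribution(P)
            Pn = np.linalg.matrix_power(P, 1000)
            np.testing.assert_allclose(Pn[0], pi, atol=1e-8)


class TestTrueEntropy:
    def test_uniform_4x4_is_ln16(self):
        assert true_entropy(np.full((4, 4), 0.25)) == pytest.approx(math.log(16), abs=1e-12)

    def test_degenerate_joint_law(self):
        assert true_entropy(np.eye(2), pi=np.array([1.0, 0.0])) == pytest.approx(0.0)

    def test_hand_evaluated_sticky_chain(self):
        # joint cells: two of 0.45 and two of 0.05
        expected = -(2 * 0.45 * math.log(0.45) + 2 * 0.05 * math.log(0.05))
        assert true_entropy([[0.9, 0.1], [0.1, 0.9]]) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(1.0182, abs=5e-5)

    def test_bounded_by_ln_k_squared(self, rng):
        for _ in range(50):
            P = make_chain(ChainSpec(4, rng.uniform(0, 1), "attract",
                                     tuple(rng.dirichlet(np.ones(4) * 0.5))))
            h = true_entropy(P)
            assert 0.0 <= h <= math.log(16) + 1e-12


class TestSimulateAdmission:
    def test_point_count_without_gaps(self):
        P = make_chain(ChainSpec(4, 0.8))
        series = simulate_admission(P, 14, gap_rate=0.0, seed=0)
        assert len(series) == 14 * 48 * 2
        _, states, report = prepare_admission(series)
        assert report["n_final"] == 672

    def test_identity_chain_stays_in_bin(self):
        series = simulate_admission(np.eye(4), 2, seed=5, start_state=2)
        assert np.all((series.scores >= 2) & (series.scores < 3))

    def test_scores_within_range(self, rng):
        P = make_chain(ChainSpec(4, 0.3, "attract", seed=9))
        series = simulate_admission(P, 7, seed=rng)
        assert series.scores.min() >= 0.0
        assert series.scores.max() <= 8.0

    def test_round_trip_recovers_states(self):
        P = make_chain(ChainSpec(4, 0.5))
        rng = np.random.default_rng(11)
        n_slots = 3 * 48
        states_true = simulate_states(P, n_slots, rng, start_state=0)
        rng2 = np.random.default_rng(11)
        series = simulate_admission(P, 3, gap_rate=0.0, seed=rng2, start_state=0)
        _, state_series, _ = prepare_admission(series)
        np.testing.assert_array_equal(state_series.states, states_true)

    def test_gap_rate_fraction_isolated(self):
        P = make_chain(ChainSpec(4, 0.8))
        series = simulate_admission(P, 100, gap_rate=0.05, seed=2)
        _, _, report = prepare_admission(series)
        n_iso = round(0.05 * 100 * 48)
        assert report["n_removed_nonadjacent"] == n_iso

    def test_duration_validation(self):
        with pytest.raises(ChainError):
            simulate_admission(np.eye(2), 0.5)


class TestSimulateOutcomes:
    def test_null_link_independent(self):
        cfg = CohortConfig(n_admissions=10_000, mortality_link=(-1.621, 0.0),
                           outcome_link=0.0, seed=1)
        rng = np.random.default_rng(1)
        H = rng.uniform(0.3, 2.5, 10_000)
        out = simulate_outcomes(H, cfg, rng)
        r = np.corrcoef(H, out["hospital_los_days"])[0, 1]
        assert abs(r) < 0.05

    def test_strong_link_correlates_with_composite(self):
        from illdyn.composite import composite_score

        cfg = CohortConfig(n_admissions=10_000, mortality_link=(-2.0, 2.0),
                           outcome_link=1.2, seed=2)
        rng = np.random.default_rng(2)
        H = rng.uniform(0.3, 2.5, 10_000)
        out = simulate_outcomes(H, cfg, rng)
        comp = composite_score(out)
        r = np.corrcoef(H, comp["composite"])[0, 1]
        assert r > 0.5

    def test_mortality_intercept_tuned(self):
        cfg = CohortConfig(n_admissions=20_000, mortality_link=(-1.621, 0.0), seed=3)
        rng = np.random.default_rng(3)
        H = rng.uniform(0.3, 2.5, 20_000)
        out = simulate_outcomes(H, cfg, rng)
        assert out["died"].mean() == pytest.approx(0.165, abs=0.01)

    def test_vent_never_exceeds_los(self, small_cohort):
        out = small_cohort["outcomes"]
        assert (out["vent_days"] <= out["hospital_los_days"]).all()
        assert (out["icu_los_days"] <= out["hospital_los_days"]).all()
        assert (out["hospital_los_days"] >= 1).all()


class TestGenerateCohort:
    def test_deterministic_byte_identical(self, tmp_path):
        cfg = CohortConfig(n_admissions=5, seed=42, duration_days_range=(1, 3))
        p1 = generate_cohort(cfg, tmp_path / "a")
        p2 = generate_cohort(cfg, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_all_tables_share_admission_ids(self, small_cohort):
        ids = set(small_cohort["truth"]["admission_id"])
        assert len(ids) == 40
        assert set(small_cohort["outcomes"]["admission_id"]) == ids
        assert set(small_cohort["scores"]["admission_id"]) == ids

    def test_seed_recorded_in_header(self, small_cohort):
        first = small_cohort["paths"]["scores"].read_text().splitlines()[0]
        assert first.startswith("# seed=7")

    def test_entropy_spectrum_spans(self, rng):
        cfg = CohortConfig(n_admissions=200, seed=0)
        specs = draw_chain_specs(cfg, rng)
        H = np.array([true_entropy(make_chain(s)) for s in specs])
        assert H.min() < 0.8 and H.max() > 2.0
        assert H.std() > 0.3


def test_empirical_entropy_consistency_subset():
    """Empirical transition-density entropy approaches the true value (spot check)."""
    spec = ChainSpec(4, 0.6, "uniform")
    P = make_chain(spec)
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        states = simulate_states(P, 20_001, rng)
        counts = np.zeros((4, 4), dtype=np.int64)
        np.add.at(counts, (states[:-1], states[1:]), 1)
        total = counts.sum()
        emp = -sum(c / total * math.log(c / total) for c in counts.flat if c)
        if abs(emp - true_entropy(P)) <= 0.02:
            hits += 1
    assert hits >= 9
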