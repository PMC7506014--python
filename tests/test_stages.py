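"""Collective action, fights, and myopic strategy revision."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hiercoop import ModelParams, fixture_society, init_society
from hiercoop.stages import (
    collective_action,
    expected_payoff,
    fight_stage,
    foresight_factor,
    myopic_best_action,
    pick_opponent,
    resolve_fight,
    revise_stage,
    utility,
)

from conftest import small_params


# ---------------------------------------------------------------------------
# Collective action


def test_collective_action_identical_groups():
    # all groups at X=4 with n=8: P=1, cooperators net 0, free riders net 1
    params = small_params(n=8, G=3, b=1.0, c=1.0)
    x = [1, 1, 1, 1, 0, 0, 0, 0] * 3
    soc = fixture_society({"n": 8, "x": x}, params=params)
    X, Xbar = collective_action(soc, params)
    assert Xbar == 4.0
    np.testing.assert_allclose(soc.pi_round, np.where(np.array(x) == 1, 0.0, 1.0))


def test_collective_action_unequal_groups():
    # X1=6, X2=2 -> Xbar=4; free riders earn 1.5 and 0.5 respectively
    params = small_params(n=8, G=2, b=1.0, c=1.0)
    x = [1] * 6 + [0] * 2 + [1] * 2 + [0] * 6
    soc = fixture_society({"n": 8, "x": x}, params=params)
    collective_action(soc, params)
    assert soc.pi_round[6] == pytest.approx(1.5)
    assert soc.pi_round[8 + 2] == pytest.approx(0.5)
    # cooperators pay c on top of the same share
    assert soc.pi_round[0] == pytest.approx(0.5)
    assert soc.pi_round[8] == pytest.approx(-0.5)


def test_collective_action_all_defect_defines_zero_production():
    params = small_params(n=4, G=2)
    soc = fixture_society({"n": 4, "x": [0] * 8}, params=params)
    X, Xbar = collective_action(soc, params)
    assert Xbar == 0.0
    np.testing.assert_array_equal(soc.pi_round, 0.0)


def test_collective_action_accumulates_group_effort():
    params = small_params(n=4, G=2)
    soc = fixture_society({"n": 4, "x": [1, 1, 0, 0, 1, 0, 0, 0]}, params=params)
    collective_action(soc, params)
    collective_action(soc, params)
    np.testing.assert_array_equal(soc.effort_total, [4.0, 2.0])


# ---------------------------------------------------------------------------
# Foresight and utility


def test_foresight_midpoint_and_symmetry():
    for gamma in (0.1, 0.5, 2.0):
        assert foresight_factor(0, gamma) == pytest.approx(0.5)
    assert foresight_factor(2, 0.5) == pytest.approx(1.0 / (1.0 + math.exp(-1.0)))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    r=st.integers(min_value=-25, max_value=25),
    gamma=st.floats(min_value=0.01, max_value=1.0),
)
def test_foresight_bounded_monotone_and_complementary(r, gamma):
    f = foresight_factor(r, gamma)
    assert 0.0 < f < 1.0
    assert foresight_factor(r, gamma) + foresight_factor(-r, gamma) == pytest.approx(1.0)
    assert foresight_factor(r + 1, gamma) > f


def test_utility_socialization_extremes():
    params = small_params(v=1.0, gamma=0.5)
    # undersocialized: pure discounted material payoff
    assert utility(1, 0.0, 3, 2.0, params) == pytest.approx(
        foresight_factor(3, 0.5) * 2.0
    )
    # oversocialized: pure norm satisfaction v*x
    assert utility(1, 1.0, -5, 99.0, params) == pytest.approx(1.0)
    assert utility(0, 1.0, -5, 99.0, params) == 0.0
    # mixed hand value: 0.5*0.5*2 + 0.5*1 = 1.0
    assert utility(1, 0.5, 0, 2.0, params) == pytest.approx(1.0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    eta=st.floats(min_value=0.0, max_value=1.0),
    r=st.integers(min_value=-20, max_value=20),
    pi=st.floats(min_value=-5.0, max_value=5.0),
    scale=st.floats(min_value=0.1, max_value=3.0),
)
def test_utility_linear_in_expected_payoff(eta, r, pi, scale):
    params = small_params()
    u0 = utility(1, eta, r, 0.0, params)
    assert utility(1, eta, r, scale * pi, params) - u0 == pytest.approx(
        scale * (utility(1, eta, r, pi, params) - u0), abs=1e-9
    )


# ---------------------------------------------------------------------------
# Fights


def test_pick_opponent_never_self_and_uniform():
    n = 6
    counts = np.zeros(n)
    for off in range(n - 1):
        j = pick_opponent(n, 2, off)
        assert j != 2
        counts[j] += 1
    assert counts[2] == 0
    assert set(np.flatnonzero(counts)) == {0, 1, 3, 4, 5}


def test_pick_opponent_two_agents_forced():
    assert pick_opponent(2, 0, 0) == 1
    assert pick_opponent(2, 1, 0) == 0


def test_resolve_fight_transfers_and_conserves():
    r = [3, 1]
    pi = [0.5, 2.0]
    w, l = resolve_fight(r, pi, 0, 1, lambda s, d: s + d, 0.9, u=0.1)
    assert (w, l) == (0, 1)
    assert pi == [2.5, 0.0]
    assert r == [4, 0]
    # losing branch of the same matchup
    r = [3, 1]
    pi = [0.5, 2.0]
    w, l = resolve_fight(r, pi, 0, 1, lambda s, d: s + d, 0.9, u=0.95)
    assert (w, l) == (1, 0)
    assert pi == [0.0, 2.5]


def test_higher_score_win_frequency_matches_p_win(rng):
    wins = 0
    trials = 20_000
    draws = rng.random(trials)
    for u in draws:
        w, _ = resolve_fight([3, 1], [0.0, 0.0], 0, 1, lambda s, d: s + d, 0.9, u)
        wins += w == 0
    # binomial 99% interval around 0.9 at 2e4 trials is ~ +/- 0.006
    assert wins / trials == pytest.approx(0.9, abs=0.01)


def test_equal_scores_are_a_fair_coin(rng):
    wins = 0
    trials = 20_000
    for u in rng.random(trials):
        w, _ = resolve_fight([2, 2], [0.0, 0.0], 0, 1, lambda s, d: s + d, 0.9, u)
        wins += w == 0
    assert wins / trials == pytest.approx(0.5, abs=0.015)


def test_fight_stage_conserves_group_payoff_and_score_sum():
    params = small_params(n=8, G=4, score_rule="unconstrained", seed=11)
    soc = init_society(params)
    collective_action(soc, params)
    before = soc.pi_round.reshape(4, 8).sum(axis=1).copy()
    fight_stage(soc, params)
    after = soc.pi_round.reshape(4, 8).sum(axis=1)
    np.testing.assert_allclose(after, before, atol=1e-12)
    # every fight awards +1 and -1, so group score sums stay exactly 0
    np.testing.assert_array_equal(soc.r.reshape(4, 8).sum(axis=1), 0)


def test_fight_stage_loser_forfeits_entire_holding():
    # 2-agent group: the single holder initiates against the other and,
    # with a losing draw guaranteed by score, the holding moves across.
    params = small_params(n=2, G=1, p_win=1.0)
    soc = fixture_society(
        {"n": 2, "x": [0, 0], "r": [0, 5], "pi_round": [3.0, 0.0]}, params=params
    )
    fight_stage(soc, params)
    assert soc.pi_round[0] == 0.0
    assert soc.pi_round[1] == pytest.approx(3.0)


def test_fight_stage_participation_counts():
    params = small_params(n=8, G=10, seed=5)
    soc = init_society(params)
    collective_action(soc, params)
    fight_stage(soc, params)
    counts = soc.fight_counts
    assert counts.min() >= 1
    assert counts.max() <= params.n
    assert counts.sum() == 2 * params.S  # each fight involves two agents


def test_pi_star_accumulates_post_fight_holdings():
    params = small_params(n=4, G=3, seed=2)
    soc = init_society(params)
    ledger = np.zeros(params.S)
    for _ in range(5):
        X, Xbar = collective_action(soc, params)
        fight_stage(soc, params)
        ledger += soc.pi_round
        revise_stage(soc, params, X, Xbar)
    np.testing.assert_allclose(soc.pi_star, ledger, atol=1e-12)


# ---------------------------------------------------------------------------
# Strategy revision


def test_no_revision_when_mu_zero():
    params = small_params(n=8, G=5, mu=0.0, seed=3)
    soc = init_society(params)
    x_before = soc.x.copy()
    X, Xbar = collective_action(soc, params)
    fight_stage(soc, params)
    revise_stage(soc, params, X, Xbar)
    np.testing.assert_array_equal(soc.x, x_before)


def test_pure_error_revision_is_a_fair_coin():
    params = small_params(n=8, G=50, mu=1.0, e=1.0, Q=10, T=10, seed=4)
    soc = init_society(params)
    fractions = []
    for _ in range(30):
        X, Xbar = collective_action(soc, params)
        fight_stage(soc, params)
        revise_stage(soc, params, X, Xbar)
        fractions.append(soc.x.mean())
    assert np.mean(fractions) == pytest.approx(0.5, abs=0.02)


def test_oversocialized_reviser_always_cooperates():
    params = small_params(n=4, G=2, mu=1.0, e=0.0, seed=6)
    soc = fixture_society(
        {"n": 4, "x": [0] * 8, "eta": [1.0] * 8, "r": [0] * 8}, params=params
    )
    X, Xbar = collective_action(soc, params)
    fight_stage(soc, params)
    revise_stage(soc, params, X, Xbar)
    np.testing.assert_array_equal(soc.x, 1)


def test_myopic_best_action_agrees_with_bruteforce_oracle(rng):
    """Vectorised revision picks the same action as direct enumeration."""
    params = small_params(b=1.0, c=1.0, v=1.0, gamma=0.5)

    def oracle(cur, eta, r, Xmi, Xbar):
        # independent arithmetic path: literal utility of each action
        best, ubest = None, None
        for xp in (0, 1):
            if Xbar > 0:
                pi = params.b * (Xmi + xp) / Xbar - params.c * xp
            else:
                pi = -params.c * xp
            u = (1 - eta) * (1.0 / (1.0 + math.exp(-params.gamma * r))) * pi
            u += params.v * eta * xp
            if ubest is None or u > ubest + 1e-15:
                best, ubest = xp, u
            elif abs(u - ubest) <= 1e-15:
                best = cur  # tie keeps the current action
        return best

    for _ in range(1_000):
        cur = int(rng.integers(0, 2))
        eta = float(rng.uniform(0, 1))
        r = int(rng.integers(-15, 16))
        Xmi = float(rng.integers(0, 8))
        Xbar = float(rng.choice([0.5, 1.0, 2.0, 4.0, 7.5]))
        u0 = utility(0, eta, r, expected_payoff(0, Xmi, Xbar, params), params)
        u1 = utility(1, eta, r, expected_payoff(1, Xmi, Xbar, params), params)
        if abs(u1 - u0) <= 1e-12:
            continue  # exact ties exercised separately
        assert myopic_best_action(cur, eta, r, Xmi, Xbar, params) == oracle(
            cur, eta, r, Xmi, Xbar
        )


def test_myopic_tie_keeps_current_action():
    params = small_params(b=1.0, c=1.0, v=1.0)
    # eta=0 and Xbar=b/c=1 makes both actions equally attractive
    assert myopic_best_action(1, 0.0, 0, 2.0, 1.0, params) == 1
    assert myopic_best_action(0, 0.0, 0, 2.0, 1.0, params) == 0
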