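"""The three within-round stages: collective action, fights, revision.

The simulation state is stored as flat per-agent arrays on a
:class:`~hiercoop.core.Society` (struct-of-arrays); agent ``i`` belongs
to group ``i // n``.  All randomness is drawn from the society's single
RNG stream in a fixed, documented order:

1. fight stage — one array of opponent offsets, one array of win draws
   (both of length S, agent-index order);
2. revision stage — one array of revision draws, one of error draws and
   one of random actions (length S each).

The fights themselves are resolved sequentially in initiator order
(group-major, agent-index order): a winner's augmented round payoff is
at stake again in later fights of the same round, and score changes
take effect immediately for later fights.
"""

from __future__ import annotations

import math
from typing import TYPE_CHECKING, MutableSequence

import numpy as np

from .params import ModelParams
from .score_rules import end_of_round_scores, per_fight_update

if TYPE_CHECKING:  # pragma: no cover
    from .core import Society

__all__ = [
    "collective_action",
    "foresight_factor",
    "expected_payoff",
    "utility",
    "myopic_best_action",
    "pick_opponent",
    "resolve_fight",
    "fight_stage",
    "revise_stage",
]


# ---------------------------------------------------------------------------
# Collective action


def collective_action(society: "Society", params: ModelParams) -> tuple[np.ndarray, float]:
    """Produce and share the public good; set every agent's round payoff.

    Group effort is ``X = sum of x`` over members, normalised by the
    society-wide mean effort ``Xbar``; every member of a group receives
    ``b * X / Xbar`` regardless of contribution, and cooperators pay the
    effort cost ``c``, so the round payoff is ``pi_CA = b*P(X) - c*x``.
    If nobody in the whole society cooperates (``Xbar == 0``) the
    normalised production is defined as 0 for all groups.

    Returns ``(X, Xbar)`` for use by the revision stage; also adds the
    group efforts to the generation's running ``effort_total``.
    """
    n, G = params.n, params.G
    X = society.x.reshape(G, n).sum(axis=1).astype(np.float64)
    Xbar = float(X.mean())
    if Xbar > 0.0:
        production = params.b * X / Xbar
    else:
        production = np.zeros(G)
    society.pi_round = np.repeat(production, n) - params.c * society.x
    society.effort_total += X
    return X, Xbar


# ---------------------------------------------------------------------------
# Utility and myopic optimisation


def foresight_factor(r: float, gamma: float) -> float:
    """Logistic discount ``F(r) = 1 / (1 + exp(-gamma * r))``.

    Captures a low-ranked agent's anticipation that resources will be
    lost to stronger group mates in future fights: strictly increasing
    in the score ``r``, bounded in (0, 1), with ``F(0) = 0.5``.
    """
    return 1.0 / (1.0 + math.exp(-gamma * r))


def expected_payoff(
    x: int, X_minus_i: float, Xbar: float, params: ModelParams
) -> float:
    """Myopic expected collective-action payoff of playing ``x``.

    Holds everyone else's current-round effort ``X_minus_i`` and the
    society mean effort ``Xbar`` fixed: ``b*(X_minus_i + x)/Xbar - c*x``.
    A society-wide zero effort (``Xbar == 0``) contributes 0 production.
    """
    if Xbar > 0.0:
        return params.b * (X_minus_i + x) / Xbar - params.c * x
    return -params.c * x


def utility(x: int, eta: float, r: float, pi_expected: float, params: ModelParams) -> float:
    """Norm-internalisation utility ``(1-eta)*F(r)*pi + v*eta*x``.

    The material term is the expected payoff discounted by the foresight
    factor; the normative term rewards following the cooperation norm
    (``x = 1``) in proportion to the internalisation trait ``eta``.
    """
    return (1.0 - eta) * foresight_factor(r, params.gamma) * pi_expected + params.v * eta * x


def myopic_best_action(
    current_x: int,
    eta: float,
    r: float,
    X_minus_i: float,
    Xbar: float,
    params: ModelParams,
) -> int:
    """Utility-maximising action; the current action is kept on a tie."""
    u0 = utility(0, eta, r, expected_payoff(0, X_minus_i, Xbar, params), params)
    u1 = utility(1, eta, r, expected_payoff(1, X_minus_i, Xbar, params), params)
    if u1 > u0:
        return 1
    if u0 > u1:
        return 0
    return current_x


# ---------------------------------------------------------------------------
# Fights


def pick_opponent(n: int, agent_local: int, offset: int) -> int:
    """Map a uniform draw on {0, .., n-2} to an opponent index != agent.

    ``offset`` is a draw from ``rng.integers(0, n - 1)``; offsets at or
    above the agent's own local index are shifted up by one, yielding a
    uniform choice over the other ``n - 1`` group members.
    """
    return offset + 1 if offset >= agent_local else offset


def resolve_fight(
    r: MutableSequence[int],
    pi: MutableSequence[float],
    i: int,
    j: int,
    update,
    p_win: float,
    u: float,
) -> tuple[int, int]:
    """Resolve one dyadic fight between agents ``i`` and ``j`` in place.

    The higher-scored contestant wins with probability ``p_win``; equal
    scores are decided by a fair coin.  The winner takes the loser's
    current round payoff and gains one score unit, the loser's payoff is
    zeroed and she loses one unit; score changes go through ``update``
    (the active score rule's per-fight updater).  ``u`` is a uniform
    [0, 1) draw.  Returns ``(winner, loser)`` indices.
    """
    ri, rj = r[i], r[j]
    if ri > rj:
        i_wins = u < p_win
    elif ri < rj:
        i_wins = u < 1.0 - p_win
    else:
        i_wins = u < 0.5
    w, l = (i, j) if i_wins else (j, i)
    pi[w] += pi[l]
    pi[l] = 0.0
    r[w] = update(r[w], +1)
    r[l] = update(r[l], -1)
    return w, l


def fight_stage(society: "Society", params: ModelParams) -> None:
    """Run the round's fights: every agent initiates exactly one.

    Initiators are processed in agent-index order; each picks a uniform
    opponent from the rest of her group, so an agent takes part in one
    to ``n`` fights per round (two on average).  Fights are resolved
    sequentially — payoffs captured earlier in the round are at stake in
    later fights.  After all fights, surviving round payoffs are
    accumulated into ``pi_star`` and, for the endogenous score rule, the
    per-round decay is applied.
    """
    n = params.n
    S = params.S
    rng = society.rng
    offsets = rng.integers(0, n - 1, size=S)
    draws = rng.random(S)
    p_win = params.p_win
    update = per_fight_update(params)

    r_start = society.r
    r = society.r.tolist()
    pi = society.pi_round.tolist()
    counts = [0] * S
    for i in range(S):
        base = i - i % n
        j = base + pick_opponent(n, i - base, int(offsets[i]))
        resolve_fight(r, pi, i, j, update, p_win, float(draws[i]))
        counts[i] += 1
        counts[j] += 1

    r_working = np.asarray(r, dtype=np.int64)
    society.r = end_of_round_scores(r_start, r_working, params)
    society.pi_round = np.asarray(pi, dtype=np.float64)
    society.pi_star += society.pi_round
    society.fight_counts = np.asarray(counts, dtype=np.int64)


# ---------------------------------------------------------------------------
# Strategy revision


def revise_stage(
    society: "Society", params: ModelParams, X: np.ndarray, Xbar: float
) -> None:
    """Myopic strategy revision with probability ``mu`` per agent.

    A revising agent picks, with probability ``1 - e``, the action that
    maximises her utility given everyone else's realised effort this
    round (``X_minus_i``) and her post-fight score; with probability
    ``e`` she picks uniformly at random.  Utility ties keep the current
    action.  Vectorised over the whole society; equivalent agent by
    agent to :func:`myopic_best_action`.
    """
    rng = society.rng
    S = params.S
    revise_draw = rng.random(S)
    error_draw = rng.random(S)
    random_x = rng.integers(0, 2, size=S).astype(np.int8)

    x = society.x
    X_minus_i = np.repeat(X, params.n) - x
    if Xbar > 0.0:
        pi0 = params.b * X_minus_i / Xbar
        pi1 = params.b * (X_minus_i + 1.0) / Xbar - params.c
    else:
        pi0 = np.zeros(S)
        pi1 = np.full(S, -params.c)
    material = (1.0 - society.eta) / (1.0 + np.exp(-params.gamma * society.r))
    u0 = material * pi0
    u1 = material * pi1 + params.v * society.eta
    best = np.where(u1 > u0, 1, np.where(u0 > u1, 0, x)).astype(np.int8)

    new_x = x.copy()
    revising = revise_draw < params.mu
    erring = revising & (error_draw < params.e)
    optimising = revising & ~erring
    new_x[optimising] = best[optimising]
    new_x[erring] = random_x[erring]
    society.x = new_x
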