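"""Score-update regimes applied to fight outcomes.

Scores are integer dominance indices updated by +1 (win) / -1 (loss).
Three regimes are supported:

``unconstrained``
    Scores grow and shrink without bound.
``exogenous``
    Scores are hard-clipped to the interval [0, n] (n = group size).
``endogenous``
    Scores decay multiplicatively toward zero as they are updated:
    ``r' = round((1 - lambda) * r + delta)``, rounded to the closest
    integer (ties away from zero, keeping the rule symmetric about 0).
    By default the decayed update is applied at every fight outcome
    (``delta = +/-1``); the alternative scope decays once per round on
    the net win/loss tally.  With ``lambda = 0`` either scope is
    identical, bit for bit, to the unconstrained regime.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np

from .params import ModelParams

__all__ = [
    "apply_unconstrained",
    "apply_exogenous",
    "apply_endogenous_decay",
    "per_fight_update",
    "round_half_away_from_zero",
]


def apply_unconstrained(r: int, delta: int) -> int:
    """Unbounded score update: ``r + delta``."""
    return r + delta


def apply_exogenous(r: int, delta: int, n: int) -> int:
    """Score update clipped to the interval [0, n]."""
    v = r + delta
    if v < 0:
        return 0
    if v > n:
        return n
    return v


def round_half_away_from_zero(v: float) -> int:
    """Round to the closest integer, ties going away from zero."""
    return int(math.copysign(math.floor(abs(v) + 0.5), v))


def apply_endogenous_decay(r: float, delta: int, lambda_decay: float) -> int:
    """Decayed score update ``round((1-lambda) * r + delta)``.

    Applied at every fight outcome (``delta = +/-1``) in the default
    per-fight scope, or once per round with ``delta`` the net win/loss
    tally in the per-round scope.
    """
    return round_half_away_from_zero((1.0 - lambda_decay) * r + delta)


def per_fight_update(params: ModelParams) -> Callable[[int, int], int]:
    """Return the per-fight score updater for the active regime.

    For the endogenous regime with per-round scope the per-fight update
    is unconstrained on a working score and the decay is applied once
    per round by :func:`end_of_round_scores`.
    """
    if params.score_rule == "exogenous":
        n = params.n
        return lambda r, delta: apply_exogenous(r, delta, n)
    if params.score_rule == "endogenous" and params.endogenous_decay_scope == "fight":
        lam = params.lambda_decay
        return lambda r, delta: apply_endogenous_decay(r, delta, lam)
    return apply_unconstrained


def end_of_round_scores(
    r_start: np.ndarray, r_working: np.ndarray, params: ModelParams
) -> np.ndarray:
    """Finalize scores at the end of a fight stage.

    ``r_start`` holds the scores at the beginning of the round and
    ``r_working`` the scores after applying the per-fight updates; the
    working scores are final except under the endogenous rule with
    per-round scope, which decays ``r_start`` and adds the net tally.
    """
    if params.score_rule != "endogenous" or params.endogenous_decay_scope == "fight":
        return r_working
    lam = params.lambda_decay
    decayed = (1.0 - lam) * r_start + (r_working - r_start)
    return np.sign(decayed).astype(np.int64) * np.floor(
        np.abs(decayed) + 0.5
    ).astype(np.int64)
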