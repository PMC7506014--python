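"""End-of-generation fitness, two-level selection, mutation, dispersal.

Reproduction is two-level: whole groups are sampled (with replacement)
in proportion to their collective effort accumulated over the
generation, then within each chosen parent group n parents are sampled
(with replacement) in proportion to individual fitness.  Offspring
inherit the internalisation trait eta subject to Gaussian mutation;
half of each new group then disperses through a global migrant pool.

RNG draw order within :func:`reproduce` (one global stream):

1. one choice of G parent-group indices;
2. for each new group in index order, one choice of n parent indices;
3. one array of S Gaussian mutation deviates;
4. one array of S Bernoulli(0.5) offspring actions;
5. dispersal — per group one choice of floor(n/2) migrant slots, then
   one permutation of the pooled migrants.
"""

from __future__ import annotations

from typing import TYPE_CHECKING

import numpy as np

from .params import ModelParams

if TYPE_CHECKING:  # pragma: no cover
    from .core import Society

__all__ = [
    "compute_fitness",
    "select_parent_groups",
    "select_parents_within_group",
    "mutate_eta",
    "disperse_offspring",
    "reproduce",
]


def compute_fitness(
    pi_star: np.ndarray | float, eta: np.ndarray | float, params: ModelParams
) -> np.ndarray | float:
    """Fitness ``w = 1 + pi_star/Q - c_opt*(1-eta) - c_int*eta``.

    The accumulated resources are normalised per round of the
    generation; the two cost terms charge payoff optimisation in
    proportion (1-eta) and norm internalisation in proportion eta.  With
    ``c_opt == c_int`` the direct cost is independent of eta.  Fitness
    may be nonpositive; selection clips negative values to weight 0.
    """
    return (
        1.0
        + np.asarray(pi_star) / params.Q
        - params.c_opt * (1.0 - np.asarray(eta))
        - params.c_int * np.asarray(eta)
    )


def _proportional_choice(
    weights: np.ndarray, size: int, rng: np.random.Generator
) -> np.ndarray:
    """``size`` draws with replacement, probability proportional to weight.

    Negative weights are clipped to zero; an all-zero weight vector
    falls back to a uniform choice.
    """
    w = np.clip(np.asarray(weights, dtype=np.float64), 0.0, None)
    total = w.sum()
    p = w / total if total > 0.0 else None
    return rng.choice(len(w), size=size, replace=True, p=p)


def select_parent_groups(
    effort_total: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """G parent-group indices, sampled proportionally to collective effort."""
    return _proportional_choice(effort_total, len(effort_total), rng)


def select_parents_within_group(
    fitness: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """n parent indices within a group, proportional to (clipped) fitness."""
    return _proportional_choice(fitness, len(fitness), rng)


def mutate_eta(
    eta: np.ndarray, params: ModelParams, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian mutation of eta, clipped to the trait range [0, 1]."""
    return np.clip(
        eta + rng.normal(0.0, params.mutation_sigma, size=np.shape(eta)), 0.0, 1.0
    )


def disperse_offspring(
    eta: np.ndarray, x: np.ndarray, params: ModelParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Disperse half of each new group through a global migrant pool.

    From every group floor(n/2) offspring slots are chosen uniformly
    without replacement; the pooled migrants are shuffled and written
    back into the vacated slots (sorted group-major order), so each
    group keeps exactly n members and the offspring multiset is
    unchanged.  Migrants may land back in their natal group.
    """
    n, G = params.n, params.G
    m = n // 2
    if m == 0 or G == 0:
        return eta, x
    slots = np.concatenate(
        [g * n + np.sort(rng.choice(n, size=m, replace=False)) for g in range(G)]
    )
    perm = rng.permutation(len(slots))
    eta = eta.copy()
    x = x.copy()
    eta[slots] = eta[slots][perm]
    x[slots] = x[slots][perm]
    return eta, x


def reproduce(society: "Society", params: ModelParams) -> None:
    """Replace the cohort with n*G offspring under two-level selection.

    Offspring eta is inherited from the parent and mutated; actions are
    re-randomised Bernoulli(0.5); scores, round payoffs and accumulated
    payoffs reset to zero.  The group effort tallies are reset for the
    next generation.
    """
    n, G, S = params.n, params.G, params.S
    rng = society.rng
    parent_groups = select_parent_groups(society.effort_total, rng)

    parent_eta = np.empty(S, dtype=np.float64)
    for k, src in enumerate(parent_groups):
        lo = src * n
        fit = society.fitness[lo : lo + n]
        parents = select_parents_within_group(fit, rng)
        parent_eta[k * n : (k + 1) * n] = society.eta[lo + parents]

    eta = mutate_eta(parent_eta, params, rng)
    x = rng.integers(0, 2, size=S).astype(np.int8)
    eta, x = disperse_offspring(eta, x, params, rng)

    society.eta = eta
    society.x = x
    society.r = np.zeros(S, dtype=np.int64)
    society.pi_round = np.zeros(S, dtype=np.float64)
    society.pi_star = np.zeros(S, dtype=np.float64)
    society.fitness = np.zeros(S, dtype=np.float64)
    society.effort_total = np.zeros(G, dtype=np.float64)
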