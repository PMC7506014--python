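"""State containers, initialization and the round/generation scheduler.

The society is stored struct-of-arrays: one flat length-S array per
agent attribute, agent ``i`` living in group ``i // n``.  A per-round
schedule is always collective action -> fights -> strategy revision;
reproduction runs at the end of every generation (Q rounds).

A single :class:`numpy.random.Generator` seeded from ``params.seed``
drives every stage in a fixed order, so a run is bit-reproducible from
its parameters alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import evolution, stages
from .params import ModelParams, ParameterError

__all__ = [
    "AgentState",
    "Society",
    "SummaryRecord",
    "Snapshot",
    "RunResult",
    "init_society",
    "run_round",
    "run_generation",
    "run",
]


@dataclass
class AgentState:
    """Scalar view of one agent's attributes.

    The simulation itself works on arrays; this record is the
    agent-level interface used by fixtures and tests.
    """

    x: int = 0  # cooperate (1) or free-ride (0) this round
    r: int = 0  # dominance score
    eta: float = 0.0  # norm internalisation, fixed within a lifetime
    pi_round: float = 0.0  # payoff currently held from this round
    pi_star: float = 0.0  # resources kept so far this generation
    fitness: float = 0.0  # computed at the end of the generation

    def __post_init__(self) -> None:
        if self.x not in (0, 1):
            raise ParameterError(f"x must be 0 or 1, got {self.x!r}")
        if not 0.0 <= self.eta <= 1.0:
            raise ParameterError(f"eta must lie in [0, 1], got {self.eta!r}")


@dataclass
class Society:
    """Full mutable simulation state (struct-of-arrays)."""

    params: ModelParams
    x: np.ndarray  # int8, shape (S,)
    r: np.ndarray  # int64, shape (S,)
    eta: np.ndarray  # float64, shape (S,)
    pi_round: np.ndarray  # float64, shape (S,)
    pi_star: np.ndarray  # float64, shape (S,)
    fitness: np.ndarray  # float64, shape (S,)
    effort_total: np.ndarray  # float64, shape (G,): group effort this generation
    rng: np.random.Generator
    round: int = 0  # 0-based; reported tables are 1-based
    generation: int = 0
    fight_counts: Optional[np.ndarray] = None  # participation in the last round

    @property
    def group_index(self) -> np.ndarray:
        return np.arange(self.params.S) // self.params.n

    def agent(self, i: int) -> AgentState:
        """Scalar copy of agent ``i``'s attributes."""
        return AgentState(
            x=int(self.x[i]),
            r=int(self.r[i]),
            eta=float(self.eta[i]),
            pi_round=float(self.pi_round[i]),
            pi_star=float(self.pi_star[i]),
            fitness=float(self.fitness[i]),
        )

    def copy(self) -> "Society":
        """Deep copy, including an independent clone of the RNG state."""
        rng = np.random.Generator(np.random.PCG64())
        rng.bit_generator.state = self.rng.bit_generator.state
        return Society(
            params=self.params,
            x=self.x.copy(),
            r=self.r.copy(),
            eta=self.eta.copy(),
            pi_round=self.pi_round.copy(),
            pi_star=self.pi_star.copy(),
            fitness=self.fitness.copy(),
            effort_total=self.effort_total.copy(),
            rng=rng,
            round=self.round,
            generation=self.generation,
            fight_counts=None if self.fight_counts is None else self.fight_counts.copy(),
        )


@dataclass
class SummaryRecord:
    """One round's society-level aggregates.

    ``coop_fraction`` and the histogram's cooperator/free-rider split
    use the actions the agents played in this round's collective action;
    histogram bins are the post-fight scores.
    """

    round: int  # 0-based round index
    coop_fraction: float
    mean_eta: float
    score_hist: dict[int, tuple[int, int]]  # score -> (n cooperators, n free riders)
    payoff_score_pairs: Optional[tuple[np.ndarray, np.ndarray]] = None  # (r, pi_star)


@dataclass
class Snapshot:
    """End-of-generation state, captured before reproduction."""

    generation: int  # 0-based
    x: np.ndarray
    r: np.ndarray
    eta: np.ndarray
    pi_star: np.ndarray
    fitness: np.ndarray
    group: np.ndarray


@dataclass
class RunResult:
    """Everything a completed run produced."""

    params: ModelParams
    records: list[SummaryRecord]
    snapshot: Snapshot  # final generation, before its reproduction step
    generation_log: pd.DataFrame  # one row per generation


def init_society(params: ModelParams) -> Society:
    """Initial egalitarian society.

    Every agent starts with a fair-coin action, zero score, zero
    payoffs, and an internalisation trait drawn uniformly from
    [0, eta_init_max] — very little internalisation at the outset.
    """
    if not isinstance(params, ModelParams):
        params = ModelParams.from_dict(dict(params))
    rng = np.random.default_rng(params.seed)
    S = params.S
    return Society(
        params=params,
        x=rng.integers(0, 2, size=S).astype(np.int8),
        r=np.zeros(S, dtype=np.int64),
        eta=rng.uniform(0.0, params.eta_init_max, size=S),
        pi_round=np.zeros(S, dtype=np.float64),
        pi_star=np.zeros(S, dtype=np.float64),
        fitness=np.zeros(S, dtype=np.float64),
        effort_total=np.zeros(params.G, dtype=np.float64),
        rng=rng,
    )


def _score_hist(r: np.ndarray, x: np.ndarray) -> dict[int, tuple[int, int]]:
    hist: dict[int, tuple[int, int]] = {}
    for score in np.unique(r):
        mask = r == score
        coop = int(x[mask].sum())
        hist[int(score)] = (coop, int(mask.sum()) - coop)
    return hist


def run_round(
    society: Society, params: ModelParams, collect_pairs: bool = False
) -> SummaryRecord:
    """Advance one round in place: collective action, fights, revision.

    Returns the round's :class:`SummaryRecord`; ``collect_pairs`` also
    stores a copy of the (score, accumulated payoff) pairs.
    """
    X, Xbar = stages.collective_action(society, params)
    coop_fraction = float(society.x.mean())
    stages.fight_stage(society, params)
    record = SummaryRecord(
        round=society.round,
        coop_fraction=coop_fraction,
        mean_eta=float(society.eta.mean()),
        score_hist=_score_hist(society.r, society.x),
        payoff_score_pairs=(society.r.copy(), society.pi_star.copy())
        if collect_pairs
        else None,
    )
    stages.revise_stage(society, params, X, Xbar)
    society.round += 1
    return record


def run_generation(
    society: Society, params: ModelParams, collect_pairs: bool = False
) -> tuple[list[SummaryRecord], Snapshot]:
    """Run Q rounds, compute fitness, snapshot, then reproduce in place."""
    if society.round % params.Q != 0:
        raise ParameterError(
            f"run_generation requires a generation boundary, at round {society.round}"
        )
    records = [run_round(society, params, collect_pairs) for _ in range(params.Q)]
    society.fitness = np.asarray(
        evolution.compute_fitness(society.pi_star, society.eta, params)
    )
    snapshot = Snapshot(
        generation=society.generation,
        x=society.x.copy(),
        r=society.r.copy(),
        eta=society.eta.copy(),
        pi_star=society.pi_star.copy(),
        fitness=society.fitness.copy(),
        group=society.group_index,
    )
    evolution.reproduce(society, params)
    society.generation += 1
    return records, snapshot


def run(params: ModelParams, collect_pairs: bool = False) -> RunResult:
    """Run a full simulation of T rounds (T/Q generations) from scratch."""
    society = init_society(params)
    records: list[SummaryRecord] = []
    gen_rows = []
    snapshot: Optional[Snapshot] = None
    for _ in range(params.generations):
        recs, snapshot = run_generation(society, params, collect_pairs)
        records.extend(recs)
        gen_rows.append(
            {
                "generation": snapshot.generation + 1,  # 1-based in output
                "coop_fraction": float(np.mean([rec.coop_fraction for rec in recs])),
                "mean_eta": float(snapshot.eta.mean()),
            }
        )
    assert snapshot is not None
    return RunResult(
        params=params,
        records=records,
        snapshot=snapshot,
        generation_log=pd.DataFrame(gen_rows),
    )
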