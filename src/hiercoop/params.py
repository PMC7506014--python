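"""Run-level parameters and configuration loading.

All constants of a simulation run live in a single immutable
:class:`ModelParams` object.  Parameters may come from a flat YAML/JSON
config file, from keyword arguments, or from CLI flags (the CLI merges
flags over the file).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

SCORE_RULES = ("unconstrained", "exogenous", "endogenous")


class ParameterError(ValueError):
    """Raised for an invalid or inconsistent parameter combination."""


@dataclass(frozen=True)
class ModelParams:
    """All run-level constants of the model.

    Attributes
    ----------
    n : agents per group (constant group size; at least 2 so that every
        agent can find a fight opponent).
    G : number of groups.
    Q : rounds per generation.
    T : total number of rounds; must be a multiple of ``Q``.
    b : multiplier of the collective effort in the public-goods payoff.
    c : individual cost of cooperating.
    v : value of following the cooperation norm in the utility function.
    gamma : steepness of the logistic foresight factor ``F(r)``.
    e : probability that a strategy revision is a uniform random choice
        instead of a utility-maximising one.
    mu : probability that an agent revises her strategy in a round.
    c_opt : fitness cost of payoff optimisation (paid in proportion 1-eta).
    c_int : fitness cost of norm internalisation (paid in proportion eta).
    p_win : probability that the higher-scored contestant wins a fight.
    score_rule : one of ``unconstrained``, ``exogenous`` (scores clipped
        to [0, n]) or ``endogenous`` (multiplicative decay toward 0).
    lambda_decay : decay rate of the endogenous score rule (ignored by
        the other two rules).
    endogenous_decay_scope : ``"fight"`` applies the decayed update at
        every fight outcome (default); ``"round"`` decays once per round
        on the net win/loss tally.
    eta_init_max : upper bound of the uniform distribution initial
        internalisation values are drawn from.
    mutation_sigma : standard deviation of the Gaussian mutation kernel
        applied to eta at reproduction.
    seed : seed of the single global random-number stream.
    """

    n: int = 8
    G: int = 500
    Q: int = 40
    T: int = 10_000
    b: float = 1.0
    c: float = 1.0
    v: float = 1.0
    gamma: float = 0.5
    e: float = 0.1
    mu: float = 0.75
    c_opt: float = 0.1
    c_int: float = 0.1
    p_win: float = 0.9
    score_rule: str = "unconstrained"
    lambda_decay: float = 0.0
    endogenous_decay_scope: str = "fight"
    eta_init_max: float = 0.05
    mutation_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.n, int) and self.n >= 2):
            raise ParameterError(f"n must be an integer >= 2, got {self.n!r}")
        if not (isinstance(self.G, int) and self.G >= 1):
            raise ParameterError(f"G must be a positive integer, got {self.G!r}")
        if not (isinstance(self.Q, int) and self.Q >= 1):
            raise ParameterError(f"Q must be a positive integer, got {self.Q!r}")
        if not (isinstance(self.T, int) and self.T >= 1):
            raise ParameterError(f"T must be a positive integer, got {self.T!r}")
        if self.T % self.Q != 0:
            raise ParameterError(
                f"T must be a multiple of Q (got T={self.T}, Q={self.Q})"
            )
        for name in ("b", "c", "v", "c_opt", "c_int", "eta_init_max"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")
        for name in ("e", "mu", "p_win", "lambda_decay"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ParameterError(f"{name} must be a probability in [0, 1], got {val}")
        if self.gamma <= 0:
            raise ParameterError(f"gamma must be positive, got {self.gamma}")
        if self.mutation_sigma < 0:
            raise ParameterError("mutation_sigma must be nonnegative")
        if self.score_rule not in SCORE_RULES:
            raise ParameterError(
                f"score_rule must be one of {SCORE_RULES}, got {self.score_rule!r}"
            )
        if self.endogenous_decay_scope not in ("fight", "round"):
            raise ParameterError(
                "endogenous_decay_scope must be 'fight' or 'round', "
                f"got {self.endogenous_decay_scope!r}"
            )

    @property
    def S(self) -> int:
        """Society size, ``n * G``."""
        return self.n * self.G

    @property
    def generations(self) -> int:
        """Number of non-overlapping generations, ``T // Q``."""
        return self.T // self.Q

    def replace(self, **changes: Any) -> "ModelParams":
        """Return a copy with the given fields changed (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_file(cls, path: str | Path, **overrides: Any) -> "ModelParams":
        """Load parameters from a flat YAML or JSON mapping.

        Keyword overrides (e.g. from CLI flags) take precedence over the
        file's values; ``None`` overrides are ignored.
        """
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        if data is None:
            data = {}
        if not isinstance(data, Mapping):
            raise ParameterError(f"config file {path} must contain a flat mapping")
        merged = dict(data)
        merged.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(merged)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)
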