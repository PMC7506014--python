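"""Summary statistics, tabular output writers, and micro-society fixtures.

The quantities here are the ones used to characterise the emergent
societies: score histograms split by norm-following, the regression of
accumulated payoff on score, and the cooperation / internalisation time
series.  Histograms bin raw integer scores (scores are integers, no
binning needed) and aggregate over all groups.
"""

from __future__ import annotations

import json
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import RunResult, Snapshot, Society, SummaryRecord, init_society
from .params import ModelParams, ParameterError

__all__ = [
    "score_histogram_by_norm",
    "payoff_score_regression",
    "RegressionResult",
    "timeseries",
    "per_generation",
    "fixture_society",
    "write_outputs",
    "load_manifest",
]


def score_histogram_by_norm(state: Society | Snapshot) -> dict[int, tuple[int, int]]:
    """Histogram of scores aggregated over all groups, split by action.

    Returns a mapping ``score -> (cooperators, free riders)``; the
    counts over all bins sum to the society size S.
    """
    r = np.asarray(state.r)
    x = np.asarray(state.x)
    hist: dict[int, tuple[int, int]] = {}
    for score in np.unique(r):
        mask = r == score
        coop = int(x[mask].sum())
        hist[int(score)] = (coop, int(mask.sum()) - coop)
    return hist


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of accumulated payoff on score."""

    slope: float
    intercept: float
    r_squared: float
    pvalue: float
    stderr: float
    degenerate: bool = False  # all scores identical: slope undefined


def payoff_score_regression(state: Society | Snapshot) -> RegressionResult:
    """Ordinary least squares of pi_star on the score, over all agents.

    With a single realised score the slope is undefined; the result is
    then flagged ``degenerate`` (slope NaN, intercept = mean payoff)
    rather than raising.
    """
    r = np.asarray(state.r, dtype=np.float64)
    pi = np.asarray(state.pi_star, dtype=np.float64)
    if np.all(r == r[0]):
        return RegressionResult(
            slope=float("nan"),
            intercept=float(pi.mean()),
            r_squared=0.0,
            pvalue=float("nan"),
            stderr=float("nan"),
            degenerate=True,
        )
    fit = sps.linregress(r, pi)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        pvalue=float(fit.pvalue),
        stderr=float(fit.stderr),
    )


def timeseries(records: Iterable[SummaryRecord], Q: int) -> pd.DataFrame:
    """Tidy per-round table: round, generation (1-based), coop, mean eta."""
    rows = [
        {
            "round": rec.round + 1,
            "generation": rec.round // Q + 1,
            "coop_fraction": rec.coop_fraction,
            "mean_eta": rec.mean_eta,
        }
        for rec in records
    ]
    return pd.DataFrame(rows)


def per_generation(table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a round table to per-generation means."""
    return (
        table.groupby("generation", as_index=False)[["coop_fraction", "mean_eta"]]
        .mean()
        .sort_values("generation", ignore_index=True)
    )


def fixture_society(
    spec: Mapping[str, object], params: ModelParams | None = None
) -> Society:
    """Build a deterministic micro-society for tests, bypassing init.

    ``spec`` maps attribute names to per-agent sequences::

        {"n": 2, "x": [1, 0], "r": [3, -1], "eta": [0.0, 0.5],
         "pi_round": [1.0, 0.0], "pi_star": [2.0, 0.0], "seed": 7}

    Lengths must be a multiple of ``n`` (the group size); groups are the
    consecutive blocks of n agents.  Omitted attributes default to
    zero.  ``params`` overrides the minimal parameter set derived from
    the spec (its n/G/seed must agree with the spec).
    """
    spec = dict(spec)
    n = int(spec.pop("n"))
    x = np.asarray(spec.pop("x"), dtype=np.int8)
    S = len(x)
    if S == 0 or S % n != 0:
        raise ParameterError(f"fixture size {S} is not a positive multiple of n={n}")
    G = S // n
    seed = int(spec.pop("seed", 0))

    def take(name: str, default: float = 0.0) -> np.ndarray:
        val = spec.pop(name, None)
        if val is None:
            return np.full(S, default, dtype=np.float64)
        arr = np.asarray(val, dtype=np.float64)
        if len(arr) != S:
            raise ParameterError(f"{name} must have length {S}")
        return arr

    r = take("r").astype(np.int64)
    eta = take("eta")
    pi_round = take("pi_round")
    pi_star = take("pi_star")
    if spec:
        raise ParameterError(f"unknown fixture field(s): {sorted(spec)}")
    if np.any((x != 0) & (x != 1)):
        raise ParameterError("x entries must be 0 or 1")
    if np.any(eta < 0) or np.any(eta > 1):
        raise ParameterError("eta entries must lie in [0, 1]")

    if params is None:
        params = ModelParams(n=n, G=G, Q=1, T=1, seed=seed)
    elif params.n != n or params.G != G:
        raise ParameterError("params.n/params.G disagree with the fixture spec")
    society = init_society(params)
    society.x = x
    society.r = r
    society.eta = eta
    society.pi_round = pi_round
    society.pi_star = pi_star
    return society


# ---------------------------------------------------------------------------
# Output writers


def _code_version() -> str:
    try:
        out = subprocess.run(
            ["git", "rev-parse", "HEAD"],
            capture_output=True,
            text=True,
            cwd=Path(__file__).parent,
            timeout=5,
        )
        if out.returncode == 0:
            return out.stdout.strip()
    except OSError:
        pass
    from . import __version__

    return __version__


def histogram_table(hist: Mapping[int, tuple[int, int]]) -> pd.DataFrame:
    rows = [
        {"score": score, "cooperators": c, "free_riders": d}
        for score, (c, d) in sorted(hist.items())
    ]
    return pd.DataFrame(rows, columns=["score", "cooperators", "free_riders"])


def snapshot_table(snapshot: Snapshot, n: int) -> pd.DataFrame:
    S = len(snapshot.x)
    return pd.DataFrame(
        {
            "group": np.asarray(snapshot.group, dtype=int) + 1,
            "agent": np.arange(S) % n + 1,
            "x": np.asarray(snapshot.x, dtype=int),
            "r": np.asarray(snapshot.r, dtype=int),
            "eta": snapshot.eta,
            "pi_star": snapshot.pi_star,
            "fitness": snapshot.fitness,
        }
    )


def write_outputs(result: RunResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the run's tables and manifest; return the written paths.

    Files (CSV: comma separated, header row, UTF-8, '.' decimal):

    - ``timeseries.csv`` — per-round coop fraction and mean eta;
    - ``generation_log.csv`` — per-generation aggregates;
    - ``snapshot.csv`` — final-generation per-agent state (pre-reproduction);
    - ``score_histogram.csv`` — final-generation score histogram by action;
    - ``manifest.json`` — full parameters, seed and code version, enough
      to reproduce the run bit for bit.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "timeseries": out / "timeseries.csv",
        "generation_log": out / "generation_log.csv",
        "snapshot": out / "snapshot.csv",
        "score_histogram": out / "score_histogram.csv",
        "manifest": out / "manifest.json",
    }
    try:
        timeseries(result.records, result.params.Q).to_csv(
            paths["timeseries"], index=False
        )
        result.generation_log.to_csv(paths["generation_log"], index=False)
        snapshot_table(result.snapshot, result.params.n).to_csv(
            paths["snapshot"], index=False
        )
        histogram_table(score_histogram_by_norm(result.snapshot)).to_csv(
            paths["score_histogram"], index=False
        )
        manifest = {
            "params": result.params.to_dict(),
            "code_version": _code_version(),
        }
        paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except OSError as err:
        raise OSError(f"cannot write run output {err.filename!r}: {err}") from err
    return paths


def load_manifest(path: str | Path) -> ModelParams:
    """Reload the parameters of a previous run from its manifest."""
    manifest = json.loads(Path(path).read_text())
    return ModelParams.from_dict(manifest["params"])
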