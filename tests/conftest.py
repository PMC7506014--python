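"""Shared fixtures: small parameter sets and cached reduced-scale runs."""

from __future__ import annotations

import numpy as np
import pytest

from hiercoop import ModelParams, run, timeseries

REDUCED = dict(G=50, T=2_000, Q=40)
SEEDS = (1, 2, 3)


def small_params(**kw) -> ModelParams:
    """A tiny, fast parameter set for unit tests."""
    defaults = dict(n=4, G=5, Q=10, T=20, seed=7)
    defaults.update(kw)
    return ModelParams(**defaults)


@pytest.fixture(scope="session")
def unconstrained_n8_runs():
    """Reduced-scale unconstrained runs, n=8, three replicate seeds."""
    out = []
    for seed in SEEDS:
        params = ModelParams(n=8, score_rule="unconstrained", seed=seed, **REDUCED)
        result = run(params)
        out.append((params, result, timeseries(result.records, params.Q)))
    return out


@pytest.fixture(scope="session")
def unconstrained_n24_runs():
    """Reduced-scale unconstrained runs, n=24, three replicate seeds."""
    out = []
    for seed in SEEDS:
        params = ModelParams(n=24, score_rule="unconstrained", seed=seed, **REDUCED)
        result = run(params)
        out.append((params, result, timeseries(result.records, params.Q)))
    return out


@pytest.fixture(scope="session")
def exogenous_n8_runs():
    """Reduced-scale exogenously clipped runs, n=8, three replicate seeds."""
    out = []
    for seed in SEEDS:
        params = ModelParams(n=8, score_rule="exogenous", seed=seed, **REDUCED)
        result = run(params)
        out.append((params, result, timeseries(result.records, params.Q)))
    return out


@pytest.fixture(scope="session")
def endogenous_n8_runs():
    """Reduced-scale endogenous-decay runs, n=8, lambda=0.75, three seeds."""
    out = []
    for seed in SEEDS:
        params = ModelParams(
            n=8, score_rule="endogenous", lambda_decay=0.75, seed=seed, **REDUCED
        )
        result = run(params)
        out.append((params, result, timeseries(result.records, params.Q)))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
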