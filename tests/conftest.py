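import numpy as np
import pandas as pd
import pytest

from survnma.model import PosteriorDraws, build_model, fit
from survnma.synthetic import (
    default_scenario,
    interval_counts_from_ipd,
    simulate_trial,
)


def scenario_intervals(seed: int, family: str = "loglogistic", n_per_arm: int = 400,
                       horizon: float = 24.0):
    """Simulate the default two-study network and return (intervals, effects, base)."""
    trials, effects, base = default_scenario(family=family, n_per_arm=n_per_arm)
    rng = np.random.default_rng(seed)
    frames = []
    for trial in trials:
        for treatment, ipd in simulate_trial(trial, seed=rng).items():
            frames.append(
                interval_counts_from_ipd(
                    ipd, study=trial.study_id, treatment=treatment, horizon=horizon
                )
            )
    return pd.concat(frames, ignore_index=True), effects, base


@pytest.fixture(scope="session")
def loglogistic_intervals():
    return scenario_intervals(seed=20160606)


@pytest.fixture(scope="session")
def loglogistic_fit(loglogistic_intervals):
    """One shared log-logistic network fit, reused across report/model tests."""
    data, effects, base = loglogistic_intervals
    model = build_model(data, "loglogistic", reference="everolimus")
    draws = fit(model, chains=3, iterations=5000, burn_in=2500, seed=42)
    return model, draws, effects, base


@pytest.fixture(scope="session")
def exponential_fit(loglogistic_intervals):
    data, _, _ = loglogistic_intervals
    model = build_model(data, "exponential", reference="everolimus")
    draws = fit(model, chains=3, iterations=5000, burn_in=2500, seed=43)
    return model, draws


def make_draws(samples, param_names, family, studies, treatments,
               reference="everolimus", baselines=None) -> PosteriorDraws:
    """Hand-assembled PosteriorDraws for report-level unit tests."""
    return PosteriorDraws(
        samples=np.asarray(samples, dtype=float),
        param_names=param_names,
        family=family,
        studies=studies,
        treatments=treatments,
        reference=reference,
        meta={"seed": 0, "chains": len(samples), "iterations": len(samples[0]), "burn_in": 0},
        baselines=baselines or {},
    )
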