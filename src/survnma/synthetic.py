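"""Synthetic two-trial survival data with known ground truth.

Generates the artifacts a published trial would provide — digitized
Kaplan-Meier coordinates, a numbers-at-risk table, monthly interval
counts — from arms whose true distribution family and parameters are
known, so every downstream stage can be tested end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .datatypes import INTERVAL_COLUMNS, KMCurve, PseudoIPD, RiskTable
from .families import EffectVector, ParamVector, get_family, inverse_survival

__all__ = [
    "ArmSpec",
    "TrialSpec",
    "simulate_arm",
    "simulate_trial",
    "km_from_ipd",
    "interval_counts_from_ipd",
    "default_scenario",
]


@dataclass(frozen=True)
class ArmSpec:
    """One treatment arm: sample size and the true event-time distribution."""

    treatment: str
    n: int
    theta: ParamVector

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("arm size must be nonnegative")
        get_family(self.theta.family)


@dataclass(frozen=True)
class TrialSpec:
    """Design of one simulated two-arm (or multi-arm) trial."""

    study_id: str
    arms: tuple[ArmSpec, ...]
    accrual_window: float = 0.0
    max_followup: float = math.inf
    random_censor_rate: float = 0.0
    risk_table_times: tuple[float, ...] = tuple(range(0, 25))

    def __post_init__(self) -> None:
        if self.max_followup <= 0:
            raise ValueError("max_followup must be positive")
        if self.accrual_window < 0 or self.random_censor_rate < 0:
            raise ValueError("accrual_window and random_censor_rate must be >= 0")
        rt = np.asarray(self.risk_table_times, dtype=float)
        if rt.size == 0 or rt[0] != 0 or np.any(np.diff(rt) <= 0):
            raise ValueError("risk_table_times must start at 0 and strictly increase")


def simulate_arm(
    arm: ArmSpec,
    accrual_window: float = 0.0,
    max_followup: float = math.inf,
    censor_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> PseudoIPD:
    """Draw one observed (time, event) record per patient in the arm.

    Death times come from the arm's family via inverse-CDF sampling.
    Each patient's censoring time is the minimum of an exponential
    loss-to-follow-up draw (rate ``censor_rate``) and the administrative
    cutoff ``max_followup - U(0, accrual_window)``; the observed time is
    the earlier of death and censoring.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = arm.n
    if n == 0:
        return PseudoIPD(np.empty(0), np.empty(0, dtype=int), arm_label=arm.treatment)
    death = np.asarray(inverse_survival(arm.theta, rng.uniform(size=n)))
    admin = max_followup - (
        rng.uniform(0.0, accrual_window, size=n) if accrual_window > 0 else 0.0
    )
    if censor_rate > 0:
        loss = rng.exponential(1.0 / censor_rate, size=n)
    else:
        loss = np.full(n, math.inf)
    censor = np.minimum(loss, admin)
    observed = np.minimum(death, censor)
    event = (death <= censor).astype(int)
    if not np.all(np.isfinite(observed)):
        raise ValueError(
            "some patients have neither a finite death time nor a censoring "
            "mechanism (defective distribution with unlimited follow-up)"
        )
    observed = np.maximum(observed, 1e-9)  # inverse sampling can hit exact 0
    return PseudoIPD(observed, event, arm_label=arm.treatment)


def simulate_trial(spec: TrialSpec, seed: int | np.random.Generator) -> dict[str, PseudoIPD]:
    """Simulate every arm of a trial; returns ``{treatment: PseudoIPD}``."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return {
        arm.treatment: simulate_arm(
            arm,
            accrual_window=spec.accrual_window,
            max_followup=spec.max_followup,
            censor_rate=spec.random_censor_rate,
            seed=rng,
        )
        for arm in spec.arms
    }


def km_from_ipd(ipd: PseudoIPD, risk_table_times) -> tuple[KMCurve, RiskTable]:
    """Product-limit estimate plus the scheduled numbers-at-risk table."""
    if len(ipd) == 0:
        raise ValueError("cannot estimate a survival curve from an empty arm")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.times, event_observed=ipd.events)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    if times[0] != 0:  # lifelines always anchors at 0, but be safe
        times = np.concatenate([[0.0], times])
        surv = np.concatenate([[1.0], surv])
    # keep only genuine steps (plus the origin): digitizers record drops
    keep = np.concatenate([[True], np.diff(surv) < 0])
    curve = KMCurve(times[keep], surv[keep], arm_label=ipd.arm_label)
    rt = np.asarray(risk_table_times, dtype=float)
    counts = np.array([(ipd.times >= t).sum() for t in rt], dtype=int)
    return curve, RiskTable(rt, counts)


def interval_counts_from_ipd(
    ipd: PseudoIPD,
    study: str = "",
    treatment: str = "",
    width: float = 1.0,
    horizon: float = 24.0,
    terminal_censor: bool = True,
) -> pd.DataFrame:
    """Bin patient records into per-interval (at-risk, deaths, censored) counts.

    Intervals are half-open ``[j*width, (j+1)*width)``.  With
    ``terminal_censor`` (the default), patients still under observation
    at the horizon are recorded as censored in the final interval, so the
    bookkeeping identity ``at_risk[j+1] = at_risk[j] - deaths[j] -
    censored[j]`` closes the table.
    """
    if width <= 0:
        raise ValueError("interval width must be positive")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    n_int = int(math.ceil(horizon / width))
    edges = np.arange(n_int + 1) * width
    deaths = np.zeros(n_int, dtype=int)
    censored = np.zeros(n_int, dtype=int)
    if len(ipd):
        inside = ipd.times < edges[-1]
        idx = np.minimum(
            np.searchsorted(edges, ipd.times[inside], side="right") - 1, n_int - 1
        )
        ev = ipd.events[inside]
        np.add.at(deaths, idx[ev == 1], 1)
        np.add.at(censored, idx[ev == 0], 1)
        if terminal_censor:
            censored[-1] += int((~inside).sum())
    at_risk = np.zeros(n_int, dtype=int)
    at_risk[0] = len(ipd)
    for j in range(1, n_int):
        at_risk[j] = at_risk[j - 1] - deaths[j - 1] - censored[j - 1]
    return pd.DataFrame(
        {
            "study": study,
            "treatment": treatment,
            "interval_start": edges[:-1],
            "n_at_risk": at_risk,
            "deaths": deaths,
            "censored": censored,
        },
        columns=list(INTERVAL_COLUMNS),
    )


def default_scenario(
    family: str = "loglogistic",
    n_per_arm: int = 400,
    reference: str = "everolimus",
) -> tuple[list[TrialSpec], dict[str, EffectVector], ParamVector]:
    """Two-study common-comparator network mirroring the motivating trials.

    Study A compares the reference against ``nivolumab``; study B against
    ``cabozantinib``.  Under the default log-logistic family the true
    nivolumab-vs-cabozantinib hazard ratio crosses 1 near month 5.
    Returns ``(trial_specs, true_effects_by_treatment, baseline_theta)``.
    """
    spec = get_family(family)
    if spec.name == "loglogistic":
        base = ParamVector("loglogistic", (19.6, 1.25))
        thetas = {
            "nivolumab": ParamVector("loglogistic", (27.0, 1.05)),
            "cabozantinib": ParamVector("loglogistic", (20.0, 1.7)),
        }
    elif spec.name == "exponential":
        base = ParamVector("exponential", (math.log(2) / 19.6,))
        thetas = {
            "nivolumab": ParamVector("exponential", (0.73 * math.log(2) / 19.6,)),
            "cabozantinib": ParamVector("exponential", (0.67 * math.log(2) / 19.6,)),
        }
    elif spec.name == "weibull":
        base = ParamVector("weibull", (0.028, 1.15))
        thetas = {
            "nivolumab": ParamVector("weibull", (0.035, 0.95)),
            "cabozantinib": ParamVector("weibull", (0.012, 1.45)),
        }
    elif spec.name == "gompertz":
        base = ParamVector("gompertz", (0.030, 0.015))
        thetas = {
            "nivolumab": ParamVector("gompertz", (0.036, -0.025)),
            "cabozantinib": ParamVector("gompertz", (0.019, 0.040)),
        }
    else:  # pragma: no cover
        raise ValueError(spec.name)
    effects = {
        k: EffectVector(spec.name, tuple(v.transformed() - base.transformed()))
        for k, v in thetas.items()
    }
    trials = [
        TrialSpec(
            study_id="study_A",
            arms=(
                ArmSpec(reference, n_per_arm, base),
                ArmSpec("nivolumab", n_per_arm, thetas["nivolumab"]),
            ),
            accrual_window=12.0,
            max_followup=38.0,
            random_censor_rate=0.005,
            risk_table_times=tuple(range(0, 39)),
        ),
        TrialSpec(
            study_id="study_B",
            arms=(
                ArmSpec(reference, n_per_arm, base),
                ArmSpec("cabozantinib", n_per_arm, thetas["cabozantinib"]),
            ),
            accrual_window=12.0,
            max_followup=30.0,
            random_censor_rate=0.005,
            risk_table_times=tuple(range(0, 31)),
        ),
    ]
    return trials, effects, base
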