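"""Posterior summaries: HR-over-time, adjusted survival, probability of
being the best treatment, and the classical Bucher indirect comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .families import hazard_matrix, log_survival_matrix, untransform_params, get_family
from .model import PosteriorDraws

__all__ = [
    "BucherResult",
    "HRSeries",
    "ProbBestSeries",
    "bucher_indirect",
    "hr_series",
    "hr_table",
    "adjusted_survival",
    "prob_best",
    "odds_best",
]


@dataclass(frozen=True)
class BucherResult:
    """Indirect hazard ratio via a common comparator."""

    hr: float
    ci95: tuple[float, float]
    log_se: float

    def __str__(self) -> str:  # pragma: no cover
        lo, hi = self.ci95
        return f"HR {self.hr:.2f} (95% CI {lo:.2f}, {hi:.2f})"


def bucher_indirect(
    hr_a: float,
    ci_a: tuple[float, float],
    hr_b: float,
    ci_b: tuple[float, float],
    level_a: float = 0.95,
    level_b: float = 0.95,
) -> BucherResult:
    """Indirect comparison of A vs B through their shared comparator.

    The point estimate is ``hr_a / hr_b``.  Each trial's log-HR standard
    error is recovered from its confidence interval at its *stated*
    confidence level, ``(ln(upper) - ln(lower)) / (2 z)``; the combined
    standard error is the root sum of squares and the returned interval
    is the conventional 95% one.
    """
    for hr, (lo, hi), level in ((hr_a, ci_a, level_a), (hr_b, ci_b, level_b)):
        if min(hr, lo, hi) <= 0:
            raise ValueError("hazard ratios and CI bounds must be positive")
        if lo > hi:
            raise ValueError(f"inverted confidence interval ({lo}, {hi})")
        if not 0 < level < 1:
            raise ValueError(f"confidence level must be in (0, 1), got {level}")
    se_a = (np.log(ci_a[1]) - np.log(ci_a[0])) / (2 * norm.ppf(0.5 + level_a / 2))
    se_b = (np.log(ci_b[1]) - np.log(ci_b[0])) / (2 * norm.ppf(0.5 + level_b / 2))
    se = float(np.hypot(se_a, se_b))
    log_hr = np.log(hr_a) - np.log(hr_b)
    z95 = norm.ppf(0.975)
    return BucherResult(
        hr=float(np.exp(log_hr)),
        ci95=(float(np.exp(log_hr - z95 * se)), float(np.exp(log_hr + z95 * se))),
        log_se=se,
    )


@dataclass(frozen=True)
class HRSeries:
    """Pointwise posterior summary of a time-varying hazard ratio."""

    pair: tuple[str, str]
    grid: np.ndarray
    mean: np.ndarray
    median: np.ndarray
    ci50: tuple[np.ndarray, np.ndarray]
    ci95: tuple[np.ndarray, np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_months": self.grid,
                "hr_mean": self.mean,
                "hr_median": self.median,
                "hr_lo50": self.ci50[0],
                "hr_hi50": self.ci50[1],
                "hr_lo95": self.ci95[0],
                "hr_hi95": self.ci95[1],
            }
        )


@dataclass(frozen=True)
class ProbBestSeries:
    """Per-treatment probability of conferring the best survival over time."""

    grid: np.ndarray
    treatments: list[str]
    probabilities: np.ndarray  # (treatments, grid)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probabilities.T, columns=self.treatments)
        df.insert(0, "time_months", self.grid)
        return df


def _arm_params(draws: PosteriorDraws, study: str, treatment: str) -> np.ndarray:
    """Natural-scale parameter draws for a treatment on a study's baseline."""
    spec = get_family(draws.family)
    return untransform_params(spec, draws.arm_z(study, treatment))


def _check_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(grid < 0):
        raise ValueError("grid must be nonnegative and non-empty")
    return grid


def hr_series(
    draws: PosteriorDraws,
    pair: tuple[str, str],
    grid,
    reference_study: str | None = None,
) -> HRSeries:
    """Posterior HR(t) of ``pair[0]`` vs ``pair[1]`` over a time grid.

    For two-parameter families the hazard ratio between two non-reference
    treatments depends on the baseline parameters; they are taken from
    ``reference_study`` (default: the first study in the network).
    """
    grid = _check_grid(grid)
    study = reference_study or draws.studies[0]
    h = []
    for treatment in pair:
        params = _arm_params(draws, study, treatment)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            h.append(hazard_matrix(draws.family, params, grid))
    bad = ~np.isfinite(h[0]) | ~np.isfinite(h[1]) | (h[1] == 0)
    if bad.any():
        t_bad = grid[np.where(bad.any(axis=0))[0][0]]
        raise ValueError(f"hazard ratio undefined at t={t_bad} months")
    ratio = h[0] / h[1]
    lo50, hi50 = np.percentile(ratio, [25, 75], axis=0)
    lo95, hi95 = np.percentile(ratio, [2.5, 97.5], axis=0)
    return HRSeries(
        pair=tuple(pair),
        grid=grid,
        mean=ratio.mean(axis=0),
        median=np.percentile(ratio, 50, axis=0),
        ci50=(lo50, hi50),
        ci95=(lo95, hi95),
    )


def hr_table(series: HRSeries, months=(3, 6, 9, 12, 15, 18, 21, 24)) -> pd.DataFrame:
    """Reporting-cadence extract of an HR series (quarterly months)."""
    df = series.to_frame()
    out = df[df["time_months"].isin(months)].reset_index(drop=True)
    missing = sorted(set(months) - set(out["time_months"]))
    if missing:
        raise ValueError(f"series grid does not cover reporting months {missing}")
    return out


def adjusted_survival(
    draws: PosteriorDraws,
    reference_study: str,
    treatments: list[str] | None = None,
    grid=None,
) -> pd.DataFrame:
    """Absolute survival curves anchored on one study's baseline.

    Per draw, each treatment's S(t) uses the reference study's baseline
    parameters shifted by the treatment effect; summaries are pointwise.
    Returns a tidy frame: treatment, time_months, mean, median, lo95, hi95.
    """
    if reference_study not in draws.studies:
        raise ValueError(
            f"unknown reference study {reference_study!r}; fitted studies: {draws.studies}"
        )
    grid = _check_grid(grid if grid is not None else np.arange(0, 25))
    treatments = treatments or [draws.reference] + draws.treatments
    frames = []
    for treatment in treatments:
        if treatment != draws.reference and treatment not in draws.treatments:
            raise ValueError(f"unknown treatment {treatment!r}")
        params = _arm_params(draws, reference_study, treatment)
        s = np.exp(log_survival_matrix(draws.family, params, grid))
        lo, hi = np.percentile(s, [2.5, 97.5], axis=0)
        frames.append(
            pd.DataFrame(
                {
                    "treatment": treatment,
                    "time_months": grid,
                    "mean": s.mean(axis=0),
                    "median": np.percentile(s, 50, axis=0),
                    "lo95": lo,
                    "hi95": hi,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def prob_best(
    draws: PosteriorDraws,
    grid,
    reference_study: str | None = None,
    treatments: list[str] | None = None,
) -> ProbBestSeries:
    """Probability each treatment attains the best survival at each time.

    Per posterior draw and grid point the treatment with the strictly
    largest adjusted survival scores 1; exact ties split their point
    equally.  Probabilities sum to one across treatments.
    """
    grid = _check_grid(grid)
    study = reference_study or draws.studies[0]
    treatments = treatments or [draws.reference] + draws.treatments
    if len(treatments) < 2:
        raise ValueError("need at least 2 treatments to rank")
    surv = np.stack(
        [
            log_survival_matrix(draws.family, _arm_params(draws, study, k), grid)
            for k in treatments
        ]
    )  # (T, draws, grid)
    best = surv.max(axis=0, keepdims=True)
    is_best = surv == best
    weights = is_best / is_best.sum(axis=0, keepdims=True)
    return ProbBestSeries(
        grid=grid,
        treatments=list(treatments),
        probabilities=weights.mean(axis=1),
    )


def odds_best(p: float) -> float:
    """Odds transform p / (1 - p)."""
    if not 0 <= p < 1:
        raise ValueError(f"probability must be in [0, 1), got {p}")
    return p / (1.0 - p)
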