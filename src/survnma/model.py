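"""Bayesian network meta-analysis of interval survival counts.

The network model ties all arms of all studies together under one
distribution family: each study gets baseline parameters ``mu`` for its
reference arm (on the transformed scale) and each non-reference
treatment gets one effect vector ``delta`` shared across studies, so
that arm parameters are ``mu_study + delta_treatment``.  The likelihood
treats the deaths of every interval as binomial with the conditional
death probability implied by the family:

    deaths_j ~ Binomial(n_at_risk_j - censored_j, 1 - S(t_{j+1}) / S(t_j))

Priors are independent zero-mean normals on every transformed-scale
parameter.  Sampling uses an adaptive random-walk Metropolis scheme
preconditioned at the posterior mode (Laplace covariance), which is
ample for the handful of parameters a star-shaped survival network has.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln

from .datatypes import validate_interval_data
from .families import FamilySpec, get_family, log_survival_matrix

__all__ = [
    "NetworkModel",
    "PosteriorDraws",
    "FitDiagnostics",
    "build_model",
    "fit",
    "psrf",
    "dic",
    "diagnostics",
]


@dataclass(frozen=True)
class _ArmData:
    study_idx: int
    effect_idx: int  # index into treatment effects; -1 for the network anchor
    base_idx: int  # effect index of the study's baseline arm; -1 for the anchor
    t0: np.ndarray
    t1: np.ndarray
    trials: np.ndarray
    deaths: np.ndarray
    log_binom: float  # sum of log C(trials, deaths), the combinatorial constant


@dataclass
class NetworkModel:
    """Fixed-effect survival NMA: per-study baselines + per-treatment effects."""

    family: FamilySpec
    studies: list[str]
    treatments: list[str]  # non-reference treatments, order fixes effect indices
    reference: str
    baselines: dict[str, str]
    prior_sd: float
    arms: list[_ArmData] = field(repr=False)

    @property
    def dim(self) -> int:
        return self.family.dim

    @property
    def n_params(self) -> int:
        return (len(self.studies) + len(self.treatments)) * self.dim

    @property
    def param_names(self) -> list[str]:
        names = [f"mu[{s},{p}]" for s in self.studies for p in self.family.param_names]
        names += [
            f"delta[{k},{p}]" for k in self.treatments for p in self.family.param_names
        ]
        return names

    def split(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(..., P) -> baselines (..., S, dim) and effects (..., T, dim)."""
        z = np.asarray(z, dtype=float)
        S, T, d = len(self.studies), len(self.treatments), self.dim
        mu = z[..., : S * d].reshape(*z.shape[:-1], S, d)
        delta = z[..., S * d :].reshape(*z.shape[:-1], T, d)
        return mu, delta

    def _natural(self, z_arm: np.ndarray) -> np.ndarray:
        out = z_arm.copy()
        for j, link in enumerate(self.family.transforms):
            if link == "log":
                out[..., j] = np.exp(np.clip(out[..., j], -700, 700))
        return out

    def log_likelihood(self, z: np.ndarray) -> np.ndarray:
        """Binomial log likelihood (with combinatorial constant).

        ``z`` may be a single parameter vector (P,) or a stack (..., P);
        the result matches the leading shape.
        """
        z = np.asarray(z, dtype=float)
        mu, delta = self.split(z)
        total = np.zeros(z.shape[:-1])
        for arm in self.arms:
            # arm parameters: study baseline + (effect vs anchor) - (baseline
            # arm's effect vs anchor); invariant under baseline relabeling
            z_arm = mu[..., arm.study_idx, :]
            if arm.effect_idx >= 0:
                z_arm = z_arm + delta[..., arm.effect_idx, :]
            if arm.base_idx >= 0:
                z_arm = z_arm - delta[..., arm.base_idx, :]
            params = self._natural(z_arm)
            ls0 = log_survival_matrix(self.family.name, params, arm.t0)
            ls1 = log_survival_matrix(self.family.name, params, arm.t1)
            log_q = ls1 - ls0  # log P(survive interval)
            with np.errstate(divide="ignore", invalid="ignore"):
                p = -np.expm1(log_q)
                log_p = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), -np.inf)
            terms = np.where(arm.deaths > 0, arm.deaths * log_p, 0.0)
            terms = terms + (arm.trials - arm.deaths) * log_q
            total = total + terms.sum(axis=-1) + arm.log_binom
        return total if total.ndim else float(total)

    def log_prior(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        out = -0.5 * (z / self.prior_sd) ** 2 - np.log(self.prior_sd * np.sqrt(2 * np.pi))
        return out.sum(axis=-1)

    def log_posterior(self, z: np.ndarray) -> np.ndarray:
        return self.log_likelihood(z) + self.log_prior(z)

    def deviance(self, z: np.ndarray) -> np.ndarray:
        return -2.0 * self.log_likelihood(z)


@dataclass
class PosteriorDraws:
    """Labelled MCMC samples on the transformed parameter scale."""

    samples: np.ndarray  # (chains, iterations, parameters)
    param_names: list[str]
    family: str
    studies: list[str]
    treatments: list[str]
    reference: str
    meta: dict
    baselines: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if s.ndim != 3 or s.shape[0] < 2:
            raise ValueError("samples must be (chains >= 2, iterations, parameters)")
        if s.shape[2] != len(self.param_names):
            raise ValueError("parameter label count does not match samples")

    @property
    def n_chains(self) -> int:
        return self.samples.shape[0]

    @property
    def n_draws(self) -> int:
        return self.samples.shape[0] * self.samples.shape[1]

    @property
    def dim(self) -> int:
        return get_family(self.family).dim

    def flat(self) -> np.ndarray:
        """(chains*iterations, parameters) with chains stacked."""
        return self.samples.reshape(-1, self.samples.shape[2])

    def mu(self, study: str) -> np.ndarray:
        """Baseline-arm draws for one study, shape (draws, dim)."""
        i = self.studies.index(study)
        d = self.dim
        return self.flat()[:, i * d : (i + 1) * d]

    def arm_z(self, study: str, treatment: str) -> np.ndarray:
        """Transformed-scale parameter draws for a treatment anchored on a
        study's baseline: ``mu_s + delta_k - delta_{baseline(s)}``."""
        base = self.baselines.get(study, self.reference)
        return self.mu(study) + self.delta(treatment) - self.delta(base)

    def delta(self, treatment: str) -> np.ndarray:
        """Effect draws for one treatment, shape (draws, dim); zeros for the reference."""
        d = self.dim
        if treatment == self.reference:
            return np.zeros((self.n_draws, d))
        i = self.treatments.index(treatment)
        off = len(self.studies) * d
        return self.flat()[:, off + i * d : off + (i + 1) * d]

    def to_frame(self) -> pd.DataFrame:
        chains, iters, P = self.samples.shape
        df = pd.DataFrame(self.flat(), columns=self.param_names)
        df.insert(0, "chain", np.repeat(np.arange(chains), iters))
        df.insert(1, "iteration", np.tile(np.arange(iters), chains))
        return df


@dataclass(frozen=True)
class FitDiagnostics:
    psrf: dict[str, float]
    dic: float
    pd: float
    mean_deviance: float

    def max_psrf(self) -> float:
        return max(self.psrf.values())


def build_model(
    data: pd.DataFrame,
    family: str | FamilySpec,
    reference: str,
    baselines: dict[str, str] | None = None,
    prior_sd: float = 10.0,
) -> NetworkModel:
    """Assemble the network model from validated interval counts.

    ``reference`` anchors the treatment effects (its effect is zero).
    Each study's likelihood is parametrized relative to a baseline arm —
    the anchor where present, overridable per study through
    ``baselines`` — and relabeling the baseline leaves every
    between-treatment contrast invariant.  Raises if the evidence
    network is disconnected or the anchor appears in no study.
    """
    spec = get_family(family)
    df = validate_interval_data(data)
    studies = sorted(df["study"].unique())
    if not studies:
        raise ValueError("no studies in interval data")
    by_study = {s: sorted(df.loc[df["study"] == s, "treatment"].unique()) for s in studies}
    for s, arms in by_study.items():
        if len(arms) < 2:
            raise ValueError(f"study {s!r} has fewer than 2 arms")
    if not any(reference in arms for arms in by_study.values()):
        raise ValueError(f"reference treatment {reference!r} appears in no study")
    _check_connected(by_study)
    baselines = dict(baselines or {})
    for s, arms in by_study.items():
        baselines.setdefault(s, reference if reference in arms else arms[0])
        if baselines[s] not in arms:
            raise ValueError(f"baseline {baselines[s]!r} is not an arm of study {s!r}")
    treatments = sorted(
        t for t in df["treatment"].unique() if t != reference
    )

    def effect_index(treatment: str) -> int:
        return treatments.index(treatment) if treatment != reference else -1

    arms: list[_ArmData] = []
    for (study, treatment), grp in df.groupby(["study", "treatment"], sort=True):
        grp = grp.sort_values("interval_start")
        t0 = grp["interval_start"].to_numpy(dtype=float)
        width = float(np.median(np.diff(t0))) if t0.size > 1 else 1.0
        t1 = t0 + width
        trials = (grp["n_at_risk"] - grp["censored"]).to_numpy(dtype=float)
        deaths = grp["deaths"].to_numpy(dtype=float)
        if np.any(deaths > trials):
            raise ValueError(
                f"{study}/{treatment}: more deaths than binomial trials in an "
                "interval (censored removed from the denominator)"
            )
        keep = trials > 0
        t0, t1, trials, deaths = t0[keep], t1[keep], trials[keep], deaths[keep]
        log_binom = float(
            (gammaln(trials + 1) - gammaln(deaths + 1) - gammaln(trials - deaths + 1)).sum()
        )
        arms.append(
            _ArmData(
                study_idx=studies.index(study),
                effect_idx=effect_index(treatment),
                base_idx=effect_index(baselines[study]),
                t0=t0,
                t1=t1,
                trials=trials,
                deaths=deaths,
                log_binom=log_binom,
            )
        )
    return NetworkModel(
        family=spec,
        studies=studies,
        treatments=treatments,
        reference=reference,
        baselines=baselines,
        prior_sd=float(prior_sd),
        arms=arms,
    )


def _check_connected(by_study: dict[str, list[str]]) -> None:
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for arms in by_study.values():
        for t in arms[1:]:
            parent[find(t)] = find(arms[0])
    roots: dict[str, list[str]] = {}
    for t in parent:
        roots.setdefault(find(t), []).append(t)
    if len(roots) > 1:
        comps = "; ".join(sorted(",".join(sorted(v)) for v in roots.values()))
        raise ValueError(f"evidence network is disconnected: components [{comps}]")


def _find_map(model: NetworkModel, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mode and a Laplace proposal covariance."""
    best_x, best_f = None, np.inf
    for attempt in range(8):
        x0 = rng.normal(scale=0.5, size=model.n_params)
        x0[: len(model.studies) * model.dim] -= 2.0  # start baselines at low rates
        res = optimize.minimize(
            lambda z: -model.log_posterior(z), x0, method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8},
        )
        res = optimize.minimize(lambda z: -model.log_posterior(z), res.x, method="BFGS")
        if np.isfinite(res.fun) and res.fun < best_f:
            best_x, best_f = res.x, res.fun
        if best_f < np.inf and attempt >= 2:
            break
    if best_x is None:
        raise RuntimeError("could not find a finite posterior mode")
    hess = _numerical_hessian(lambda z: -model.log_posterior(z), best_x)
    try:
        cov = np.linalg.inv(hess)
        # symmetrize and check positive definiteness
        cov = 0.5 * (cov + cov.T)
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        cov = np.eye(model.n_params) * 0.01
    return best_x, cov


def _numerical_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = x.size
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
    return H


def fit(
    model: NetworkModel,
    chains: int = 3,
    iterations: int = 20_000,
    burn_in: int = 10_000,
    seed: int = 0,
    init_retries: int = 50,
) -> PosteriorDraws:
    """Adaptive random-walk Metropolis sampling of the network posterior.

    The proposal is a multivariate normal scaled from the Laplace
    covariance at the posterior mode; the global step size adapts toward
    a 23% acceptance rate during burn-in and is frozen afterwards.
    Only post-burn-in draws are retained.
    """
    if iterations <= burn_in:
        raise ValueError("iterations must exceed burn_in")
    if chains < 2:
        raise ValueError("at least 2 chains are required for diagnostics")
    rng = np.random.default_rng(seed)
    mode, cov = _find_map(model, rng)
    chol = np.linalg.cholesky(cov)
    P = model.n_params
    kept = iterations - burn_in
    samples = np.empty((chains, kept, P))
    for c in range(chains):
        # over-dispersed start near the mode
        for attempt in range(init_retries):
            x = mode + chol @ rng.normal(size=P) * 2.0
            lp = model.log_posterior(x)
            if np.isfinite(lp):
                break
        else:
            raise RuntimeError(
                f"chain {c}: no finite-posterior initial value after {init_retries} tries"
            )
        log_step = np.log(2.38 / np.sqrt(P))
        for it in range(iterations):
            step = np.exp(log_step)
            prop = x + step * (chol @ rng.normal(size=P))
            lp_prop = model.log_posterior(prop)
            accept = np.log(rng.uniform()) < lp_prop - lp
            if accept:
                x, lp = prop, lp_prop
            if it < burn_in:
                # Robbins-Monro drift toward 23% acceptance
                log_step += ((1.0 if accept else 0.0) - 0.234) / np.sqrt(1 + it * 0.1)
            else:
                samples[c, it - burn_in] = x
    return PosteriorDraws(
        samples=samples,
        param_names=model.param_names,
        family=model.family.name,
        studies=list(model.studies),
        treatments=list(model.treatments),
        reference=model.reference,
        meta={"seed": seed, "chains": chains, "iterations": iterations, "burn_in": burn_in},
        baselines=dict(model.baselines),
    )


def psrf(draws: PosteriorDraws | np.ndarray) -> dict[str, float] | np.ndarray:
    """Gelman-Rubin potential scale reduction factor per parameter.

    Accepts a :class:`PosteriorDraws` (returns a name->value dict) or a
    raw (chains, iterations, parameters) array (returns an array).
    """
    arr = draws.samples if isinstance(draws, PosteriorDraws) else np.asarray(draws)
    if arr.ndim != 3 or arr.shape[0] < 2:
        raise ValueError("psrf needs at least 2 chains of equal length")
    m, n = arr.shape[0], arr.shape[1]
    chain_means = arr.mean(axis=1)
    W = arr.var(axis=1, ddof=1).mean(axis=0)
    B_over_n = chain_means.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_plus = (n - 1) / n * W + B_over_n
        R = np.sqrt(var_plus / W)
    # identical constant chains and the (n-1)/n deflation both floor at 1
    R = np.where(W == 0, 1.0, np.maximum(R, 1.0))
    if isinstance(draws, PosteriorDraws):
        return {name: float(r) for name, r in zip(draws.param_names, R)}
    return R


def dic(draws: PosteriorDraws, model: NetworkModel) -> tuple[float, float, float]:
    """Deviance information criterion: ``(dic, pD, mean_deviance)``.

    ``pD = mean(D) - D(posterior mean)`` with the posterior mean taken on
    the transformed scale; the binomial combinatorial constant is kept in
    the deviance.
    """
    flat = draws.flat()
    devs = model.deviance(flat)
    mean_dev = float(np.mean(devs))
    dev_at_mean = float(model.deviance(flat.mean(axis=0)))
    p_d = mean_dev - dev_at_mean
    return mean_dev + p_d, p_d, mean_dev


def diagnostics(draws: PosteriorDraws, model: NetworkModel) -> FitDiagnostics:
    """Convenience bundle of PSRF and DIC for one fitted family."""
    d, p_d, mean_dev = dic(draws, model)
    return FitDiagnostics(psrf=psrf(draws), dic=d, pd=p_d, mean_deviance=mean_dev)
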