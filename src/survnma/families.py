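"""Closed-form machinery for the four parametric survival families.

Each family is parametrized on the natural scale as follows:

===========  ==============================  ==========================
family       parameters (natural scale)      survival function
===========  ==============================  ==========================
exponential  rate ``lam`` (/month)           ``exp(-lam*t)``
weibull      rate ``lam``, shape ``k``       ``exp(-lam*t**k)``
gompertz     rate ``lam``, shape ``gamma``   ``exp(-(lam/gamma)*(exp(gamma*t)-1))``
loglogistic  scale ``alpha``, shape ``beta``  ``1/(1+(t/alpha)**beta)``
===========  ==============================  ==========================

Treatment effects act additively on the *transformed* scale: every
positivity-constrained parameter gets a log link, while the Gompertz
shape (which may be negative) keeps an identity link.  The exponential
family is the ``k = 1`` sub-case of the Weibull, so its single effect
is a log hazard ratio and the family enforces proportional hazards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FAMILY_NAMES",
    "FamilySpec",
    "ParamVector",
    "EffectVector",
    "get_family",
    "survival",
    "log_survival",
    "hazard",
    "interval_death_prob",
    "apply_effect",
    "hazard_ratio",
    "inverse_survival",
]

FAMILY_NAMES = ("exponential", "weibull", "gompertz", "loglogistic")

# below this magnitude the Gompertz shape is treated as exactly zero
_GOMPERTZ_EPS = 1e-300


@dataclass(frozen=True)
class FamilySpec:
    """A survival distribution family: name, dimension and per-parameter link."""

    name: str
    dim: int
    transforms: tuple[str, ...]  # "log" or "identity" per parameter

    @property
    def param_names(self) -> tuple[str, ...]:
        return _PARAM_NAMES[self.name]


_SPECS = {
    "exponential": FamilySpec("exponential", 1, ("log",)),
    "weibull": FamilySpec("weibull", 2, ("log", "log")),
    "gompertz": FamilySpec("gompertz", 2, ("log", "identity")),
    "loglogistic": FamilySpec("loglogistic", 2, ("log", "log")),
}

_PARAM_NAMES = {
    "exponential": ("rate",),
    "weibull": ("rate", "shape"),
    "gompertz": ("rate", "shape"),
    "loglogistic": ("scale", "shape"),
}


def get_family(name: str | FamilySpec) -> FamilySpec:
    """Resolve a family label, raising with the list of allowed names."""
    if isinstance(name, FamilySpec):
        return name
    try:
        return _SPECS[name]
    except KeyError:
        raise ValueError(
            f"unknown family {name!r}; allowed families are {', '.join(FAMILY_NAMES)}"
        ) from None


@dataclass(frozen=True)
class ParamVector:
    """Natural-scale parameters of one survival distribution."""

    family: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        spec = get_family(self.family)
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if len(self.values) != spec.dim:
            raise ValueError(
                f"{self.family} expects {spec.dim} parameter(s), got {len(self.values)}"
            )
        for v, link in zip(self.values, spec.transforms):
            if link == "log" and v <= 0:
                raise ValueError(
                    f"{self.family} parameter must be positive, got {v}"
                )
            if not np.isfinite(v):
                raise ValueError(f"non-finite parameter {v} for {self.family}")

    @property
    def spec(self) -> FamilySpec:
        return get_family(self.family)

    def transformed(self) -> np.ndarray:
        """Parameters on the additive-effect (link) scale."""
        return transform_params(self.spec, np.asarray(self.values))


@dataclass(frozen=True)
class EffectVector:
    """Additive treatment effect on the transformed parameter scale."""

    family: str
    delta: tuple[float, ...]

    def __post_init__(self) -> None:
        spec = get_family(self.family)
        object.__setattr__(self, "delta", tuple(float(v) for v in self.delta))
        if len(self.delta) != spec.dim:
            raise ValueError(
                f"{self.family} effect expects {spec.dim} component(s), got {len(self.delta)}"
            )
        if not all(np.isfinite(v) for v in self.delta):
            raise ValueError("effect vector entries must be finite")


def transform_params(spec: FamilySpec, values: np.ndarray) -> np.ndarray:
    out = np.array(values, dtype=float, copy=True)
    for j, link in enumerate(spec.transforms):
        if link == "log":
            out[..., j] = np.log(out[..., j])
    return out


def untransform_params(spec: FamilySpec, z: np.ndarray) -> np.ndarray:
    out = np.array(z, dtype=float, copy=True)
    for j, link in enumerate(spec.transforms):
        if link == "log":
            out[..., j] = np.exp(out[..., j])
    return out


# ---------------------------------------------------------------------------
# vectorized kernels on natural-scale parameter arrays
# ---------------------------------------------------------------------------

def _log_surv_arr(name: str, values: np.ndarray, t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if name == "exponential":
        (lam,) = values
        return -lam * t
    if name == "weibull":
        lam, k = values
        return -lam * np.power(t, k)
    if name == "gompertz":
        lam, gamma = values
        if abs(gamma) < _GOMPERTZ_EPS:
            return -lam * t
        return -lam * np.expm1(gamma * t) / gamma
    if name == "loglogistic":
        alpha, beta = values
        return -np.log1p(np.power(t / alpha, beta))
    raise ValueError(f"unknown family {name!r}")  # pragma: no cover


def _hazard_arr(name: str, values: np.ndarray, t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if name == "exponential":
        (lam,) = values
        return np.full_like(t, lam)
    if name == "weibull":
        lam, k = values
        return lam * k * np.power(t, k - 1.0)
    if name == "gompertz":
        lam, gamma = values
        return lam * np.exp(gamma * t)
    if name == "loglogistic":
        alpha, beta = values
        u = np.power(t / alpha, beta - 1.0)
        return (beta / alpha) * u / (1.0 + u * (t / alpha))
    raise ValueError(f"unknown family {name!r}")  # pragma: no cover


def log_survival_matrix(name: str, params: np.ndarray, t: np.ndarray) -> np.ndarray:
    """log S(t) with ``params`` shaped (..., dim) broadcasting against ``t``.

    Natural-scale parameters; intended for whole posterior-draw stacks.
    """
    if name == "exponential":
        return -params[..., 0:1] * t
    if name == "weibull":
        return -params[..., 0:1] * np.power(t, params[..., 1:2])
    if name == "gompertz":
        lam, gamma = params[..., 0:1], params[..., 1:2]
        safe = np.where(gamma == 0, 1.0, gamma)
        out = -lam * np.expm1(gamma * t) / safe
        return np.where(gamma == 0, -lam * t, out)
    if name == "loglogistic":
        return -np.log1p(np.power(t / params[..., 0:1], params[..., 1:2]))
    raise ValueError(f"unknown family {name!r}")


def hazard_matrix(name: str, params: np.ndarray, t: np.ndarray) -> np.ndarray:
    """h(t) with ``params`` shaped (..., dim) broadcasting against ``t > 0``."""
    if name == "exponential":
        return params[..., 0:1] * np.ones_like(t)
    if name == "weibull":
        lam, k = params[..., 0:1], params[..., 1:2]
        return lam * k * np.power(t, k - 1.0)
    if name == "gompertz":
        lam, gamma = params[..., 0:1], params[..., 1:2]
        return lam * np.exp(gamma * t)
    if name == "loglogistic":
        alpha, beta = params[..., 0:1], params[..., 1:2]
        u = np.power(t / alpha, beta - 1.0)
        return (beta / alpha) * u / (1.0 + u * (t / alpha))
    raise ValueError(f"unknown family {name!r}")


# ---------------------------------------------------------------------------
# public operations on ParamVector
# ---------------------------------------------------------------------------

def log_survival(theta: ParamVector, t) -> np.ndarray | float:
    """log S(t); vectorized over ``t``."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("survival requires t >= 0")
    out = _log_surv_arr(theta.family, np.asarray(theta.values), t_arr)
    return out if out.ndim else float(out)


def survival(theta: ParamVector, t) -> np.ndarray | float:
    """Survival probability S(t); vectorized over ``t``."""
    out = np.exp(log_survival(theta, t))
    return out if np.ndim(out) else float(out)


def hazard(theta: ParamVector, t) -> np.ndarray | float:
    """Instantaneous hazard h(t) in events per month; vectorized over ``t``.

    Raises for t = 0 when the hazard diverges there (Weibull shape < 1,
    log-logistic shape < 1).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("hazard requires t >= 0")
    name, values = theta.family, np.asarray(theta.values)
    if np.any(t_arr == 0):
        shape = values[1] if len(values) > 1 else None
        if name in ("weibull", "loglogistic") and shape is not None and shape < 1:
            raise ValueError(
                f"{name} hazard is infinite at t=0 for shape {shape} < 1"
            )
    out = _hazard_arr(name, values, t_arr)
    return out if out.ndim else float(out)


def interval_death_prob(theta: ParamVector, t0: float, t1: float) -> float:
    """P(death in (t0, t1] | alive at t0) = 1 - S(t1)/S(t0)."""
    if not 0 <= t0 < t1:
        raise ValueError(f"need 0 <= t0 < t1, got ({t0}, {t1})")
    ls0 = log_survival(theta, t0)
    ls1 = log_survival(theta, t1)
    if ls0 < np.log(np.finfo(float).tiny):  # S(t0) numerically zero
        raise ValueError(f"S(t0={t0}) = 0: no probability mass at risk under the model")
    return float(-np.expm1(ls1 - ls0))


def apply_effect(mu: ParamVector, delta: EffectVector) -> ParamVector:
    """Shift ``mu`` by ``delta`` on the transformed scale and back-transform."""
    if mu.family != delta.family:
        raise ValueError(
            f"family mismatch: parameters are {mu.family}, effect is {delta.family}"
        )
    spec = mu.spec
    z = mu.transformed() + np.asarray(delta.delta)
    return ParamVector(mu.family, tuple(untransform_params(spec, z)))


def hazard_ratio(theta_a: ParamVector, theta_b: ParamVector, t) -> np.ndarray | float:
    """h_a(t) / h_b(t); vectorized over ``t``."""
    h_a = np.asarray(hazard(theta_a, t), dtype=float)
    h_b = np.asarray(hazard(theta_b, t), dtype=float)
    if np.any(h_b == 0) or np.any(~np.isfinite(h_b)) or np.any(~np.isfinite(h_a)):
        raise ValueError("hazard ratio undefined: zero or non-finite hazard")
    out = h_a / h_b
    return out if out.ndim else float(out)


def inverse_survival(theta: ParamVector, u) -> np.ndarray | float:
    """Solve S(t) = u for t; returns inf where the target is never reached.

    Vectorized over ``u`` (each entry in (0, 1]).  A defective Gompertz
    distribution (negative shape) has S(inf) > 0, so draws below that
    plateau map to infinite survival times.
    """
    u_arr = np.asarray(u, dtype=float)
    if np.any((u_arr <= 0) | (u_arr > 1)):
        raise ValueError("u must lie in (0, 1]")
    name, values = theta.family, np.asarray(theta.values)
    neg_log_u = -np.log(u_arr)
    if name == "exponential":
        (lam,) = values
        out = neg_log_u / lam
    elif name == "weibull":
        lam, k = values
        out = np.power(neg_log_u / lam, 1.0 / k)
    elif name == "gompertz":
        lam, gamma = values
        if abs(gamma) < _GOMPERTZ_EPS:
            out = neg_log_u / lam
        else:
            arg = 1.0 + gamma * neg_log_u / lam
            with np.errstate(invalid="ignore", divide="ignore"):
                out = np.where(arg > 0, np.log(np.maximum(arg, 1e-300)) / gamma, np.inf)
    elif name == "loglogistic":
        alpha, beta = values
        with np.errstate(divide="ignore"):
            out = alpha * np.power(1.0 / u_arr - 1.0, 1.0 / beta)
    else:  # pragma: no cover
        raise ValueError(f"unknown family {name!r}")
    return out if out.ndim else float(out)
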