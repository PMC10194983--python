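"""Trend families for annual mortality proportions.

Two secular-trend families are supported, each with any number of
superimposed lognormal-density excess terms inside the linear predictor:

* ``"logistic"`` — a floored logistic curve
  ``rate(t) = alpha + (1 - alpha) * expit(eta(t))`` whose lower limit
  ``alpha`` represents the irreducible mortality floor, with a linear
  time trend ``eta = beta1 + beta2*t + ...``;
* ``"expcubic"`` — an exponential of a cubic polynomial,
  ``rate(t) = exp(beta1 + beta2*t + beta3*t^2 + beta4*t^3 + ...)``.

Each excess term contributes ``(a / t) * exp(-(log t - mu)^2 / (2 sigma^2))``
to the linear predictor: a lognormal density in time, scaled by the
amplitude ``a``.  Its maximum in time is at ``t = exp(mu - sigma^2)`` (the
lognormal mode).  Terms may share a common width through *width ties*, and a
designated *war term* can model a pre-baseline disturbance that is treated
as part of the undisturbed trend when estimating post-war excess.  Pulse and
step intervention dummies (for reporting-definition changes) are also
additive in the linear predictor.

The model time index is ``t = year - time_origin`` (default origin 1930) and
must satisfy ``t >= 1`` so ``log t`` is defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "ExcessTerm",
    "Intervention",
    "ModelSpec",
    "ParameterSet",
    "excess_term",
    "linear_predictor",
    "eval_rate",
    "undisturbed_rate",
]

Family = Literal["logistic", "expcubic"]

# interface aliases for the two families (and the war-term variant)
_FAMILY_ALIASES = {
    "logistic": "logistic",
    "model1": "logistic",
    "expcubic": "expcubic",
    "model2": "expcubic",
    "model3": "expcubic",  # expcubic trend + designated war term
}


@dataclass(frozen=True)
class ExcessTerm:
    """One lognormal-density excess term ``(a/t)·exp(−(log t − mu)²/(2 sigma²))``.

    ``mu`` is the location on the log-time scale (the log of the median year
    offset) and ``sigma`` the log-time width (geometric standard deviation).
    """

    amplitude: float
    mu: float
    sigma: float

    @property
    def mode_t(self) -> float:
        """Time index of the term's maximum, ``exp(mu − sigma²)``."""
        return float(np.exp(self.mu - self.sigma**2))


@dataclass(frozen=True)
class Intervention:
    """A dummy regressor in the linear predictor.

    ``kind="pulse"`` is active in ``year`` only; ``kind="step"`` is active
    from ``year`` onward (a level shift).
    """

    kind: Literal["pulse", "step"]
    year: int

    def design(self, years: np.ndarray) -> np.ndarray:
        years = np.asarray(years)
        if self.kind == "pulse":
            return (years == self.year).astype(float)
        if self.kind == "step":
            return (years >= self.year).astype(float)
        raise ValueError(f"unknown intervention kind {self.kind!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Structural description of a trend model.

    Parameters
    ----------
    family
        ``"logistic"`` (floored logistic, linear trend) or ``"expcubic"``
        (exponential cubic trend).  The aliases ``"model1"``/``"model2"`` are
        accepted; ``"model3"`` means the expcubic family with the first
        excess term designated as the war term.
    n_excess
        Number of excess terms, including a war term if present.
    width_ties
        Map ``tied index -> master index`` (0-based) forcing equal widths;
        a tied index must be greater than its master.
    war_term
        If True, excess term 0 models a pre-baseline wartime disturbance and
        is by default retained in the undisturbed trend.
    interventions
        Dummy regressors (pulse/step) added to the linear predictor.
    time_origin
        Calendar year mapped to ``t = 0``.
    """

    family: str = "logistic"
    n_excess: int = 0
    width_ties: Mapping[int, int] = field(default_factory=dict)
    war_term: bool = False
    interventions: tuple[Intervention, ...] = ()
    time_origin: int = 1930

    def __post_init__(self) -> None:
        fam = _FAMILY_ALIASES.get(str(self.family).lower())
        if fam is None:
            raise ValueError(f"unknown family {self.family!r}")
        war = self.war_term or str(self.family).lower() == "model3"
        object.__setattr__(self, "family", fam)
        object.__setattr__(self, "war_term", war)
        object.__setattr__(self, "width_ties", dict(self.width_ties))
        object.__setattr__(self, "interventions", tuple(self.interventions))
        if self.n_excess < 0:
            raise ValueError("n_excess must be >= 0")
        for tied, master in self.width_ties.items():
            if not (0 <= master < tied < self.n_excess):
                raise ValueError(
                    f"width tie {tied}->{master}: tied index must exceed its master "
                    f"and both must be < n_excess={self.n_excess}"
                )
        if self.war_term and self.n_excess < 1:
            raise ValueError("war_term requires at least one excess term")

    # -- tie resolution -----------------------------------------------------

    def master_of(self, k: int) -> int:
        """Resolve the width master of term ``k`` (itself if untied)."""
        seen = set()
        while k in self.width_ties:
            if k in seen:
                raise ValueError("cyclic width tie")
            seen.add(k)
            k = self.width_ties[k]
        return k

    def with_n_excess(self, n: int) -> "ModelSpec":
        """Copy of the spec with ``n`` excess terms (ties restricted to < n)."""
        ties = {k: v for k, v in self.width_ties.items() if k < n and v < n}
        return replace(self, n_excess=n, width_ties=ties,
                       war_term=self.war_term and n >= 1)

    def free_parameter_names(self) -> list[str]:
        """Names of the free parameters, in packing order."""
        if self.family == "logistic":
            names = ["alpha", "beta1", "beta2"]
        else:
            names = ["beta1", "beta2", "beta3", "beta4"]
        for k in range(self.n_excess):
            names += [f"a{k + 1}", f"mu{k + 1}"]
            if self.master_of(k) == k:
                names.append(f"sigma{k + 1}")
        names += [f"iv{j + 1}" for j in range(len(self.interventions))]
        return names

    @property
    def n_free(self) -> int:
        return len(self.free_parameter_names())

    def pack(self, params: "ParameterSet") -> np.ndarray:
        """Flatten a consistent ParameterSet into the free-parameter vector."""
        self.validate_params(params)
        x: list[float] = []
        if self.family == "logistic":
            x.append(params.alpha)
        x += [params.beta1, params.beta2]
        if self.family == "expcubic":
            x += [params.beta3, params.beta4]
        for k, term in enumerate(params.excess):
            x += [term.amplitude, term.mu]
            if self.master_of(k) == k:
                x.append(term.sigma)
        x += list(params.interventions)
        return np.asarray(x, dtype=float)

    def unpack(self, x: Sequence[float]) -> "ParameterSet":
        """Rebuild a ParameterSet from the free vector, applying width ties."""
        x = np.asarray(x, dtype=float)
        if x.size != self.n_free:
            raise ValueError(f"expected {self.n_free} free parameters, got {x.size}")
        i = 0
        alpha = None
        beta3 = beta4 = 0.0
        if self.family == "logistic":
            alpha = float(x[i]); i += 1
        beta1 = float(x[i]); beta2 = float(x[i + 1]); i += 2
        if self.family == "expcubic":
            beta3 = float(x[i]); beta4 = float(x[i + 1]); i += 2
        raw: list[list[float]] = []
        for k in range(self.n_excess):
            a = float(x[i]); mu = float(x[i + 1]); i += 2
            if self.master_of(k) == k:
                sigma = float(x[i]); i += 1
            else:
                sigma = np.nan  # filled below from master
            raw.append([a, mu, sigma])
        for k in range(self.n_excess):
            m = self.master_of(k)
            if m != k:
                raw[k][2] = raw[m][2]
        ivs = tuple(float(v) for v in x[i:])
        terms = tuple(ExcessTerm(*r) for r in raw)
        return ParameterSet(alpha=alpha, beta1=beta1, beta2=beta2, beta3=beta3,
                            beta4=beta4, excess=terms, interventions=ivs)

    def validate_params(self, params: "ParameterSet") -> None:
        if self.family == "logistic":
            if params.alpha is None:
                raise ValueError("logistic family requires alpha")
            if params.beta3 != 0.0 or params.beta4 != 0.0:
                raise ValueError("logistic family has no quadratic/cubic trend terms")
        elif params.alpha is not None:
            raise ValueError("expcubic family has no alpha")
        if len(params.excess) != self.n_excess:
            raise ValueError(
                f"spec declares {self.n_excess} excess term(s), "
                f"parameters carry {len(params.excess)}"
            )
        if len(params.interventions) != len(self.interventions):
            raise ValueError("intervention coefficient count mismatch")
        for k, term in enumerate(params.excess):
            m = self.master_of(k)
            if m != k and term.sigma != params.excess[m].sigma:
                raise ValueError(f"tied width of term {k} differs from master {m}")
            if m == k and not term.sigma > 0:
                raise ValueError(f"sigma of term {k} must be > 0")


@dataclass(frozen=True)
class ParameterSet:
    """All model coefficients for one :class:`ModelSpec`.

    ``alpha`` is the mortality floor (logistic family only, a proportion in
    [0, 1)); ``beta1`` the intercept and ``beta2`` the linear slope per year
    of the linear predictor; ``beta3``/``beta4`` the quadratic and cubic
    coefficients (expcubic family only).  ``excess`` holds the lognormal
    terms in order; ``interventions`` the dummy coefficients, matching the
    spec's intervention declarations.
    """

    beta1: float
    beta2: float
    alpha: float | None = None
    beta3: float = 0.0
    beta4: float = 0.0
    excess: tuple[ExcessTerm, ...] = ()
    interventions: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.alpha is not None and not (0.0 <= self.alpha < 1.0):
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")
        terms = tuple(
            t if isinstance(t, ExcessTerm) else ExcessTerm(*t) for t in self.excess
        )
        object.__setattr__(self, "excess", terms)
        object.__setattr__(self, "interventions", tuple(float(v) for v in self.interventions))

    def zero_excess(self, keep: Iterable[int] = (), zero_interventions: bool = False) -> "ParameterSet":
        """Copy with excess amplitudes set to zero except indices in ``keep``."""
        keep = set(keep)
        terms = tuple(
            t if k in keep else replace(t, amplitude=0.0) for k, t in enumerate(self.excess)
        )
        ivs = tuple(0.0 for _ in self.interventions) if zero_interventions else self.interventions
        return replace(self, excess=terms, interventions=ivs)


# ---------------------------------------------------------------------------
# model evaluation


def _check_t(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 1):
        raise ValueError(f"time index must be >= 1 (log-time undefined); got min {t.min()}")
    return t


def excess_term(t, amplitude: float, mu: float, sigma: float) -> np.ndarray:
    """Evaluate ``(a/t)·exp(−(log t − mu)²/(2 sigma²))`` on ``t >= 1``."""
    t = _check_t(t)
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    z = (np.log(t) - mu) / sigma
    return (amplitude / t) * np.exp(-0.5 * z * z)


def linear_predictor(t, params: ParameterSet, spec: ModelSpec, years=None) -> np.ndarray:
    """Linear predictor eta(t): polynomial trend + excess terms + interventions."""
    spec.validate_params(params)
    t = _check_t(t)
    eta = params.beta1 + params.beta2 * t
    if spec.family == "expcubic":
        eta = eta + params.beta3 * t**2 + params.beta4 * t**3
    for term in params.excess:
        eta = eta + excess_term(t, term.amplitude, term.mu, term.sigma)
    if spec.interventions:
        if years is None:
            years = np.asarray(t) + spec.time_origin
        for iv, coef in zip(spec.interventions, params.interventions):
            eta = eta + coef * iv.design(np.asarray(years))
    return eta


def eval_rate(t, params: ParameterSet, spec: ModelSpec, years=None) -> np.ndarray:
    """Predicted mortality proportion at time index ``t``.

    Logistic family: ``alpha + (1 - alpha) * expit(eta)`` (stable for any
    finite eta).  Expcubic family: ``exp(eta)``; a predictor large enough to
    overflow yields ``inf`` and is reported by the caller, never clamped.
    """
    eta = linear_predictor(t, params, spec, years=years)
    if np.any(np.isnan(eta)):
        raise ValueError("NaN in linear predictor (check parameters)")
    if spec.family == "logistic":
        return params.alpha + (1.0 - params.alpha) * expit(eta)
    with np.errstate(over="ignore"):
        return np.exp(eta)


def undisturbed_rate(
    t,
    params: ParameterSet,
    spec: ModelSpec,
    years=None,
    zero_war_term: bool = False,
    zero_interventions: bool = False,
) -> np.ndarray:
    """Predicted rate with the excess bells switched off (the secular trend).

    A designated war term is retained by default: it models a disturbance
    before the excess-estimation window and is part of the baseline there.
    Intervention dummies are likewise retained by default (they encode
    reporting changes, not excess mortality).
    """
    keep = {0} if (spec.war_term and not zero_war_term) else set()
    base = params.zero_excess(keep=keep, zero_interventions=zero_interventions)
    return eval_rate(t, base, spec, years=years)
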