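"""Binomial-variance reweighted nonlinear least squares for rate trends.

The estimator minimises the weighted residual sum of squares

    sum_y  (obs_y - rate_y(theta))^2 / var_y,   var_y = fit_y (1 - fit_y) / LB_y,

where ``LB_y`` is the number of live births in year ``y``.  The variance is
the binomial variance of an observed proportion at the *fitted* rate, so the
weights depend on the parameters: fitting iterates between minimising the
frozen-weight objective and refreshing the weights from the current fit
(iteratively reweighted nonlinear least squares), to a fixed point.  The
reported ``deviance`` is the Pearson-type weighted residual sum of squares
at the converged fit, and ``overdispersion = deviance / df`` measures
extra-binomial variability (values far above 1 are typical of national
vital-statistics series).

A Poisson log-linear trend fit with a polynomial time trend and a
``log(births)`` offset is also provided (:func:`fit_loglinear_trend`) for
legacy-style excess estimation by window exclusion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import find_peaks
from scipy.special import logit

import statsmodels.api as sm

from .models import ExcessTerm, ModelSpec, ParameterSet, eval_rate, linear_predictor
from .series import MortalitySeries

logger = logging.getLogger(__name__)

__all__ = [
    "FitResult",
    "IdentifiabilityError",
    "deviance_and_residuals",
    "fit_model",
    "initialize_parameters",
    "fit_loglinear_trend",
]

#: relative deviance change below which outer reweighting stops
REWEIGHT_TOL = 1e-8
#: maximum outer reweighting cycles
MAX_REWEIGHT = 25
#: lower bound on free lognormal widths
SIGMA_FLOOR = 1e-3


class IdentifiabilityError(RuntimeError):
    """Raised when the weighted Jacobian is numerically singular."""


@dataclass
class FitResult:
    """Result of a weighted nonlinear (or log-linear) trend fit.

    ``se``/``tvalues`` are keyed by free-parameter name; tied widths appear
    once, under their master's name.  ``deviance`` is the binomial-variance
    weighted residual sum of squares, ``df`` the observations minus free
    parameters, and ``overdispersion = deviance / df``.
    """

    spec: ModelSpec
    params: ParameterSet
    se: dict[str, float]
    tvalues: dict[str, float]
    fitted: np.ndarray
    var: np.ndarray
    deviance: float
    df: int
    overdispersion: float
    converged: bool
    n_iter: int
    free_names: list[str]
    cov: np.ndarray | None = None
    fixed: dict[str, float] = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        """Estimate / SE / t-value table in fit order."""
        x = self.spec.pack(self.params)
        names = self.spec.free_parameter_names()
        rows = []
        for name, est in zip(names, x):
            if name in self.fixed:
                rows.append((name, est, np.nan, np.nan, "fixed"))
            else:
                rows.append((name, est, self.se.get(name, np.nan),
                             self.tvalues.get(name, np.nan), ""))
        return pd.DataFrame(rows, columns=["parameter", "estimate", "se", "t", "note"])


def deviance_and_residuals(
    observed: np.ndarray, fitted: np.ndarray, births: np.ndarray
) -> tuple[float, np.ndarray]:
    """Weighted deviance and standardized residuals under binomial variance.

    ``residual_y = (obs_y - fit_y) / sqrt(fit_y (1 - fit_y) / births_y)`` and
    the deviance is the sum of squared residuals.  Residuals are in units of
    standard deviations, so they are invariant to the per-1000 presentation
    convention.
    """
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    births = np.asarray(births, dtype=float)
    if np.any(fitted <= 0.0) or np.any(fitted >= 1.0):
        raise ValueError("fitted proportions must lie strictly in (0, 1)")
    var = fitted * (1.0 - fitted) / births
    resid = (observed - fitted) / np.sqrt(var)
    return float(resid @ resid), resid


# ---------------------------------------------------------------------------
# initialisation


def _crude_trend_params(series: MortalitySeries, spec: ModelSpec) -> ParameterSet:
    """Closed-form starting values for the trend part (no excess terms)."""
    t = series.t.astype(float)
    r = series.rate
    if spec.family == "logistic":
        alpha0 = 0.8 * float(r.min())
        u = np.clip((r - alpha0) / (1.0 - alpha0), 1e-9, 1 - 1e-9)
        b2, b1 = np.polyfit(t, logit(u), 1)
        return ParameterSet(alpha=alpha0, beta1=float(b1), beta2=float(b2))
    coef = np.polyfit(t, np.log(r), 3)  # highest power first
    b4, b3, b2, b1 = (float(c) for c in coef)
    return ParameterSet(beta1=b1, beta2=b2, beta3=b3, beta4=b4)


def _predictor_scale_residual(
    series: MortalitySeries, params: ParameterSet, spec: ModelSpec
) -> np.ndarray:
    """Observed minus fitted on the linear-predictor (log / logit) scale."""
    t = series.t.astype(float)
    eta_fit = linear_predictor(t, params, spec, years=series.year)
    r = series.rate
    if spec.family == "logistic":
        u = np.clip((r - params.alpha) / (1.0 - params.alpha), 1e-9, 1 - 1e-9)
        eta_obs = logit(u)
    else:
        eta_obs = np.log(r)
    return eta_obs - eta_fit


def _terms_from_residual_peaks(
    series: MortalitySeries, delta: np.ndarray, n_terms: int, sigma0: float = 0.15
) -> list[ExcessTerm]:
    """Seed excess terms at positive residual peaks by iterative peeling.

    The highest-prominence positive peak at time ``t_p`` with
    predictor-scale height ``d_p`` seeds a term with ``mu = log t_p``,
    ``sigma = sigma0`` and amplitude ``a = d_p * t_p`` (the term's central
    contribution is ``a / t``); that term's contribution is subtracted and
    the search repeats, so overlapping bells are peeled off one at a time.
    Missing peaks are filled at equally spaced time quantiles.
    """
    t = series.t.astype(float)
    work = np.asarray(delta, dtype=float).copy()
    terms: list[ExcessTerm] = []
    for _ in range(n_terms):
        idx, props = find_peaks(work, prominence=0.0)
        positive = work[idx] > 0
        if not positive.any():
            break
        idx, prom = idx[positive], props["prominences"][positive]
        i = idx[int(np.argmax(prom))]
        term = ExcessTerm(float(work[i] * t[i]), float(np.log(t[i])), sigma0)
        terms.append(term)
        work = work - excess_term_eval(t, term)
    missing = n_terms - len(terms)
    if missing > 0:
        logger.info("only %d residual peak(s) found for %d excess term(s); "
                    "seeding the rest at time quantiles", len(terms), n_terms)
        scale = float(np.median(np.abs(delta))) or 1e-3
        qs = np.quantile(t, [(j + 1) / (missing + 1) for j in range(missing)])
        terms += [ExcessTerm(0.5 * scale * float(tq), float(np.log(tq)), sigma0) for tq in qs]
    terms.sort(key=lambda term: term.mu)
    return terms


def excess_term_eval(t: np.ndarray, term: ExcessTerm) -> np.ndarray:
    z = (np.log(t) - term.mu) / term.sigma
    return (term.amplitude / t) * np.exp(-0.5 * z * z)


def _with_terms(params: ParameterSet, spec_n: ModelSpec,
                terms: Sequence[ExcessTerm]) -> ParameterSet:
    """Attach ``terms`` (time-ordered, ties applied) to ``params``."""
    from dataclasses import replace as _replace

    terms = sorted(terms, key=lambda term: term.mu)
    sigmas = [term.sigma for term in terms]
    for k in range(spec_n.n_excess):
        m = spec_n.master_of(k)
        sigmas[k] = sigmas[m]
    terms = tuple(ExcessTerm(t.amplitude, t.mu, s) for t, s in zip(terms, sigmas))
    return _replace(params, excess=terms)


def augment_with_new_terms(
    series: MortalitySeries, prev_params: ParameterSet, prev_spec: ModelSpec,
    spec_n: ModelSpec,
) -> ParameterSet:
    """Previous estimates plus residual-seeded new term(s), ordered in time."""
    n_new = spec_n.n_excess - len(prev_params.excess)
    if n_new <= 0:
        return prev_params
    delta = _predictor_scale_residual(series, prev_params, prev_spec)
    new_terms = _terms_from_residual_peaks(series, delta, n_new)
    return _with_terms(prev_params, spec_n, prev_params.excess + tuple(new_terms))


def candidate_augmented_inits(
    series: MortalitySeries, prev_params: ParameterSet, prev_spec: ModelSpec,
    spec_n: ModelSpec, n_candidates: int = 3, sigma0s: Sequence[float] = (0.15, 0.08),
) -> list[ParameterSet]:
    """Candidate starting points for one added excess term.

    One candidate per (residual peak, starting width) pair, peaks taken in
    decreasing prominence.  Fitting every candidate and keeping the lowest
    deviance avoids committing to the wrong peak when bells overlap.
    """
    if spec_n.n_excess - len(prev_params.excess) != 1:
        return [augment_with_new_terms(series, prev_params, prev_spec, spec_n)]
    delta = _predictor_scale_residual(series, prev_params, prev_spec)
    t = series.t.astype(float)
    idx, props = find_peaks(delta, prominence=0.0)
    positive = delta[idx] > 0
    idx, prom = idx[positive], props["prominences"][positive]
    order = np.argsort(prom)[::-1][:n_candidates]
    inits = []
    for i in idx[order]:
        for s0 in sigma0s:
            term = ExcessTerm(float(delta[i] * t[i]), float(np.log(t[i])), s0)
            inits.append(_with_terms(prev_params, spec_n,
                                     prev_params.excess + (term,)))
    if not inits:
        inits = [augment_with_new_terms(series, prev_params, prev_spec, spec_n)]
    return inits


def initialize_parameters(series: MortalitySeries, spec: ModelSpec) -> ParameterSet:
    """Deterministic staged starting values for :func:`fit_model`.

    Stage one fits the trend-only family; stage two seeds lognormal terms at
    prominent positive residual peaks on the predictor scale, introducing
    the bells one at a time (each intermediate model is refitted before the
    next bell is seeded, so overlapping bells are resolved correctly).  The
    result depends only on the series and the spec (no randomness).
    """
    if spec.n_excess > 1:
        return _stagewise_init(series, spec)
    return _oneshot_init(series, spec)


def _oneshot_init(series: MortalitySeries, spec: ModelSpec) -> ParameterSet:
    """Trend-only fit, then all bells seeded at once from peeled residual peaks."""
    trend_spec = ModelSpec(family=spec.family, interventions=spec.interventions,
                           time_origin=spec.time_origin)
    crude = ParameterSet(
        **{**_crude_trend_params(series, spec).__dict__,
           "interventions": tuple(0.0 for _ in spec.interventions)}
    )
    if spec.n_excess == 0:
        return crude
    trend_fit = fit_model(series, trend_spec, init=crude, compute_se=False)
    base = trend_fit.params
    delta = _predictor_scale_residual(series, base, trend_spec)
    terms = _terms_from_residual_peaks(series, delta, spec.n_excess)
    # honour width ties in the starting point
    sigmas = [term.sigma for term in terms]
    for k in range(spec.n_excess):
        m = spec.master_of(k)
        sigmas[k] = sigmas[m]
    terms = tuple(ExcessTerm(t.amplitude, t.mu, s) for t, s in zip(terms, sigmas))
    return ParameterSet(
        alpha=base.alpha, beta1=base.beta1, beta2=base.beta2,
        beta3=base.beta3, beta4=base.beta4, excess=terms,
        interventions=base.interventions,
    )


def _tie_sigmas(spec: ModelSpec, terms: Sequence[ExcessTerm]) -> tuple[ExcessTerm, ...]:
    """Apply width ties positionally (no reordering)."""
    sigmas = [term.sigma for term in terms]
    for k in range(len(terms)):
        m = spec.master_of(k)
        sigmas[k] = sigmas[m]
    return tuple(ExcessTerm(t.amplitude, t.mu, s) for t, s in zip(terms, sigmas))


def _reseed_polish(
    series: MortalitySeries, spec: ModelSpec, fit: FitResult,
    fixed: Mapping[str, float] | None = None, max_rounds: int = 2, **fit_kwargs,
) -> FitResult:
    """Escape local minima by reseeding one bell at a time.

    Each bell in turn is removed, the model refitted residuals are scanned
    for the strongest positive peak, the bell is reseeded there (at two
    candidate widths) and the model refitted; any refit that lowers the
    deviance is kept.  Rounds repeat until no bell moves.  Deterministic.
    """
    from dataclasses import replace as _replace

    t = series.t.astype(float)
    best = fit
    for _ in range(max_rounds):
        improved = False
        for k in range(spec.n_excess):
            dropped = _replace(
                best.params,
                excess=_tie_sigmas(spec, tuple(
                    _replace(term, amplitude=0.0) if j == k else term
                    for j, term in enumerate(best.params.excess))),
            )
            delta = _predictor_scale_residual(series, dropped, spec)
            idx, props = find_peaks(delta, prominence=0.0)
            positive = delta[idx] > 0
            if not positive.any():
                continue
            idx, prom = idx[positive], props["prominences"][positive]
            i = idx[int(np.argmax(prom))]
            for s0 in (0.15, 0.05):
                terms = list(best.params.excess)
                terms[k] = ExcessTerm(float(delta[i] * t[i]), float(np.log(t[i])), s0)
                cand = _replace(best.params, excess=_tie_sigmas(spec, tuple(terms)))
                try:
                    trial = _irls_fit(series, spec, cand, fixed,
                                      compute_se=False, **fit_kwargs)
                except Exception:
                    continue
                if trial.deviance < best.deviance * (1 - 1e-9):
                    best = trial
                    improved = True
        if not improved:
            break
    return best


def _stagewise_init(series: MortalitySeries, spec: ModelSpec,
                    fixed: Mapping[str, float] | None = None,
                    **fit_kwargs) -> ParameterSet:
    """Starting values for a multi-bell fit by stepwise build-up.

    Bells are introduced one at a time — fit one term, seed the next from
    the residuals of the current fit, refit — mirroring how such models are
    refined in practice.  Far more robust than seeding every term at once
    when bells overlap.  Deterministic.
    """
    fit_kwargs = {**fit_kwargs, "compute_se": False}

    def step_fixed(spec_n: ModelSpec) -> dict[str, float]:
        names = set(spec_n.free_parameter_names())
        return {k: v for k, v in (fixed or {}).items() if k in names}

    spec1 = spec.with_n_excess(1)
    current = _irls_fit(series, spec1, initialize_parameters(series, spec1),
                        step_fixed(spec1), **fit_kwargs)
    for n in range(2, spec.n_excess + 1):
        spec_n = spec.with_n_excess(n)
        best = None
        for init_n in candidate_augmented_inits(series, current.params,
                                                spec.with_n_excess(n - 1), spec_n):
            trial = _irls_fit(series, spec_n, init_n, step_fixed(spec_n), **fit_kwargs)
            if best is None or trial.deviance < best.deviance:
                best = trial
        current = best
    return current.params


# ---------------------------------------------------------------------------
# the estimator


def _bounds(names: Sequence[str], series: MortalitySeries) -> tuple[np.ndarray, np.ndarray]:
    lo = np.full(len(names), -np.inf)
    hi = np.full(len(names), np.inf)
    max_mu = np.log(float(series.t.max())) + 1.0
    for i, name in enumerate(names):
        if name == "alpha":
            lo[i], hi[i] = 0.0, float(series.rate.min())
        elif name.startswith("sigma"):
            lo[i] = SIGMA_FLOOR
        elif name.startswith("mu"):
            lo[i], hi[i] = 0.0, max_mu
    return lo, hi


def _check_identifiable(jac: np.ndarray, names: Sequence[str]) -> np.ndarray:
    """Covariance from the weighted Jacobian; raise if numerically singular.

    Columns are normalised before the conditioning test so that parameter
    units (e.g. cubic time coefficients) do not masquerade as collinearity.
    """
    norms = np.linalg.norm(jac, axis=0)
    if np.any(norms == 0):
        worst = [names[i] for i in np.flatnonzero(norms == 0)]
        raise IdentifiabilityError(f"parameter(s) without leverage: {worst}")
    u, s, vt = np.linalg.svd(jac / norms, full_matrices=False)
    if s[0] <= 0 or s[-1] / s[0] < 1e-9:
        null = np.abs(vt[-1])
        worst = [names[i] for i in np.argsort(null)[::-1][:3]]
        raise IdentifiabilityError(
            "weighted Jacobian is numerically singular; near-collinear "
            f"parameter(s): {worst}"
        )
    vinv = vt.T / s
    return (vinv @ vinv.T) / np.outer(norms, norms)


def fit_model(
    series: MortalitySeries,
    spec: ModelSpec,
    init: ParameterSet | None = None,
    fixed: Mapping[str, float] | None = None,
    *,
    one_shot: bool = False,
    od_scaled_se: bool = False,
    compute_se: bool = True,
    max_outer: int = MAX_REWEIGHT,
    rel_tol: float = REWEIGHT_TOL,
) -> FitResult:
    """Fit a trend model by iteratively reweighted nonlinear least squares.

    Parameters
    ----------
    series, spec
        Data and model structure.  Every modelled year must have ``t >= 1``.
    init
        Starting :class:`ParameterSet`; derived with
        :func:`initialize_parameters` when omitted.
    fixed
        Map of free-parameter names to frozen values (used for profile
        likelihood and slope-fixed refits).  Fixed parameters do not count
        against the residual degrees of freedom.
    one_shot
        Stop after a single weighted pass instead of iterating the weights
        to a fixed point (sensitivity option).
    od_scaled_se
        Scale the covariance by the overdispersion, inflating the standard
        errors accordingly.
    compute_se
        Skip the covariance computation (cheaper; used in inner refits).

    Notes
    -----
    Non-convergence of the outer reweighting loop is flagged on the result
    and warned about, never raised.  A numerically singular weighted
    Jacobian raises :class:`IdentifiabilityError` naming the near-collinear
    parameters.

    When no starting point is supplied and the model has two or more excess
    terms, the fit is built up stagewise (one bell at a time) and finished
    with a deterministic reseeding pass over the bells, which guards against
    local minima from overlapping bells.
    """
    auto = init is None
    kw = dict(one_shot=one_shot, max_outer=max_outer, rel_tol=rel_tol)
    if not (auto and spec.n_excess >= 2):
        if auto:
            init = initialize_parameters(series, spec)
        return _irls_fit(series, spec, init, fixed,
                         od_scaled_se=od_scaled_se, compute_se=compute_se, **kw)
    # auto-started multi-bell fit: race the two deterministic starting
    # strategies, polish each by bell reseeding, keep the lower deviance.
    # The search runs at reduced precision (capped reweighting cycles,
    # looser inner tolerances); the winner is refitted at full precision.
    search = dict(one_shot=one_shot, max_outer=min(max_outer, 8),
                  rel_tol=max(rel_tol, 1e-7), inner_tol=1e-10, warn=False)
    starts = [
        _stagewise_init(series, spec, fixed=fixed, **search),
        _oneshot_init(series, spec),
    ]
    best: FitResult | None = None
    for start in starts:
        try:
            trial = _irls_fit(series, spec, start, fixed, compute_se=False, **search)
            trial = _reseed_polish(series, spec, trial, fixed=fixed, **search)
        except Exception:
            continue
        if best is None or trial.deviance < best.deviance:
            best = trial
    if best is None:  # both paths failed; surface the error from the first
        return _irls_fit(series, spec, starts[0], fixed,
                         od_scaled_se=od_scaled_se, compute_se=compute_se, **kw)
    return _irls_fit(series, spec, best.params, fixed,
                     od_scaled_se=od_scaled_se, compute_se=compute_se, **kw)


def _irls_fit(
    series: MortalitySeries,
    spec: ModelSpec,
    init: ParameterSet,
    fixed: Mapping[str, float] | None = None,
    *,
    one_shot: bool = False,
    od_scaled_se: bool = False,
    compute_se: bool = True,
    max_outer: int = MAX_REWEIGHT,
    rel_tol: float = REWEIGHT_TOL,
    inner_tol: float = 1e-12,
    warn: bool = True,
) -> FitResult:
    """One iteratively reweighted fit from an explicit starting point."""
    if np.any(series.t < 1):
        raise ValueError("all modelled years must satisfy t >= 1; "
                         "restrict the series or change the time origin")
    fixed = dict(fixed or {})
    names = spec.free_parameter_names()
    unknown = set(fixed) - set(names)
    if unknown:
        raise ValueError(f"fixed parameter(s) {sorted(unknown)} not in model: {names}")
    free_idx = [i for i, n in enumerate(names) if n not in fixed]
    free_names = [names[i] for i in free_idx]
    n_obs = len(series)
    if len(free_names) >= n_obs:
        raise ValueError(f"{len(free_names)} free parameters for {n_obs} observations")

    x_full = spec.pack(init)
    for name, value in fixed.items():
        x_full[names.index(name)] = float(value)

    t = series.t.astype(float)
    obs = series.rate
    births = series.births.astype(float)
    lo_full, hi_full = _bounds(names, series)
    x_full = np.clip(x_full, lo_full, hi_full)
    lo, hi = lo_full[free_idx], hi_full[free_idx]

    def rate_of(x_free: np.ndarray) -> np.ndarray:
        xf = x_full.copy()
        xf[free_idx] = x_free
        return eval_rate(t, spec.unpack(xf), spec, years=series.year)

    def self_weighted_deviance(x_free: np.ndarray) -> float:
        fit = rate_of(x_free)
        if np.any(fit <= 0) or np.any(fit >= 1):
            return np.inf
        dev, _ = deviance_and_residuals(obs, fit, births)
        return dev

    x = x_full[free_idx].copy()
    dev = self_weighted_deviance(x)
    converged = False
    res = None
    n_outer = 0
    for n_outer in range(1, max_outer + 1):
        fit = rate_of(x)
        fit = np.clip(fit, 1e-12, 1 - 1e-12)  # weights only
        w = 1.0 / np.sqrt(fit * (1.0 - fit) / births)

        def weighted_residual(x_free: np.ndarray) -> np.ndarray:
            return (obs - rate_of(x_free)) * w

        res = least_squares(
            weighted_residual, x, bounds=(lo, hi), method="trf",
            x_scale="jac", ftol=inner_tol, xtol=inner_tol, gtol=inner_tol,
            max_nfev=2000,
        )
        x = res.x
        new_dev = self_weighted_deviance(x)
        if one_shot:
            converged = True
            break
        if abs(new_dev - dev) <= rel_tol * max(new_dev, 1e-12):
            dev = new_dev
            converged = True
            break
        dev = new_dev
    if not converged and warn:
        warnings.warn("reweighting did not converge within "
                      f"{max_outer} cycles (deviance {dev:.6g})", RuntimeWarning)

    x_full[free_idx] = x
    params = spec.unpack(x_full)
    fitted = eval_rate(t, params, spec, years=series.year)
    deviance, _ = deviance_and_residuals(obs, fitted, births)
    var = fitted * (1.0 - fitted) / births
    df = n_obs - len(free_names)
    od = deviance / df

    se: dict[str, float] = {}
    tv: dict[str, float] = {}
    cov = None
    if compute_se and res is not None:
        cov = _check_identifiable(res.jac, free_names)
        if od_scaled_se:
            cov = cov * od
        ses = np.sqrt(np.diag(cov))
        se = dict(zip(free_names, ses.tolist()))
        tv = {n: float(x[i] / ses[i]) if ses[i] > 0 else np.nan
              for i, n in enumerate(free_names)}

    return FitResult(
        spec=spec, params=params, se=se, tvalues=tv, fitted=fitted, var=var,
        deviance=float(deviance), df=int(df), overdispersion=float(od),
        converged=converged, n_iter=n_outer, free_names=free_names,
        cov=cov, fixed=fixed,
    )


# ---------------------------------------------------------------------------
# Poisson log-linear trend (legacy-style window-exclusion analyses)


def fit_loglinear_trend(
    series: MortalitySeries,
    degree: int = 2,
    exclude_window: tuple[int, int] | None = None,
) -> FitResult:
    """Poisson log-linear trend fit with a polynomial in time.

    Models ``deaths ~ Poisson(births * exp(b1 + b2 t + ... ))`` via a
    ``log(births)`` offset.  When ``exclude_window`` is given, those years
    are left out of the estimation and the fitted rates over the full series
    (including the window) are returned, supporting excess estimation
    against a trend extrapolated or interpolated from the retained years.
    """
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2 or 3")
    t = series.t.astype(float)
    mask = np.ones(len(series), dtype=bool)
    if exclude_window is not None:
        lo_y, hi_y = exclude_window
        mask = (series.year < lo_y) | (series.year > hi_y)
    n_used = int(mask.sum())
    if n_used < degree + 2:
        raise ValueError(f"only {n_used} observations retained for degree {degree}")
    X = np.column_stack([t**p for p in range(degree + 1)])
    try:
        glm = sm.GLM(
            series.deaths[mask].astype(float), X[mask],
            family=sm.families.Poisson(),
            offset=np.log(series.births[mask].astype(float)),
        )
        glm_res = glm.fit()
    except Exception as exc:  # degenerate design, separation
        raise RuntimeError(f"log-linear trend fit failed: {exc}") from exc

    coef = np.zeros(4)
    coef[: degree + 1] = glm_res.params
    params = ParameterSet(beta1=coef[0], beta2=coef[1], beta3=coef[2], beta4=coef[3])
    spec = ModelSpec(family="expcubic", time_origin=series.time_origin)
    fitted = eval_rate(t, params, spec, years=series.year)
    var = fitted * (1.0 - fitted) / series.births.astype(float)
    dev_used, _ = deviance_and_residuals(series.rate[mask], fitted[mask],
                                         series.births[mask].astype(float))
    df = n_used - (degree + 1)
    names = [f"beta{i + 1}" for i in range(degree + 1)]
    se = dict(zip(names, np.asarray(glm_res.bse).tolist()))
    tv = dict(zip(names, np.asarray(glm_res.tvalues).tolist()))
    return FitResult(
        spec=spec, params=params, se=se, tvalues=tv, fitted=fitted, var=var,
        deviance=float(dev_used), df=int(df), overdispersion=float(dev_used / df),
        converged=bool(glm_res.converged), n_iter=int(glm_res.fit_history.get("iteration", 0))
        if hasattr(glm_res, "fit_history") else 0,
        free_names=names, cov=np.asarray(glm_res.cov_params()),
    )
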