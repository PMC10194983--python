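"""Model selection and single-parameter confidence intervals.

Nested trend models are compared with an overdispersion-scaled F-test:

    OD = dev1 / df2,     F = (dev0 - dev1) / df1 / OD,

where ``dev0``/``dev1`` are the weighted deviances of the reduced and the
refined model, ``df1`` the number of parameters added, and ``df2`` the
residual degrees of freedom of the refined model.  The p-value is the
upper tail of F(df1, df2).  Scaling by the overdispersion makes the test
valid when the counts are far more variable than binomial, as is typical
for national vital statistics.

Profile confidence intervals fix one parameter on a grid, re-optimise all
others, and bound the interval where the profiled deviance exceeds the
minimum by ``OD * F_level(1, df2)`` — the same scaled-F calibration as the
model comparison.  A parametric-bootstrap interval is available as an
independent cross-check.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import f as f_dist

from .fitting import FitResult, _reseed_polish, candidate_augmented_inits, fit_model
from .models import ModelSpec, ParameterSet
from .series import MortalitySeries

logger = logging.getLogger(__name__)

__all__ = ["ModelComparison", "f_test", "stepwise_fit", "profile_ci", "bootstrap_ci", "comparison_table"]


@dataclass(frozen=True)
class ModelComparison:
    """Overdispersion-scaled F comparison of two nested fits."""

    dev0: float
    dev1: float
    df1: int
    df2: int
    od: float
    fvalue: float
    pvalue: float


def f_test(dev0: float, dev1: float, df1: int, df2: int) -> ModelComparison:
    """Overdispersion-scaled F-test for ``df1`` added parameters.

    ``dev0`` is the reduced model's deviance, ``dev1`` the refined model's;
    the overdispersion is estimated from the refined model
    (``OD = dev1/df2``) and the statistic is
    ``F = (dev0 - dev1)/df1/OD`` with an upper-tail F(df1, df2) p-value.
    """
    if df1 < 1 or df2 < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got df1={df1}, df2={df2}")
    if dev0 < 0 or dev1 < 0:
        raise ValueError("deviances must be non-negative")
    od = dev1 / df2
    if dev1 > dev0:
        warnings.warn("refined model has larger deviance than reduced model; "
                      "reporting F = 0", RuntimeWarning)
        fvalue = 0.0
    else:
        fvalue = (dev0 - dev1) / df1 / od
    pvalue = float(f_dist.sf(fvalue, df1, df2)) if fvalue > 0 else 1.0
    return ModelComparison(dev0=float(dev0), dev1=float(dev1), df1=int(df1),
                           df2=int(df2), od=float(od), fvalue=float(fvalue),
                           pvalue=pvalue)


def stepwise_fit(
    series: MortalitySeries,
    base_spec: ModelSpec,
    max_terms: int,
    **fit_kwargs,
) -> tuple[list[FitResult | None], list[ModelComparison | None]]:
    """Fit 0..max_terms excess terms sequentially with scaled-F comparisons.

    Each refinement is initialised from the previous fit plus one new term
    seeded at the most prominent positive peak of the current predictor-scale
    residuals.  All fits and the successive comparisons are returned; no
    stopping rule is applied silently (inspect the comparisons to decide).
    A failed step is recorded as ``None`` and later steps continue from the
    last successful fit.
    """
    if max_terms > 5:
        raise ValueError("max_terms must be <= 5")
    fits: list[FitResult | None] = []
    comps: list[ModelComparison | None] = []
    prev: FitResult | None = None
    for n in range(max_terms + 1):
        spec_n = base_spec.with_n_excess(n)
        try:
            if prev is None:
                fit = fit_model(series, spec_n, **fit_kwargs)
            else:
                best = None
                for init in candidate_augmented_inits(series, prev.params,
                                                      prev.spec, spec_n):
                    trial = fit_model(series, spec_n, init=init,
                                      **{**fit_kwargs, "compute_se": False})
                    if best is None or trial.deviance < best.deviance:
                        best = trial
                if spec_n.n_excess >= 2:
                    best = _reseed_polish(series, spec_n, best)
                fit = fit_model(series, spec_n, init=best.params, **fit_kwargs)
        except Exception as exc:
            logger.warning("stepwise step with %d term(s) failed: %s", n, exc)
            fits.append(None)
            comps.append(None)
            continue
        fits.append(fit)
        if prev is not None:
            df1 = prev.df - fit.df
            if df1 >= 1:
                comps.append(f_test(prev.deviance, fit.deviance, df1, fit.df))
            else:
                comps.append(None)
        prev = fit
    return fits, comps


def comparison_table(
    fits: list[FitResult | None], comps: list[ModelComparison | None]
) -> pd.DataFrame:
    """Stepwise refinement table (terms, deviance, df2, OD, df1, F, p)."""
    rows = []
    for n, fit in enumerate(fits):
        if fit is None:
            rows.append((n,) + (np.nan,) * 6)
            continue
        comp = comps[n - 1] if n >= 1 and n - 1 < len(comps) else None
        rows.append((
            n, fit.deviance, fit.df, fit.overdispersion,
            comp.df1 if comp else np.nan,
            comp.fvalue if comp else np.nan,
            comp.pvalue if comp else np.nan,
        ))
    return pd.DataFrame(rows, columns=["excess_terms", "deviance", "df2", "OD", "df1", "F", "p"])


# ---------------------------------------------------------------------------
# profile confidence intervals


def profile_ci(
    series: MortalitySeries,
    spec: ModelSpec,
    fit: FitResult,
    param: str,
    level: float = 0.90,
    max_se: float = 10.0,
) -> tuple[float, float]:
    """Profile confidence interval for one free parameter.

    The parameter is fixed on a bracketing grid while all other parameters
    are re-optimised; the bounds are where the profiled deviance crosses
    ``dev_min + OD * F_level(1, df2)``.  With the overdispersion scaling this
    reduces to the Wald interval when the objective is exactly quadratic.
    Entirely deterministic.

    If no crossing is found within ``max_se`` standard errors a warning is
    issued and the reached bound is returned (open interval).
    """
    if param not in fit.free_names:
        raise ValueError(f"{param!r} is not a free parameter of this fit")
    if not fit.se:
        raise ValueError("fit carries no standard errors; refit with compute_se=True")
    est = float(spec.pack(fit.params)[spec.free_parameter_names().index(param)])
    se = fit.se[param]
    dev_min = fit.deviance
    od = fit.overdispersion
    target = dev_min + od * float(f_dist.ppf(level, 1, fit.df))

    warm = {"params": fit.params}

    def profile_dev(value: float) -> float:
        refit = fit_model(series, spec, init=warm["params"],
                          fixed={**fit.fixed, param: value}, compute_se=False)
        warm["params"] = refit.params
        return refit.deviance

    bounds = []
    for direction in (-1.0, 1.0):
        warm["params"] = fit.params
        prev_val, prev_dev = est, dev_min
        bound = None
        for step in (0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, max_se):
            value = est + direction * step * se
            dev = profile_dev(value)
            if dev >= target:
                bound = brentq(
                    lambda v: profile_dev(v) - target,
                    *sorted((prev_val, value)), xtol=max(1e-3 * se, 1e-12),
                )
                break
            prev_val, prev_dev = value, dev
        if bound is None:
            warnings.warn(
                f"profile for {param} did not cross the threshold within "
                f"{max_se} SE; returning the reached bound", RuntimeWarning)
            bound = prev_val
        bounds.append(float(bound))
    lo, hi = sorted(bounds)
    return lo, hi


def bootstrap_ci(
    series: MortalitySeries,
    spec: ModelSpec,
    fit: FitResult,
    param: str,
    level: float = 0.90,
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """Parametric-bootstrap percentile interval (cross-check for profile_ci).

    Death counts are redrawn binomially at the fitted rates, the model is
    refitted from the original estimates, and the percentile interval of the
    refitted parameter is returned.
    """
    rng = np.random.default_rng(seed)
    names = spec.free_parameter_names()
    idx = names.index(param)
    values = []
    for _ in range(n_boot):
        deaths = rng.binomial(series.births, fit.fitted)
        deaths = np.minimum(deaths, series.births)
        boot = replace(series, deaths=np.maximum(deaths, 0))
        try:
            refit = fit_model(boot, spec, init=fit.params, fixed=fit.fixed,
                              compute_se=False)
        except Exception:
            continue
        values.append(spec.pack(refit.params)[idx])
    if len(values) < max(20, n_boot // 2):
        raise RuntimeError("too many bootstrap refits failed")
    lo, hi = np.quantile(values, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)
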