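"""Windowed excess-death estimation and peak-timing extraction.

Over a calendar window (default 1950-2000 inclusive) the observed deaths
``O`` are compared with the deaths ``E`` expected under the undisturbed
secular trend — the fitted model with its excess bells switched off:

    E = sum_y births_y * undisturbed_rate(t_y),    excess = O - E,
    ratio = O / E.

Confidence intervals for the excess follow the slope-fixed refit scheme:
the profile interval for the linear slope ``beta2`` is computed, the model
is refitted with ``beta2`` frozen at each bound (all other parameters
free), and ``E`` is recomputed at each bound.  The slope controls how fast
the secular trend declines, hence the expected counts, so its uncertainty
dominates the uncertainty of the excess.

Each lognormal excess term peaks at time ``t = exp(mu - sigma^2)`` (the
mode of the lognormal density), converted to a calendar year through the
series' time origin.  Peak-year intervals come from the delta method on
``(mu, sigma)`` by default, with a parametric bootstrap as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm

from .fitting import FitResult, fit_model
from .inference import profile_ci
from .models import ModelSpec, undisturbed_rate
from .series import MortalitySeries

__all__ = ["ExcessEstimate", "PeakEstimate", "excess_summary", "excess_ci", "peak_estimate"]


@dataclass(frozen=True)
class ExcessEstimate:
    """Observed vs expected deaths over a calendar window."""

    window: tuple[int, int]
    observed: float
    expected: float
    excess: float
    ratio: float
    ci_excess: tuple[float, float] | None = None
    ci_ratio: tuple[float, float] | None = None
    level: float | None = None

    @classmethod
    def from_counts(
        cls, observed: float, expected: float, window: tuple[int, int] = (1950, 2000)
    ) -> "ExcessEstimate":
        """Pure bookkeeping from already-known observed and expected totals."""
        return cls(window=window, observed=float(observed), expected=float(expected),
                   excess=float(observed) - float(expected),
                   ratio=float(observed) / float(expected))


@dataclass(frozen=True)
class PeakEstimate:
    """Calendar timing of one excess term's maximum."""

    term_index: int
    mu: float
    sigma: float
    peak_year: float
    ci_peak: tuple[float, float] | None = None
    level: float | None = None


def _window_mask(series: MortalitySeries, window: tuple[int, int]) -> np.ndarray:
    lo, hi = int(window[0]), int(window[1])
    if lo > hi:
        raise ValueError(f"invalid window {window}")
    wanted = set(range(lo, hi + 1))
    have = set(series.year.tolist())
    missing = sorted(wanted - have)
    if missing:
        raise ValueError(f"window year(s) missing from series: {missing}")
    return (series.year >= lo) & (series.year <= hi)


def _expected_deaths(
    series: MortalitySeries, params, spec: ModelSpec, mask: np.ndarray
) -> float:
    base = undisturbed_rate(series.t[mask].astype(float), params, spec,
                            years=series.year[mask])
    return float(np.sum(series.births[mask] * base))


def excess_summary(
    series: MortalitySeries,
    fit: FitResult,
    spec: ModelSpec,
    window: tuple[int, int] = (1950, 2000),
) -> ExcessEstimate:
    """Windowed O, E, O-E and O/E from a fitted model.

    ``E`` sums ``births * undisturbed_rate`` over the window using the
    full-data fit with excess amplitudes zeroed; ``O`` sums the observed
    deaths.  Every calendar year inside the window must be present.
    """
    mask = _window_mask(series, window)
    observed = float(series.deaths[mask].sum())
    expected = _expected_deaths(series, fit.params, spec, mask)
    return ExcessEstimate(
        window=(int(window[0]), int(window[1])), observed=observed,
        expected=expected, excess=observed - expected, ratio=observed / expected,
    )


def excess_ci(
    series: MortalitySeries,
    spec: ModelSpec,
    fit: FitResult,
    window: tuple[int, int] = (1950, 2000),
    level: float = 0.90,
) -> ExcessEstimate:
    """Excess estimate with slope-fixed confidence intervals.

    The profile interval for ``beta2`` at ``level`` is computed; the model
    is refitted with the slope frozen at each bound and the expected deaths
    recomputed, giving the interval for O-E and O/E.
    """
    point = excess_summary(series, fit, spec, window)
    lo_b2, hi_b2 = profile_ci(series, spec, fit, "beta2", level=level)
    mask = _window_mask(series, window)
    excesses, ratios = [], []
    for value in (lo_b2, hi_b2):
        refit = fit_model(series, spec, init=fit.params,
                          fixed={**fit.fixed, "beta2": value}, compute_se=False)
        expected = _expected_deaths(series, refit.params, spec, mask)
        excesses.append(point.observed - expected)
        ratios.append(point.observed / expected)
    return replace(
        point,
        ci_excess=tuple(sorted(excesses)),
        ci_ratio=tuple(sorted(ratios)),
        level=level,
    )


def peak_estimate(
    fit: FitResult,
    term_index: int,
    level: float = 0.95,
    method: str = "delta",
) -> PeakEstimate:
    """Calendar year of an excess term's maximum, ``exp(mu - sigma^2) + origin``.

    The default interval is the delta method on ``(mu, sigma)`` with their
    estimated covariance; a term with a tied width uses the master term's
    width and covariance entries.  ``method="none"`` skips the interval.
    """
    if not 0 <= term_index < len(fit.params.excess):
        raise IndexError(f"no excess term {term_index}")
    term = fit.params.excess[term_index]
    if not term.sigma > 0:
        raise ValueError("peak timing requires sigma > 0")
    origin = fit.spec.time_origin
    g = float(np.exp(term.mu - term.sigma**2))
    peak_year = g + origin

    ci = None
    if method == "delta" and fit.cov is not None:
        mu_name = f"mu{term_index + 1}"
        master = fit.spec.master_of(term_index)
        sigma_name = f"sigma{master + 1}"
        if mu_name in fit.free_names and sigma_name in fit.free_names:
            i = fit.free_names.index(mu_name)
            j = fit.free_names.index(sigma_name)
            grad = np.zeros(len(fit.free_names))
            grad[i] = g
            grad[j] = -2.0 * term.sigma * g
            var = float(grad @ fit.cov @ grad)
            if var >= 0:
                half = norm.ppf(0.5 + level / 2) * np.sqrt(var)
                ci = (peak_year - half, peak_year + half)
    elif method not in ("delta", "none"):
        raise ValueError(f"unknown method {method!r}")
    return PeakEstimate(term_index=term_index, mu=term.mu, sigma=term.sigma,
                        peak_year=peak_year, ci_peak=ci,
                        level=level if ci is not None else None)
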