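"""Published reference estimates for national infant-mortality trend fits.

These constants are the published parameter estimates of the floored-logistic
and exponential-cubic trend decompositions of annual infant-mortality series
for the United States (1934-2018), the pooled five large European countries
(EU5: United Kingdom, Germany, France, Italy, Spain; 1950-2018), the five
countries individually, and the central (UK, Germany, France) and southern
(Italy, Spain) European pools.  They serve two purposes:

* ground truth for noise-free fixtures and simulation studies (exact and
  stochastic parameter recovery), and
* inputs to worked examples such as peak-timing extraction.

Each entry records the trend family, the excess-term triples
``(amplitude, mu, sigma)`` in fit order, the width ties, the observation
years, and the published deviance / residual degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .models import ExcessTerm, ModelSpec, ParameterSet

__all__ = ["ReferenceFit", "REFERENCE_FITS", "reference_fit"]


@dataclass(frozen=True)
class ReferenceFit:
    """One published fit: spec, estimates, data range and fit summary."""

    label: str
    spec: ModelSpec
    params: ParameterSet
    start_year: int
    end_year: int
    deviance: float
    df: int
    births_per_year: int  # representative annual live births for fixtures

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1


def _logistic(label, alpha, beta1, beta2, terms, ties, years, dev, df, births):
    spec = ModelSpec(family="logistic", n_excess=len(terms), width_ties=ties)
    params = ParameterSet(
        alpha=alpha, beta1=beta1, beta2=beta2,
        excess=tuple(ExcessTerm(*t) for t in terms),
    )
    return ReferenceFit(label, spec, params, years[0], years[1], dev, df, births)


def _expcubic(label, beta1, beta2, beta3, beta4, terms, ties, years, dev, df, births):
    spec = ModelSpec(family="expcubic", n_excess=len(terms), width_ties=ties)
    params = ParameterSet(
        beta1=beta1, beta2=beta2, beta3=beta3, beta4=beta4,
        excess=tuple(ExcessTerm(*t) for t in terms),
    )
    return ReferenceFit(label, spec, params, years[0], years[1], dev, df, births)


REFERENCE_FITS: Mapping[str, ReferenceFit] = {
    # United States, floored logistic, three bells, widths of terms 1-2 tied
    "US-Model1": _logistic(
        "United States", 0.0048, -2.717, -0.050,
        [(11.572, 3.534, 0.191), (14.492, 3.811, 0.191), (10.202, 4.076, 0.045)],
        {1: 0}, (1934, 2018), 2264.0, 74, 3_500_000,
    ),
    # United States, exponential cubic
    "US-Model2": _expcubic(
        "United States", -2.729, -0.043, 9.8e-05, 9.0e-07,
        [(7.717, 3.508, 0.180), (9.349, 3.760, 0.180), (4.673, 4.072, 0.043)],
        {1: 0}, (1934, 2018), 2352.0, 73, 3_500_000,
    ),
    # Pooled EU5, floored logistic
    "EU5-Model1": _logistic(
        "EU5", 0.0027, -1.510, -0.068,
        [(4.582, 3.473, 0.133), (17.538, 3.782, 0.133), (15.667, 4.088, 0.099)],
        {1: 0}, (1950, 2018), 726.5, 58, 3_000_000,
    ),
    # Pooled EU5, exponential cubic
    "EU5-Model2": _expcubic(
        "EU5", -1.714, -0.056, -2.2e-04, 3.8e-06,
        [(3.583, 3.470, 0.127), (12.830, 3.770, 0.127), (7.672, 4.071, 0.087)],
        {1: 0}, (1950, 2018), 711.0, 57, 3_000_000,
    ),
    # Individual countries, floored logistic (three bells, widths 1-2 tied).
    # The UK third width was published with a negative sign; the width enters
    # only squared, so its magnitude is stored.
    "UK": _logistic(
        "United Kingdom", 0.0026, -2.590, -0.046,
        [(4.969, 3.534, 0.124), (16.551, 3.817, 0.124), (11.147, 4.055, 0.034)],
        {1: 0}, (1950, 2018), 258.7, 58, 800_000,
    ),
    "Germany": _logistic(
        "Germany", 0.0029, -1.261, -0.077,
        [(4.998, 3.439, 0.098), (20.390, 3.761, 0.098), (25.120, 4.044, 0.156)],
        {1: 0}, (1950, 2018), 228.9, 58, 1_000_000,
    ),
    # France: all three widths tied
    "France": _logistic(
        "France", 0.0029, -1.457, -0.074,
        [(5.667, 3.611, 0.098), (10.910, 3.787, 0.098), (28.190, 4.094, 0.098)],
        {1: 0, 2: 0}, (1950, 2018), 585.8, 59, 800_000,
    ),
    "Italy": _logistic(
        "Italy", 0.0019, -1.306, -0.067,
        [(6.158, 3.469, 0.133), (18.424, 3.759, 0.133), (17.280, 4.103, 0.127)],
        {1: 0}, (1950, 2018), 1052.0, 58, 800_000,
    ),
    "Spain": _logistic(
        "Spain", 0.0015, -1.346, -0.063,
        [(3.875, 3.394, 0.121), (11.288, 3.649, 0.121), (2.888, 3.865, 0.053)],
        {1: 0}, (1950, 2018), 559.5, 58, 600_000,
    ),
    # Central (UK+Germany+France) and southern (Italy+Spain) pools
    "CentralEurope": _logistic(
        "Central Europe", 0.0031, -1.637, -0.069,
        [(3.609, 3.479, 0.112), (18.310, 3.780, 0.112), (20.793, 4.069, 0.108)],
        {1: 0}, (1950, 2018), 511.0, 58, 2_600_000,
    ),
    "SouthernEurope": _logistic(
        "Southern Europe", 0.0021, -1.233, -0.071,
        [(6.079, 3.462, 0.163), (18.262, 3.764, 0.163), (19.349, 4.132, 0.125)],
        {1: 0}, (1950, 2018), 812.0, 58, 1_400_000,
    ),
}


def reference_fit(source: str) -> ReferenceFit:
    """Look up a reference fit by identifier (e.g. ``"EU5-Model1"``, ``"UK"``)."""
    try:
        return REFERENCE_FITS[source]
    except KeyError:
        raise KeyError(
            f"unknown reference fit {source!r}; available: {sorted(REFERENCE_FITS)}"
        ) from None
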