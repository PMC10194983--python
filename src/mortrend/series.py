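"""Annual vital-statistics series: reading, validation, pooling and filtering.

A :class:`MortalitySeries` holds one annual series of live births and deaths
(infant deaths or stillbirths).  Rates are always derived proportions
``deaths / births`` in (0, 1); the per-1000 convention used in publications is
presentation only.  The model time index is ``t = year - time_origin`` with a
default origin of 1930, so that ``log t`` is defined for every modelled year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_TIME_ORIGIN = 1930


class SeriesValidationError(ValueError):
    """Raised when a series violates a structural invariant."""


@dataclass(frozen=True)
class MortalitySeries:
    """Annual series of live births and deaths with derived rates.

    Parameters
    ----------
    year
        Strictly increasing calendar years.  Gaps are allowed (some national
        series have missing war years) and are simply absent from any fit.
    births
        Live births per year (positive).
    deaths
        Death counts per year (non-negative, at most ``births``).  The
        ``role`` tag records whether these are infant deaths or stillbirths.
    role
        Free-text tag, by convention ``"infant"`` or ``"stillbirth"``.
    label
        Optional display name (country or region).
    time_origin
        Calendar year subtracted from ``year`` to form the model time index.
    """

    year: np.ndarray
    births: np.ndarray
    deaths: np.ndarray
    role: str = "infant"
    label: str = ""
    time_origin: int = DEFAULT_TIME_ORIGIN

    def __post_init__(self) -> None:
        year = np.asarray(self.year, dtype=int)
        births = np.asarray(self.births, dtype=np.int64)
        deaths = np.asarray(self.deaths, dtype=np.int64)
        if not (year.shape == births.shape == deaths.shape) or year.ndim != 1:
            raise SeriesValidationError("year, births and deaths must be 1-D and equal length")
        if year.size == 0:
            raise SeriesValidationError("empty series")
        if np.any(np.diff(year) <= 0):
            dup = year[1:][np.diff(year) <= 0]
            raise SeriesValidationError(f"years must be strictly increasing; offending year(s): {dup.tolist()}")
        if np.any(births < 1):
            bad = year[births < 1]
            raise SeriesValidationError(f"births must be >= 1; offending year(s): {bad.tolist()}")
        if np.any(deaths < 0):
            bad = year[deaths < 0]
            raise SeriesValidationError(f"deaths must be >= 0; offending year(s): {bad.tolist()}")
        if np.any(deaths > births):
            bad = year[deaths > births]
            raise SeriesValidationError(f"deaths exceed births in year(s): {bad.tolist()}")
        object.__setattr__(self, "year", year)
        object.__setattr__(self, "births", births)
        object.__setattr__(self, "deaths", deaths)

    # -- derived quantities -------------------------------------------------

    @property
    def t(self) -> np.ndarray:
        """Model time index ``year - time_origin``."""
        return self.year - self.time_origin

    @property
    def rate(self) -> np.ndarray:
        """Death proportion per year, recomputed from counts."""
        return self.deaths / self.births

    def __len__(self) -> int:
        return int(self.year.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MortalitySeries):
            return NotImplemented
        return (
            np.array_equal(self.year, other.year)
            and np.array_equal(self.births, other.births)
            and np.array_equal(self.deaths, other.deaths)
            and self.role == other.role
            and self.time_origin == other.time_origin
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": self.year, "births": self.births, "deaths": self.deaths,
             "rate": self.rate, "t": self.t}
        )

    def restrict(self, start: int, end: int) -> "MortalitySeries":
        """Return the sub-series with ``start <= year <= end`` (inclusive)."""
        mask = (self.year >= start) & (self.year <= end)
        if not mask.any():
            raise SeriesValidationError(f"no observations in {start}-{end}")
        return replace(self, year=self.year[mask], births=self.births[mask], deaths=self.deaths[mask])


_DEFAULT_DIALECT = {"year": "year", "births": "births", "deaths": "deaths"}


def read_series(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    role: str = "infant",
    label: str = "",
    time_origin: int = DEFAULT_TIME_ORIGIN,
) -> MortalitySeries:
    """Read a delimited text file into a validated :class:`MortalitySeries`.

    ``dialect`` maps the canonical column names (``year``, ``births``,
    ``deaths``) to the file's column headers, accommodating external exports.
    Rows with missing counts are dropped with a warning, which supports
    series with genuinely non-existent years.
    """
    colmap = dict(_DEFAULT_DIALECT)
    if dialect:
        colmap.update(dialect)
    df = pd.read_csv(path)
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise SeriesValidationError(f"missing column(s) {missing} in {path}")
    df = df.rename(columns={v: k for k, v in colmap.items()})[["year", "births", "deaths"]]
    incomplete = df[["births", "deaths"]].isna().any(axis=1)
    if incomplete.any():
        dropped = df.loc[incomplete, "year"].tolist()
        logger.warning("dropping %d row(s) with missing counts (year(s) %s)", incomplete.sum(), dropped)
        df = df[~incomplete]
    try:
        year = df["year"].astype(int).to_numpy()
        births = df["births"].astype(np.int64).to_numpy()
        deaths = df["deaths"].astype(np.int64).to_numpy()
    except (ValueError, TypeError) as exc:
        raise SeriesValidationError(f"unparseable numeric value in {path}: {exc}") from exc
    order = np.argsort(year)
    return MortalitySeries(year[order], births[order], deaths[order],
                           role=role, label=label, time_origin=time_origin)


def write_series(series: MortalitySeries, path: str | Path) -> None:
    """Write the tidy ``year,births,deaths`` CSV (exact round trip with read_series)."""
    pd.DataFrame({"year": series.year, "births": series.births, "deaths": series.deaths}).to_csv(
        path, index=False
    )


def pool_series(members: Sequence[MortalitySeries], label: str = "pooled") -> MortalitySeries:
    """Pool several series by summing births and deaths over the common years.

    Only years present in every member are pooled (the intersection is
    logged); the pooled rate is the ratio of summed deaths to summed births.
    """
    if not members:
        raise SeriesValidationError("cannot pool an empty member list")
    common = members[0].year
    for m in members[1:]:
        common = np.intersect1d(common, m.year)
    if common.size == 0:
        raise SeriesValidationError("members share no common years")
    full = {m.year.min() for m in members} | {m.year.max() for m in members}
    if len(full) > 2:
        logger.info("pooling over year intersection %d-%d", common.min(), common.max())
    births = np.zeros(common.size, dtype=np.int64)
    deaths = np.zeros(common.size, dtype=np.int64)
    for m in members:
        idx = np.searchsorted(m.year, common)
        births += m.births[idx]
        deaths += m.deaths[idx]
    return MortalitySeries(common, births, deaths, role=members[0].role,
                           label=label, time_origin=members[0].time_origin)


def exclude_years(series: MortalitySeries, years: Iterable[int]) -> MortalitySeries:
    """Return a copy of ``series`` without the listed calendar years.

    Excluding a year that is not present is a no-op.  Used for outlier years
    that would otherwise distort a trend fit.
    """
    drop = set(int(y) for y in years)
    if not drop:
        return series
    mask = ~np.isin(series.year, sorted(drop))
    present = sorted(set(series.year.tolist()) & drop)
    if present:
        logger.info("excluding year(s) %s from series %s", present, series.label or "<unnamed>")
    return replace(series, year=series.year[mask], births=series.births[mask], deaths=series.deaths[mask])
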