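"""Annual survey time series: reading, writing, validation and alignment.

Abundance series are stored in units of 1e9 individuals so that log
abundances land on the scale used throughout the model (e.g. a capelin
stock of 209e9 fish is carried as 209 and enters the model as
ln(209) = 5.34).  Covariates (sea temperature, winter NAO) are carried in
raw units until :func:`align` z-scores them over the analysis window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "AnnualSeries",
    "LagConvention",
    "AlignedDataset",
    "read_series",
    "write_series",
    "zscore",
    "align",
]


class SeriesValidationError(ValueError):
    """Raised when an annual series violates a structural invariant."""


@dataclass(frozen=True)
class AnnualSeries:
    """A year-indexed series of abundances or covariate values.

    Parameters
    ----------
    years
        Strictly increasing, consecutive calendar years.
    values
        Abundance (strictly positive, in 1e9 individuals) or covariate
        values, one per year.
    label
        Free-text name used in reports.
    kind
        Either ``"abundance"`` or ``"covariate"``.
    """

    years: np.ndarray
    values: np.ndarray
    label: str = ""
    kind: str = "abundance"

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if years.ndim != 1 or values.ndim != 1 or len(years) != len(values):
            raise SeriesValidationError(
                f"{self.label!r}: years and values must be 1-d and equal length"
            )
        if len(years) < 3:
            raise SeriesValidationError(
                f"{self.label!r}: need at least 3 years, got {len(years)}"
            )
        if self.kind not in ("abundance", "covariate"):
            raise SeriesValidationError(f"unknown series kind {self.kind!r}")
        diffs = np.diff(years)
        if np.any(diffs <= 0):
            bad = years[1:][diffs <= 0][0]
            raise SeriesValidationError(
                f"{self.label!r}: years not strictly increasing at {bad}"
            )
        if np.any(diffs != 1):
            bad = years[:-1][diffs != 1][0]
            raise SeriesValidationError(
                f"{self.label!r}: gap in years after {bad}"
            )
        if not np.all(np.isfinite(values)):
            bad = years[~np.isfinite(values)][0]
            raise SeriesValidationError(
                f"{self.label!r}: non-finite value in year {bad}"
            )
        if self.kind == "abundance" and np.any(values <= 0):
            bad = years[values <= 0][0]
            raise SeriesValidationError(
                f"{self.label!r}: non-positive abundance in year {bad}"
            )

    def __len__(self) -> int:
        return len(self.years)

    @property
    def log_values(self) -> np.ndarray:
        """Natural log of the values (only meaningful for abundances)."""
        return np.log(self.values)

    def window(self, start: int, end: int) -> "AnnualSeries":
        """Restrict to calendar years ``start..end`` inclusive."""
        mask = (self.years >= start) & (self.years <= end)
        return replace(self, years=self.years[mask], values=self.values[mask])


@dataclass(frozen=True)
class LagConvention:
    """Which lag of the partner species and covariates each equation uses.

    The survey-timing convention of the Barents Sea system: the predator
    (winter trawl survey) responds to the prey observed the previous
    autumn (lag 1), while the prey responds to the predator surveyed the
    same calendar year (lag 0).  Covariates enter both equations at lag 1.
    """

    predator_prey_lag: int = 1
    prey_predator_lag: int = 0
    covariate_lag: int = 1

    def __post_init__(self) -> None:
        for name in ("predator_prey_lag", "prey_predator_lag", "covariate_lag"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1")


@dataclass(frozen=True)
class AlignedDataset:
    """Predator, prey and z-scored covariates on one common year range."""

    predator: AnnualSeries
    prey: AnnualSeries
    covariates: list[AnnualSeries] = field(default_factory=list)
    lag: LagConvention = field(default_factory=LagConvention)

    def __post_init__(self) -> None:
        ref = self.predator.years
        for s in [self.prey, *self.covariates]:
            if len(s.years) != len(ref) or np.any(s.years != ref):
                raise SeriesValidationError(
                    f"series {s.label!r} not aligned to predator years"
                )
        for c in self.covariates:
            if abs(float(np.mean(c.values))) > 1e-8:
                raise SeriesValidationError(f"covariate {c.label!r} not centred")
            if abs(float(np.std(c.values, ddof=1)) - 1.0) > 1e-8:
                raise SeriesValidationError(f"covariate {c.label!r} not unit-sd")

    @property
    def years(self) -> np.ndarray:
        return self.predator.years

    @property
    def n_years(self) -> int:
        return len(self.predator)

    def covariate(self, label: str) -> AnnualSeries:
        for c in self.covariates:
            if c.label == label:
                return c
        raise KeyError(label)


def read_series(
    path,
    year_col: str = "year",
    value_col: str = "value",
    label: str = "",
    kind: str = "abundance",
    scale: float = 1.0,
) -> AnnualSeries:
    """Read a ``year,value`` delimited text file into an :class:`AnnualSeries`.

    ``scale`` divides raw file values, e.g. ``scale=1e9`` converts a file
    holding individuals into the package's 1e9-individual convention.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in (year_col, value_col):
        if col not in df.columns:
            raise SeriesValidationError(f"{path}: missing column {col!r}")
    years_raw = df[year_col]
    if not np.all(years_raw == years_raw.astype(int)):
        raise SeriesValidationError(f"{path}: non-integer year entries")
    years = years_raw.astype(int).to_numpy()
    dup = pd.Series(years).duplicated()
    if dup.any():
        raise SeriesValidationError(
            f"{path}: duplicate year {years[dup.to_numpy()][0]}"
        )
    vals = pd.to_numeric(df[value_col], errors="coerce")
    if vals.isna().any():
        bad_year = years[vals.isna().to_numpy()][0]
        raise SeriesValidationError(
            f"{path}: non-numeric value in year {bad_year}"
        )
    return AnnualSeries(
        years=years,
        values=vals.to_numpy() / scale,
        label=label or str(path),
        kind=kind,
    )


def write_series(series: AnnualSeries, path) -> None:
    """Write a series as ``year,value`` text at full float precision."""
    with open(path, "w") as fh:
        fh.write("year,value\n")
        for y, v in zip(series.years, series.values):
            fh.write(f"{y},{float(v)!r}\n")


def zscore(series: AnnualSeries) -> AnnualSeries:
    """Standardize to mean 0 and sample (ddof=1) standard deviation 1."""
    v = series.values
    sd = float(np.std(v, ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise SeriesValidationError(
            f"{series.label!r}: degenerate variance, cannot z-score"
        )
    return replace(series, values=(v - np.mean(v)) / sd, kind="covariate")


def align(
    predator: AnnualSeries,
    prey: AnnualSeries,
    covariates: list[AnnualSeries] | None = None,
    lag: LagConvention | None = None,
) -> AlignedDataset:
    """Trim all series to their common year range and z-score covariates.

    Covariates are standardized over the aligned analysis window (not
    their full historical extent), since only the window enters the model.
    """
    covariates = covariates or []
    lag = lag or LagConvention()
    start = max(s.years[0] for s in [predator, prey, *covariates])
    end = min(s.years[-1] for s in [predator, prey, *covariates])
    if end - start + 1 < 3:
        raise SeriesValidationError(
            f"insufficient overlap: common range {start}..{end}"
        )
    return AlignedDataset(
        predator=predator.window(start, end),
        prey=prey.window(start, end),
        covariates=[zscore(c.window(start, end)) for c in covariates],
        lag=lag,
    )
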