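"""Calibration of the linear-in-time rates from yearly surveillance tables.

Each rate series is fitted through the origin -- ``rate(t) = slope * t`` with
``t = year - baseline_year`` -- because the model has no constant terms.  The
through-origin least-squares slope has the closed form ``sum(t*y)/sum(t*t)``.

Fitting the packaged Fujian 2012-2016 table against baseline 2011 reproduces
the canonical lambda (0.02/yr^2), theta (0.01) and incidence (0.05) slopes at
two decimals; the nu+delta and mu columns do *not* reproduce the canonical
0.007 and 0.002 defaults by any simple fit, so the package ships the canonical
values as simulation defaults and reports the fitted ones separately (see
docs/methods.md).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .model import LinearCoefficients

__all__ = [
    "RATE_COLUMNS",
    "SurveillanceTable",
    "CalibrationResult",
    "load_table",
    "table1",
    "fit_slope",
    "calibrate",
    "generate_fixture",
]

#: CSV column -> LinearCoefficients slope-field mapping
RATE_COLUMNS = {
    "lambda": "lam_slope",
    "theta": "theta_slope",
    "incidence": "inc_slope",
    "nu_delta": "nu_delta_slope",
    "mu": "mu_slope",
}


class TableParseError(ValueError):
    """Malformed surveillance table."""


class UndefinedFitError(ValueError):
    """Through-origin fit undefined (all time indices zero)."""


@dataclass(frozen=True)
class SurveillanceTable:
    """Yearly observed rates: one row per calendar year, five rate columns."""

    data: pd.DataFrame  # columns: year + RATE_COLUMNS keys

    def __post_init__(self) -> None:
        df = self.data
        missing = {"year", *RATE_COLUMNS} - set(df.columns)
        if missing:
            raise TableParseError(f"missing columns: {sorted(missing)}")
        if len(df) < 1:
            raise TableParseError("table has no rows")
        years = df["year"].to_numpy()
        if not np.array_equal(years, years.astype(int)):
            raise TableParseError("years must be integers")
        if np.any(np.diff(years) <= 0):
            raise TableParseError("years must be strictly increasing")
        rates = df[list(RATE_COLUMNS)].to_numpy(dtype=float)
        if not np.all(np.isfinite(rates)):
            bad = int(np.argwhere(~np.isfinite(rates))[0, 0])
            raise TableParseError(f"non-finite rate in row {bad}")
        if np.any(rates < 0):
            bad = int(np.argwhere(rates < 0)[0, 0])
            raise TableParseError(f"negative rate in row {bad}")

    @property
    def years(self) -> np.ndarray:
        return self.data["year"].to_numpy(dtype=int)

    def to_csv(self, path: str | Path | io.IOBase) -> None:
        self.data.to_csv(path, index=False)


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted slopes plus per-series residual sums of squares.

    ``t_index`` maps each calendar year to its model time t (years since
    baseline).  ``slopes`` converts directly into simulation coefficients.
    """

    slopes: LinearCoefficients
    residual_sum_squares: dict[str, float]
    t_index: dict[int, int]
    baseline_year: int

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "baseline_year": self.baseline_year,
            "slopes": {f: getattr(self.slopes, f) for f in RATE_COLUMNS.values()},
            "residual_sum_squares": self.residual_sum_squares,
            "t_index": {str(y): t for y, t in self.t_index.items()},
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def load_table(source) -> SurveillanceTable:
    """Parse a surveillance CSV (columns ``year,lambda,theta,incidence,nu_delta,mu``).

    Rejects missing cells, non-numeric values and duplicate years, naming the
    offending row in the error message.
    """
    try:
        df = pd.read_csv(source)
    except Exception as exc:
        raise TableParseError(f"cannot parse CSV: {exc}") from exc
    missing = {"year", *RATE_COLUMNS} - set(df.columns)
    if missing:
        raise TableParseError(f"missing columns: {sorted(missing)}")
    if len(df) < 1:
        raise TableParseError("table has no rows")
    if df.isna().any().any():
        row = int(df.index[df.isna().any(axis=1)][0])
        raise TableParseError(f"missing or non-numeric cell in row {row}")
    for col in ("year", *RATE_COLUMNS):
        if not pd.api.types.is_numeric_dtype(df[col]):
            row = int(df.index[pd.to_numeric(df[col], errors="coerce").isna()][0])
            raise TableParseError(f"non-numeric value in column {col!r}, row {row}")
    dupes = df["year"][df["year"].duplicated()]
    if len(dupes):
        raise TableParseError(f"duplicate year {int(dupes.iloc[0])}")
    df = df[["year", *RATE_COLUMNS]].copy()
    df["year"] = df["year"].astype(int)
    return SurveillanceTable(df)


def table1() -> SurveillanceTable:
    """The packaged Fujian-province 2012-2016 surveillance table."""
    ref = resources.files("diabsde").joinpath("data/fujian_2012_2016.csv")
    with ref.open("r") as fh:
        return load_table(fh)


def fit_slope(values, t) -> tuple[float, float]:
    """Through-origin least squares: slope = sum(t*y)/sum(t^2).

    Returns ``(slope, residual_sum_squares)``.
    """
    y = np.asarray(values, dtype=float)
    tt = np.asarray(t, dtype=float)
    if y.shape != tt.shape or y.ndim != 1 or len(y) < 1:
        raise UndefinedFitError("values and t must be equal-length 1-D, len >= 1")
    denom = float(np.sum(tt * tt))
    if denom == 0.0:
        raise UndefinedFitError("all time indices are zero; slope undefined")
    slope = float(np.sum(tt * y)) / denom
    rss = float(np.sum((y - slope * tt) ** 2))
    return slope, rss


def calibrate(table: SurveillanceTable, baseline_year: int = 2011) -> CalibrationResult:
    """Fit all five slopes with t = year - baseline_year."""
    years = table.years
    if baseline_year >= years[0]:
        raise ValueError(
            f"baseline_year {baseline_year} must precede first table year {years[0]}"
        )
    t = (years - baseline_year).astype(float)
    fitted: dict[str, float] = {}
    rss: dict[str, float] = {}
    for col, fieldname in RATE_COLUMNS.items():
        slope, r = fit_slope(table.data[col].to_numpy(dtype=float), t)
        fitted[fieldname] = slope
        rss[fieldname] = r
    return CalibrationResult(
        slopes=LinearCoefficients(**fitted),
        residual_sum_squares=rss,
        t_index={int(y): int(y - baseline_year) for y in years},
        baseline_year=int(baseline_year),
    )


def generate_fixture(
    slopes: LinearCoefficients,
    n_years: int = 5,
    noise_sd: float = 0.0,
    seed: int = 0,
    first_year: int = 2012,
) -> SurveillanceTable:
    """Synthetic surveillance table with known ground-truth slopes.

    Row i (t = i+1) carries ``slope * t + N(0, noise_sd)`` per rate, truncated
    at zero so the table stays valid.  Deterministic given ``seed``.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(1, n_years + 1, dtype=float)
    cols = {"year": np.arange(first_year, first_year + n_years)}
    for col, fieldname in RATE_COLUMNS.items():
        clean = getattr(slopes, fieldname) * t
        noisy = clean + rng.normal(0.0, noise_sd, size=n_years) if noise_sd else clean
        cols[col] = np.maximum(noisy, 0.0)
    return SurveillanceTable(pd.DataFrame(cols))
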