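"""Ecological regression of disease rates on extreme low temperature.

Country-level (ecological) analysis: each record is a population with its
national record extreme low temperature (degC, signed — colder is more
negative) and an age-standardized incidence or prevalence per 100,000.
The model is plain univariate ordinary least squares of the outcome on
temperature; inference is the two-sided t-test on the slope with n - 2
degrees of freedom, and fit quality is reported as R^2 and the
single-predictor adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - 2).

Scenario support (re-fitting with particular populations excluded by flag,
or within strata such as sex or disorder) covers the usual sensitivity
questions of ecological analyses, e.g. whether a single extreme population
drives the association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "CountryRecord",
    "RegressionResult",
    "Scenario",
    "read_country_table",
    "fit_univariate",
    "run_scenarios",
    "plot_scenario",
]

logger = logging.getLogger(__name__)

# Physical sanity bounds on a national extreme low temperature.
_TEMP_RANGE = (-95.0, 30.0)

COUNTRY_COLUMNS = {
    "population": "population",
    "extreme_low_temp": "extreme_low_temp_c",
    "outcome": "outcome",
    "stratum": "stratum",
    "flags": "flags",
}


@dataclass(frozen=True)
class CountryRecord:
    """One population: extreme low temperature and an outcome rate."""

    population: str
    extreme_low_temp: float
    outcome: float
    stratum: Optional[str] = None
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not (_TEMP_RANGE[0] <= self.extreme_low_temp <= _TEMP_RANGE[1]):
            raise ValueError(
                f"extreme_low_temp {self.extreme_low_temp} degC outside sanity "
                f"bounds {_TEMP_RANGE} for {self.population!r}"
            )
        if self.outcome < 0:
            raise ValueError("outcome rate must be non-negative")
        object.__setattr__(self, "flags", frozenset(self.flags))


@dataclass(frozen=True)
class RegressionResult:
    """Univariate OLS summary: slope, intercept, fit quality, slope test."""

    slope: float
    intercept: float
    r2: float
    adj_r2: float
    p_slope: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need at least 3 observations")
        if not (-1e-9 <= self.r2 <= 1 + 1e-9):
            raise ValueError("r2 out of range")


@dataclass(frozen=True)
class Scenario:
    """A labelled re-fit: optional stratum restriction and flag exclusions."""

    label: str
    stratum: Optional[str] = None
    exclude_flags: Sequence[str] = field(default_factory=tuple)


def read_country_table(path: str | Path) -> list[CountryRecord]:
    """Read country records from CSV.

    Expected columns: ``population``, ``extreme_low_temp_c``, ``outcome``,
    optional ``stratum`` and ``flags`` (flags semicolon-separated).  Rows
    with missing temperature or outcome are logged and skipped; a missing
    file or missing required column is fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    required = [
        COUNTRY_COLUMNS["population"],
        COUNTRY_COLUMNS["extreme_low_temp"],
        COUNTRY_COLUMNS["outcome"],
    ]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"country table {path} is missing column {col!r}")
    records: list[CountryRecord] = []
    n_skipped = 0
    for i, row in df.iterrows():
        temp = pd.to_numeric(row[COUNTRY_COLUMNS["extreme_low_temp"]], errors="coerce")
        outcome = pd.to_numeric(row[COUNTRY_COLUMNS["outcome"]], errors="coerce")
        if pd.isna(temp) or pd.isna(outcome):
            n_skipped += 1
            logger.warning("skipping row %d of %s: missing temperature or outcome", i, path.name)
            continue
        stratum = row.get(COUNTRY_COLUMNS["stratum"])
        flags_raw = row.get(COUNTRY_COLUMNS["flags"])
        flags = (
            frozenset(f.strip() for f in str(flags_raw).split(";") if f.strip())
            if isinstance(flags_raw, str) and flags_raw.strip()
            else frozenset()
        )
        records.append(
            CountryRecord(
                population=str(row[COUNTRY_COLUMNS["population"]]),
                extreme_low_temp=float(temp),
                outcome=float(outcome),
                stratum=None if pd.isna(stratum) else str(stratum),
                flags=flags,
            )
        )
    logger.info("read %d country records from %s (%d skipped)", len(records), path, n_skipped)
    return records


def fit_univariate(
    records: Sequence[CountryRecord],
    exclude_flags: Iterable[str] = (),
) -> RegressionResult:
    """OLS of outcome on extreme low temperature.

    The predictor is the signed temperature in degC; a negative slope
    therefore means higher rates in colder countries.
    """
    exclude = set(exclude_flags)
    kept = [r for r in records if not (r.flags & exclude)]
    if len(kept) < 3:
        raise ValueError("need at least 3 records after exclusions")
    x = np.array([r.extreme_low_temp for r in kept])
    y = np.array([r.outcome for r in kept])
    if np.ptp(x) == 0:
        raise ValueError("temperature has zero variance; slope is unidentifiable")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    n = len(kept)
    r2 = float(model.rsquared)
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r2=r2,
        adj_r2=1.0 - (1.0 - r2) * (n - 1) / (n - 2),
        p_slope=float(model.pvalues[1]),
        n=n,
    )


def run_scenarios(
    records: Sequence[CountryRecord], scenarios: Sequence[Scenario]
) -> list[tuple[str, RegressionResult]]:
    """Fit each scenario; scenarios emptied by their filters are skipped."""
    out: list[tuple[str, RegressionResult]] = []
    for sc in scenarios:
        subset = [r for r in records if sc.stratum is None or r.stratum == sc.stratum]
        try:
            result = fit_univariate(subset, exclude_flags=sc.exclude_flags)
        except ValueError as exc:
            logger.warning("skipping scenario %r: %s", sc.label, exc)
            continue
        out.append((sc.label, result))
    return out


def plot_scenario(
    records: Sequence[CountryRecord],
    result: RegressionResult,
    path: str | Path,
    title: str = "",
) -> Path:
    """Scatter of outcome vs temperature with the fitted line, saved to file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.array([r.extreme_low_temp for r in records])
    y = np.array([r.outcome for r in records])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=18, alpha=0.7)
    grid = np.linspace(x.min(), x.max(), 50)
    ax.plot(grid, result.intercept + result.slope * grid, color="firebrick")
    ax.set_xlabel("extreme low temperature (degC)")
    ax.set_ylabel("rate per 100,000")
    ax.set_title(
        title or f"adj R2={result.adj_r2:.3f}, p={result.p_slope:.2e}, n={result.n}"
    )
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
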