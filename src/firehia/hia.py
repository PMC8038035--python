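"""Concentration-response health impact model.

The exposure-response link is the standard log-linear short-term model: a
relative risk RR quoted per 10 µg/m³ of PM2.5 implies a risk multiplier

    IF(ΔX) = RR ** (ΔX / 10)

at an arbitrary increment ΔX (the *impact function*), and the expected
number of events attributable to the increment in a population with a
known baseline incidence rate is

    AN = (IF - 1) × Pop × rate.

Confidence bounds propagate by plugging the low/high RR bounds through the
same two formulas, matching how epidemiological CI triples are reported;
no Monte Carlo is used.  Annual incidence rates are converted to daily
rates by dividing by 365 so that attributable numbers can be accumulated
day by day over an episode.

Default endpoints bundle the WHO HRAPIE short-term coefficients for
all-cause mortality and cardiovascular hospitalizations and a California
wildfire coefficient for respiratory hospitalizations, each per 10 µg/m³.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Literal, Optional

import numpy as np
import pandas as pd

from firehia.errors import InvalidParameterError, MissingDataError

DAYS_PER_YEAR = 365.0

ArrayLike = "float | np.ndarray"


@dataclass(frozen=True)
class HealthEndpoint:
    """A health endpoint with its relative risk and confidence bounds.

    ``rr_central``/``rr_low``/``rr_high`` are unitless relative risks per
    ``ref_increment`` µg/m³ of PM2.5 (default 10).
    """

    name: str
    rr_central: float
    rr_low: float
    rr_high: float
    ref_increment: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.rr_low <= self.rr_central <= self.rr_high):
            raise InvalidParameterError(
                f"{self.name}: require 0 < rr_low <= rr_central <= rr_high, "
                f"got ({self.rr_low}, {self.rr_central}, {self.rr_high})"
            )
        if self.ref_increment <= 0:
            raise InvalidParameterError(f"{self.name}: ref_increment must be positive")


#: Relative risks per 10 µg/m³ PM2.5: HRAPIE short-term coefficients for
#: all-cause mortality and CVD hospitalizations; 2003 California wildfire
#: study for respiratory hospitalizations.
DEFAULT_ENDPOINTS: Dict[str, HealthEndpoint] = {
    "mortality": HealthEndpoint("mortality", 1.0123, 1.0045, 1.0201),
    "cvd_hosp": HealthEndpoint("cvd_hosp", 1.0091, 1.0017, 1.0201),
    "resp_hosp": HealthEndpoint("resp_hosp", 1.03, 1.01, 1.04),
}


def impact_function(rr, delta_x, ref_increment: float = 10.0):
    """Risk multiplier ``rr ** (delta_x / ref_increment)``.

    Accepts scalars or arrays for ``delta_x``.  Returns 1 at ``delta_x = 0``
    and is strictly increasing in ``delta_x`` for ``rr > 1``.
    """
    rr = np.asarray(rr, dtype=float)
    if np.any(rr <= 0):
        raise InvalidParameterError("relative risk must be positive")
    if ref_increment <= 0:
        raise InvalidParameterError("ref_increment must be positive")
    delta_x = np.asarray(delta_x, dtype=float)
    if np.any(delta_x < 0):
        raise InvalidParameterError("delta_x must be non-negative (clamp upstream)")
    out = rr ** (delta_x / ref_increment)
    return out.item() if np.isscalar(delta_x) or out.ndim == 0 else out


def attributable_number(if_value, population, daily_rate):
    """Expected events attributable to the increment: ``(IF - 1) × Pop × rate``."""
    population = np.asarray(population, dtype=float)
    daily_rate = np.asarray(daily_rate, dtype=float)
    if np.any(population < 0):
        raise InvalidParameterError("population must be non-negative")
    if np.any(daily_rate < 0):
        raise InvalidParameterError("daily rate must be non-negative")
    out = (np.asarray(if_value, dtype=float) - 1.0) * population * daily_rate
    return out.item() if out.ndim == 0 else out


def annual_to_daily_rate(annual_rate):
    """Convert events/person/year to events/person/day (divide by 365)."""
    annual_rate = np.asarray(annual_rate, dtype=float)
    if np.any(annual_rate < 0):
        raise InvalidParameterError("annual rate must be non-negative")
    out = annual_rate / DAYS_PER_YEAR
    return out.item() if out.ndim == 0 else out


def compute_endpoint_series(
    exposure: pd.DataFrame,
    population: pd.DataFrame,
    rates: pd.DataFrame,
    endpoint: HealthEndpoint,
    fill: Optional[Literal["domain_mean"]] = None,
) -> pd.DataFrame:
    """Daily attributable numbers with CI bounds per district.

    Parameters
    ----------
    exposure
        Columns ``district_id, date, delta_x`` (µg/m³ daily means).
    population
        Columns ``district_id, population`` (2016-style snapshot, held
        constant over the episode).
    rates
        District-level annual incidence rates: columns ``district_id``
        (or ``region_id``), ``endpoint``, ``rate``; filtered to
        ``endpoint.name``.
    fill
        ``None`` (default): a district missing its population or rate is a
        hard error.  ``"domain_mean"``: fill with the mean over districts
        that do have values.

    Returns a DataFrame with columns ``district_id, date, endpoint,
    an_central, an_low, an_high``; the ordering ``an_low <= an_central <=
    an_high`` holds wherever ``delta_x >= 0``.
    """
    pop_map = population.set_index("district_id")["population"].astype(float)
    r = rates.rename(columns={"region_id": "district_id"})
    r = r[r["endpoint"] == endpoint.name]
    rate_map = r.set_index("district_id")["rate"].astype(float)

    districts = exposure["district_id"].unique()
    missing_pop = [d for d in districts if d not in pop_map.index]
    missing_rate = [d for d in districts if d not in rate_map.index]
    if fill == "domain_mean":
        pop_map = pop_map.reindex(districts).fillna(pop_map.mean())
        rate_map = rate_map.reindex(districts).fillna(rate_map.mean())
    elif missing_pop or missing_rate:
        parts = []
        if missing_pop:
            parts.append(f"no population for district(s) {sorted(missing_pop)}")
        if missing_rate:
            parts.append(
                f"no {endpoint.name!r} rate for district(s) {sorted(missing_rate)}"
            )
        raise MissingDataError("; ".join(parts))

    df = exposure[["district_id", "date", "delta_x"]].copy()
    pop = df["district_id"].map(pop_map).to_numpy()
    daily_rate = annual_to_daily_rate(df["district_id"].map(rate_map).to_numpy())
    dx = np.clip(df["delta_x"].to_numpy(dtype=float), 0.0, None)

    out = pd.DataFrame(
        {
            "district_id": df["district_id"].to_numpy(),
            "date": df["date"].to_numpy(),
            "endpoint": endpoint.name,
        }
    )
    for col, rr in (
        ("an_central", endpoint.rr_central),
        ("an_low", endpoint.rr_low),
        ("an_high", endpoint.rr_high),
    ):
        iv = impact_function(rr, dx, endpoint.ref_increment)
        out[col] = attributable_number(iv, pop, daily_rate)
    return out


def aggregate_an(an: pd.DataFrame, by: Literal["day", "district", "total"]) -> pd.DataFrame:
    """Sum attributable numbers over the collapsed dimensions.

    ``by="day"`` keeps (date, endpoint); ``by="district"`` keeps
    (district_id, endpoint); ``by="total"`` keeps endpoint only.  All three
    AN columns are summed, so the grand total equals the sum of any
    complete partition.
    """
    if an.empty:
        raise InvalidParameterError("cannot aggregate an empty AN collection")
    keys = {"day": ["endpoint", "date"], "district": ["endpoint", "district_id"], "total": ["endpoint"]}
    if by not in keys:
        raise InvalidParameterError(f"unknown aggregation key {by!r}; use day|district|total")
    cols = ["an_central", "an_low", "an_high"]
    return an.groupby(keys[by], as_index=False)[cols].sum()
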