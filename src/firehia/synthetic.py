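"""Synthetic smoke-episode world with known ground truth.

Real inputs to this kind of assessment — chemistry-transport model PM2.5
fields, census district shapefiles, health-administration rate tables and
monitoring-station records — are rarely deposited.  This module generates
structurally faithful stand-ins:

* **Concentration fields** from a Gaussian-puff kernel: each fire source
  contributes, on each day it is active, an anisotropic Gaussian centred
  downwind of the source by the day's wind displacement, elongated along
  the wind, with amplitude decaying per day of fire age.  Cell value =
  background + Σ contributions.  This is a transport *picture*, not a
  dispersion model: no chemistry, deposition or vertical structure — it
  exists to exercise the overlay and attribution arithmetic with episodic
  multi-day peaks spanning tens to >1000 µg/m³.
* **District layers** as jittered rectangular tessellations of the grid
  extent — full coverage, no overlaps — generated independently for the
  census-district (exposure) layer and the rate-region layer so the two
  are non-nested, as real administrative geographies are.
* **Population and rate tables** with magnitudes typical of Australian
  census districts: populations log-uniform in [1e4, 1e6]; annual
  incidence rates uniform in [0.005, 0.01] for mortality and [0.01, 0.05]
  for hospitalizations.
* **Station observations** as the containing-cell model value perturbed
  by multiplicative lognormal noise.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from shapely.geometry import box

from firehia.districts import District, DistrictLayer
from firehia.errors import InvalidParameterError
from firehia.evaluation import StationSeries
from firehia.grid import ConcentrationGrid

SECONDS_PER_DAY = 86_400.0

#: plausible annual incidence bands (events/person/year)
RATE_BANDS: Dict[str, Tuple[float, float]] = {
    "mortality": (0.005, 0.01),
    "cvd_hosp": (0.01, 0.05),
    "resp_hosp": (0.01, 0.05),
}
POPULATION_BAND = (1e4, 1e6)


@dataclass(frozen=True)
class FireSource:
    """A point smoke source standing in for a satellite-detected hot spot."""

    x: float
    y: float
    strength: float  # µg/m³ at the plume core on the first active day
    start_day: int = 0
    end_day: int = 10**9
    decay: float = 1.0  # per-day strength multiplier

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise InvalidParameterError("fire strength must be non-negative")
        if self.start_day > self.end_day:
            raise InvalidParameterError("start_day must not exceed end_day")


@dataclass
class SyntheticScenario:
    """Full parameterisation of a synthetic smoke episode.

    Defaults mirror the scale of a regional chemistry-transport run over
    south-eastern Australia: a 100 × 100 grid of 12 km cells (a 1200 km
    domain) with daily fields over a multi-week episode.
    """

    nx: int = 100
    ny: int = 100
    cell_size: float = 12_000.0  # metres
    crs: str = "local-metre"
    n_days: int = 30
    start_date: str = "2019-11-01"
    wind: Optional[Sequence[Tuple[float, float]]] = None  # (u, v) m/s per day
    fires: List[FireSource] = field(default_factory=list)
    background: float = 0.0  # µg/m³ increment floor
    sigma_along: float = 60_000.0  # along-wind plume spread, metres
    sigma_cross: float = 25_000.0  # cross-wind plume spread, metres
    field_noise_sd: float = 0.0  # multiplicative lognormal sd on the field
    seed: int = 0

    @property
    def extent(self) -> Tuple[float, float, float, float]:
        return (0.0, 0.0, self.nx * self.cell_size, self.ny * self.cell_size)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=self.n_days, freq="D")


def default_scenario(seed: int = 0) -> SyntheticScenario:
    """A multi-source episodic scenario with plausible magnitudes.

    Several coastal fire clusters ignite at staggered times, burn for one
    to several weeks with slow decay, and are advected by a persistent
    westerly with a synoptic oscillation — producing multi-day district
    peaks from tens to above 1000 µg/m³ over the default 30-day episode.
    """
    rng = np.random.default_rng(seed)
    L = 1_200_000.0  # domain edge, metres
    n_days = 30
    wind = [
        (5.0 + 3.0 * np.sin(2 * np.pi * d / 10.0), 2.0 * np.cos(2 * np.pi * d / 7.0))
        for d in range(n_days)
    ]
    fires = []
    for _ in range(6):
        start = int(rng.integers(0, 18))
        fires.append(
            FireSource(
                x=float(rng.uniform(0.1 * L, 0.5 * L)),
                y=float(rng.uniform(0.2 * L, 0.8 * L)),
                strength=float(rng.uniform(200.0, 1500.0)),
                start_day=start,
                end_day=start + int(rng.integers(7, 21)),
                decay=float(rng.uniform(0.85, 0.98)),
            )
        )
    return SyntheticScenario(
        n_days=n_days, wind=wind, fires=fires, background=2.0, seed=seed
    )


def generate_concentration_fields(scenario: SyntheticScenario) -> ConcentrationGrid:
    """Render the scenario into a daily gridded PM2.5 increment field."""
    s = scenario
    ys = (np.arange(s.ny) + 0.5) * s.cell_size
    xs = (np.arange(s.nx) + 0.5) * s.cell_size
    X, Y = np.meshgrid(xs, ys)
    wind = s.wind if s.wind is not None else [(0.0, 0.0)] * s.n_days
    if len(wind) < s.n_days:
        raise InvalidParameterError("need one (u, v) wind vector per day")
    values = np.full((s.n_days, s.ny, s.nx), float(s.background))
    for day in range(s.n_days):
        u, v = wind[day]
        speed = float(np.hypot(u, v))
        dx, dy = u * SECONDS_PER_DAY, v * SECONDS_PER_DAY
        if speed > 0:
            ex, ey = u / speed, v / speed  # along-wind unit vector
        else:
            ex, ey = 1.0, 0.0
        for fire in s.fires:
            if not (fire.start_day <= day <= fire.end_day):
                continue
            amp = fire.strength * fire.decay ** (day - fire.start_day)
            cx, cy = fire.x + dx, fire.y + dy
            rx, ry = X - cx, Y - cy
            along = rx * ex + ry * ey
            cross = -rx * ey + ry * ex
            values[day] += amp * np.exp(
                -0.5 * ((along / s.sigma_along) ** 2 + (cross / s.sigma_cross) ** 2)
            )
    if s.field_noise_sd > 0:
        rng = np.random.default_rng(s.seed)
        values *= np.exp(rng.normal(0.0, s.field_noise_sd, size=values.shape))
    return ConcentrationGrid(
        values=values,
        x0=0.0,
        y0=0.0,
        cell_size=s.cell_size,
        crs=s.crs,
        timestamps=s.timestamps,
    )


def _tessellate(
    extent: Tuple[float, float, float, float],
    n: int,
    rng: np.random.Generator,
    prefix: str,
    jitter: float = 0.3,
) -> DistrictLayer:
    """Rectangular tiling with jittered cut lines: n polygons, full cover."""
    xmin, ymin, xmax, ymax = extent
    n_rows = max(int(np.floor(np.sqrt(n))), 1)
    base, extra = divmod(n, n_rows)
    cols_per_row = [base + (1 if r < extra else 0) for r in range(n_rows)]

    def cuts(lo: float, hi: float, k: int) -> np.ndarray:
        edges = np.linspace(lo, hi, k + 1)
        if k > 1:
            step = (hi - lo) / k
            edges[1:-1] += rng.uniform(-jitter * step, jitter * step, size=k - 1)
        return edges

    y_edges = cuts(ymin, ymax, n_rows)
    districts = []
    for r in range(n_rows):
        x_edges = cuts(xmin, xmax, cols_per_row[r])
        for c in range(cols_per_row[r]):
            districts.append(
                District(
                    district_id=f"{prefix}{len(districts):03d}",
                    geometry=box(x_edges[c], y_edges[r], x_edges[c + 1], y_edges[r + 1]),
                )
            )
    return DistrictLayer(districts=districts, crs="local-metre")


def generate_district_layers(
    scenario: SyntheticScenario,
    n_districts: int = 28,
    n_rate_regions: int = 60,
    seed: int = 0,
) -> Tuple[DistrictLayer, DistrictLayer]:
    """Two independent, non-nested tessellations of the grid extent.

    The first layer plays the census-district (exposure) role — O(30)
    polygons, like NSW's SA4 partition; the second the finer
    rate-region role (LGA/LHD-like).  Independent jitter makes the layers
    non-nested: rate regions straddle district boundaries.
    """
    if n_districts < 1 or n_rate_regions < 1:
        raise InvalidParameterError("need at least one polygon per layer")
    rng = np.random.default_rng(seed)
    districts = _tessellate(scenario.extent, n_districts, rng, "SA")
    regions = _tessellate(scenario.extent, n_rate_regions, rng, "RR")
    layers = (
        DistrictLayer(districts.districts, scenario.crs),
        DistrictLayer(regions.districts, scenario.crs),
    )
    return layers


def generate_population_and_rates(
    districts: DistrictLayer,
    rate_regions: DistrictLayer,
    endpoints: Sequence[str] = ("mortality", "cvd_hosp", "resp_hosp"),
    years: Sequence[int] = (2014, 2015, 2016),
    seed: int = 0,
    rate_bands: Optional[Dict[str, Tuple[float, float]]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Population per district and per-year annual incidence rates.

    Mortality rates sit on the district (census) layer, mirroring national
    statistics; hospitalization rates sit on the rate-region layer and
    must be projected.  Rates are drawn per year so three-year averaging
    is exercised; year-to-year variation is ±10% around the region draw.
    """
    bands = dict(RATE_BANDS)
    if rate_bands:
        bands.update(rate_bands)
    rng = np.random.default_rng(seed)
    lo, hi = POPULATION_BAND
    pop = pd.DataFrame(
        {
            "district_id": districts.ids,
            "population": np.round(
                np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(districts)))
            ).astype(int),
        }
    )
    records = []
    for endpoint in endpoints:
        layer = districts if endpoint == "mortality" else rate_regions
        b_lo, b_hi = bands[endpoint]
        for rid in layer.ids:
            base = rng.uniform(b_lo, b_hi)
            for year in years:
                wiggle = rng.uniform(0.9, 1.1) if b_hi > b_lo else 1.0
                records.append(
                    {"region_id": rid, "endpoint": endpoint, "year": year, "rate": base * wiggle}
                )
    return pop, pd.DataFrame.from_records(records)


def generate_station_obs(
    grid: ConcentrationGrid,
    stations: Sequence[Tuple[str, float, float]],
    noise_sd_fraction: float = 0.3,
    seed: int = 0,
) -> List[StationSeries]:
    """Noisy pseudo-observations at station locations.

    observed = cell value × exp(ε), ε ~ Normal(0, noise_sd_fraction);
    predicted = cell value.  Zero noise gives observed ≡ predicted.
    """
    if noise_sd_fraction < 0:
        raise InvalidParameterError("noise_sd_fraction must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for station_id, x, y in stations:
        i, j = grid.cell_index(x, y)  # raises if outside extent
        truth = grid.values[:, i, j]
        noise = rng.normal(0.0, noise_sd_fraction, size=truth.shape) if noise_sd_fraction else 0.0
        out.append(
            StationSeries(
                station_id=station_id,
                x=x,
                y=y,
                timestamps=grid.timestamps,
                observed=truth * np.exp(noise),
                predicted=truth.copy(),
            )
        )
    return out
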