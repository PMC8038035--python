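"""End-to-end orchestration: simulate → exposure → rates → impact → evaluate.

Each stage reads the previous stage's files from the output directory and
writes its own, so the whole run is re-startable and every intermediate
is inspectable.  All CSVs are UTF-8, comma-separated, ISO-8601 dates,
'.' decimal, with fixed column orders; a run with the same configuration
and seed is byte-identical.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Any, Dict, List, Optional

import numpy as np
import pandas as pd

from firehia.config import endpoints_from_config, load_config
from firehia.districts import DistrictLayer
from firehia.errors import ValidationError
from firehia.evaluation import StationSeries, evaluate_station, extract_prediction_at_station
from firehia.exposure import zonal_mean
from firehia.grid import ConcentrationGrid
from firehia.hia import aggregate_an, compute_endpoint_series
from firehia.rates import average_rates_over_years, project_rates
from firehia.synthetic import (
    default_scenario,
    generate_concentration_fields,
    generate_district_layers,
    generate_population_and_rates,
    generate_station_obs,
)

log = logging.getLogger("firehia")

FILES = {
    "grid": "grid.nc",
    "districts": "districts.geojson",
    "rate_regions": "rate_regions.geojson",
    "population": "population.csv",
    "rates": "rates.csv",
    "stations": "stations.csv",
    "observations": "observations.csv",
    "exposure": "exposure.csv",
    "rates_projected": "rates_projected.csv",
    "an": "an.csv",
    "totals": "totals.csv",
    "stats": "stats.csv",
}


def _path(outdir: str | Path, key: str) -> Path:
    return Path(outdir) / FILES[key]


def _timed(stage: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            out = fn(*args, **kwargs)
            log.info("stage %s finished in %.2fs", stage, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


@_timed("simulate")
def stage_simulate(cfg: Dict[str, Any], seed: int, outdir: str | Path) -> None:
    """Generate and write the full synthetic input bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sc_cfg = cfg["scenario"]
    scenario = default_scenario(seed=seed)
    scenario.n_days = int(sc_cfg.get("n_days", scenario.n_days))
    if "background" in sc_cfg:
        scenario.background = float(sc_cfg["background"])
    if sc_cfg.get("no_fires"):
        scenario.fires = []
    grid = generate_concentration_fields(scenario)
    districts, regions = generate_district_layers(
        scenario,
        n_districts=int(sc_cfg["n_districts"]),
        n_rate_regions=int(sc_cfg["n_rate_regions"]),
        seed=seed,
    )
    pop, rates = generate_population_and_rates(districts, regions, seed=seed)
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = scenario.extent
    stations = [
        (f"ST{k:02d}", float(rng.uniform(xmin, xmax)), float(rng.uniform(ymin, ymax)))
        for k in range(int(sc_cfg["n_stations"]))
    ]
    obs = generate_station_obs(
        grid, stations, noise_sd_fraction=float(sc_cfg["noise_sd_fraction"]), seed=seed
    )

    grid.to_netcdf(_path(outdir, "grid"))
    districts.to_geojson(_path(outdir, "districts"))
    regions.to_geojson(_path(outdir, "rate_regions"))
    pop.to_csv(_path(outdir, "population"), index=False)
    rates[["region_id", "endpoint", "year", "rate"]].to_csv(
        _path(outdir, "rates"), index=False
    )
    pd.DataFrame(stations, columns=["station_id", "x", "y"]).to_csv(
        _path(outdir, "stations"), index=False
    )
    obs_rows = []
    for s in obs:
        for ts, value in zip(s.timestamps, s.observed):
            obs_rows.append(
                {"station_id": s.station_id, "timestamp": ts, "variable": "pm25", "value": value}
            )
    pd.DataFrame(obs_rows).to_csv(_path(outdir, "observations"), index=False)
    log.info("simulated %d days on a %dx%d grid, seed=%d", grid.shape[0], grid.ny, grid.nx, seed)


@_timed("exposure")
def stage_exposure(cfg: Dict[str, Any], outdir: str | Path) -> pd.DataFrame:
    """Zonal-average the gridded field over the exposure districts."""
    grid = ConcentrationGrid.from_netcdf(_path(outdir, "grid"))
    districts = DistrictLayer.from_geojson(_path(outdir, "districts"))
    exp = zonal_mean(grid, districts, method=cfg["exposure"]["method"])
    exp.to_csv(_path(outdir, "exposure"), index=False)
    log.info("exposure: %d district-days", len(exp))
    return exp


@_timed("rates")
def stage_rates(cfg: Dict[str, Any], outdir: str | Path) -> pd.DataFrame:
    """Average rates over years and project them onto exposure districts."""
    districts = DistrictLayer.from_geojson(_path(outdir, "districts"))
    regions = DistrictLayer.from_geojson(_path(outdir, "rate_regions"))
    rates = pd.read_csv(_path(outdir, "rates"))
    yearly_avg = average_rates_over_years(rates, years=cfg["rates"]["years"])

    pieces = []
    by_layer = {"districts": [], "rate_regions": []}
    for name, spec in cfg["endpoints"].items():
        by_layer[spec["rate_layer"]].append(name)
    native = yearly_avg[yearly_avg["endpoint"].isin(by_layer["districts"])]
    if not native.empty:
        pieces.append(native)
    to_project = yearly_avg[yearly_avg["endpoint"].isin(by_layer["rate_regions"])]
    if not to_project.empty:
        pieces.append(
            project_rates(regions, to_project, districts, method=cfg["rates"]["method"])
        )
    projected = pd.concat(pieces, ignore_index=True)
    projected = projected.sort_values(["endpoint", "region_id"]).reset_index(drop=True)
    projected.to_csv(_path(outdir, "rates_projected"), index=False)
    log.info("rates projected for %d endpoint-districts", len(projected))
    return projected


@_timed("impact")
def stage_impact(cfg: Dict[str, Any], outdir: str | Path) -> pd.DataFrame:
    """Attributable numbers per district-day-endpoint, plus totals."""
    exposure = pd.read_csv(_path(outdir, "exposure"), parse_dates=["date"])
    population = pd.read_csv(_path(outdir, "population"))
    rates = pd.read_csv(_path(outdir, "rates_projected"))
    endpoints = endpoints_from_config(cfg)
    an = pd.concat(
        [
            compute_endpoint_series(exposure, population, rates, ep)
            for ep in endpoints.values()
        ],
        ignore_index=True,
    )
    an = an[["district_id", "date", "endpoint", "an_central", "an_low", "an_high"]]
    an.to_csv(_path(outdir, "an"), index=False)
    totals = aggregate_an(an, by="total")
    totals.to_csv(_path(outdir, "totals"), index=False)
    for _, row in totals.iterrows():
        log.info(
            "total %s: %.2f (CI %.2f, %.2f)",
            row["endpoint"],
            row["an_central"],
            row["an_low"],
            row["an_high"],
        )
    return an


@_timed("evaluate")
def stage_evaluate(cfg: Dict[str, Any], outdir: str | Path) -> pd.DataFrame:
    """Paired-series statistics of the gridded field vs station records."""
    grid = ConcentrationGrid.from_netcdf(_path(outdir, "grid"))
    stations = pd.read_csv(_path(outdir, "stations"))
    observations = pd.read_csv(_path(outdir, "observations"), parse_dates=["timestamp"])
    rows = []
    for _, st in stations.iterrows():
        obs = observations[observations["station_id"] == st["station_id"]]
        obs = obs.sort_values("timestamp")
        predicted = extract_prediction_at_station(grid, (st["x"], st["y"]))
        series = StationSeries(
            station_id=st["station_id"],
            x=st["x"],
            y=st["y"],
            timestamps=pd.DatetimeIndex(obs["timestamp"]),
            observed=obs["value"].to_numpy(),
            predicted=predicted,
        )
        rows.append(evaluate_station(series, scale="daily"))
    stats = pd.DataFrame(
        rows, columns=["station_id", "variable", "scale", "n", "r2", "ioa", "rmse", "mean_bias"]
    )
    stats.to_csv(_path(outdir, "stats"), index=False)
    log.info("evaluated %d stations; median IOA %.3f", len(stats), stats["ioa"].median())
    return stats


def validate_inputs(outdir: str | Path) -> List[str]:
    """Schema checks over an input bundle; returns the list of violations."""
    outdir = Path(outdir)
    violations: List[str] = []
    try:
        grid = ConcentrationGrid.from_netcdf(_path(outdir, "grid"))
        finite = grid.values[np.isfinite(grid.values)]
        if finite.size and finite.min() < 0:
            violations.append("grid: negative concentration values present")
        if len(grid.timestamps) > 1 and not grid.timestamps.is_monotonic_increasing:
            violations.append("grid: timestamps not monotone")
    except Exception as exc:  # noqa: BLE001 — every defect becomes a report line
        violations.append(f"grid: unreadable ({exc})")
    for key in ("districts", "rate_regions"):
        try:
            layer = DistrictLayer.from_geojson(_path(outdir, key))
            if layer.crs is None:
                violations.append(f"{key}: missing CRS")
        except Exception as exc:
            violations.append(f"{key}: {exc}")
    try:
        pop = pd.read_csv(_path(outdir, "population"))
        dupes = pop[pop["district_id"].duplicated()]["district_id"]
        for d in dupes:
            violations.append(f"population: duplicated district_id {d!r}")
        for d in pop[pop["population"] < 0]["district_id"]:
            violations.append(f"population: negative population for district {d!r}")
    except Exception as exc:
        violations.append(f"population: unreadable ({exc})")
    try:
        rates = pd.read_csv(_path(outdir, "rates"))
        bad = rates[rates["rate"] < 0]
        for _, row in bad.iterrows():
            violations.append(
                f"rates: negative rate for region {row['region_id']!r} "
                f"endpoint {row['endpoint']!r}"
            )
    except Exception as exc:
        violations.append(f"rates: unreadable ({exc})")
    return violations


def run_pipeline(
    cfg: Optional[Dict[str, Any]] = None,
    seed: int = 0,
    outdir: str | Path = "out",
) -> Dict[str, pd.DataFrame]:
    """Full run: simulate, validate, then every downstream stage.

    Returns the in-memory tables of each stage; files land in *outdir*.
    On a validation failure the partial outputs of the failed run are
    removed and :class:`ValidationError` is raised.
    """
    cfg = cfg if cfg is not None else load_config()
    outdir = Path(outdir)
    log.info("pipeline run: seed=%d outdir=%s", seed, outdir)
    try:
        stage_simulate(cfg, seed, outdir)
        violations = validate_inputs(outdir)
        if violations:
            raise ValidationError(violations)
        exposure = stage_exposure(cfg, outdir)
        rates = stage_rates(cfg, outdir)
        an = stage_impact(cfg, outdir)
        stats = stage_evaluate(cfg, outdir)
    except Exception:
        for key in ("exposure", "rates_projected", "an", "totals", "stats"):
            _path(outdir, key).unlink(missing_ok=True)
        raise
    totals = pd.read_csv(_path(outdir, "totals"))
    return {"exposure": exposure, "rates": rates, "an": an, "totals": totals, "stats": stats}
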