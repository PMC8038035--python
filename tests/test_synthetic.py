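"""Synthetic world: puff fields, tessellations, tables, station noise."""

import numpy as np
import pytest

from firehia.errors import InvalidParameterError
from firehia.evaluation import index_of_agreement
from firehia.synthetic import (
    FireSource,
    SyntheticScenario,
    default_scenario,
    generate_concentration_fields,
    generate_district_layers,
    generate_population_and_rates,
    generate_station_obs,
)


def small_scenario(**kwargs):
    defaults = dict(nx=20, ny=20, cell_size=10_000.0, n_days=5)
    defaults.update(kwargs)
    return SyntheticScenario(**defaults)


def test_no_fires_gives_flat_background():
    grid = generate_concentration_fields(small_scenario(background=5.0))
    assert np.allclose(grid.values, 5.0)


def test_zero_wind_peak_at_source_cell():
    fire = FireSource(x=105_000.0, y=55_000.0, strength=800.0)
    grid = generate_concentration_fields(small_scenario(fires=[fire]))
    for t in range(grid.shape[0]):
        i, j = np.unravel_index(np.argmax(grid.values[t]), grid.values[t].shape)
        assert (i, j) == grid.cell_index(fire.x, fire.y)


def test_wind_displaces_peak_downwind():
    fire = FireSource(x=40_000.0, y=100_000.0, strength=800.0)
    wind = [(1.0, 0.0)] * 5  # 86.4 km/day eastward
    grid = generate_concentration_fields(small_scenario(fires=[fire], wind=wind))
    i, j = np.unravel_index(np.argmax(grid.values[0]), grid.values[0].shape)
    ic, jc = grid.cell_index(fire.x + 86_400.0, fire.y)
    assert (i, j) == (ic, jc)


def test_doubling_strength_doubles_anomaly():
    fire = FireSource(x=100_000.0, y=100_000.0, strength=300.0)
    double = FireSource(x=100_000.0, y=100_000.0, strength=600.0)
    g1 = generate_concentration_fields(small_scenario(fires=[fire], background=2.0))
    g2 = generate_concentration_fields(small_scenario(fires=[double], background=2.0))
    np.testing.assert_allclose(g2.values - 2.0, 2 * (g1.values - 2.0), rtol=1e-12)


def test_fire_activity_window_and_decay():
    fire = FireSource(x=100_000.0, y=100_000.0, strength=500.0, start_day=1, end_day=2, decay=0.5)
    grid = generate_concentration_fields(small_scenario(fires=[fire], n_days=4))
    anomaly = grid.values.max(axis=(1, 2))
    assert anomaly[0] == 0.0 and anomaly[3] == 0.0
    assert anomaly[2] == pytest.approx(anomaly[1] / 2, rel=1e-9)


def test_field_reproducible_and_nonnegative():
    sc = default_scenario(seed=7)
    g1 = generate_concentration_fields(sc)
    g2 = generate_concentration_fields(default_scenario(seed=7))
    np.testing.assert_array_equal(g1.values, g2.values)
    assert (g1.values >= 0).all()


def test_default_scenario_has_episodic_extremes():
    grid = generate_concentration_fields(default_scenario(seed=0))
    assert grid.values.max() > 1000.0  # core plume exceeds 1000 µg/m³
    assert np.median(grid.values) < 50.0  # most of the domain stays near background


def test_single_district_is_grid_extent():
    sc = small_scenario()
    districts, regions = generate_district_layers(sc, n_districts=1, n_rate_regions=1, seed=0)
    xmin, ymin, xmax, ymax = sc.extent
    assert districts.districts[0].geometry.area == pytest.approx((xmax - xmin) * (ymax - ymin))


@pytest.mark.parametrize("n_districts,n_rate_regions", [(7, 13), (28, 60)])
def test_tessellation_full_cover_no_overlap(n_districts, n_rate_regions):
    sc = small_scenario()
    districts, regions = generate_district_layers(
        sc, n_districts=n_districts, n_rate_regions=n_rate_regions, seed=3
    )
    xmin, ymin, xmax, ymax = sc.extent
    extent_area = (xmax - xmin) * (ymax - ymin)
    for layer, n in ((districts, n_districts), (regions, n_rate_regions)):
        assert len(layer) == n
        assert layer.total_area() == pytest.approx(extent_area, rel=1e-9)
        from shapely.ops import unary_union

        union = unary_union([d.geometry for d in layer])
        assert union.area == pytest.approx(extent_area, rel=1e-9)  # no overlaps


def test_layers_are_non_nested():
    districts, regions = generate_district_layers(small_scenario(), 6, 15, seed=2)
    straddles = any(
        sum(
            1
            for s in regions
            if d.geometry.intersection(s.geometry).area > 1e-6 * d.geometry.area
        )
        >= 2
        for d in districts
    )
    assert straddles


def test_population_and_rate_tables():
    districts, regions = generate_district_layers(small_scenario(), 10, 20, seed=1)
    pop, rates = generate_population_and_rates(districts, regions, seed=1)
    pop2, rates2 = generate_population_and_rates(districts, regions, seed=1)
    assert pop.equals(pop2) and rates.equals(rates2)
    assert (pop["population"] >= 1e4).all() and (pop["population"] <= 1e6).all()
    assert (rates["rate"] >= 0).all()
    # mortality keyed to districts, hospitalizations to rate regions, 3 years each
    mort = rates[rates["endpoint"] == "mortality"]
    assert set(mort["region_id"]) == set(districts.ids)
    assert mort.groupby("region_id")["year"].nunique().eq(3).all()
    hosp = rates[rates["endpoint"] == "cvd_hosp"]
    assert set(hosp["region_id"]) == set(regions.ids)


def test_degenerate_rate_band_forces_constant_rate():
    districts, regions = generate_district_layers(small_scenario(), 5, 9, seed=0)
    _, rates = generate_population_and_rates(
        districts, regions, seed=0, rate_bands={k: (0.02, 0.02) for k in ("mortality", "cvd_hosp", "resp_hosp")}
    )
    assert np.allclose(rates["rate"], 0.02)


def test_station_obs_noise_free_matches_prediction():
    grid = generate_concentration_fields(default_scenario(seed=4))
    obs = generate_station_obs(grid, [("S1", 500_000.0, 500_000.0)], noise_sd_fraction=0.0)
    np.testing.assert_array_equal(obs[0].observed, obs[0].predicted)
    assert index_of_agreement(obs[0].predicted, obs[0].observed) == 1.0


def test_station_obs_seed_reproducible_and_outside_errors():
    grid = generate_concentration_fields(default_scenario(seed=4))
    a = generate_station_obs(grid, [("S1", 300_000.0, 300_000.0)], 0.3, seed=5)
    b = generate_station_obs(grid, [("S1", 300_000.0, 300_000.0)], 0.3, seed=5)
    np.testing.assert_array_equal(a[0].observed, b[0].observed)
    with pytest.raises(InvalidParameterError):
        generate_station_obs(grid, [("S1", -10.0, 0.0)], 0.3, seed=5)


def test_median_ioa_decreases_with_station_noise():
    """More observation noise -> stochastically worse agreement (20+ seeds)."""
    grid = generate_concentration_fields(default_scenario(seed=11))
    station = [("S1", 450_000.0, 550_000.0)]
    medians = []
    for noise in (0.05, 0.3, 0.8):
        ioas = [
            index_of_agreement(
                *(lambda s: (s.predicted, s.observed))(
                    generate_station_obs(grid, station, noise, seed=seed)[0]
                )
            )
            for seed in range(25)
        ]
        medians.append(float(np.median(ioas)))
    assert medians[0] > medians[1] > medians[2]
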