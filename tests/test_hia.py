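"""Impact function, attributable numbers, CI propagation, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from firehia.errors import InvalidParameterError, MissingDataError
from firehia.hia import (
    DEFAULT_ENDPOINTS,
    HealthEndpoint,
    aggregate_an,
    annual_to_daily_rate,
    attributable_number,
    compute_endpoint_series,
    impact_function,
)


@pytest.mark.parametrize(
    "rr, dx, ref, expected",
    [
        (1.0123, 10.0, 10.0, 1.0123),  # RR at the reference increment
        (1.05, 0.0, 10.0, 1.0),  # zero increment -> null multiplier
        (1.03, 20.0, 10.0, 1.0609),  # two reference increments square the RR
        (1.0, 500.0, 10.0, 1.0),  # null relative risk -> no attribution
    ],
)
def test_impact_function_values(rr, dx, ref, expected):
    assert impact_function(rr, dx, ref) == pytest.approx(expected, rel=1e-12)


def test_impact_function_rejects_bad_parameters():
    with pytest.raises(InvalidParameterError):
        impact_function(0.0, 10.0)
    with pytest.raises(InvalidParameterError):
        impact_function(1.01, 10.0, ref_increment=0.0)
    with pytest.raises(InvalidParameterError):
        impact_function(1.01, -1.0)


@given(
    rr=st.floats(1.0 + 1e-6, 1.2),
    dx=st.floats(0.0, 1000.0),
    eps=st.floats(1e-6, 100.0),
)
@settings(max_examples=100, derandomize=True)
def test_impact_function_strictly_increasing(rr, dx, eps):
    assert impact_function(rr, dx + eps) > impact_function(rr, dx)


@pytest.mark.parametrize(
    "iv, pop, rate, expected",
    [
        (1.0, 123456, 1e-5, 0.0),
        (1.0609, 100000, 5e-5, 0.3045),
        (1.0123, 0, 1e-5, 0.0),
    ],
)
def test_attributable_number_values(iv, pop, rate, expected):
    assert attributable_number(iv, pop, rate) == pytest.approx(expected, abs=1e-12)


def test_attributable_number_linear_in_pop_and_rate():
    base = attributable_number(1.02, 1e5, 1e-4)
    assert attributable_number(1.02, 3e5, 1e-4) == pytest.approx(3 * base)
    assert attributable_number(1.02, 1e5, 5e-4) == pytest.approx(5 * base)


def test_attributable_number_rejects_negative_inputs():
    with pytest.raises(InvalidParameterError):
        attributable_number(1.01, -1, 1e-5)
    with pytest.raises(InvalidParameterError):
        attributable_number(1.01, 100, -1e-5)


def test_annual_to_daily_rate():
    assert annual_to_daily_rate(0.0) == 0.0
    assert annual_to_daily_rate(0.365) == pytest.approx(0.001)
    assert annual_to_daily_rate(365 * 7.3e-4) == pytest.approx(7.3e-4)
    with pytest.raises(InvalidParameterError):
        annual_to_daily_rate(-0.1)


def test_default_endpoints_hold_published_risk_triples():
    m = DEFAULT_ENDPOINTS["mortality"]
    assert (m.rr_low, m.rr_central, m.rr_high) == (1.0045, 1.0123, 1.0201)
    c = DEFAULT_ENDPOINTS["cvd_hosp"]
    assert (c.rr_low, c.rr_central, c.rr_high) == (1.0017, 1.0091, 1.0201)
    r = DEFAULT_ENDPOINTS["resp_hosp"]
    assert (r.rr_low, r.rr_central, r.rr_high) == (1.01, 1.03, 1.04)
    # implied per-10 µg/m³ mortality risk increase is 1.23%
    assert (m.rr_central - 1) * 100 == pytest.approx(1.23)


def test_endpoint_rejects_disordered_ci():
    with pytest.raises(InvalidParameterError):
        HealthEndpoint("bad", 1.01, 1.02, 1.03)


def _exposure(districts, days, dx):
    rows = [
        {"district_id": d, "date": pd.Timestamp("2019-11-01") + pd.Timedelta(days=k), "delta_x": dx}
        for d in districts
        for k in range(days)
    ]
    return pd.DataFrame(rows)


def test_endpoint_series_closed_form_single_district():
    # (1.03 - 1) x 100000 x 1e-4 = 0.30 per day; bounds 0.10 and 0.40
    exposure = _exposure(["A"], 1, 10.0)
    pop = pd.DataFrame({"district_id": ["A"], "population": [100_000]})
    rates = pd.DataFrame({"district_id": ["A"], "endpoint": ["resp"], "rate": [0.0365]})
    ep = HealthEndpoint("resp", 1.03, 1.01, 1.04)
    an = compute_endpoint_series(exposure, pop, rates, ep)
    assert an["an_central"].iloc[0] == pytest.approx(0.30, rel=1e-9)
    assert an["an_low"].iloc[0] == pytest.approx(0.10, rel=1e-9)
    assert an["an_high"].iloc[0] == pytest.approx(0.40, rel=1e-9)


def test_endpoint_series_zero_exposure_gives_zero_an():
    exposure = _exposure(["A", "B"], 3, 0.0)
    pop = pd.DataFrame({"district_id": ["A", "B"], "population": [1e5, 2e5]})
    rates = pd.DataFrame(
        {"district_id": ["A", "B"], "endpoint": ["mortality"] * 2, "rate": [0.01, 0.02]}
    )
    an = compute_endpoint_series(exposure, pop, rates, DEFAULT_ENDPOINTS["mortality"])
    assert (an[["an_central", "an_low", "an_high"]].to_numpy() == 0).all()


def test_endpoint_series_ci_ordering_random_exposures():
    rng = np.random.default_rng(42)
    districts = [f"D{k}" for k in range(10)]
    exposure = _exposure(districts, 5, 0.0)
    exposure["delta_x"] = rng.uniform(0, 500, size=len(exposure))
    pop = pd.DataFrame({"district_id": districts, "population": rng.integers(1e4, 1e6, 10)})
    rates = pd.DataFrame(
        {"district_id": districts, "endpoint": "cvd_hosp", "rate": rng.uniform(0.01, 0.05, 10)}
    )
    an = compute_endpoint_series(exposure, pop, rates, DEFAULT_ENDPOINTS["cvd_hosp"])
    assert (an["an_low"] <= an["an_central"] + 1e-15).all()
    assert (an["an_central"] <= an["an_high"] + 1e-15).all()
    assert (an["an_low"] >= 0).all()


def test_endpoint_series_missing_rate_names_district():
    exposure = _exposure(["A", "B"], 1, 10.0)
    pop = pd.DataFrame({"district_id": ["A", "B"], "population": [1e5, 1e5]})
    rates = pd.DataFrame({"district_id": ["A"], "endpoint": ["mortality"], "rate": [0.01]})
    with pytest.raises(MissingDataError, match="'B'"):
        compute_endpoint_series(exposure, pop, rates, DEFAULT_ENDPOINTS["mortality"])
    # domain_mean fill policy makes it computable
    an = compute_endpoint_series(
        exposure, pop, rates, DEFAULT_ENDPOINTS["mortality"], fill="domain_mean"
    )
    a, b = an.set_index("district_id")["an_central"].loc[["A", "B"]]
    assert b == pytest.approx(a)  # B filled with the only available rate


def test_aggregate_conservation():
    rng = np.random.default_rng(7)
    districts = [f"D{k}" for k in range(6)]
    exposure = _exposure(districts, 4, 0.0)
    exposure["delta_x"] = rng.uniform(0, 300, len(exposure))
    pop = pd.DataFrame({"district_id": districts, "population": rng.integers(1e4, 1e6, 6)})
    rates = pd.DataFrame(
        {"district_id": districts, "endpoint": "mortality", "rate": rng.uniform(0.005, 0.01, 6)}
    )
    an = compute_endpoint_series(exposure, pop, rates, DEFAULT_ENDPOINTS["mortality"])
    total = aggregate_an(an, by="total")
    by_day = aggregate_an(an, by="day")
    by_district = aggregate_an(an, by="district")
    for col in ("an_central", "an_low", "an_high"):
        t = total[col].iloc[0]
        assert by_day[col].sum() == pytest.approx(t, rel=1e-12)
        assert by_district[col].sum() == pytest.approx(t, rel=1e-12)
        assert an[col].sum() == pytest.approx(t, rel=1e-12)


def test_aggregate_closed_form_constant_records():
    # D days x K districts of constant a sums to D*K*a
    D, K, a = 4, 3, 0.25
    rows = [
        {
            "district_id": f"D{k}", "date": f"2019-11-{d+1:02d}", "endpoint": "mortality",
            "an_central": a, "an_low": a / 2, "an_high": 2 * a,
        }
        for d in range(D)
        for k in range(K)
    ]
    total = aggregate_an(pd.DataFrame(rows), by="total")
    assert total["an_central"].iloc[0] == pytest.approx(D * K * a, rel=1e-12)


def test_aggregate_rejects_unknown_key_and_empty():
    df = pd.DataFrame(
        [{"district_id": "A", "date": "2019-11-01", "endpoint": "m",
          "an_central": 1.0, "an_low": 0.5, "an_high": 2.0}]
    )
    with pytest.raises(InvalidParameterError):
        aggregate_an(df, by="month")
    with pytest.raises(InvalidParameterError):
        aggregate_an(df.iloc[0:0], by="total")
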