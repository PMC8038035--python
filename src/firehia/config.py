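"""Run configuration: TOML loading and endpoint construction.

The default configuration carries the three bundled endpoints (HRAPIE
mortality and CVD, California-wildfire respiratory) and the default
methods (area-weighted zonal overlay, simple-mean rate projection,
three-year rate averaging).  A user TOML file overrides any subset.
"""

from __future__ import annotations

import tomllib
from copy import deepcopy
from pathlib import Path
from typing import Any, Dict

from firehia.hia import DEFAULT_ENDPOINTS, HealthEndpoint

#: which layer carries each endpoint's incidence rates
DEFAULT_RATE_LAYER = {
    "mortality": "districts",
    "cvd_hosp": "rate_regions",
    "resp_hosp": "rate_regions",
}

DEFAULT_CONFIG: Dict[str, Any] = {
    "scenario": {
        "n_days": 30,
        "n_districts": 28,
        "n_rate_regions": 60,
        "n_stations": 12,
        "noise_sd_fraction": 0.3,
    },
    "exposure": {"method": "area_weighted"},
    "rates": {"method": "simple_mean", "years": [2014, 2015, 2016]},
    "endpoints": {
        name: {
            "rr_central": ep.rr_central,
            "rr_low": ep.rr_low,
            "rr_high": ep.rr_high,
            "ref_increment": ep.ref_increment,
            "rate_layer": DEFAULT_RATE_LAYER[name],
        }
        for name, ep in DEFAULT_ENDPOINTS.items()
    },
}


def load_config(path: str | Path | None = None) -> Dict[str, Any]:
    """Default configuration, with *path* (TOML) merged over it if given."""
    cfg = deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path, "rb") as fh:
            user = tomllib.load(fh)
        _deep_update(cfg, user)
    return cfg


def endpoints_from_config(cfg: Dict[str, Any]) -> Dict[str, HealthEndpoint]:
    """Build validated HealthEndpoint objects from a config dict."""
    out = {}
    for name, spec in cfg["endpoints"].items():
        out[name] = HealthEndpoint(
            name=name,
            rr_central=float(spec["rr_central"]),
            rr_low=float(spec["rr_low"]),
            rr_high=float(spec["rr_high"]),
            ref_increment=float(spec.get("ref_increment", 10.0)),
        )
    return out


def _deep_update(base: Dict[str, Any], patch: Dict[str, Any]) -> None:
    for key, value in patch.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value
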