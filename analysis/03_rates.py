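#!/usr/bin/env python
"""Average incidence rates over 2014-2016 and project hospitalization
rates from the rate-region layer onto the census districts (simple mean of
intersected regions; mortality rates are native to the district layer).

Reads results/run/rates.csv + both polygon layers; writes
results/run/rates_projected.csv.
"""

import logging

from firehia.config import load_config
from firehia.pipeline import stage_rates

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")

projected = stage_rates(load_config(), "results/run")
print(projected.groupby("endpoint")["rate"].describe()[["count", "min", "mean", "max"]])
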