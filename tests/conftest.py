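"""Shared fixtures: synthetic forcing records and spun-up stands.

Heavy fixtures are session-scoped so the multi-decade simulations behind
them run once per test session.
"""

import numpy as np
import pandas as pd
import pytest

import nscsim as ns

SITES = (ns.HIGH_SITE, ns.MID_SITE, ns.LOW_SITE)

# the default drought scenario: 23 water years with a 3-year severe drought
# (precipitation halved, +1 degC) in water years 15-17, i.e. inside the
# 16-year evaluation window that follows the 7-year lead-in
DROUGHT = ns.DroughtSpec(start_year=15, duration_years=3,
                         precip_multiplier=0.5, temp_offset_c=1.0)


@pytest.fixture(scope="session")
def met50():
    """50-year baseline station record (no drought block)."""
    return ns.generate_synthetic_forcing(50, seed=1)


@pytest.fixture(scope="session")
def spinup_states(met50):
    """Final carbon pools of a 100-year spinup for each gradient site."""
    return {s.name: ns.spinup(s, met50, years=100)[0] for s in SITES}


@pytest.fixture(scope="session")
def spinup_diags(met50):
    return {s.name: ns.spinup(s, met50, years=100)[1] for s in SITES}


@pytest.fixture(scope="session")
def drought23():
    """23-year station record containing the default drought block."""
    return ns.generate_synthetic_forcing(23, seed=2, drought=DROUGHT)


@pytest.fixture(scope="session")
def window_cells(spinup_states, drought23):
    """Default-parameter evaluation-window summaries for all three sites."""
    params = ns.NSCParams(nsc_npp_frac=0.3, minl_agc=0.05)
    cells = {}
    for site in SITES:
        met = ns.adjust_to_site(drought23, ns.STATION_ELEV_M, site)
        _, _, cell = ns.run_window(site, spinup_states[site.name].copy(),
                                   met, params)
        cells[site.name] = cell
    return cells
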