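"""Shared fixtures: packaged reference data and a balanced closed model."""

import numpy as np
import pytest

from spermca import CellState, ClosedModelParams, ReducedParams
from spermca.cli_io import fixtures


@pytest.fixture(scope="session")
def fit_table():
    """The 15 per-experiment dynamic fits as a DataFrame."""
    return fixtures.load_dynamic_fit_table()


@pytest.fixture(scope="session")
def mean_params(fit_table):
    # independent arithmetic oracle: plain column means of the fixture CSV
    return ReducedParams(
        *(float(fit_table[name].mean()) for name in ("p", "q", "r", "d", "g"))
    )


@pytest.fixture(scope="session")
def initial_params():
    return fixtures.load_initial_reduced_params()


@pytest.fixture(scope="session")
def cell():
    return fixtures.load_cell_fixture()


@pytest.fixture(scope="session")
def geometry(cell):
    return cell["geometry"]


@pytest.fixture(scope="session")
def ss_pre():
    return fixtures.load_steady_state_fixture("pre")


@pytest.fixture(scope="session")
def ss_post():
    return fixtures.load_steady_state_fixture("post")


@pytest.fixture(scope="session")
def dose_pre():
    return fixtures.load_dose_response_fixture("pre")


@pytest.fixture(scope="session")
def dose_post():
    return fixtures.load_dose_response_fixture("post")


@pytest.fixture(scope="session")
def resting_state(cell):
    ch = cell["characteristic"]
    return CellState(ca_cyt=ch["ca_cyt_ss_nM"], ca_ret=ch["ca_ret_nM"],
                     ca_ves=ch["ca_ves_nM"])


@pytest.fixture(scope="session")
def closed_params(cell, resting_state):
    """Closed model whose pumps exactly balance the leaks at rest."""
    geom = cell["geometry"]
    phys = cell["physical"]
    ch = cell["characteristic"]
    sat = ch["atp_mM"] / (phys.km_atp + ch["atp_mM"])
    leak_ret = phys.p_leak1 * geom.a_ret * (resting_state.ca_ret - resting_state.ca_cyt)
    leak_ves = phys.p_leak2 * geom.a_ves * (resting_state.ca_ves - resting_state.ca_cyt)
    quad = resting_state.ca_cyt ** 2 * sat
    return ClosedModelParams(
        geom=geom,
        p_leak_ret=phys.p_leak1,
        p_leak_ves=phys.p_leak2,
        pump_rate_ret=leak_ret / quad,
        pump_rate_ves=leak_ves / quad,
        atp_mM=ch["atp_mM"],
        km_atp_mM=phys.km_atp,
        serca_active=True,
    )
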