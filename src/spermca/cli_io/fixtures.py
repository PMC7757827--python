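"""Packaged reference fixtures.

The published per-experiment dynamic fit constants, the two
dose-response tables, the two steady-state parameter sets (and the
common starting values of their fit), the initial dynamic constants, and
the cell geometry / physical constants.  Values are stored exactly as
printed in the source tables and parsed to floats at load time.
"""

from __future__ import annotations

import json
from importlib.resources import files

import pandas as pd

from spermca.cli_io import io as _io
from spermca.model_core import CellGeometry, PhysicalParams, ReducedParams
from spermca.steady_state import LactateResponse, SteadyStateParams

__all__ = [
    "load_dynamic_fit_table",
    "load_dynamic_fit_params",
    "load_initial_reduced_params",
    "load_dose_response_fixture",
    "load_steady_state_fixture",
    "load_cell_fixture",
]

_DATA = files("spermca.cli_io") / "data"


def _data_path(name: str):
    return _DATA / name


def load_dynamic_fit_table() -> pd.DataFrame:
    """The 15 per-experiment dynamic fits as a DataFrame.

    Columns: experiment, p, q, r, d, g, r2.
    """
    with _data_path("dynamic_fits.csv").open(encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_dynamic_fit_params() -> list:
    """The 15 per-experiment fits as :class:`ReducedParams` objects."""
    frame = load_dynamic_fit_table()
    return [
        ReducedParams(p=row.p, q=row.q, r=row.r, d=row.d, g=row.g)
        for row in frame.itertuples()
    ]


def load_initial_reduced_params() -> ReducedParams:
    """The common starting values used for every dynamic fit."""
    with _data_path("reduced_init.json").open(encoding="utf-8") as fh:
        return ReducedParams.from_dict(json.load(fh))


def load_dose_response_fixture(condition: str) -> LactateResponse:
    """The measured dose-response table; ``condition`` is 'pre' or 'post'."""
    if condition not in ("pre", "post"):
        raise ValueError("condition must be 'pre' or 'post'")
    path = _data_path(f"dose_response_{condition}.csv")
    with path.open(encoding="utf-8") as fh:
        frame = pd.read_csv(fh)
    return LactateResponse(
        frame["lactate_mM"].to_numpy(float),
        frame["ca_ss_nM"].to_numpy(float),
        sem=frame["sem_nM"].to_numpy(float),
    )


def load_steady_state_fixture(condition: str) -> SteadyStateParams:
    """Fitted steady-state constants; 'pre', 'post' or 'init'."""
    if condition not in ("pre", "post", "init"):
        raise ValueError("condition must be 'pre', 'post' or 'init'")
    with _data_path(f"steady_state_{condition}.json").open(encoding="utf-8") as fh:
        return SteadyStateParams.from_dict(json.load(fh))


def load_cell_fixture() -> dict:
    """Cell geometry, physical constants and characteristic values.

    Returns a dict with keys ``geometry`` (:class:`CellGeometry`),
    ``physical`` (:class:`PhysicalParams`) and ``characteristic``
    (plain dict of nM / mM reference values).
    """
    with _data_path("cell.json").open(encoding="utf-8") as fh:
        raw = json.load(fh)
    return {
        "geometry": CellGeometry(**raw["geometry"]),
        "physical": PhysicalParams(**raw["physical"]),
        "characteristic": raw["characteristic"],
    }
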