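"""Compartment models of cytosolic Ca2+ handling in round spermatids.

Two model layers live here:

* a *closed* three-compartment model (cytosol, endoplasmic reticulum,
  acidic vesicles) in which leak fluxes follow concentration gradients
  and both Ca2+-ATPase pumps remove cytosolic Ca2+ with a quadratic
  concentration dependence scaled by ATP Michaelis saturation; total
  cell calcium is conserved by construction, and
* a *reduced* two-variable system describing the cytosol/ER pair once
  the ER pump has been blocked::

      d[Ca]cyt/dt = p - q*[Ca]cyt + r*[Ca]ret - d*[Ca]cyt**2
      d[Ca]ret/dt = g*([Ca]cyt - [Ca]ret)

Units are fixed package-wide: free concentrations in nM, time in s,
volumes in dm^3, membrane areas in dm^2, permeabilities in dm/s, ATP in
mM.  Converters exist only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "IntegrationError",
    "PARAM_NAMES",
    "ReducedParams",
    "CellGeometry",
    "PhysicalParams",
    "CellState",
    "CalciumTrace",
    "ClosedModelParams",
    "reduced_rhs",
    "simulate_reduced",
    "reduced_steady_state",
    "total_calcium",
    "ves_from_conservation",
    "map_physical_to_reduced",
    "closed_rhs",
    "simulate_closed",
]

#: Canonical ordering of the reduced dynamic constants.
PARAM_NAMES = ("p", "q", "r", "d", "g")


class IntegrationError(RuntimeError):
    """Adaptive integration failed (step-size underflow or similar).

    Attributes
    ----------
    t_fail : float or None
        Time at which the integrator gave up, when known.
    """

    def __init__(self, message: str, t_fail: Optional[float] = None):
        super().__init__(message)
        self.t_fail = t_fail


def _check_positive(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be finite and > 0, got {value!r}")


def _check_nonnegative(name: str, value: float) -> None:
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class ReducedParams:
    """Phenomenological constants of the reduced cytosol/ER system.

    Parameters
    ----------
    p : float
        Constant production term, nM/s.
    q : float
        Linear cytosolic removal rate, 1/s.
    r : float
        ER-to-cytosol transfer rate, 1/s.
    d : float
        Quadratic (pump-mediated) removal coefficient, 1/(nM s).
    g : float
        Cytosol/ER equilibration rate, 1/s.

    All constants must be nonnegative; ``d > 0`` is additionally required
    for a finite positive steady state.
    """

    p: float
    q: float
    r: float
    d: float
    g: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            _check_nonnegative(name, getattr(self, name))

    def as_array(self) -> np.ndarray:
        return np.array([self.p, self.q, self.r, self.d, self.g], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "ReducedParams":
        values = np.asarray(values, dtype=float)
        if values.shape != (5,):
            raise ValueError(f"expected 5 parameters, got shape {values.shape}")
        return cls(*values)

    def to_dict(self) -> dict:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    @classmethod
    def from_dict(cls, mapping: dict) -> "ReducedParams":
        return cls(**{name: float(mapping[name]) for name in PARAM_NAMES})


@dataclass(frozen=True)
class CellGeometry:
    """Compartment volumes, membrane areas and free-Ca fractions."""

    vol_cyt: float  # dm^3
    vol_ret: float  # dm^3
    vol_ves: float  # dm^3
    a_ret: float    # dm^2
    a_ves: float    # dm^2
    f_cyt: float
    f_ret: float
    f_ves: float

    def __post_init__(self) -> None:
        for name in ("vol_cyt", "vol_ret", "vol_ves", "a_ret", "a_ves"):
            _check_positive(name, getattr(self, name))
        for name in ("f_cyt", "f_ret", "f_ves"):
            value = getattr(self, name)
            if not np.isfinite(value) or not (0 < value <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {value!r}")


@dataclass(frozen=True)
class PhysicalParams:
    """Membrane permeabilities and composite pump constants.

    ``alpha``, ``beta``, ``k2_atpase_ret`` and ``k2p_k1p_atpase_ves`` are
    opaque composite constants supplied by the user; they are never
    derived here.
    """

    p_leak1: float          # ER leak permeability, dm/s
    p_leak2: float          # vesicular leak permeability, dm/s
    alpha: float            # opaque composite constant
    beta: float             # opaque composite constant
    k3_prime: float         # AV-pump rate constant
    k2_atpase_ret: float    # ER-pump composite rate
    k2p_k1p_atpase_ves: float  # AV-pump composite rate
    km_atp: float           # pump ATP affinity, mM

    def __post_init__(self) -> None:
        _check_nonnegative("p_leak1", self.p_leak1)
        _check_nonnegative("p_leak2", self.p_leak2)
        _check_positive("km_atp", self.km_atp)


@dataclass(frozen=True)
class CellState:
    """Free Ca2+ concentrations of the three compartments, nM."""

    ca_cyt: float
    ca_ret: float
    ca_ves: float

    def __post_init__(self) -> None:
        for name in ("ca_cyt", "ca_ret", "ca_ves"):
            _check_nonnegative(name, getattr(self, name))

    def as_array(self) -> np.ndarray:
        return np.array([self.ca_cyt, self.ca_ret, self.ca_ves], dtype=float)


@dataclass(frozen=True)
class CalciumTrace:
    """A timestamped cytosolic Ca2+ record.

    Parameters
    ----------
    t : array_like
        Strictly increasing sample times, s.
    ca_cyt : array_like
        Cytosolic free Ca2+ at each time, nM, nonnegative.
    thapsigargin_time : float, optional
        Time at which the ER pump blocker was added, if any.
    """

    t: np.ndarray
    ca_cyt: np.ndarray
    thapsigargin_time: Optional[float] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        ca = np.asarray(self.ca_cyt, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "ca_cyt", ca)
        if t.ndim != 1 or ca.ndim != 1 or len(t) != len(ca):
            raise ValueError("t and ca_cyt must be 1-D arrays of equal length")
        if len(t) < 2:
            raise ValueError("a trace needs at least 2 samples")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(ca))):
            raise ValueError("trace contains non-finite values")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(ca < 0):
            raise ValueError("ca_cyt must be nonnegative")

    def __len__(self) -> int:
        return len(self.t)

    def post_thapsigargin(self) -> "CalciumTrace":
        """Restrict the record to times at/after the blocker addition.

        Returns the trace unchanged when no event time is set.
        """
        if self.thapsigargin_time is None:
            return self
        mask = self.t >= self.thapsigargin_time
        if mask.sum() < 2:
            raise ValueError("fewer than 2 samples after thapsigargin_time")
        return CalciumTrace(self.t[mask], self.ca_cyt[mask],
                            thapsigargin_time=self.thapsigargin_time)


def reduced_rhs(state, params: ReducedParams):
    """Right-hand side of the reduced cytosol/ER system.

    Parameters
    ----------
    state : (float, float)
        ``(ca_cyt, ca_ret)`` in nM; both must be nonnegative.
    params : ReducedParams

    Returns
    -------
    (float, float)
        ``(d ca_cyt/dt, d ca_ret/dt)`` in nM/s.
    """
    ca_cyt, ca_ret = float(state[0]), float(state[1])
    if ca_cyt < 0 or ca_ret < 0:
        raise ValueError("state components must be nonnegative")
    dcyt = params.p - params.q * ca_cyt + params.r * ca_ret - params.d * ca_cyt ** 2
    dret = params.g * (ca_cyt - ca_ret)
    return (dcyt, dret)


def _reduced_rhs_raw(t, y, p, q, r, d, g):
    # unchecked form for the integrator (tiny negative excursions allowed)
    return (p - q * y[0] + r * y[1] - d * y[0] * y[0], g * (y[0] - y[1]))


def simulate_reduced(
    params: ReducedParams,
    ic,
    t_grid,
    rel_tol: float = 1e-8,
    abs_tol: float = 1e-3,
) -> np.ndarray:
    """Integrate the reduced system on a given time grid.

    Uses an adaptive explicit Runge-Kutta 4(5) pair.

    Parameters
    ----------
    params : ReducedParams
    ic : (float, float)
        Initial ``(ca_cyt, ca_ret)`` at ``t_grid[0]``, nM.
    t_grid : array_like
        Strictly increasing evaluation times, s.
    rel_tol, abs_tol : float
        Integrator tolerances (abs_tol in nM); both must be positive.

    Returns
    -------
    ndarray of shape (len(t_grid), 2)
        Columns ``(ca_cyt, ca_ret)``; the first row equals ``ic`` exactly.

    Raises
    ------
    IntegrationError
        If the adaptive integrator fails; the message carries the time
        reached before the failure.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 1:
        raise ValueError("t_grid must be a 1-D array with at least one time")
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if rel_tol <= 0 or abs_tol <= 0:
        raise ValueError("tolerances must be positive")
    ic = (float(ic[0]), float(ic[1]))
    sol = solve_ivp(
        _reduced_rhs_raw,
        (t[0], t[-1]),
        ic,
        method="RK45",
        t_eval=t,
        rtol=rel_tol,
        atol=abs_tol,
        args=params.as_array().tolist(),
    )
    if not sol.success:
        t_fail = float(sol.t[-1]) if len(sol.t) else float(t[0])
        raise IntegrationError(
            f"integration failed near t={t_fail:.6g} s: {sol.message}", t_fail
        )
    out = sol.y.T.copy()
    out[0] = ic
    return out


def reduced_steady_state(params: ReducedParams) -> float:
    """Analytic steady-state cytosolic concentration of the reduced system.

    At the fixed point both compartments equalize and the concentration
    solves ``d*x**2 - (r - q)*x - p = 0``; the unique nonnegative root is
    returned.

    Raises
    ------
    ValueError
        If ``d <= 0`` (no finite positive steady state when ``p > 0``).
    """
    if params.d <= 0:
        raise ValueError("d must be > 0 for a finite steady state")
    rq = params.r - params.q
    disc = rq * rq + 4.0 * params.d * params.p
    return (rq + np.sqrt(disc)) / (2.0 * params.d)


def total_calcium(state: CellState, geom: CellGeometry) -> float:
    """Total cell calcium implied by the free concentrations.

    Each free concentration is converted to total compartment calcium by
    ``ca * vol / f`` (division by the free fraction) and the three
    compartments are summed.  Units: nmol when concentrations are nM and
    volumes dm^3.
    """
    return (
        state.ca_cyt * geom.vol_cyt / geom.f_cyt
        + state.ca_ret * geom.vol_ret / geom.f_ret
        + state.ca_ves * geom.vol_ves / geom.f_ves
    )


def ves_from_conservation(
    total: float, ca_cyt: float, ca_ret: float, geom: CellGeometry
) -> float:
    """Vesicular concentration implied by conservation of total calcium.

    Inverts :func:`total_calcium` for the vesicular compartment.

    Raises
    ------
    ValueError
        If the implied concentration is negative (inconsistent inputs).
    """
    residual = (
        total
        - ca_cyt * geom.vol_cyt / geom.f_cyt
        - ca_ret * geom.vol_ret / geom.f_ret
    )
    ca_ves = residual * geom.f_ves / geom.vol_ves
    if ca_ves < 0:
        scale = abs(total) * geom.f_ves / geom.vol_ves + 1e-300
        if abs(ca_ves) > 1e-9 * scale:
            raise ValueError(
                f"inconsistent inputs: implied ca_ves = {ca_ves:.6g} nM < 0"
            )
        ca_ves = 0.0
    return ca_ves


def map_physical_to_reduced(
    geom: CellGeometry, phys: PhysicalParams, a_total: float
) -> ReducedParams:
    """Compose the reduced constants from physical cell constants.

    Only the composition of ``g`` — ER leak permeability x ER area x ER
    free fraction / ER volume — is fully pinned by the printed groupings;
    the remaining compositions follow the same permeability-area-fraction
    / volume pattern with the opaque composite factors ``alpha``,
    ``beta`` and ``a_total`` entering multiplicatively.  All terms vanish
    with the permeabilities except ``d``, which depends only on
    ``k3_prime``.
    """
    fc_vc = geom.f_cyt / geom.vol_cyt
    leak2 = phys.p_leak2 * geom.a_ves
    leak1 = phys.p_leak1 * geom.a_ret
    p = phys.alpha * a_total * leak2 * fc_vc
    q = phys.alpha * leak2 * (phys.beta * geom.f_ves / geom.vol_ves + fc_vc) \
        + leak1 * fc_vc
    r = leak1 * fc_vc - (
        phys.alpha * phys.beta * leak2
        * (geom.vol_ret * geom.f_ret) / (geom.f_ves * geom.vol_ves)
        * fc_vc
    )
    d = fc_vc * phys.k3_prime
    g = phys.p_leak1 * geom.a_ret * geom.f_ret / geom.vol_ret
    return ReducedParams(p=p, q=max(q, 0.0), r=max(r, 0.0), d=d, g=g)


# ---------------------------------------------------------------------------
# Closed three-compartment model


@dataclass(frozen=True)
class ClosedModelParams:
    """Constants of the closed three-compartment model.

    Leak fluxes are ``P * A * ([Ca]_store - [Ca]_cyt)`` (nmol/s); pump
    fluxes are ``k * [Ca]_cyt**2 * [ATP]/(Km + [ATP])``.  ``serca_active``
    toggles the ER pump (False once the blocker has been applied).
    """

    geom: CellGeometry
    p_leak_ret: float   # dm/s
    p_leak_ves: float   # dm/s
    pump_rate_ret: float  # nmol/s/nM^2
    pump_rate_ves: float  # nmol/s/nM^2
    atp_mM: float
    km_atp_mM: float
    serca_active: bool = True

    def __post_init__(self) -> None:
        for name in ("p_leak_ret", "p_leak_ves", "pump_rate_ret", "pump_rate_ves"):
            _check_nonnegative(name, getattr(self, name))
        _check_nonnegative("atp_mM", self.atp_mM)
        _check_positive("km_atp_mM", self.km_atp_mM)

    @property
    def atp_saturation(self) -> float:
        return self.atp_mM / (self.km_atp_mM + self.atp_mM)


def closed_fluxes(state, params: ClosedModelParams) -> dict:
    """Individual fluxes (nmol/s) at a given state.

    Keys: ``j_pump_ret``, ``j_pump_ves`` (cytosol into stores),
    ``j_leak_ret``, ``j_leak_ves`` (stores into cytosol).
    """
    ca_cyt, ca_ret, ca_ves = state
    geom = params.geom
    sat = params.atp_saturation
    j1 = params.pump_rate_ret * ca_cyt ** 2 * sat if params.serca_active else 0.0
    j2 = params.pump_rate_ves * ca_cyt ** 2 * sat
    j3 = params.p_leak_ret * geom.a_ret * (ca_ret - ca_cyt)
    j4 = params.p_leak_ves * geom.a_ves * (ca_ves - ca_cyt)
    return {"j_pump_ret": j1, "j_pump_ves": j2, "j_leak_ret": j3, "j_leak_ves": j4}


def closed_rhs(state, params: ClosedModelParams):
    """Time derivatives of the three free concentrations (nM/s).

    Net amount fluxes sum to zero across compartments, so the total
    calcium of :func:`total_calcium` is a conserved quantity.
    """
    fluxes = closed_fluxes(state, params)
    geom = params.geom
    net_cyt = (-fluxes["j_pump_ret"] - fluxes["j_pump_ves"]
               + fluxes["j_leak_ret"] + fluxes["j_leak_ves"])
    net_ret = fluxes["j_pump_ret"] - fluxes["j_leak_ret"]
    net_ves = fluxes["j_pump_ves"] - fluxes["j_leak_ves"]
    return (
        geom.f_cyt / geom.vol_cyt * net_cyt,
        geom.f_ret / geom.vol_ret * net_ret,
        geom.f_ves / geom.vol_ves * net_ves,
    )


def simulate_closed(
    params: ClosedModelParams,
    state0: CellState,
    t_grid,
    rel_tol: float = 1e-9,
    abs_tol: float = 1e-6,
) -> np.ndarray:
    """Integrate the closed model; returns shape ``(len(t_grid), 3)``."""
    t = np.asarray(t_grid, dtype=float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    sol = solve_ivp(
        lambda tt, y: closed_rhs(y, params),
        (t[0], t[-1]),
        state0.as_array(),
        method="RK45",
        t_eval=t,
        rtol=rel_tol,
        atol=abs_tol,
    )
    if not sol.success:
        t_fail = float(sol.t[-1]) if len(sol.t) else float(t[0])
        raise IntegrationError(
            f"integration failed near t={t_fail:.6g} s: {sol.message}", t_fail
        )
    out = sol.y.T.copy()
    out[0] = state0.as_array()
    return out
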