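"""Lactate-modulated steady states of cytosolic Ca2+.

Extracellular lactate feeds ATP synthesis through a saturable
transporter; ATP in turn scales pump activity through Michaelis
saturation.  At steady state the cytosolic concentration solves a
quadratic whose pump coefficient differs between the blocked
(``with_thapsigargin``) and unblocked conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "SS_PARAM_NAMES",
    "ATPModelParams",
    "SteadyStateParams",
    "LactateResponse",
    "atp_steady_state",
    "lactate_saturation",
    "ca_steady_state",
    "predict_curve",
    "compare_conditions",
]

#: Canonical ordering of the steady-state fit constants.
SS_PARAM_NAMES = ("delta", "phi", "omega", "k_l", "b")


@dataclass(frozen=True)
class ATPModelParams:
    """Constants of the lactate-driven ATP balance.

    ``d[ATP]/dt = nu + gamma*L/(k_l + L) - k*[ATP]``.
    """

    nu: float      # constitutive synthesis rate, mM/s
    gamma: float   # maximal lactate-driven synthesis rate, mM/s
    k: float       # first-order hydrolysis constant, 1/s
    k_l: float     # lactate transporter affinity, mM
    km_atp: float  # pump ATP affinity, mM

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.k_l <= 0:
            raise ValueError("k_l must be > 0")
        if self.nu < 0 or self.gamma < 0:
            raise ValueError("nu and gamma must be >= 0")
        if self.km_atp <= 0:
            raise ValueError("km_atp must be > 0")

    def to_saturation_params(self) -> tuple:
        """Composite ``(phi, omega, k_l)`` identified by steady-state data."""
        return (self.nu / (self.k * self.km_atp),
                self.gamma / (self.k * self.km_atp),
                self.k_l)


@dataclass(frozen=True)
class SteadyStateParams:
    """Constants of the steady-state quadratic.

    ``delta`` is the pump coefficient (nM^-2): the AV pump alone when
    ``with_thapsigargin`` is true, ER + AV pumps otherwise.  ``b`` (nM^-1)
    collects the linear dynamic terms.
    """

    delta: float
    phi: float
    omega: float
    k_l: float
    b: float
    with_thapsigargin: bool = True

    def __post_init__(self) -> None:
        if not (np.isfinite(self.delta) and self.delta > 0):
            raise ValueError("delta must be > 0")
        if not (np.isfinite(self.k_l) and self.k_l > 0):
            raise ValueError("k_l must be > 0")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.phi < 0:
            raise ValueError("phi must be >= 0")
        if not np.isfinite(self.b):
            raise ValueError("b must be finite")

    def to_dict(self) -> dict:
        out = {name: float(getattr(self, name)) for name in SS_PARAM_NAMES}
        out["with_thapsigargin"] = bool(self.with_thapsigargin)
        return out

    @classmethod
    def from_dict(cls, mapping: dict) -> "SteadyStateParams":
        kwargs = {name: float(mapping[name]) for name in SS_PARAM_NAMES}
        kwargs["with_thapsigargin"] = bool(mapping.get("with_thapsigargin", True))
        return cls(**kwargs)

    def replace(self, **changes) -> "SteadyStateParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class LactateResponse:
    """Dose-response records of (lactate, steady-state cytosolic Ca2+)."""

    l: np.ndarray       # mM
    ca_ss: np.ndarray   # nM
    sem: Optional[np.ndarray] = None  # nM

    def __post_init__(self) -> None:
        l = np.asarray(self.l, dtype=float)
        ca = np.asarray(self.ca_ss, dtype=float)
        object.__setattr__(self, "l", l)
        object.__setattr__(self, "ca_ss", ca)
        if l.ndim != 1 or ca.ndim != 1 or len(l) != len(ca):
            raise ValueError("l and ca_ss must be 1-D arrays of equal length")
        if np.any(l < 0):
            raise ValueError("lactate concentrations must be >= 0")
        if np.any(ca <= 0):
            raise ValueError("ca_ss must be > 0")
        if len(np.unique(l)) != len(l):
            raise ValueError("lactate values must be unique")
        if self.sem is not None:
            sem = np.asarray(self.sem, dtype=float)
            if len(sem) != len(l):
                raise ValueError("sem length mismatch")
            object.__setattr__(self, "sem", sem)

    def __len__(self) -> int:
        return len(self.l)


def atp_steady_state(params: ATPModelParams, l: float) -> float:
    """Stationary ATP concentration at lactate ``l`` (mM).

    ``[ATP] = nu/k + (gamma/k) * L/(k_l + L)``; monotone nondecreasing
    in ``l``.
    """
    if np.any(np.asarray(l) < 0):
        raise ValueError("l must be >= 0")
    return params.nu / params.k + (params.gamma / params.k) * l / (params.k_l + l)


def lactate_saturation(phi: float, omega: float, k_l: float, l):
    """ATP Michaelis saturation expressed through the lactate composites.

    ``h(L) = (phi + omega*L/(k_l+L)) / (1 + phi + omega*L/(k_l+L))``;
    strictly within (0, 1) whenever ``phi + omega > 0``.
    """
    l = np.asarray(l, dtype=float)
    if np.any(l < 0):
        raise ValueError("l must be >= 0")
    s = phi + omega * l / (k_l + l)
    out = s / (1.0 + s)
    return float(out) if out.ndim == 0 else out


def ca_steady_state(params: SteadyStateParams, l: float):
    """Stationary cytosolic Ca2+ (nM) at lactate ``l`` (mM).

    Solves ``a*x**2 + b*x - 1 = 0`` with
    ``a = delta * h(L)`` and returns the unique positive root
    ``x = (-b + sqrt(b**2 + 4a)) / (2a)``.  Strictly decreasing in ``l``
    when ``omega > 0``.

    Raises
    ------
    ValueError
        If the quadratic coefficient ``a`` is not positive.
    """
    h = lactate_saturation(params.phi, params.omega, params.k_l, l)
    a = params.delta * np.asarray(h)
    if np.any(a <= 0):
        raise ValueError("delta * h(l) must be > 0 (is phi + omega zero?)")
    b = params.b
    x = (-b + np.sqrt(b * b + 4.0 * a)) / (2.0 * a)
    return float(x) if np.ndim(x) == 0 else x


def predict_curve(params: SteadyStateParams, l_values) -> np.ndarray:
    """Vectorized :func:`ca_steady_state` over an array of lactate values."""
    l_values = np.atleast_1d(np.asarray(l_values, dtype=float))
    return np.asarray([ca_steady_state(params, l) for l in l_values])


def compare_conditions(pre: SteadyStateParams, post: SteadyStateParams) -> dict:
    """Condition-contrast summary of two fitted parameter sets.

    Parameters
    ----------
    pre : SteadyStateParams
        Fit without the pump blocker (``with_thapsigargin`` must be False).
    post : SteadyStateParams
        Fit with the pump blocker (``with_thapsigargin`` must be True).

    Returns
    -------
    dict
        ``pump_ratio`` — relative excess of the unblocked pump
        coefficient, ``(delta_pre - delta_post) / delta_post``;
        ``phi_change_fraction`` — ``(phi_pre - phi_post) / phi_pre``.
    """
    if pre.with_thapsigargin or not post.with_thapsigargin:
        raise ValueError("expected pre.with_thapsigargin=False and "
                         "post.with_thapsigargin=True")
    if post.delta <= 0:
        raise ValueError("post delta must be > 0")
    if pre.phi <= 0:
        raise ValueError("pre phi must be > 0 for a relative change")
    return {
        "pump_ratio": (pre.delta - post.delta) / post.delta,
        "phi_change_fraction": (pre.phi - post.phi) / pre.phi,
    }
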