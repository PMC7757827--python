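"""Synthetic experiment generators.

Stand-ins for unreleased fluorometric records: noisy post-blocker
cytosolic Ca2+ traces, cohorts of experiments with log-normally
dispersed rate constants, and noisy dose-response tables — each
deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from spermca.model_core import CalciumTrace, ReducedParams, simulate_reduced
from spermca.steady_state import LactateResponse, SteadyStateParams, predict_curve

__all__ = [
    "TraceGenSpec",
    "CohortGenSpec",
    "generate_trace",
    "draw_cohort_params",
    "generate_cohort",
    "generate_lactate_dataset",
    "peak_cytosolic",
]


@dataclass(frozen=True)
class TraceGenSpec:
    """Recipe for one synthetic post-blocker trace."""

    params: ReducedParams
    ca_cyt0: float = 30.0       # nM
    ca_ret0: float = 60000.0    # nM
    duration: float = 1800.0    # s
    dt: float = 3.0             # s
    noise_sd: float = 10.0      # nM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.ca_cyt0 < 0 or self.ca_ret0 < 0:
            raise ValueError("initial concentrations must be >= 0")

    def time_grid(self) -> np.ndarray:
        return np.arange(0.0, self.duration + self.dt / 2.0, self.dt)


@dataclass(frozen=True)
class CohortGenSpec:
    """Recipe for a cohort of experiments with dispersed rate constants.

    ``cv_percent`` maps parameter names to coefficients of variation (in
    percent) of the per-experiment log-normal draws around ``central``;
    omitted names get 0 (no dispersion).
    """

    n_experiments: int
    central: ReducedParams
    cv_percent: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0
    ca_cyt0: float = 30.0
    ca_ret0: float = 60000.0
    duration: float = 1800.0
    dt: float = 3.0
    noise_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be >= 1")
        for name, cv in dict(self.cv_percent).items():
            if cv < 0:
                raise ValueError(f"cv_percent[{name!r}] must be >= 0")


def generate_trace(spec: TraceGenSpec) -> CalciumTrace:
    """Simulate one trace on a uniform grid and add observation noise.

    Gaussian noise of sd ``noise_sd`` is added i.i.d. per sample and the
    result clipped at zero; the blocker event time is 0 (the generator
    covers the post-addition segment only).  Deterministic given
    ``spec.seed``.
    """
    t = spec.time_grid()
    traj = simulate_reduced(spec.params, (spec.ca_cyt0, spec.ca_ret0), t)
    ca = traj[:, 0]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        ca = ca + rng.normal(0.0, spec.noise_sd, size=len(t))
    return CalciumTrace(t, np.clip(ca, 0.0, None), thapsigargin_time=0.0)


def draw_cohort_params(spec: CohortGenSpec) -> list:
    """Draw the per-experiment rate constants of a cohort.

    Each constant with a nonzero CV% is drawn log-normally with mean
    exactly the central value and sd = cv/100 * mean (the log-normal
    ``mu``/``sigma`` are solved from those moments); zero-CV constants
    are copied.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    cv = dict(spec.cv_percent)
    out = []
    for _ in range(spec.n_experiments):
        values = {}
        for name in ("p", "q", "r", "d", "g"):
            central = getattr(spec.central, name)
            c = cv.get(name, 0.0) / 100.0
            if c == 0.0 or central == 0.0:
                values[name] = central
            else:
                sigma2 = np.log1p(c * c)
                mu = np.log(central) - sigma2 / 2.0
                values[name] = float(rng.lognormal(mu, np.sqrt(sigma2)))
        out.append(ReducedParams(**values))
    return out


def generate_cohort(spec: CohortGenSpec) -> list:
    """Generate ``(true_params, trace)`` pairs for a cohort.

    Parameter draws and per-trace noise seeds all derive from
    ``spec.seed``, so the whole cohort is reproducible.
    """
    params_list = draw_cohort_params(spec)
    seed_rng = np.random.default_rng(spec.seed + 1)
    cohort = []
    for params in params_list:
        trace_spec = TraceGenSpec(
            params=params,
            ca_cyt0=spec.ca_cyt0,
            ca_ret0=spec.ca_ret0,
            duration=spec.duration,
            dt=spec.dt,
            noise_sd=spec.noise_sd,
            seed=int(seed_rng.integers(0, 2 ** 31 - 1)),
        )
        cohort.append((params, generate_trace(trace_spec)))
    return cohort


def generate_lactate_dataset(
    pre: SteadyStateParams,
    post: SteadyStateParams,
    l_values: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple:
    """Noisy dose-response tables for both conditions.

    Returns ``(pre_response, post_response)``; values are clipped to stay
    positive.  Deterministic given ``seed``.
    """
    l_values = np.asarray(l_values, dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    for params in (pre, post):
        values = predict_curve(params, l_values)
        if noise_sd > 0:
            values = values + rng.normal(0.0, noise_sd, size=len(l_values))
        out.append(LactateResponse(l_values, np.clip(values, 1e-9, None)))
    return tuple(out)


def peak_cytosolic(
    params: ReducedParams,
    ca_cyt0: float,
    ca_ret0: float,
    duration: float = 1800.0,
    dt: float = 1.0,
    rel_tol: float = 1e-10,
    abs_tol: float = 1e-6,
) -> float:
    """Noiseless peak cytosolic concentration on a fine grid (nM)."""
    t = np.arange(0.0, duration + dt / 2.0, dt)
    traj = simulate_reduced(params, (ca_cyt0, ca_ret0), t,
                            rel_tol=rel_tol, abs_tol=abs_tol)
    return float(traj[:, 0].max())
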