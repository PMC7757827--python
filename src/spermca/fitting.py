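"""Inference procedures: dynamic trace fits, exponential-decay
extrapolation, dose-response fits and cross-fit summary statistics.

All nonlinear minimization uses the Nelder-Mead simplex over
log-transformed parameters, which enforces positivity without explicit
constraints (mirroring an unconstrained simplex applied to
positive-valued rate constants).  A multiplicative step-halving
coordinate descent is available as an alternative for the dose-response
fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit, minimize

from spermca.model_core import (
    PARAM_NAMES,
    CalciumTrace,
    IntegrationError,
    ReducedParams,
    simulate_reduced,
)
from spermca.steady_state import (
    SS_PARAM_NAMES,
    LactateResponse,
    SteadyStateParams,
    predict_curve,
)

__all__ = [
    "FitResult",
    "ExpDecayFit",
    "SummaryTable",
    "INTEGRATION_FAILURE_PENALTY",
    "mse_objective",
    "fit_trace",
    "fit_exponential_decay",
    "fit_lactate_curve",
    "fit_lactate_two_stage",
    "r_squared",
    "summarize_fits",
]

#: Sentinel objective value returned when the integrator fails inside a
#: simplex evaluation, large enough that the simplex retreats but finite
#: so it can recover.
INTEGRATION_FAILURE_PENALTY = 1e12


@dataclass
class FitResult:
    """Outcome of a nonlinear fit."""

    params: object                 # ReducedParams or SteadyStateParams
    mse: float
    r2: float
    n_iter: int
    converged: bool
    fixed_names: tuple = ()
    ca_ret0: Optional[float] = None
    history: list = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "mse": float(self.mse),
            "r2": float(self.r2),
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
            "fixed_names": list(self.fixed_names),
            "ca_ret0": None if self.ca_ret0 is None else float(self.ca_ret0),
        }


@dataclass
class ExpDecayFit:
    """Exponential-decay extrapolation ``y = ca_ss + amplitude*exp(-rate*(t-t0))``."""

    ca_ss: float
    amplitude: float
    rate: float
    r2: float
    decaying: bool = True


@dataclass
class SummaryTable:
    """Per-parameter aggregates over a collection of fits.

    ``mean``, ``cv_percent`` (100*sd/mean with the n-1 sample standard
    deviation) and ``ratio_to_initial`` (mean / initial value), keyed by
    parameter name.
    """

    mean: dict
    cv_percent: dict
    ratio_to_initial: dict
    n: int

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "cv_percent": self.cv_percent,
            "ratio_to_initial": self.ratio_to_initial,
            "n": self.n,
        }


def r_squared(observed, predicted) -> float:
    """Coefficient of determination, ``1 - SS_res / SS_tot``.

    ``SS_tot`` is taken about the observed mean.  Raises on length
    mismatch, fewer than two points, or zero variance in ``observed``.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be 1-D of equal length")
    if len(obs) < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = np.sum((obs - obs.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("observed values have zero variance")
    ss_res = np.sum((obs - pred) ** 2)
    return float(1.0 - ss_res / ss_tot)


def mse_objective(
    params: ReducedParams,
    trace: CalciumTrace,
    ic_ret: float,
    rel_tol: float = 1e-6,
    abs_tol: float = 1e-2,
    penalty: float = INTEGRATION_FAILURE_PENALTY,
) -> float:
    """Mean squared residual between the model and an observed record.

    The record is restricted to times at/after the blocker addition; the
    model is integrated from ``(first observed ca_cyt, ic_ret)``.
    Integrator failures return ``penalty`` instead of raising, so a
    simplex search can back away from pathological parameter regions.
    """
    obs = trace.post_thapsigargin()
    try:
        traj = simulate_reduced(params, (obs.ca_cyt[0], ic_ret), obs.t,
                                rel_tol=rel_tol, abs_tol=abs_tol)
    except IntegrationError:
        return penalty
    resid = traj[:, 0] - obs.ca_cyt
    return float(np.mean(resid ** 2))


def _nelder_mead(objective, x0, max_iter, xatol, fatol):
    """Run Nelder-Mead with a best-objective history per iteration.

    Objective values are memoized so the per-iteration callback can look
    up the best vertex without re-evaluating the model.
    """
    cache: dict = {}

    def wrapped(x):
        key = x.tobytes()
        if key not in cache:
            cache[key] = objective(x)
        return cache[key]

    history: list = []

    def callback(xk):
        history.append(cache.get(xk.tobytes(), wrapped(xk)))

    res = minimize(
        wrapped,
        x0,
        method="Nelder-Mead",
        callback=callback,
        options={
            "maxiter": max_iter,
            "maxfev": 4 * max_iter,
            "xatol": xatol,
            "fatol": fatol,
            "adaptive": True,
        },
    )
    return res, history


def fit_trace(
    trace: CalciumTrace,
    init: ReducedParams,
    init_ca_ret: float = 60000.0,
    fit_initial_er: bool = True,
    fixed_names: Sequence[str] = (),
    max_iter: int = 5000,
    rel_tol: float = 1e-6,
    abs_tol: float = 1e-2,
    xatol: float = 1e-6,
    fatol: float = 1e-10,
) -> FitResult:
    """Fit the reduced dynamic constants to a post-blocker record.

    Minimizes :func:`mse_objective` over ``(p, q, r, d, g)`` — and the
    initial ER load when ``fit_initial_er`` — by Nelder-Mead on
    log-parameters.  Constants listed in ``fixed_names`` are held at
    their ``init`` values (useful for ``q``, whose contribution is
    dominated by the quadratic term and which trades off against ``p``
    on noisy records).  Requires at least 10 post-blocker observations.
    Non-convergence within ``max_iter`` is flagged on the result and the
    best parameters found are still returned.
    """
    obs = trace.post_thapsigargin()
    if len(obs) < 10:
        raise ValueError("need at least 10 post-thapsigargin observations")
    fixed_names = tuple(fixed_names)
    unknown = set(fixed_names) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter names: {sorted(unknown)}")
    free = [name for name in PARAM_NAMES if name not in fixed_names]
    if not free and not fit_initial_er:
        raise ValueError("nothing to fit: all parameters fixed")
    init_values = init.to_dict()
    free_init = np.array([init_values[name] for name in free], dtype=float)
    if np.any(free_init <= 0) or init_ca_ret <= 0:
        raise ValueError("log-parameterization requires strictly positive "
                         "initial parameter values")
    x0 = np.log(free_init)
    if fit_initial_er:
        x0 = np.append(x0, np.log(init_ca_ret))

    def assemble(x):
        values = dict(init_values)
        values.update(zip(free, np.exp(x[: len(free)])))
        params = ReducedParams.from_dict(values)
        icr = float(np.exp(x[-1])) if fit_initial_er else float(init_ca_ret)
        return params, icr

    def objective(x):
        params, icr = assemble(x)
        return mse_objective(params, obs, icr, rel_tol=rel_tol, abs_tol=abs_tol)

    res, history = _nelder_mead(objective, x0, max_iter, xatol, fatol)
    params, ca_ret0 = assemble(res.x)
    traj = simulate_reduced(params, (obs.ca_cyt[0], ca_ret0), obs.t,
                            rel_tol=rel_tol, abs_tol=abs_tol)
    r2 = r_squared(obs.ca_cyt, traj[:, 0])
    return FitResult(
        params=params,
        mse=float(res.fun),
        r2=r2,
        n_iter=int(res.nit),
        converged=bool(res.success),
        fixed_names=fixed_names,
        ca_ret0=ca_ret0,
        history=history,
    )


def fit_exponential_decay(trace: CalciumTrace, t_start: Optional[float] = None) -> ExpDecayFit:
    """Extrapolate the asymptote of a decaying record.

    Least-squares fit of ``y(t) = ca_ss + amplitude*exp(-rate*(t - t_start))``
    to the samples at/after ``t_start`` (default: the first sample).
    ``ca_ss`` is the extrapolated steady state.  Records that do not
    decay (``rate <= 0`` at the optimum) are returned with
    ``decaying=False``.
    """
    if t_start is None:
        t_start = float(trace.t[0])
    mask = trace.t >= t_start
    t = trace.t[mask]
    y = trace.ca_cyt[mask]
    if len(t) < 4:
        raise ValueError("need at least 4 samples after t_start")
    if np.ptp(y) == 0:
        return ExpDecayFit(ca_ss=float(y[0]), amplitude=0.0, rate=0.0,
                           r2=float("nan"), decaying=False)

    def model(tt, ca_ss, amplitude, rate):
        return ca_ss + amplitude * np.exp(-rate * (tt - t_start))

    span = t[-1] - t_start
    p0 = (float(y[-1]), float(y[0] - y[-1]), 2.0 / span if span > 0 else 1.0)
    popt, _ = curve_fit(model, t, y, p0=p0, maxfev=20000)
    ca_ss, amplitude, rate = (float(v) for v in popt)
    r2 = r_squared(y, model(t, *popt))
    return ExpDecayFit(ca_ss=ca_ss, amplitude=amplitude, rate=rate,
                       r2=r2, decaying=rate > 0)


def _ss_objective(data: LactateResponse):
    def objective_of(params: SteadyStateParams) -> float:
        pred = predict_curve(params, data.l)
        return float(np.mean((pred - data.ca_ss) ** 2))
    return objective_of


def _descending_step(objective, x0, max_iter):
    """Multiplicative step-halving coordinate descent on log-parameters.

    Each sweep tries scaling every coordinate up and down by the current
    factor, keeping improvements; the factor is halved (in log space)
    whenever a full sweep yields none.
    """
    x = x0.copy()
    fx = objective(x)
    step = math.log(2.0)
    history = [fx]
    n_iter = 0
    while step > 1e-10 and n_iter < max_iter:
        improved = False
        for i in range(len(x)):
            for sign in (+1.0, -1.0):
                trial = x.copy()
                trial[i] += sign * step
                f_trial = objective(trial)
                if f_trial < fx:
                    x, fx = trial, f_trial
                    improved = True
        n_iter += 1
        history.append(fx)
        if not improved:
            step *= 0.5
    return x, fx, n_iter, history


def fit_lactate_curve(
    data: LactateResponse,
    init: SteadyStateParams,
    fixed_names: Sequence[str] = (),
    max_iter: int = 5000,
    algorithm: str = "nelder-mead",
    xatol: float = 1e-9,
    fatol: float = 1e-12,
) -> FitResult:
    """Fit the steady-state quadratic constants to a dose-response table.

    Any subset of ``(delta, phi, omega, k_l, b)`` may be held fixed at
    its initial value via ``fixed_names``.  With everything fixed the
    result simply scores ``init`` (zero iterations).  ``algorithm`` is
    ``"nelder-mead"`` (default) or ``"descending-step"`` for the
    multiplicative coordinate-descent fallback.
    """
    fixed_names = tuple(fixed_names)
    unknown = set(fixed_names) - set(SS_PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter names: {sorted(unknown)}")
    free = [name for name in SS_PARAM_NAMES if name not in fixed_names]
    objective_of = _ss_objective(data)
    if not free:
        mse = objective_of(init)
        r2 = r_squared(data.ca_ss, predict_curve(init, data.l))
        return FitResult(params=init, mse=mse, r2=r2, n_iter=0,
                         converged=True, fixed_names=fixed_names)
    if len(data) < len(free):
        raise ValueError(
            f"{len(free)} free parameters but only {len(data)} data points"
        )
    init_free = np.array([getattr(init, name) for name in free], dtype=float)
    if np.any(init_free <= 0):
        raise ValueError("log-parameterization requires positive initial values "
                         "for all free parameters")

    def assemble(x):
        values = dict(zip(free, np.exp(x)))
        return init.replace(**values)

    def objective(x):
        try:
            return objective_of(assemble(x))
        except ValueError:
            return INTEGRATION_FAILURE_PENALTY

    x0 = np.log(init_free)
    if algorithm == "nelder-mead":
        res, history = _nelder_mead(objective, x0, max_iter, xatol, fatol)
        x_best, f_best, n_iter, converged = res.x, res.fun, res.nit, res.success
    elif algorithm == "descending-step":
        x_best, f_best, n_iter, history = _descending_step(objective, x0, max_iter)
        converged = n_iter < max_iter
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    params = assemble(x_best)
    r2 = r_squared(data.ca_ss, predict_curve(params, data.l))
    return FitResult(params=params, mse=float(f_best), r2=r2,
                     n_iter=int(n_iter), converged=bool(converged),
                     fixed_names=fixed_names, history=history)


def fit_lactate_two_stage(
    post_data: LactateResponse,
    pre_data: LactateResponse,
    init: SteadyStateParams,
    fixed_names: Sequence[str] = (),
    **kwargs,
) -> dict:
    """Canonical two-stage dose-response protocol.

    Stage 1 fits the with-blocker data over all constants not listed in
    ``fixed_names``; stage 2 fits only ``(delta, phi)`` to the
    without-blocker data, holding ``(omega, k_l, b)`` at their stage-1
    values and starting ``delta``/``phi`` from the stage-1 starting
    values.  Fixing ``(omega, k_l)`` in stage 1 is useful on short
    dose-response tables, where those two constants are only jointly
    identified.

    Returns ``{"post": FitResult, "pre": FitResult}``.
    """
    post_fit = fit_lactate_curve(
        post_data, init.replace(with_thapsigargin=True),
        fixed_names=tuple(fixed_names), **kwargs)
    stage1 = post_fit.params
    pre_init = init.replace(
        omega=stage1.omega, k_l=stage1.k_l, b=stage1.b,
        with_thapsigargin=False,
    )
    stage2_fixed = tuple(dict.fromkeys(("omega", "k_l", "b", *fixed_names)))
    pre_fit = fit_lactate_curve(
        pre_data, pre_init, fixed_names=stage2_fixed, **kwargs)
    return {"post": post_fit, "pre": pre_fit}


def summarize_fits(
    results: Sequence[ReducedParams],
    initial: ReducedParams,
) -> SummaryTable:
    """Aggregate a collection of per-experiment dynamic fits.

    Per parameter: arithmetic mean, CV% with the sample (n-1) standard
    deviation, and the mean-to-initial ratio.  A zero mean makes CV%
    undefined and is reported as NaN.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 result sets")
    matrix = np.array([r.as_array() for r in results], dtype=float)
    init_values = initial.as_array()
    means, cvs, ratios = {}, {}, {}
    for j, name in enumerate(PARAM_NAMES):
        column = matrix[:, j]
        mean = float(column.mean())
        means[name] = mean
        if mean == 0:
            cvs[name] = float("nan")
        else:
            cvs[name] = float(100.0 * column.std(ddof=1) / mean)
        ratios[name] = float(mean / init_values[j]) if init_values[j] != 0 else float("nan")
    return SummaryTable(mean=means, cv_percent=cvs, ratio_to_initial=ratios,
                        n=len(results))
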