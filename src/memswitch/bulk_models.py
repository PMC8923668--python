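"""Bulk (qPCR) mRNA-accumulation models and nonlinear regression.

The mean mRNA count per cell obeys

    dm/dt = production(t) - m / tau

with first-order degradation (lifetime tau, minutes).  Production is
either constant (P per cell), linearly increasing (a * t per cell), or
``n_loci * mean_production_rate(model, t)`` for the mechanistic promoter
models.  Fits follow the two-stage design used in practice: tau is
measured once from a transcription-shutoff decay series, then held
fixed while the accumulation parameters are fit by nonlinear least
squares.  All per-locus fits assume an average of six gene copies per
cell (tetraploid cells, half G1 / half G2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.integrate import solve_ivp

from .kinetics import (
    FAST_K_A,
    MODEL1,
    MODEL2,
    MEMORY_SWITCH,
    KineticParams,
    PromoterModelSpec,
    mean_production_rate,
)

__all__ = [
    "BULK_COLUMNS",
    "DegradationFit",
    "BulkFitResult",
    "mean_constant_production",
    "mean_linear_production",
    "mean_model_curve",
    "fit_degradation",
    "fit_accumulation",
    "accumulation_rate",
]

BULK_COLUMNS = ["condition", "induction", "time_min", "replicate",
                "mrna_per_cell"]

_TAU_UPPER = 1e6  # minutes; reported when the data do not decay


@dataclass
class DegradationFit:
    lifetime_tau: float
    m0: float
    ci95: dict[str, tuple[float, float]]
    warning: str | None = None


@dataclass
class BulkFitResult:
    model: str
    params: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    rss: float
    n_loci: int
    tau: float


# ---------------------------------------------------------------------
# Mean curves
# ---------------------------------------------------------------------

def mean_constant_production(P_cell: float, tau: float, m0: float, t):
    """m(t) for constant per-cell production P: relaxes to P*tau."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    t = np.asarray(t, dtype=float)
    decay = np.exp(-t / tau)
    return m0 * decay + P_cell * tau * (1.0 - decay)


def mean_linear_production(a_cell: float, tau: float, m0: float, t):
    """m(t) when per-cell production grows linearly, a * t."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    t = np.asarray(t, dtype=float)
    decay = np.exp(-t / tau)
    return m0 * decay + a_cell * tau * (t - tau * (1.0 - decay))


def mean_model_curve(
    spec: PromoterModelSpec,
    params: KineticParams,
    tau: float,
    n_loci: int,
    t_grid,
    m0: float = 0.0,
    f_M0: float = 0.0,
):
    """Numerically integrate dm/dt = n_loci * rate(t) - m/tau.

    ``f_M0`` is the memory fraction at t = 0 of the induction (carried
    over from earlier protocol segments).  Agrees with the closed forms
    where they exist.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        return np.empty(0)
    if np.any(t_grid < 0):
        raise ValueError("t_grid must be non-negative")
    # replicate-stacked series arrive unsorted with duplicates
    t_unique, inverse = np.unique(t_grid, return_inverse=True)
    t_end = float(t_unique[-1])

    def rhs(t, m):
        rate = mean_production_rate(spec, params, t, f_M0=f_M0)
        return n_loci * rate - m / tau

    sol = solve_ivp(
        rhs, (0.0, max(t_end, 1e-9)), [m0], t_eval=t_unique,
        rtol=1e-9, atol=1e-12, dense_output=False, method="RK45",
        max_step=max(t_end / 50.0, 1.0),
    )
    if not sol.success:
        raise RuntimeError(f"mean-curve integration failed: {sol.message}")
    return sol.y[0][inverse]


def model1_closed_form(
    k_A: float, k_pol: float, tau: float, n_loci: int, t, m0: float = 0.0
):
    """Analytic solution of the Model 1 mean curve (linear ODE)."""
    t = np.asarray(t, dtype=float)
    decay = np.exp(-t / tau)
    c = n_loci * k_pol
    out = m0 * decay + c * tau * (1.0 - decay)
    if k_A > 0:
        denom = 1.0 / tau - k_A
        if abs(denom) < 1e-12:
            out -= c * t * np.exp(-k_A * t)
        else:
            out -= c / denom * (np.exp(-k_A * t) - decay)
    return out


# ---------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------

def _ci95_from_cov(names, popt, pcov):
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    return {
        n: (p - 1.96 * s, p + 1.96 * s)
        for n, p, s in zip(names, popt, se)
    }


def fit_degradation(series: pd.DataFrame) -> DegradationFit:
    """Fit m0 * exp(-t/tau) to a transcription-shutoff time series.

    ``series`` needs columns time_min and mrna_per_cell (replicates as
    extra rows).  Returns the lifetime with asymptotic 95% CIs; if the
    data do not decay, the fit is returned with a warning flag and tau
    pinned at the upper search bound.
    """
    t = series["time_min"].to_numpy(dtype=float)
    y = series["mrna_per_cell"].to_numpy(dtype=float)
    if np.unique(t).size < 4:
        raise ValueError("need >= 4 distinct time points after shutoff")

    slope = np.polyfit(t, np.log(np.maximum(y, 1e-12)), 1)[0]
    if slope >= -1.0 / _TAU_UPPER:
        m0 = float(np.mean(y))
        return DegradationFit(
            lifetime_tau=_TAU_UPPER, m0=m0,
            ci95={"lifetime_tau": (0.0, _TAU_UPPER), "m0": (m0, m0)},
            warning="series does not decay; tau at upper bound",
        )

    def model(t, m0, tau):
        return m0 * np.exp(-t / tau)

    p0 = (float(y.max()), float(-1.0 / slope))
    popt, pcov = optimize.curve_fit(
        model, t, y, p0=p0, bounds=([0.0, 1e-6], [np.inf, _TAU_UPPER]),
        maxfev=10000,
    )
    ci = _ci95_from_cov(["m0", "lifetime_tau"], popt, pcov)
    return DegradationFit(
        lifetime_tau=float(popt[1]), m0=float(popt[0]),
        ci95={"lifetime_tau": ci["lifetime_tau"], "m0": ci["m0"]},
    )


_MODEL_PARAMS: dict[str, list[str]] = {
    "constant": ["P_cell"],
    "linear": ["a_cell"],
    MODEL1: ["k_A", "k_pol"],
    MODEL2: ["alpha", "footprint_nt"],
    MEMORY_SWITCH: ["k_A", "k_C", "k_polL", "k_polH"],
}

_DEFAULT_P0: dict[str, float] = {
    "P_cell": 1.0, "a_cell": 0.01, "k_A": 5e-3, "k_pol": 1.0,
    "alpha": 1e-2, "footprint_nt": 100.0,
    "k_C": 1e-3, "k_polL": 0.3, "k_polH": 4.0,
}

_DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "P_cell": (0.0, np.inf), "a_cell": (0.0, np.inf),
    "k_A": (1e-8, 1.0), "k_pol": (1e-7, 10.0),
    "alpha": (1e-7, 10.0), "footprint_nt": (1.0, 2000.0),
    "k_C": (1e-8, 1.0), "k_polL": (1e-7, 10.0), "k_polH": (1e-7, 10.0),
}


def fit_accumulation(
    model: str,
    series: pd.DataFrame,
    tau: float,
    n_loci: int = 6,
    m0: float | None = None,
    f_M0: float = 0.0,
    p0: dict[str, float] | None = None,
    base_params: KineticParams | None = None,
) -> BulkFitResult:
    """Nonlinear least squares of an accumulation model to a qPCR series.

    ``tau`` comes from the separately measured degradation fit and is
    held fixed.  ``model`` is one of constant / linear /
    two_state_model1 / two_state_model2 / memory_switch.  For Model 2,
    activation is fixed essentially instantaneous (k_A = 1000/min) so
    only the acceleration and the Pol II footprint are free.
    """
    if model not in _MODEL_PARAMS:
        raise ValueError(f"unknown model {model!r}")
    t = series["time_min"].to_numpy(dtype=float)
    y = series["mrna_per_cell"].to_numpy(dtype=float)
    if m0 is None:
        m0 = float(np.mean(y[t == t.min()])) if np.any(t == 0) else 0.0
    names = _MODEL_PARAMS[model]
    base = base_params if base_params is not None else KineticParams()
    p0_vec = [
        (p0 or {}).get(n, _DEFAULT_P0[n]) for n in names
    ]
    lo = [_DEFAULT_BOUNDS[n][0] for n in names]
    hi = [_DEFAULT_BOUNDS[n][1] for n in names]

    def predict(t, *theta):
        kw = dict(zip(names, theta))
        if model == "constant":
            return mean_constant_production(kw["P_cell"], tau, m0, t)
        if model == "linear":
            return mean_linear_production(kw["a_cell"], tau, m0, t)
        if model == MODEL1:
            return model1_closed_form(
                kw["k_A"], kw["k_pol"], tau, n_loci, t, m0
            )
        if model == MODEL2:
            params = base.replace(
                alpha=kw["alpha"], footprint_nt=max(int(round(
                    kw["footprint_nt"])), 1),
            )
            spec = PromoterModelSpec(MODEL2)
            return mean_model_curve(spec, params, tau, n_loci, t, m0)
        params = base.replace(**{
            k: v for k, v in kw.items() if k != "footprint_nt"
        })
        spec = PromoterModelSpec(MEMORY_SWITCH)
        return mean_model_curve(spec, params, tau, n_loci, t, m0, f_M0=f_M0)

    try:
        popt, pcov = optimize.curve_fit(
            predict, t, y, p0=p0_vec, bounds=(lo, hi), maxfev=20000
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"accumulation fit for {model!r} did not converge: {err}"
        ) from err
    resid = y - predict(t, *popt)
    return BulkFitResult(
        model=model,
        params={n: float(p) for n, p in zip(names, popt)},
        ci95=_ci95_from_cov(names, popt, pcov),
        rss=float(np.sum(resid**2)),
        n_loci=n_loci,
        tau=tau,
    )


def accumulation_rate(
    fit: BulkFitResult, t_grid, m0: float = 0.0, f_M0: float = 0.0
) -> pd.DataFrame:
    """Accumulation rate dm/dt and per-locus transcription rate.

    The accumulation rate is the derivative of the fitted mean curve
    (production minus degradation); the transcription rate is the
    production term alone divided by the locus count.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    p = fit.params
    if fit.model == "constant":
        production = np.full_like(t_grid, p["P_cell"])
        m = mean_constant_production(p["P_cell"], fit.tau, m0, t_grid)
    elif fit.model == "linear":
        production = p["a_cell"] * t_grid
        m = mean_linear_production(p["a_cell"], fit.tau, m0, t_grid)
    else:
        base = KineticParams()
        if fit.model == MODEL2:
            params = base.replace(
                alpha=p["alpha"],
                footprint_nt=max(int(round(p.get("footprint_nt", 150))), 1),
            )
            spec = PromoterModelSpec(MODEL2)
        elif fit.model == MODEL1:
            params = base.replace(k_A=p["k_A"], k_pol=p["k_pol"])
            spec = PromoterModelSpec(MODEL1)
        else:
            params = base.replace(**{
                k: v for k, v in p.items() if k in base.to_dict()
            })
            spec = PromoterModelSpec(MEMORY_SWITCH)
        production = fit.n_loci * np.array([
            mean_production_rate(spec, params, ti, f_M0=f_M0)
            for ti in t_grid
        ])
        m = mean_model_curve(
            spec, params, fit.tau, fit.n_loci, t_grid, m0, f_M0=f_M0
        )
    dm_dt = production - m / fit.tau
    return pd.DataFrame({
        "time_min": t_grid,
        "accumulation_rate": dm_dt,
        "transcription_rate_per_locus": production / fit.n_loci,
    })
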