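"""Chi-square fitting of the two-exponential convolution model to CT records.

The model (see :mod:`calodose.waveform`) is linear in the amplitudes k1, k2
and in each run's drift slope/offset, and nonlinear only in the two time
constants.  The fit therefore uses variable projection: for any trial
(tau1, tau2) the amplitudes and all per-run drift nuisances are solved
exactly by linear least squares, and a derivative-free Nelder-Mead simplex
(seeded from a coarse log-spaced grid when no initial guess is supplied)
minimizes the resulting profiled sum of squared residuals over
(log tau1, log tau2).  This sidesteps the ~450x separation between the two
time scales that defeats naive joint gradient starts, and is deterministic
for a given initialization.

The objective is the unit-weight chi-square (plain sum of squared
residuals, mK^2); parameter uncertainties are quoted as the deviations at
which that chi-square doubles from its minimum, scanning one parameter at a
time with the drift nuisances re-optimized at each scan point (a profile
over nuisances; a strict frozen-slice option is also available).

Amplitudes are understood per 100 mA*s: a run recorded at setting s is
modeled with k1, k2 scaled by s/100, so a single (k1, k2, tau1, tau2) set
is shared across all dose rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

from .midpoint import analyze_run, run_dose
from .waveform import (
    DriftParams,
    IrradiationSchedule,
    TemperatureWaveform,
    TransientParams,
    _analytic_term,
    _discrete_term,
    forward_waveform,
)

__all__ = [
    "FitResult",
    "ParamInterval",
    "PSComponentDose",
    "fit_transient",
    "param_uncertainty",
    "chi_square_doubling_interval",
    "ps_component_dose",
]

#: Search bounds for the time constants, s: (fast, slow).
DEFAULT_TAU_BOUNDS = ((0.05, 50.0), (10.0, 1.0e5))

_PARAM_NAMES = ("k1", "k2", "tau1", "tau2")


@dataclass(frozen=True)
class FitResult:
    """Best-fit shared response parameters and per-run drift nuisances."""

    params: TransientParams
    per_run_drifts: tuple[DriftParams, ...]
    chi2_min: float  # unit-weight sum of squared residuals, mK^2
    n_points: int
    mode: str
    converged: bool

    def __post_init__(self) -> None:
        if self.chi2_min < 0:
            raise ValueError("chi2_min cannot be negative")


@dataclass(frozen=True)
class ParamInterval:
    """Chi-square-doubling uncertainty interval for one parameter.

    ``lower_dev`` <= 0 <= ``upper_dev`` are the deviations from
    ``best_value`` at which the chi-square reaches twice its minimum; an
    ``*_open`` flag marks a direction in which doubling was not reached
    within the scan bounds (the corresponding deviation is then the scan
    limit, not a crossing).
    """

    param_name: str
    best_value: float
    lower_dev: float
    upper_dev: float
    lower_open: bool = False
    upper_open: bool = False

    def __post_init__(self) -> None:
        if not (self.lower_dev <= 0.0 <= self.upper_dev):
            raise ValueError("need lower_dev <= 0 <= upper_dev")


@dataclass(frozen=True)
class PSComponentDose:
    """Dose carried by the slow (polystyrene staircase) term of a fit.

    Per cycle, per 100 mA*s: the isolated k2 term is reconstructed
    noiselessly, midpoint-extrapolated cycle by cycle, and the mean rise
    converted through the heat capacity.
    """

    mean_delta_T_mK: float
    dose_mGy: float  # per cycle per 100 mA*s
    cp_used: float
    n_cycles: int

    def factor_vs_ic(self, ic_dose_mGy: float, *, rounded: bool = False) -> float:
        """Ratio of the staircase dose to a reference chamber dose."""
        if ic_dose_mGy <= 0:
            raise ValueError("reference dose must be positive")
        f = self.dose_mGy / ic_dose_mGy
        return float(round(f)) if rounded else f


def _basis(
    waveforms: Sequence[TemperatureWaveform],
    schedule: IrradiationSchedule,
    tau: float,
    mode: str,
) -> list[np.ndarray]:
    """Unit-amplitude (k = 1) response of one exponential term, per run."""
    cols = []
    for wf in waveforms:
        t = wf.times
        if mode == "analytic":
            cols.append(_analytic_term(t, 1.0, tau, schedule))
        else:
            cols.append(_discrete_term(t, 1.0, tau, schedule, wf.dt))
    return cols


def _stack_design(
    waveforms: Sequence[TemperatureWaveform],
    scales: np.ndarray,
    b1: list[np.ndarray],
    b2: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Global design matrix: shared k1, k2 columns + per-run drift blocks."""
    sizes = [len(w) for w in waveforms]
    n = sum(sizes)
    n_runs = len(waveforms)
    X = np.zeros((n, 2 + 2 * n_runs))
    y = np.concatenate([w.samples for w in waveforms])
    row = 0
    for r, wf in enumerate(waveforms):
        sl = slice(row, row + sizes[r])
        X[sl, 0] = scales[r] * b1[r]
        X[sl, 1] = scales[r] * b2[r]
        X[sl, 2 + 2 * r] = wf.times
        X[sl, 3 + 2 * r] = 1.0
        row += sizes[r]
    return X, y


def _profiled_chi2(
    waveforms, schedule, scales, tau1: float, tau2: float, mode: str
) -> tuple[float, np.ndarray]:
    """SSR with amplitudes and drifts solved linearly at fixed time constants."""
    b1 = _basis(waveforms, schedule, tau1, mode)
    b2 = _basis(waveforms, schedule, tau2, mode)
    X, y = _stack_design(waveforms, scales, b1, b2)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), coef


def fit_transient(
    waveforms: Sequence[TemperatureWaveform],
    schedule: IrradiationSchedule,
    init: TransientParams | None = None,
    *,
    settings_mAs: Sequence[float] | None = None,
    mode: str = "analytic",
    tau_bounds: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_TAU_BOUNDS,
) -> FitResult:
    """Fit shared (k1, k2, tau1, tau2) plus per-run drift to a set of records.

    Parameters
    ----------
    waveforms : sequence of TemperatureWaveform
        One or more records sharing ``schedule``.
    schedule : IrradiationSchedule
        Beam timing common to all runs.
    init : TransientParams, optional
        Starting point for the time constants; when omitted a coarse
        log-spaced grid seeds the simplex.
    settings_mAs : sequence of float, optional
        Tube current-time product of each run; amplitudes are per
        100 mA*s and each run's model is scaled by setting/100.  Defaults
        to 100 for every run.
    mode : {"analytic", "discrete"}
        Convolution evaluation (see :func:`calodose.waveform.forward_waveform`).
    tau_bounds
        Allowed (lower, upper) ranges for tau1 and tau2; an ``init``
        outside them is an error, and a fit pressed against them is
        flagged as not converged.
    """
    waveforms = list(waveforms)
    if not waveforms:
        raise ValueError("need at least one waveform")
    if settings_mAs is None:
        settings_mAs = [100.0] * len(waveforms)
    if len(settings_mAs) != len(waveforms):
        raise ValueError("one mA*s setting per waveform required")
    scales = np.asarray(settings_mAs, dtype=float) / 100.0
    (lo1, hi1), (lo2, hi2) = tau_bounds
    if init is not None and not (lo1 <= init.tau1 <= hi1 and lo2 <= init.tau2 <= hi2):
        raise ValueError(
            f"initial time constants ({init.tau1}, {init.tau2}) violate bounds {tau_bounds}"
        )

    def objective(logtau: np.ndarray) -> float:
        t1, t2 = np.exp(logtau)
        if not (lo1 <= t1 <= hi1 and lo2 <= t2 <= hi2):
            return np.inf
        return _profiled_chi2(waveforms, schedule, scales, t1, t2, mode)[0]

    if init is not None:
        x0 = np.log([init.tau1, init.tau2])
    else:
        g1 = np.geomspace(max(lo1, 0.2), min(hi1, 30.0), 8)
        g2 = np.geomspace(max(lo2, 20.0), min(hi2, 5000.0), 8)
        best = min(
            ((t1, t2) for t1 in g1 for t2 in g2),
            key=lambda tt: _profiled_chi2(waveforms, schedule, scales, *tt, mode)[0],
        )
        x0 = np.log(best)

    res = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-14, "maxiter": 2000},
    )
    tau1, tau2 = np.exp(res.x)
    chi2, coef = _profiled_chi2(waveforms, schedule, scales, tau1, tau2, mode)
    at_bound = min(tau1 - lo1, hi1 - tau1, tau2 - lo2, hi2 - tau2) <= 1e-9
    drifts = tuple(
        DriftParams(slope=float(coef[2 + 2 * r]), offset=float(coef[3 + 2 * r]))
        for r in range(len(waveforms))
    )
    return FitResult(
        params=TransientParams(k1=float(coef[0]), k2=float(coef[1]), tau1=tau1, tau2=tau2),
        per_run_drifts=drifts,
        chi2_min=chi2,
        n_points=sum(len(w) for w in waveforms),
        mode=mode,
        converged=bool(res.success) and not at_bound,
    )


def _chi2_slice(
    fit: FitResult,
    name: str,
    waveforms: Sequence[TemperatureWaveform],
    schedule: IrradiationSchedule,
    scales: np.ndarray,
    profile_drifts: bool,
) -> Callable[[float], float]:
    """Chi-square as a function of one transient parameter.

    The other three transient parameters stay at their best-fit values;
    drift nuisances are re-solved at each point (``profile_drifts=True``)
    or frozen at the best fit.
    """
    p = fit.params

    def chi2(theta: float) -> float:
        vals = {"k1": p.k1, "k2": p.k2, "tau1": p.tau1, "tau2": p.tau2}
        vals[name] = theta
        if vals["tau1"] <= 0 or vals["tau2"] <= 0:
            return np.inf
        b1 = _basis(waveforms, schedule, vals["tau1"], fit.mode)
        b2 = _basis(waveforms, schedule, vals["tau2"], fit.mode)
        total = 0.0
        for r, wf in enumerate(waveforms):
            signal = scales[r] * (vals["k1"] * b1[r] + vals["k2"] * b2[r])
            resid = wf.samples - signal
            if profile_drifts:
                D = np.column_stack([wf.times, np.ones(len(wf))])
                coef, *_ = np.linalg.lstsq(D, resid, rcond=None)
                resid = resid - D @ coef
            else:
                resid = resid - fit.per_run_drifts[r].line(wf.times)
            total += float(resid @ resid)
        return total

    return chi2


def chi_square_doubling_interval(
    chi2_fn: Callable[[float], float],
    best: float,
    chi2_min: float | None = None,
    *,
    initial_step: float | None = None,
    max_expand: int = 60,
) -> tuple[float, float, bool, bool]:
    """Deviations about ``best`` at which ``chi2_fn`` reaches twice its minimum.

    Returns ``(lower_dev, upper_dev, lower_open, upper_open)``; a True open
    flag means the doubling level was not reached within the geometric scan
    (the deviation returned is then the last scanned offset).  The crossing
    itself is located by Brent root finding on chi2(theta) - 2*chi2_min.
    """
    f0 = chi2_fn(best) if chi2_min is None else chi2_min
    if not np.isfinite(f0) or f0 <= 0:
        raise ValueError(
            f"chi-square minimum must be positive and finite to double it, got {f0}"
        )
    target = 2.0 * f0
    if initial_step is None:
        initial_step = 0.01 * abs(best) if best != 0 else 0.01

    devs = []
    opens = []
    for sign in (-1.0, 1.0):
        step = initial_step
        prev = 0.0
        crossing = None
        for _ in range(max_expand):
            theta = best + sign * step
            if chi2_fn(theta) >= target:
                crossing = (prev, step)
                break
            prev = step
            step *= 2.0
        if crossing is None:
            devs.append(sign * prev)
            opens.append(True)
            continue
        lo, hi = crossing
        root = optimize.brentq(
            lambda s: chi2_fn(best + sign * s) - target, lo, hi, xtol=1e-12, rtol=1e-10
        )
        devs.append(sign * root)
        opens.append(False)
    return devs[0], devs[1], opens[0], opens[1]


def param_uncertainty(
    fit: FitResult,
    param_name: str,
    waveforms: Sequence[TemperatureWaveform],
    schedule: IrradiationSchedule,
    *,
    settings_mAs: Sequence[float] | None = None,
    profile_drifts: bool = True,
) -> ParamInterval:
    """Chi-square-doubling interval for one of k1, k2, tau1, tau2.

    The named parameter is scanned away from its best-fit value in both
    directions until the unit-weight chi-square doubles; the other
    transient parameters stay at the best fit and the per-run drift
    nuisances are re-optimized at every scan point unless
    ``profile_drifts=False`` (strict frozen slice).
    """
    if param_name not in _PARAM_NAMES:
        raise ValueError(f"unknown parameter {param_name!r}; expected one of {_PARAM_NAMES}")
    if not fit.converged:
        raise ValueError("cannot scan uncertainties of a non-converged fit")
    waveforms = list(waveforms)
    if settings_mAs is None:
        settings_mAs = [100.0] * len(waveforms)
    scales = np.asarray(settings_mAs, dtype=float) / 100.0
    chi2 = _chi2_slice(fit, param_name, waveforms, schedule, scales, profile_drifts)
    best = getattr(fit.params, param_name)
    lo, hi, lo_open, hi_open = chi_square_doubling_interval(chi2, best, fit.chi2_min)
    return ParamInterval(
        param_name=param_name,
        best_value=best,
        lower_dev=lo,
        upper_dev=hi,
        lower_open=lo_open,
        upper_open=hi_open,
    )


def ps_component_dose(
    fit: FitResult,
    schedule: IrradiationSchedule,
    cp: float,
    *,
    window_fraction: float = 0.5,
    settle_time: float = 0.0,
) -> PSComponentDose:
    """Dose to the polystyrene core from the isolated slow (k2) term.

    Reconstructs the staircase component at 100 mA*s from the fitted
    parameters (no drift, no noise), runs midpoint extrapolation on every
    cycle, and converts the mean per-cycle rise to dose in mGy per cycle
    per 100 mA*s.
    """
    if not fit.converged:
        raise ValueError("cannot reconstruct components of a non-converged fit")
    lead = schedule.t_off
    wf = forward_waveform(
        fit.params,
        DriftParams(),
        schedule,
        fit.mode,
        t0=schedule.t_start - lead,
        terms="slow",
    )
    estimates = analyze_run(wf, schedule, window_fraction, settle_time)
    rd = run_dose(estimates, cp)
    return PSComponentDose(
        mean_delta_T_mK=rd.mean_delta_T,
        dose_mGy=rd.dose_mGy,
        cp_used=cp,
        n_cycles=rd.n_cycles,
    )
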