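"""Per-cycle temperature-rise extraction by midpoint extrapolation.

The standard calorimetric estimate of the temperature rise produced by one
irradiation cycle: fit a straight line to the beam-off segment before the
pulse and another to the beam-off segment after it, extrapolate both to the
temporal midpoint of the beam-on interval, and take the difference.  Any
background trend common to both segments — in particular an arbitrary
global linear drift — cancels exactly, which is the method's point.

The module also summarizes a run (mean and spread of the per-cycle rises,
converted to dose through the polystyrene heat capacity) and performs the
linearity regression of calorimeter dose against reference
ionization-chamber dose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .thermal import dose_from_delta_T
from .waveform import IrradiationSchedule, TemperatureWaveform

__all__ = [
    "CycleEstimate",
    "RunDose",
    "DoseComparison",
    "extrapolate_midpoint",
    "analyze_run",
    "run_dose",
    "linear_calibration",
]


@dataclass(frozen=True)
class CycleEstimate:
    """Midpoint-extrapolated temperature rise of one cycle.

    ``pre_fit`` and ``post_fit`` are (slope, offset) of the lines fitted to
    the beam-off windows before and after the pulse, in mK/s and mK
    (offset at the pulse midpoint).
    """

    cycle_index: int
    delta_T: float  # mK
    pre_fit: tuple[float, float]
    post_fit: tuple[float, float]


@dataclass(frozen=True)
class RunDose:
    """Run-level summary: mean/SD of per-cycle rises and the implied dose.

    ``dose`` = mean_delta_T * cp, expressed in Gy (mean_delta_T in mK gives
    mGy; divided by 1000 here since the 6 MV doses are order-Gy).  ``sd`` is
    the sample standard deviation over cycles; for a single cycle it is
    reported as 0 with ``single_cycle`` set.
    """

    mean_delta_T: float  # mK
    sd_delta_T: float  # mK
    n_cycles: int
    dose: float  # Gy
    cp_used: float
    single_cycle: bool = False

    @property
    def dose_mGy(self) -> float:
        return self.dose * 1000.0


@dataclass(frozen=True)
class DoseComparison:
    """Ordinary least-squares comparison of paired calorimeter/reference doses."""

    calorimeter_doses: tuple[float, ...]
    reference_doses: tuple[float, ...]
    slope: float
    intercept: float
    residuals: tuple[float, ...]
    slope_uncertainty: float

    @property
    def slope_deviation_from_unity(self) -> float:
        """Fractional deviation of the fitted slope from 1 (e.g. +0.016 = +1.6%)."""
        return self.slope - 1.0


def _fit_line(t: np.ndarray, y: np.ndarray, t_ref: float) -> tuple[float, float]:
    """Least-squares line through (t, y); returns (slope, value at t_ref)."""
    if t.size < 3:
        raise ValueError(f"need at least 3 samples in extrapolation window, got {t.size}")
    slope, intercept = np.polyfit(t - t_ref, y, 1)
    return float(slope), float(intercept)


def extrapolate_midpoint(
    waveform: TemperatureWaveform,
    schedule: IrradiationSchedule,
    cycle_index: int,
    window_fraction: float = 0.5,
    settle_time: float = 0.0,
) -> CycleEstimate:
    """Midpoint-extrapolated temperature rise of one irradiation cycle.

    Parameters
    ----------
    waveform, schedule
        The record and the beam timing; the cycle (including its leading
        beam-off segment) must lie within the record.
    cycle_index : int
        Which cycle, 0-based.
    window_fraction : float in (0, 1]
        Fraction of each beam-off segment used for the line fits: the
        trailing fraction of the segment before the pulse, and the leading
        fraction (after ``settle_time``) of the segment after it.
    settle_time : float
        Dead time, s, skipped at the start of the post-pulse segment before
        fitting — used in the CT regime to let the fast thermistor
        transient decay (5 * tau1 is a practical choice); 0 for staircase
        (6 MV) records.

    Returns
    -------
    CycleEstimate
        ``delta_T`` is the post-line minus the pre-line, both evaluated at
        the temporal midpoint of the beam-on interval.
    """
    if not 0 < window_fraction <= 1:
        raise ValueError(f"window_fraction must be in (0, 1], got {window_fraction}")
    if settle_time < 0:
        raise ValueError(f"settle_time must be non-negative, got {settle_time}")
    a = schedule.pulse_start(cycle_index)  # validates cycle_index
    mid = schedule.pulse_midpoint(cycle_index)
    off = schedule.t_off

    # trailing window_fraction of the beam-off segment preceding the pulse
    pre_t, pre_y = waveform.slice_time(a - off * window_fraction, a)
    # leading window_fraction of the post-pulse beam-off segment, after settle
    post_lo = a + schedule.t_open + settle_time
    post_hi = post_lo + (off - settle_time) * window_fraction
    if post_hi <= post_lo:
        raise ValueError("settle_time leaves no post-pulse fitting window")
    post_t, post_y = waveform.slice_time(post_lo, post_hi)

    pre = _fit_line(pre_t, pre_y, mid)
    post = _fit_line(post_t, post_y, mid)
    return CycleEstimate(
        cycle_index=cycle_index,
        delta_T=post[1] - pre[1],
        pre_fit=pre,
        post_fit=post,
    )


def analyze_run(
    waveform: TemperatureWaveform,
    schedule: IrradiationSchedule,
    window_fraction: float = 0.5,
    settle_time: float = 0.0,
) -> list[CycleEstimate]:
    """Midpoint extrapolation of every cycle in the schedule."""
    return [
        extrapolate_midpoint(waveform, schedule, m, window_fraction, settle_time)
        for m in range(schedule.n_cycles)
    ]


def run_dose(estimates: list[CycleEstimate], cp: float) -> RunDose:
    """Average the per-cycle rises and convert to absorbed dose.

    The mean rise (mK) times ``cp`` gives the dose in mGy; ``RunDose.dose``
    is in Gy.  The SD is the sample standard deviation over cycles
    (ddof=1); a single-cycle run reports SD 0 with the degenerate case
    flagged.
    """
    if not estimates:
        raise ValueError("need at least one cycle estimate")
    dT = np.array([e.delta_T for e in estimates])
    single = dT.size == 1
    mean = float(dT.mean())
    sd = 0.0 if single else float(dT.std(ddof=1))
    return RunDose(
        mean_delta_T=mean,
        sd_delta_T=sd,
        n_cycles=dT.size,
        dose=dose_from_delta_T(mean, cp) / 1000.0,  # mK*cp = mGy -> Gy
        cp_used=cp,
        single_cycle=single,
    )


def linear_calibration(calorimeter_doses, reference_doses) -> DoseComparison:
    """Ordinary least-squares fit of calorimeter dose against reference dose.

    Requires at least two distinct reference doses.  Returns the fitted
    slope with its standard error, the intercept, and the residuals
    (calorimeter minus fit).
    """
    cal = np.asarray(calorimeter_doses, dtype=float)
    ref = np.asarray(reference_doses, dtype=float)
    if cal.shape != ref.shape:
        raise ValueError(f"paired arrays differ in length: {cal.shape} vs {ref.shape}")
    if cal.size < 2:
        raise ValueError("need at least two dose pairs")
    if np.ptp(ref) == 0:
        raise ValueError("reference doses are all equal; slope is undefined")
    fit = stats.linregress(ref, cal)
    resid = cal - (fit.slope * ref + fit.intercept)
    return DoseComparison(
        calorimeter_doses=tuple(cal),
        reference_doses=tuple(ref),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        residuals=tuple(resid),
        slope_uncertainty=float(fit.stderr),
    )
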