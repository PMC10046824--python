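"""Frequency-domain extraction of the per-cycle temperature rise.

For a periodic pulse train of period P and beam-on time w, the ideal
(lossless) calorimeter response is a sloping staircase whose harmonic
amplitudes obey

    amp_n = A * (w / (n*pi)) * sinc(n*pi*w / P),      sinc(x) = sin(x)/x,

where A is the heating rate (mK/s) during irradiation, so the per-cycle
temperature rise is A*w.  Reading the discrete-Fourier-transform amplitude
at the cycle frequency therefore yields the rise without any time-domain
model of the transients — a useful cross-check when the record is too
nonlinear for midpoint extrapolation.

Conventions fixed here: one-sided amplitude 2|X_k|/N; the record is
linearly detrended over the analysis window first; the harmonic bin is
located from the declared schedule (k = n * n_periods for an
integer-period window), never by peak search, which makes the estimate
immune to drift leakage into neighboring bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .thermal import excess_heat_factor
from .waveform import IrradiationSchedule, TemperatureWaveform

__all__ = [
    "SpectralEstimate",
    "SpectralResponse",
    "fundamental_amplitude",
    "rate_from_amplitude",
    "amplitude_to_rise",
    "dose_response",
]


@dataclass(frozen=True)
class SpectralEstimate:
    """Harmonic amplitude and the heating rate / per-cycle rise it implies.

    Invariant: ``per_cycle_rise == heating_rate_A * t_open``.
    """

    fundamental_amplitude: float  # mK, one-sided 2|X_k|/N
    heating_rate_A: float  # mK/s during beam-on
    per_cycle_rise: float  # mK
    n_harmonic: int = 1


@dataclass(frozen=True)
class SpectralResponse:
    """Regression of FFT-derived per-cycle rises against reference doses."""

    rises_mK: tuple[float, ...]
    reference_doses_mGy: tuple[float, ...]
    slope_mK_per_mGy: float
    intercept_mK: float
    slope_uncertainty: float
    r_squared: float
    excess_factor: float


def _sinc(x: float) -> float:
    """sin(x)/x with sinc(0) = 1 (unnormalized convention)."""
    return 1.0 if x == 0 else math.sin(x) / x


def fundamental_amplitude(
    waveform: TemperatureWaveform,
    schedule: IrradiationSchedule,
    n_harmonic: int = 1,
    *,
    detrend: bool = True,
) -> float:
    """One-sided DFT amplitude of the record at harmonic ``n_harmonic`` of the cycle.

    The analysis window starts at ``schedule.t_start`` and spans the largest
    whole number of periods the record contains (at most ``n_cycles``); the
    record must cover at least one full period past t_start.  A straight
    line is fitted over the window and subtracted first (``detrend=True``),
    then the amplitude 2|X_k|/N is read at bin k = n_harmonic * n_periods.
    """
    if n_harmonic < 1:
        raise ValueError(f"n_harmonic must be >= 1, got {n_harmonic}")
    dt = waveform.dt
    per = int(round(schedule.period / dt))
    if not math.isclose(per * dt, schedule.period, rel_tol=1e-9):
        raise ValueError(
            f"period {schedule.period} is not an integer multiple of dt {dt}"
        )
    t = waveform.times
    i0 = int(np.searchsorted(t, schedule.t_start - 1e-9 * dt))
    avail = len(waveform) - i0
    n_periods = min(avail // per, schedule.n_cycles)
    if n_periods < 1:
        raise ValueError("record covers less than one full period past t_start")
    n = n_periods * per
    y = waveform.samples[i0 : i0 + n]
    if detrend:
        tt = t[i0 : i0 + n]
        y = y - np.polyval(np.polyfit(tt - tt[0], y, 1), tt - tt[0])
    X = np.fft.rfft(y)
    k = n_harmonic * n_periods
    if k >= len(X):
        raise ValueError(f"harmonic {n_harmonic} is beyond Nyquist for this record")
    return float(2.0 * np.abs(X[k]) / n)


def rate_from_amplitude(
    amplitude: float, schedule: IrradiationSchedule, n_harmonic: int = 1
) -> SpectralEstimate:
    """Invert the staircase harmonic relation: A = amp * n*pi / (w * sinc(n*pi*w/P)).

    Raises if the duty cycle puts the requested harmonic at a zero of the
    sinc (t_open/period = m/n), where the staircase carries no power.
    """
    if amplitude < 0:
        raise ValueError(f"amplitude must be non-negative, got {amplitude}")
    if n_harmonic < 1:
        raise ValueError(f"n_harmonic must be >= 1, got {n_harmonic}")
    x = n_harmonic * math.pi * schedule.duty_cycle
    s = _sinc(x)
    if abs(s) < 1e-12:
        raise ValueError(
            f"harmonic {n_harmonic} falls on a sinc zero at duty cycle "
            f"{schedule.duty_cycle}; the staircase has no amplitude there"
        )
    A = amplitude * n_harmonic * math.pi / (schedule.t_open * s)
    return SpectralEstimate(
        fundamental_amplitude=amplitude,
        heating_rate_A=A,
        per_cycle_rise=A * schedule.t_open,
        n_harmonic=n_harmonic,
    )


def amplitude_to_rise(
    waveform: TemperatureWaveform,
    schedule: IrradiationSchedule,
    n_harmonic: int = 1,
) -> SpectralEstimate:
    """Per-cycle rise straight from a record: DFT amplitude then sinc inversion."""
    amp = fundamental_amplitude(waveform, schedule, n_harmonic)
    return rate_from_amplitude(amp, schedule, n_harmonic)


def dose_response(rises_mK, reference_doses_mGy, cp: float) -> SpectralResponse:
    """Least-squares slope of per-cycle rise versus reference dose, plus excess factor.

    The slope (mK/mGy) divided by the ideal polystyrene-only slope 1/cp
    gives the excess-heat factor.  Requires >= 2 points with distinct
    reference doses.
    """
    rises = np.asarray(rises_mK, dtype=float)
    doses = np.asarray(reference_doses_mGy, dtype=float)
    if rises.shape != doses.shape or rises.size < 2:
        raise ValueError("need >= 2 paired (rise, dose) points")
    if np.ptp(doses) == 0:
        raise ValueError("reference doses are all equal; slope is undefined")
    fit = stats.linregress(doses, rises)
    return SpectralResponse(
        rises_mK=tuple(rises),
        reference_doses_mGy=tuple(doses),
        slope_mK_per_mGy=float(fit.slope),
        intercept_mK=float(fit.intercept),
        slope_uncertainty=float(fit.stderr),
        r_squared=float(fit.rvalue**2),
        excess_factor=excess_heat_factor(float(fit.slope), cp),
    )
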