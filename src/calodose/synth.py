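"""Seeded synthetic waveform generators emulating the two measurement regimes.

Two regimes are emulated:

* **6 MV staircase runs** — in a megavolt therapy beam the excess heat is
  negligible and the record is an ideal staircase: during each beam-on
  interval the temperature rises linearly by ``dose_per_cycle / Cp`` and is
  flat while the beam is off, apart from a linear background drift and
  Gaussian read noise.
* **CT transient series** — in a 120 kV CT beam the record is dominated by
  the fast thermistor excess-heat transient riding on a small polystyrene
  staircase, i.e. the two-exponential convolution model of
  :mod:`calodose.waveform`, evaluated at a ladder of tube current-time
  products (mA*s).  Amplitudes are specified per 100 mA*s and scale linearly
  with the setting; the response shape is dose-rate independent.

All randomness flows through the single seed in :class:`NoiseSpec`; the
generators never touch global random state, so a fixed seed reproduces a
record bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .thermal import delta_T_from_dose
from .waveform import (
    DriftParams,
    IrradiationSchedule,
    TemperatureWaveform,
    TransientParams,
    forward_waveform,
)

__all__ = [
    "NoiseSpec",
    "ReferenceDoses",
    "REFERENCE_DOSES",
    "simulate_6mv_run",
    "simulate_ct_series",
    "normalize_to_100mAs",
    "write_fixture_set",
]

#: Default Gaussian noise sigma, mK, for CT-regime fixtures.
CT_NOISE_SIGMA = 0.002
#: Default Gaussian noise sigma, mK, for 6 MV-regime fixtures.
SIX_MV_NOISE_SIGMA = 0.005


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian white read noise: standard deviation in mK plus the RNG seed."""

    sigma: float = CT_NOISE_SIGMA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class ReferenceDoses:
    """Ionization-chamber reference doses for the two experiments.

    ``six_mv_ic_doses`` are the per-cycle doses (Gy) at the five therapy
    dose-rate settings; ``ct_ic_dose_per_100mAs`` is the chamber dose in the
    phantom per cycle per 100 mA*s; ``ct_current_settings`` the ladder of
    tube current-time products in mA*s.
    """

    six_mv_ic_doses: tuple[float, ...] = (0.536, 1.07, 1.61, 2.15, 2.69)
    ct_ic_dose_per_100mAs: float = 2.46
    ct_current_settings: tuple[int, ...] = tuple(range(150, 651, 50))

    def __post_init__(self) -> None:
        for name in ("six_mv_ic_doses", "ct_current_settings"):
            vals = getattr(self, name)
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"{name} must be strictly increasing")

    def ct_ic_dose(self, setting_mAs: float) -> float:
        """IC dose in mGy per cycle at a given mA*s setting."""
        return self.ct_ic_dose_per_100mAs * setting_mAs / 100.0


REFERENCE_DOSES = ReferenceDoses()


def _staircase(t: np.ndarray, step_mK: float, schedule: IrradiationSchedule) -> np.ndarray:
    """Ideal lossless staircase: linear rise of ``step_mK`` per beam-on interval."""
    starts = schedule.t_start + schedule.period * np.arange(schedule.n_cycles)
    frac = np.clip((t[:, None] - starts[None, :]) / schedule.t_open, 0.0, 1.0)
    return step_mK * frac.sum(axis=1)


def simulate_6mv_run(
    dose_per_cycle: float,
    schedule: IrradiationSchedule,
    cp: float,
    drift: DriftParams = DriftParams(),
    noise: NoiseSpec = NoiseSpec(sigma=SIX_MV_NOISE_SIGMA),
    *,
    lead_in: float | None = None,
    tail: float = 0.0,
) -> TemperatureWaveform:
    """Synthetic megavolt-beam staircase record.

    Parameters
    ----------
    dose_per_cycle : float
        Absorbed dose per cycle in Gy (non-negative).
    schedule : IrradiationSchedule
        Beam timing; the 6 MV experiments used symmetric on/off cycles
        (60 s on / 60 s off, or 20 s on / 20 s off in water).
    cp : float
        Polystyrene heat capacity in J/(kg K); the noiseless per-cycle step
        is exactly ``dose_per_cycle / cp`` (in mK per mGy equivalently).
    drift, noise
        Linear background drift and seeded Gaussian read noise.
    lead_in : float, optional
        Baseline recorded before the first pulse, s.  Defaults to one
        beam-off interval so the first cycle has a pre-irradiation segment.
    tail : float
        Extra record beyond the last cycle, s.
    """
    if dose_per_cycle < 0:
        raise ValueError(f"dose_per_cycle must be non-negative, got {dose_per_cycle}")
    if lead_in is None:
        lead_in = schedule.t_off
    t0 = schedule.t_start - lead_in
    n = int(round((schedule.t_end + tail - t0) / schedule.dt)) + 1
    t = t0 + schedule.dt * np.arange(n)

    step_mK = delta_T_from_dose(dose_per_cycle, cp) * 1000.0  # K -> mK
    u = _staircase(t, step_mK, schedule) + drift.line(t)
    u = u + noise.rng().normal(0.0, noise.sigma, size=n)
    return TemperatureWaveform(t0=t0, dt=schedule.dt, samples=u)


def simulate_ct_series(
    settings_mAs: Sequence[float],
    params_per_100mAs: TransientParams,
    schedule: IrradiationSchedule,
    drifts: Sequence[DriftParams] | DriftParams = DriftParams(),
    noise: NoiseSpec = NoiseSpec(),
    *,
    lead_in: float | None = None,
    mode: str = "analytic",
) -> list[TemperatureWaveform]:
    """Synthetic CT-beam series: one transient-plus-staircase record per mA*s setting.

    Amplitudes k1, k2 are given per 100 mA*s and scaled by ``setting/100``
    for each run (the response shape is dose-rate independent).  ``drifts``
    may be a single DriftParams applied to every run or one per run.  Noise
    is drawn from a single seeded generator across the series, so the whole
    series is reproducible from one seed.
    """
    settings = list(settings_mAs)
    if not settings:
        raise ValueError("settings list must not be empty")
    if isinstance(drifts, DriftParams):
        drifts = [drifts] * len(settings)
    if len(drifts) != len(settings):
        raise ValueError(f"{len(drifts)} drifts for {len(settings)} settings")
    if lead_in is None:
        lead_in = schedule.t_off
    rng = noise.rng()

    out = []
    for setting, drift in zip(settings, drifts):
        wf = forward_waveform(
            params_per_100mAs.scaled(setting / 100.0),
            drift,
            schedule,
            mode,
            t0=schedule.t_start - lead_in,
            duration=schedule.t_end - schedule.t_start + lead_in,
        )
        noisy = wf.samples + rng.normal(0.0, noise.sigma, size=len(wf))
        out.append(wf.with_samples(noisy))
    return out


def normalize_to_100mAs(waveform: TemperatureWaveform, setting_mAs: float) -> TemperatureWaveform:
    """Rescale a record taken at ``setting_mAs`` to the 100 mA*s overlay convention."""
    if setting_mAs <= 0:
        raise ValueError(f"setting must be positive, got {setting_mAs}")
    return waveform.with_samples(waveform.samples * (100.0 / setting_mAs))


def write_fixture_set(
    outdir,
    waveforms: Sequence[TemperatureWaveform],
    labels: Sequence,
    schedule: IrradiationSchedule,
    noise: NoiseSpec,
    extra: dict | None = None,
) -> Path:
    """Write waveform CSVs plus a JSON manifest recording full provenance.

    Returns the manifest path.  ``labels`` (one per waveform, e.g. mA*s
    settings or doses) become part of the file names and the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    runs = []
    for wf, label in zip(waveforms, labels, strict=True):
        name = f"run_{label}.csv"
        wf.to_csv(outdir / name)
        runs.append({"file": name, "label": label})
    manifest = {
        "schedule": {
            "t_open": schedule.t_open,
            "period": schedule.period,
            "n_cycles": schedule.n_cycles,
            "t_start": schedule.t_start,
            "dt": schedule.dt,
        },
        "noise": {"sigma": noise.sigma, "seed": noise.seed},
        "runs": runs,
    }
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
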