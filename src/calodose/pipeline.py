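"""End-to-end analysis drivers and the TOML run-manifest format.

A *manifest* is a single TOML file describing one run set: the irradiation
schedule, the heat-capacity constants (overridable, with published
polystyrene defaults), the per-run waveform files with their reference
doses or mA*s settings, analysis options, and — for simulation — the
generator parameters and seed.  ``run_pipeline`` executes one of four
modes against a manifest and writes a JSON summary (plus CSV tables)
into an output directory:

* ``simulate``      — generate synthetic waveform CSVs + a provenance manifest
* ``6mv-midpoint``  — per-cycle midpoint extrapolation, run doses, linearity
* ``ct-transient``  — shared two-exponential fit, uncertainties, PS-term dose
* ``ct-fft``        — fundamental-amplitude rises and the dose-response slope

Every summary embeds the SHA-256 of the manifest file and all decided
defaults, so a run is fully reproducible (bit-identical outputs) from the
manifest plus its seed; nothing time- or host-dependent is written.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from . import synth
from .midpoint import analyze_run, linear_calibration, run_dose
from .spectral import amplitude_to_rise, dose_response
from .thermal import HeatCapacityModel, heat_capacity
from .transient import fit_transient, param_uncertainty, ps_component_dose
from .waveform import DriftParams, IrradiationSchedule, TemperatureWaveform, TransientParams

__all__ = ["MODES", "load_manifest", "run_pipeline"]

log = logging.getLogger("calodose")

MODES = ("simulate", "6mv-midpoint", "ct-transient", "ct-fft")

#: Analysis defaults recorded in every summary.
DEFAULTS = {
    "window_fraction": 0.5,
    "settle_time": 0.0,
    "fit_mode": "analytic",
    "dft_convention": "one-sided 2|X_k|/N, schedule-located bin, linear detrend",
    "temperature_K": 297.65,
    "ct_ic_dose_per_100mAs": synth.REFERENCE_DOSES.ct_ic_dose_per_100mAs,
}


def load_manifest(path) -> dict:
    """Parse and minimally validate a TOML manifest."""
    path = Path(path)
    with open(path, "rb") as fh:
        m = tomllib.load(fh)
    if "schedule" not in m:
        raise ValueError(f"{path}: manifest lacks a [schedule] section")
    for run in m.get("runs", []):
        f = path.parent / run["file"]
        if not f.exists():
            raise FileNotFoundError(f"{path}: referenced waveform {f} does not exist")
    m["_path"] = path
    m["_sha256"] = hashlib.sha256(path.read_bytes()).hexdigest()
    return m


def _schedule(m: dict) -> IrradiationSchedule:
    s = m["schedule"]
    return IrradiationSchedule(
        t_open=float(s["t_open"]),
        period=float(s["period"]),
        n_cycles=int(s["n_cycles"]),
        t_start=float(s.get("t_start", 0.0)),
        dt=float(s.get("dt", 0.25)),
    )


def _cp(m: dict) -> float:
    hc = m.get("heat_capacity", {})
    model = HeatCapacityModel(
        molar_mass=float(hc.get("molar_mass", 104.15)),
        coeff_a=float(hc.get("coeff_a", 7.755e5)),
        coeff_b=float(hc.get("coeff_b", 0.5345)),
        coeff_c=float(hc.get("coeff_c", -41.58)),
    )
    return heat_capacity(float(hc.get("temperature_K", DEFAULTS["temperature_K"])), model)


def _analysis_opts(m: dict) -> dict:
    a = m.get("analysis", {})
    return {
        "window_fraction": float(a.get("window_fraction", DEFAULTS["window_fraction"])),
        "settle_time": float(a.get("settle_time", DEFAULTS["settle_time"])),
        "fit_mode": a.get("fit_mode", DEFAULTS["fit_mode"]),
        "uncertainties": bool(a.get("uncertainties", False)),
    }


def _load_runs(m: dict) -> list[tuple[dict, TemperatureWaveform]]:
    runs = m.get("runs", [])
    if not runs:
        raise ValueError("manifest lists no [[runs]]")
    base = m["_path"].parent
    return [(run, TemperatureWaveform.from_csv(base / run["file"])) for run in runs]


def _summary_base(m: dict, mode: str, opts: dict) -> dict:
    return {
        "mode": mode,
        "manifest_sha256": m["_sha256"],
        "seed": m.get("seed"),
        "defaults": {**DEFAULTS, **{k: v for k, v in opts.items() if k != "uncertainties"}},
    }


def _write_summary(outdir: Path, summary: dict) -> Path:
    out = outdir / "summary.json"
    out.write_text(json.dumps(summary, indent=2, sort_keys=True))
    return out


def _run_simulate(m: dict, outdir: Path) -> dict:
    sim = m.get("simulate")
    if not sim:
        raise ValueError("mode 'simulate' needs a [simulate] section")
    schedule = _schedule(m)
    cp = _cp(m)
    seed = int(m.get("seed", 0))
    regime = sim.get("regime")
    drift = DriftParams(
        slope=float(sim.get("drift_slope", 0.0)), offset=float(sim.get("drift_offset", 0.0))
    )
    if regime == "6mv":
        sigma = float(sim.get("noise_sigma", synth.SIX_MV_NOISE_SIGMA))
        doses = [float(d) for d in sim["doses_Gy"]]
        waveforms = [
            synth.simulate_6mv_run(
                d, schedule, cp, drift, synth.NoiseSpec(sigma=sigma, seed=seed + i)
            )
            for i, d in enumerate(doses)
        ]
        labels = doses
    elif regime == "ct":
        sigma = float(sim.get("noise_sigma", synth.CT_NOISE_SIGMA))
        settings = [float(s) for s in sim["settings_mAs"]]
        params = TransientParams(
            k1=float(sim["k1"]), k2=float(sim["k2"]),
            tau1=float(sim["tau1"]), tau2=float(sim["tau2"]),
        )
        noise = synth.NoiseSpec(sigma=sigma, seed=seed)
        waveforms = synth.simulate_ct_series(settings, params, schedule, drift, noise)
        labels = settings
    else:
        raise ValueError(f"unknown simulate regime {regime!r}; expected '6mv' or 'ct'")
    manifest_path = synth.write_fixture_set(
        outdir, waveforms, labels, schedule, synth.NoiseSpec(sigma=sigma, seed=seed),
        extra={"regime": regime, "cp": cp},
    )
    return {"n_waveforms": len(waveforms), "fixture_manifest": manifest_path.name,
            "files": [f"run_{lab}.csv" for lab in labels]}


def _run_6mv_midpoint(m: dict, outdir: Path, opts: dict) -> dict:
    schedule = _schedule(m)
    cp = _cp(m)
    rows, cal, ref = [], [], []
    cycle_rows = []
    for run, wf in _load_runs(m):
        est = analyze_run(wf, schedule, opts["window_fraction"], opts["settle_time"])
        rd = run_dose(est, cp)
        rows.append(
            {"file": run["file"], "reference_dose_Gy": run.get("reference_dose_Gy"),
             "mean_delta_T_mK": rd.mean_delta_T, "sd_delta_T_mK": rd.sd_delta_T,
             "n_cycles": rd.n_cycles, "dose_Gy": rd.dose}
        )
        cycle_rows += [
            {"file": run["file"], "cycle": e.cycle_index, "delta_T_mK": e.delta_T}
            for e in est
        ]
        if run.get("reference_dose_Gy") is not None:
            cal.append(rd.dose)
            ref.append(float(run["reference_dose_Gy"]))
    pd.DataFrame(rows).to_csv(outdir / "run_doses.csv", index=False)
    pd.DataFrame(cycle_rows).to_csv(outdir / "cycle_estimates.csv", index=False)
    summary: dict = {"cp": cp, "runs": rows}
    if len(cal) >= 2:
        cmp_ = linear_calibration(cal, ref)
        summary["calibration"] = {
            "slope": cmp_.slope,
            "intercept_Gy": cmp_.intercept,
            "slope_uncertainty": cmp_.slope_uncertainty,
            "slope_deviation_from_unity": cmp_.slope_deviation_from_unity,
            "residuals_Gy": list(cmp_.residuals),
        }
    return summary


def _run_ct_transient(m: dict, outdir: Path, opts: dict) -> dict:
    schedule = _schedule(m)
    cp = _cp(m)
    pairs = _load_runs(m)
    waveforms = [wf for _, wf in pairs]
    settings = [float(run.get("setting_mAs", 100.0)) for run, _ in pairs]
    init = None
    if "init" in m:
        i = m["init"]
        init = TransientParams(
            k1=float(i["k1"]), k2=float(i["k2"]), tau1=float(i["tau1"]), tau2=float(i["tau2"])
        )
    fit = fit_transient(
        waveforms, schedule, init, settings_mAs=settings, mode=opts["fit_mode"]
    )
    log.info("transient fit: chi2_min=%.4g converged=%s", fit.chi2_min, fit.converged)
    summary: dict = {
        "cp": cp,
        "settings_mAs": settings,
        "params": {"k1": fit.params.k1, "k2": fit.params.k2,
                   "tau1": fit.params.tau1, "tau2": fit.params.tau2},
        "k1_over_k2": fit.params.k1 / fit.params.k2 if fit.params.k2 else None,
        "per_run_drifts": [{"slope": d.slope, "offset": d.offset} for d in fit.per_run_drifts],
        "chi2_min": fit.chi2_min,
        "n_points": fit.n_points,
        "converged": fit.converged,
    }
    if fit.converged:
        ps = ps_component_dose(
            fit, schedule, cp,
            window_fraction=opts["window_fraction"], settle_time=opts["settle_time"],
        )
        summary["ps_component"] = {
            "mean_delta_T_mK": ps.mean_delta_T_mK,
            "dose_mGy_per_cycle_per_100mAs": ps.dose_mGy,
            "factor_vs_ic": ps.factor_vs_ic(DEFAULTS["ct_ic_dose_per_100mAs"]),
        }
        if opts["uncertainties"]:
            summary["intervals"] = {
                name: {
                    "best": iv.best_value, "lower_dev": iv.lower_dev,
                    "upper_dev": iv.upper_dev,
                    "open": iv.lower_open or iv.upper_open,
                }
                for name in ("k1", "k2", "tau1", "tau2")
                for iv in [param_uncertainty(fit, name, waveforms, schedule,
                                             settings_mAs=settings)]
            }
    return summary


def _run_ct_fft(m: dict, outdir: Path, opts: dict) -> dict:
    schedule = _schedule(m)
    cp = _cp(m)
    per100 = float(m.get("ct_ic_dose_per_100mAs", DEFAULTS["ct_ic_dose_per_100mAs"]))
    rows, rises, doses = [], [], []
    for run, wf in _load_runs(m):
        est = amplitude_to_rise(wf, schedule)
        setting = run.get("setting_mAs")
        ic = run.get("ic_dose_mGy")
        if ic is None and setting is not None:
            ic = per100 * float(setting) / 100.0
        rows.append(
            {"file": run["file"], "setting_mAs": setting, "ic_dose_mGy": ic,
             "fundamental_amplitude_mK": est.fundamental_amplitude,
             "heating_rate_mK_per_s": est.heating_rate_A,
             "per_cycle_rise_mK": est.per_cycle_rise}
        )
        if ic is not None:
            rises.append(est.per_cycle_rise)
            doses.append(float(ic))
    pd.DataFrame(rows).to_csv(outdir / "spectral_estimates.csv", index=False)
    summary: dict = {"cp": cp, "runs": rows}
    if len(rises) >= 2 and np.ptp(doses) > 0:
        resp = dose_response(rises, doses, cp)
        summary["dose_response"] = {
            "slope_mK_per_mGy": resp.slope_mK_per_mGy,
            "intercept_mK": resp.intercept_mK,
            "slope_uncertainty": resp.slope_uncertainty,
            "r_squared": resp.r_squared,
            "excess_factor": resp.excess_factor,
        }
    return summary


def run_pipeline(manifest_path, mode: str, outdir) -> dict:
    """Execute one analysis mode against a manifest; returns the JSON summary."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    m = load_manifest(manifest_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    opts = _analysis_opts(m)
    log.info("mode=%s manifest=%s -> %s", mode, manifest_path, outdir)

    if mode == "simulate":
        body = _run_simulate(m, outdir)
    elif mode == "6mv-midpoint":
        body = _run_6mv_midpoint(m, outdir, opts)
    elif mode == "ct-transient":
        body = _run_ct_transient(m, outdir, opts)
    else:
        body = _run_ct_fft(m, outdir, opts)

    summary = {**_summary_base(m, mode, opts), **body}
    _write_summary(outdir, summary)
    return summary
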