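# Methods

## Model and assumptions

The calorimeter signal is treated as a one-dimensional temperature record
u(t) in mK sampled uniformly in time. Under a pulse train f(t) (unit
height during beam-on), the response is modeled semi-empirically as the
convolution of f with a two-exponential impulse response plus a linear
background drift:

    u(t) = (k1 e^(−t/τ1) + k2 e^(−t/τ2)) ⊛ f(t) + slope·t + offset.

The two exponentials arise from a Newton's-law picture of conduction at two
interfaces: thermistor→core (fast, τ1 ~ seconds) and core→phantom (slow,
τ2 ~ hundreds of seconds). The model is deliberately not a solution of the
heat equation; the amplitudes absorb geometry and transfer effects. Key
assumptions:

* the response shape is dose-rate independent — amplitudes scale linearly
  with the tube current-time product (mA·s), so one (k1, k2, τ1, τ2) set
  serves a whole series when each run is scaled by setting/100;
* drift is strictly linear per run (higher-order baselines out of scope);
* dose converts to temperature through the polystyrene heat-capacity law
  Cp(T) = (1000/M)(aT⁻² + bT + c); dose = Cp·ΔT, identical numerically in
  Gy-per-K and mGy-per-mK.

Internal units are fixed: time s, temperature differences mK, absolute
temperature K, dose mGy (Gy at the 6 MV run-summary surface, where doses
are order-1 Gy). Unit conversions live only at API boundaries.

## Parameters that matter

| parameter | units | default | rationale |
|---|---|---|---|
| Cp coefficients M, a, b, c | — | 104.15, 7.755e5, 0.5345, −41.58 | published polystyrene law; Cp(297.65 K) = 1212.36 J/(kg K) |
| CT schedule | s | 2 on / 8 off × 10 cycles, dt = 0.25 | the axial-scan sequence and sampling of the CT experiment |
| 6 MV schedule | s | 60 on / 60 off × 20 cycles, dt = 1 | the therapy-beam linearity experiment |
| CT response (k1, k2, τ1, τ2) | mK/s, s | 0.27, 0.016, 1.4, 628 (per 100 mA·s) | published best-fit values; exposed as `CT_FIT_PARAMS` |
| noise σ | mK | 0.002 (CT), 0.005 (6 MV) | consistent with micro-Kelvin bridge sensitivity; free parameters of the fixtures, not measured values |
| midpoint window fraction | — | 0.5 | latter half of the pre-pulse off-segment and leading half of the post-pulse segment; balances leverage against curvature |
| post-pulse settle time | s | 0 (6 MV); 5·τ1 recommended for raw CT records | lets the fast transient decay below noise before the post-fit |
| discrete-mode compensation | — | 1/0.82 | see "Numerical choices" |
| τ search bounds | s | (0.05, 50) × (10, 1e5) | brackets the two physical time scales by two orders each way |

The amplitude convention is *per 100 mA·s*: fits to multi-rate series
return amplitudes on that scale regardless of the settings supplied. This
is the only convention under which the slow-term step k2·t_open ≈ 0.032 mK
is consistent with the staircase analysis of the normalized records.

## Synthetic-data generators

`simulate_6mv_run` produces an ideal lossless staircase: linear rise of
dose/Cp per beam-on interval, flat otherwise, plus drift and white
Gaussian noise. It emulates the megavolt regime where excess heat is
negligible. It does **not** emulate conduction losses, convection
artifacts in water, or 1/f bridge noise — so passing tests demonstrate the
*estimator* chain (windowing, extrapolation, regression), not robustness
to those effects in real records.

`simulate_ct_series` evaluates the convolution model exactly (closed form)
per setting with per-run drift and a single seeded noise stream. It
emulates waveform statistics only: no scanner geometry, rotation, bowtie
filtration or spectra. Parameter-recovery results on these fixtures bound
estimator error under the model; they cannot detect model misspecification
in measured data.

All randomness flows through the seed in `NoiseSpec`; no global RNG state
is touched, and identical seeds give bit-identical records.

## Numerical choices

* **Analytic convolution (default).** Boxcar ⊛ exponential has a closed
  form per pulse; responses are summed over pulses with `expm1` used for
  the (1 − e^(−w/τ)) factors so that τ ≫ period (staircase limit) keeps
  full precision. This mode is exact at the sample instants.
* **Discrete mode.** A right-endpoint rectangle-rule convolution at the
  sample spacing, provided to replicate coarse-step numerical analyses. At
  dt = 0.25 s it underestimates the exact integral by a few percent of the
  fast-term peak (first order in dt/τ1) and converges to the analytic mode
  as dt → 0 (< 0.1% at dt = 1 ms). A historical 18% underestimate at this
  step size cannot be re-derived because the original quadrature convention
  is unknown; the compensation is therefore a configurable multiplicative
  factor on k1 and k2 (default 1/0.82), never a derived constant.
* **Timing function.** Evaluated at sample instants with a half-open
  convention (on at the leading edge); no sub-sample pulse fractions.
* **Fitting.** The model is linear in (k1, k2) and in every drift
  parameter, so the fit uses variable projection: at fixed (τ1, τ2) all
  linear parameters are solved by `lstsq` on a stacked design with shared
  amplitude columns and per-run drift blocks; Nelder-Mead then minimizes
  the profiled residual over (log τ1, log τ2), seeded from a coarse
  log-spaced grid when no initial guess is given. Deterministic for a given
  initialization; noiseless self-consistency is at the 1e-3 level or
  better. The objective is the unit-weight chi-square (mK²) — no per-point
  σ — because the doubling criterion below presupposes an unnormalized
  objective.
* **Uncertainty intervals.** One parameter is scanned from its best value
  in each direction (geometric bracketing, then Brent root finding) until
  the chi-square reaches twice its minimum. The other transient parameters
  stay at the best fit; drift nuisances are re-optimized at each scan point
  (profile over nuisances), with a strict frozen-slice option since the
  original prescription is ambiguous. A direction that never doubles within
  the scan is flagged open, never silently truncated.
* **DFT convention.** One-sided amplitude 2|X_k|/N; the analysis window
  starts at the first pulse and spans a whole number of periods; a linear
  detrend over the window precedes the transform; the harmonic bin is
  located from the schedule (k = n·n_periods), not by peak search, making
  the readout immune to drift leakage. The record's thermal transfer
  function at the single readout frequency is absorbed into the heating
  rate A, so A is an *apparent* rate.
* **Midpoint extrapolation.** Straight-line fits (degree-1 polyfit, times
  referenced to the pulse midpoint for conditioning) on the two off-segment
  windows; at least 3 samples per window enforced. Cycle boundaries come
  from the declared schedule, never from edge detection.

## Design choices at genuinely open points

* The diffusive length estimate is implemented as r = sqrt(δ·τ): the
  product δτ alone is dimensionally a squared length, and only the square
  root reproduces the quoted ~8 mm (core) and ~0.37 mm (thermistor-scale)
  values.
* Time constants as well as amplitudes are shared across dose rates in
  multi-run fits (per-run refit of τ is not offered); the dose-rate
  independence assumption covers the shape, not just the scale.
* The excess-heat factor reports the raw ratio (e.g. 16.79 from slope
  0.0139 mK/mGy at Cp = 1208); an integer-rounding presentation flag exists
  for factor-of-N statements (15 from the staircase chain).
* The 6 MV generator omits heat loss by default (an optional slow-decay
  term exists in the CT model if needed); per-cycle dose conservation is
  then exact, which the tests exploit.

## Known limitations

* Midpoint extrapolation on the reconstructed slow term returns the
  loss-corrected step k2·τ2(1 − e^(−t_open/τ2)) ≈ k2·t_open = 0.0320 mK
  per cycle per 100 mA·s (≈ 38.7 mGy at Cp = 1208), slightly above the
  ≈ 0.030 mK / 36 mGy net per-cycle rise of the decaying staircase: the
  method cancels within-cycle conduction decay by design. Both numbers are
  reported by the package (the dose-conversion identity accepts any rise);
  the PS-component path is checked at 10% against the 0.030/36 chain.
* The fundamental amplitude of a *full* CT record (fast transient included)
  is dominated by the transient term and is therefore not a polystyrene
  dose estimate; the FFT inversion is quantitative only for staircase-like
  records, and is tested for linearity in mA·s and for oracle equivalence
  with the time-domain rise on staircases. Measured kilovolt slopes enter
  the excess-heat diagnostics as inputs.
* Chi-square-doubling interval widths scale with the record set: a single
  433-point run yields much wider τ2 intervals than an 11-run series. Since
  the measured noise level behind the published intervals is unknown, only
  same-decade agreement is checked (11-run seeded series: (−126, +200) vs
  the published (−50, +86) for τ2).
* No radiation transport, spectra, air-kerma formalism, hardware
  (bridge/lock-in) simulation, or finite-element heat modeling; inputs are
  already temperature records.

## Problem sizes

The test suite runs CT fixtures of 433 samples (10 cycles at 0.25 s plus
lead-in) and 6 MV fixtures of 2461 samples; parameter-recovery statistics
use 24 seeds (unit suite) and 9 seeds (acceptance checks), with medians
quoted. The full suite completes in a few seconds; the acceptance script
performs one CT fit and one 20-cycle midpoint analysis per invocation.
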