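# Methods

## What the package models

`cmas` is a hardware-free reimplementation of the computational core of an
open-hardware concentration measurement and adjustment system: a device that
pumps a fluidic sample (fish sperm, microalgae) past an LED/photodiode
optical module, estimates its cell concentration from the transmitted-light
voltage, and dilutes it to a target concentration by co-pumping diluent at a
computed flow ratio. The library reproduces the device's calibration
mathematics, dilution planning, pump scheduling and workflow control, and
supplies a digital twin that stands in for the instrument so the whole
closed loop can be exercised and stress-tested on a desk.

## Sensor model

The physical chain (12-bit DAC → LED at 624 nm → 1 mm of sample in
transparent tubing → photodiode → ×20 op-amp → 10-bit ADC) is not modelled
mechanistically. The twin uses the empirical log-linear response that the
calibration procedure itself assumes:

    v(c) = a · log10(c) + b,   a < 0,

valid on a concentration window [c_min, c_max]. Below `c_min` the measured
response flattens (dilute samples are optically indistinguishable), so the
twin returns the plateau value `v(c_min)`; above `c_max` the response is
clamped at `v(c_max)` rather than extrapolated toward negative voltages.
Output is always clipped to [0 V, supply]. Readings below ~0.5 V or above
~4.1 V are classified as saturated (opaque-dye and clean-water limits of the
reference build with its 1.50 V empty-tube baseline).

Measurement noise is additive Gaussian on voltage with configurable SD
(default 0.02 V — a plausible electronics-plus-pulsation scatter; the
reference experiments do not report one). Optional features, both off by
default so analytic tests stay exact: quantization to the 10-bit ADC grid,
and averaging of `n_adc_samples` draws per reading (whether the bench
instrument averaged its ADC samples is unknown, so it is a parameter, not an
assertion). Only the red LED channel is modelled.

Baseline calibration searches the 4096 DAC codes for the one whose
empty-tube voltage best matches the 1.50 V target. The search is a bisection
over the (assumed monotone) blank response with neighbour refinement, which
equals the exhaustive argmin; ties between two equally close codes break
toward the higher code so results are platform-stable.

## Calibration fitting and inversion

The curve is fitted by unweighted ordinary least squares of response on
log10 concentration, restricted to points with `concentration >= c_min`
(replicates enter individually, never pre-averaged). Including plateau
points would bias the slope and depress r²; the restricted-vs-unrestricted
r² ordering is asserted as a property test. Default validity bounds follow
the reference experiments: 1e8 cells/mL for sperm-type curves, 3e5 cells/mL
for algae-type curves; `c_max` is taken from the largest included point.

Inverse prediction solves for concentration:

    c(v) = 10^(inv_intercept − inv_slope · v),
    inv_slope = 1/|a|,  inv_intercept = b/|a|.

Two coefficient sets exist. `invert` is the exact full-precision inverse,
used everywhere internally. `rounded_estimator` reproduces the constants as
deployed on instrument firmware: the regression coefficients are first
rounded half-up to their 2-decimal report precision, then inverted, then
rounded again (slope to 3 decimals, intercept to 2). Inverting at full
precision and rounding once does not yield the deployed constants (e.g. it
gives 0.509 where firmware uses 0.508), so the two-step rule is the
documented convention.

Estimates are flagged against the validity range rather than raised as
errors. The lower bound is inclusive with a 1e-9 relative guard band: a
plateau reading inverts to ≈`c_min` exactly, and such a sample is physically
indistinguishable from one below the range, so it must flag `below_range`
deterministically despite floating-point round-trip error.

Percent transmittance from a bench spectrophotometer is converted as
`%T = 10^(2 − A)` and fitted with the same OLS machinery for method
comparison.

## Dilution planning and mixing

The dilution factor is `D = c_measured / c_target` (an error if `D < 1`:
the device can only add diluent, and failing loudly is the quality-control
intent). The diluent:sample flow ratio is `D − 1`. Mixing is ideal —
volumes add, cell count and cryoprotectant (CPA) volume are conserved; no
partial-volume corrections. The two-stage cryopreservation protocol dilutes
raw sample to an intermediate target with isotonic extender, then mixes 1:1
with double-strength CPA medium, exactly halving both concentration and CPA
fraction (2e9 cells/mL + 20% medium → 1e9 cells/mL at 10% CPA). Planning is
real-valued; quantization to pump steps happens only in the pumping layer.

## Pump scheduling

Delivered volume is `steps × volume_per_step`; `volume_per_step` (default
0.5 µL/step) is a per-build calibration constant to be measured on each
fabricated pump, not a published value. Step counts round half-up, bounding
the delivered-volume error by half a step. Each pump is rate-limited
(default 1.1 mL/min). Co-flow scheduling holds `Q_diluent/Q_sample` equal to
the planned ratio with equal durations; the binding pump runs at its
maximum and the other is scaled down, so the ceiling is never exceeded. A
sequential mode runs each pump at its own maximum instead (which of the two
the original firmware used is not documented; both are supported, co-flow
is the default). Flow is treated as continuous (the six-roller geometry
only smooths pulsation) and viscosity-independent over 0.96–1.68 cP; a
`viscosity_cp` annotation is carried but deliberately ignored.

## Workflow control and timing

One run walks the fixed state graph IDLE → PRIME → MEASURE → COMPUTE →
DILUTE → FLUSH → DONE; any undefined (state, trigger) pair resolves to an
ERROR state (saturated reading, out-of-range estimate, cannot-concentrate),
never an exception, and DONE/ERROR re-arm to IDLE. The eight states are a
faithful reconstruction of the documented workflow, not a verbatim firmware
state list. Timestamps are simulated by accumulating stage durations, so
run records are bit-reproducible; a wall-clock adapter would be an
interface concern only.

Processing time is affine in sample volume: `t(V) = 50 + 55·V` seconds,
the 50 s decomposing as 30 s tubing replacement (skippable) + 20 s priming,
and 55 s/mL being one minute per mL at 1.1 mL/min. Displayed times round
half-up (286.5 s → 287 s). The manual benchmark is 288 s/sample
(12.5 samples/h), giving a break-even volume of (288−50)/55 ≈ 4.3 mL.
Flush duration defaults to the priming duration (no published value).

## Digital twin and synthetic experiments

The twin regenerates the reference experiments: a 1:1 serial dilution series
(sperm: 10 samples from 4.0e9 cells/mL; algae: 8 from 3.6e6 cells/mL)
measured in repeated pulls (default 4; the source figures are ambiguous
between 4 and 5 replicates, so the count is a parameter), a single-blinded
estimation trial with a dedicated shuffle seed independent of the noise
seed, and closed-loop automatic dilution to 1e6 cells/mL.

Imperfections are deliberately minimal: voltage noise as above, plus a
single per-pass multiplicative `loss_fraction` of cells (tubing adhesion
and similar mechanisms are plausible but unquantified, so the twin claims a
magnitude, not a mechanism). The packaged auto-dilution scenarios use
noise_sd = 0.02 V and loss_fraction = 0.15. Under these conditions the
replayed trials land near 85% of target with CV ≈ 1–3%. The bench trials
reported 89% and 71% of target with ±12.6% and ±6.7% precision; those
numbers are treated as reference bands ([60, 100]% of target, CV ≤ 15%),
not exact targets, because matching them exactly would mean tuning the loss
fraction to the answer, and because the twin omits real variance sources
(flow-rate variation, manual chamber counting of the product, biological
heterogeneity). Passing the band check therefore shows the closed loop is
consistent with the reported behaviour, not that the twin predicts a real
instrument's error budget. Reported precision is the full-precision CV of
the simulated outcomes (sample SD, n−1 denominator); published precision
values appear to have been computed before rounding their summary
statistics and are not re-derivable from them.

## Numerical conventions

- All regression and planning math is full precision; rounding (half-up via
  `decimal`, truncation toward zero, 2-significant-figure series rendering)
  is presentation-layer only.
- Seeded `numpy` Generators drive every stochastic path; identical
  configurations are bit-reproducible across runs and platforms.
- "Hits the target exactly" in the noiseless, lossless limit is asserted at
  1e-9 relative tolerance: estimates pass through `10^log10(·)`, which is
  not bit-exact in binary floating point.
- Problem sizes in the test-suite and acceptance computations match the
  bench experiments (40-point sperm and 32-point algae calibration sets,
  5-trial dilution runs); Monte Carlo checks use 1e4 draws or 200 seeded
  repetitions, comfortably enough for the asserted tolerances.

## Known limitations

- No mechanistic optics (Beer–Lambert scattering, LED spectra) — the
  forward model is the empirical calibration itself, so the twin cannot
  predict behaviour outside the fitted ranges.
- No fluid dynamics: ideal instantaneous T-junction mixing, no pulsation,
  dead volume, or carry-over between samples.
- The loss model is a single per-run scalar; it cannot reproduce
  concentration-dependent or time-dependent losses.
- Manual-counting error on the adjusted product (how the bench trials were
  scored) is outside the twin, which reports true simulated concentrations.
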