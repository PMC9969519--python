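# cmas

Photometric cell-concentration calibration, automated dilution planning, and
a digital-twin simulator of an open-hardware concentration measurement and
adjustment system (CMAS) for germplasm cryopreservation workflows.

Cryopreservation outcomes for aquatic germplasm (fish sperm, microalgae)
depend strongly on cell concentration, yet most laboratories freeze samples
without measuring or adjusting it. The CMAS concept couples a turbidimetric
sensor (LED + photodiode reading transmitted light through 1 mm of sample in
tubing) with peristaltic pumps that co-flow sample and diluent at a computed
ratio, so a sample is measured and brought to a target concentration in one
automated pass. This package reimplements the device's computational core —
no hardware required — for anyone who wants to plan dilutions, analyse
calibration data, or stress-test the closed loop in simulation: repository
technicians, open-hardware builders, and method developers.

## The model

The sensor responds log-linearly over a validity window `[c_min, c_max]`:

    v = a·log10(c) + b,  a < 0,

fitted by OLS restricted to `c ≥ c_min` (below the bound the response
plateaus and samples become indistinguishable). Concentration is recovered
by inverse prediction,

    c = 10^(b/|a| − v/|a|),

and the dilution to a target uses factor `D = c_measured/c_target` with
diluent:sample flow ratio `D − 1`. Reference curves are packaged for channel
catfish sperm (`v = −1.9658·log10(c) + 19.702`, valid above 1e8 cells/mL)
and *Tetraselmis chuii* algae (`v = −2.9698·log10(c) + 20.94`, valid above
3e5 cells/mL). A finite-state machine (IDLE → PRIME → MEASURE → COMPUTE →
DILUTE → FLUSH → DONE, faults to ERROR) orchestrates runs; a digital twin
supplies noisy measurements and a configurable cell-loss fraction so the
whole loop runs without an instrument. See `docs/methods.md` for the full
model description and its limitations.

## Worked example

```python
from cmas import (CalibrationModel, TwinConfig, generate_calibration_dataset,
                  plan_dilution, rounded_estimator, simulate_auto_dilution)
from cmas.scenarios import ALGAE_CURVE, ALGAE_SERIES

# regenerate the algae serial-dilution experiment on the twin and refit it
twin = TwinConfig(noise_sd=0.02, rng_seed=42)
points = generate_calibration_dataset(ALGAE_CURVE, ALGAE_SERIES, n_pulls=4, twin=twin)
fit = CalibrationModel(points, c_min=3e5, label="Tetraselmis chuii").fit()
print(fit.summary())
```

```
Log-linear calibration fit [Tetraselmis chuii]
==========================================================
response = slope * log10(concentration) + intercept  [V]
slope      -2.98917  (SE 0.00915)
intercept   21.0609  (SE 0.0559)
r-squared  0.9999
points     16 used, 16 below c_min excluded
validity   [3e+05, 3.6e+06] cells/mL
inverse    c = 10^(7.04573 - 0.334541 * reading)
```

The fitted slope and intercept recover the generating curve to within their
standard errors; half the series lies below the 3e5 cells/mL validity bound
and is excluded as plateau data. Planning and closed-loop simulation:

```python
plan = plan_dilution(c_measured=3.6e6, c_target=1.0e6, sample_volume_ml=1.0)
print(f"D = {plan.factor_d}, flow ratio = {plan.flow_ratio:.1f}, "
      f"diluent = {plan.diluent_volume_ml:.1f} mL")

result = simulate_auto_dilution(
    3.6e6, 1.0e6, n_trials=5,
    twin=TwinConfig(noise_sd=0.02, loss_fraction=0.15, rng_seed=1),
    curve=ALGAE_CURVE)
print(f"auto-dilution: mean {result.mean:.3g} cells/mL "
      f"({result.pct_of_target:.0f}% of target, CV {result.precision_pct:.1f}%)")
```

```
D = 3.6, flow ratio = 2.6, diluent = 2.6 mL
auto-dilution: mean 8.53e+05 cells/mL (85% of target, CV 1.4%)
```

A 3.6e6 cells/mL culture needs a 3.6-fold dilution (2.6 mL of diluent per mL
of sample); with 0.02 V measurement noise and a 15% cell-loss fraction, five
simulated closed-loop trials average 85% of the 1e6 cells/mL target with a
1.4% coefficient of variation.

The same operations are available on the command line:

```sh
cmas plan --measured 3.6e6 --target 1e6 --volume 1.0
cmas time --volume 4.3
cmas generate --scenario sperm_calibration --out points.csv --seed 1
cmas fit --csv points.csv --c-min 1e8
cmas run --config run.yaml --log events.jsonl
```

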