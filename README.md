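# spermca

Compartmental modeling of cytosolic Ca²⁺ homeostasis in rat round
spermatids: the dynamic response of the cytosol/ER pair to blockade of
the ER Ca²⁺-ATPase (thapsigargin), and the modulation of steady-state
cytosolic Ca²⁺ by extracellular lactate through ATP availability.

The package provides:

- **`spermca.model_core`** — a closed three-compartment model (cytosol,
  ER, acidic vesicles) with conserved total calcium, and the reduced
  two-variable post-blocker system
  `d[Ca]cyt/dt = p − q·[Ca]cyt + r·[Ca]ret − d·[Ca]cyt²`,
  `d[Ca]ret/dt = g·([Ca]cyt − [Ca]ret)`, with adaptive Runge–Kutta 4(5)
  integration, the analytic steady state, and the composition of the
  reduced constants from physical cell constants.
- **`spermca.steady_state`** — the lactate → ATP → pump-saturation
  model: stationary ATP, the saturation factor
  `h(L) = (ϕ + ωL/(K_L+L)) / (1 + ϕ + ωL/(K_L+L))`, and the steady-state
  quadratic `δ·h(L)·x² + B·x − 1 = 0` for both conditions, plus
  condition contrasts.
- **`spermca.fitting`** — Nelder–Mead trace fitting on log-parameters,
  exponential-decay steady-state extrapolation, dose-response fitting
  (with a descending-step coordinate-descent alternative and a two-stage
  protocol), R², and cross-fit summary statistics (mean, CV%,
  mean/initial ratios).
- **`spermca.synthetic_data`** — seeded generators for noisy traces,
  cohorts with log-normally dispersed constants, and dose-response
  tables.
- **`spermca.cli_io`** — CSV/JSON formats, packaged fixtures carrying
  the published tables, a reproduction harness, and the CLI.

Units package-wide: concentrations nM, time s, volumes dm³, areas dm²,
lactate and ATP mM.

## CLI

```sh
spermca simulate --params params.json --out trace.csv
spermca fit-trace trace.csv --init params.json --out fit.json
spermca fit-steady-state dose.csv --init ss.json --fix omega,k_l,b
spermca extrapolate trace.csv --from-time 600
spermca summarize fit1.json fit2.json --initial params.json
spermca generate trace|cohort|dose --spec spec.json --seed 1 --out dir/
spermca reproduce [--json]
```

`spermca reproduce` recomputes every reference quantity from the
packaged fixtures and prints a pass/fail table (nonzero exit on any
failure). Logging goes to stderr; repeat `-v` for more detail.

Trace CSV format: header `time_s,ca_cyt_nM`, with an optional comment
line `# thapsigargin_time_s=<float>`. Dose-response CSV format:
`lactate_mM,ca_ss_nM,sem_nM`.

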