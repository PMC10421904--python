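# saltmir

An ODE model of how salt stress modulates the miR165/166–PHB–cytokinin
incoherent feedforward loop in the Arabidopsis root apical meristem, with
everything needed to test it end-to-end offline:

- **`saltmir.model`** — parameters, state, genotypes (`wild_type`,
  `phb_1d`), piecewise-constant salt forcing, and the ODE right-hand
  side. The printed repression terms are ambiguous, so three repairs are
  available as *dialects* (`multiplicative` [default],
  `subtractive_clamped`, `literal_plus`); the first two coincide exactly
  at salt = 0 with default parameters.
- **`saltmir.steady`** — steady-state solver (damped fixed-point
  iteration + Newton polish) and salt-gradient sweeps over [0, 10] with
  continuation.
- **`saltmir.timecourse`** — adaptive Runge–Kutta integration restarted
  at protocol breakpoints, including the reference perturbation: step
  salt 0 → 0.5 at t = 0 from the pre-step steady state, total time 50.
- **`saltmir.synth`** — synthetic qRT-PCR-style 2^−ΔΔCt fold-change
  datasets (miR166 and PHB vs. untreated control) for a 150 mM NaCl
  time course (0.5–4 h) and a 0/100/150/200 mM dose–response at 5 h,
  with seeded multiplicative lognormal replicate noise. Doses map
  linearly to model salt through the anchor 150 mM ↔ salt 0.5 (`s_ref`);
  model time maps to hours via `time_scale` (default 2 units/h).
- **`saltmir.inference`** — least-squares fitting of identifiable
  parameters (`s_ref`, `dmiR`, `alphamiR`, `time_scale`) on log2 fold
  changes, multi-start and seeded, with an exhaustive grid-search
  cross-check.
- **`saltmir.cli`** — `saltmir` command with subcommands `steady`,
  `simulate`, `fig4`, `synth`, `fit`.

In the `phb_1d` genotype the miR-induced PHB degradation route is
switched off; the model then shows elevated cytokinin and complete salt
resistance of PHB and CK, while wild type responds to salt with lower
miR165/166 and higher PHB and cytokinin.

## CLI

Every command takes `--out DIR` (writes TSV tables plus a
`manifest.json` capturing the fully resolved configuration) and
optionally `--config FILE` (flat YAML; a previously written
`manifest.json` can be replayed as a config), `--genotype`, `--dialect`,
`--seed`. Defaults reproduce the reference setup with no config at all.

```sh
saltmir steady --out out/steady                 # steady-state sweep, salt 0..10
saltmir simulate --out out/sim                  # salt-step time course to t=50
saltmir fig4 --out out/fig4                     # 4 panel tables: {wt,phb1d} x {sweep,step}
saltmir synth --out out/data --seed 1           # synthetic fold-change dataset
saltmir fit out/data/dataset.tsv --out out/fit  # fit s_ref to a dataset
```

Example config keys: model parameters (`alphaCK`, `betaCK2`, …, `n`,
`dialect`) plus per-command settings (`n_points`, `t_end`,
`noise_sd_log2`, `free_params`, `bounds`, …); unknown keys are rejected.

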