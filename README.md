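# ocumark

Markov cohort cost-utility model comparing two anti-VEGF strategies
(brolucizumab vs aflibercept) for neovascular age-related macular
degeneration, from the Italian National Health Service and societal
perspectives.

The model tracks a cohort of 75.8-year-old patients across six
visual-acuity bands (ETDRS letters, best 86–100 to worst ≤25) over
annual cycles. Annual transition matrices are derived parametrically
from trial BCVA-change summaries: letter changes are assumed
Normal(mean, SD), and the normal CDF at the ±7.5 / ±22.5 letter
cut-offs gives the probabilities of moving one or two bands (at most two
per cycle). The engine layers age/sex mortality, bilateral-disease
accrual and an optional discontinuation flow on top, and the outcome
layer accumulates discounted life-years, QALYs (state utilities minus
injection discomfort and adverse-event disutilities) and per-category
costs. Incremental analysis (ICER, dominance, net monetary benefit),
one-way deterministic sensitivity analysis (tornado) and a seeded
probabilistic sensitivity analysis (beta/gamma/normal families, method
of moments) sit on top.

## Command-line interface

```sh
ocumark validate                      # check a config (defaults if none)
ocumark run   --out-dir out           # base-case comparison
ocumark run   --perspective societal  # societal-perspective scenario
ocumark run   --horizon 40            # long-horizon scenario
ocumark dsa   --out-dir out           # one-way tornado analysis
ocumark psa   --n-reps 1000 --seed 1  # probabilistic analysis
ocumark make-fixtures                 # write synthetic inputs to CSV/YAML
```

`run` writes `results.txt` (rounded, table-style), `results.csv` /
`results.json` (full precision), per-strategy cohort traces and a
`manifest.json` recording the resolved-config hash and seed. `dsa`
writes `tornado.csv`; `psa` writes `ce_plane.csv`, `ceac.csv` and
`psa_summary.json`.

All inputs can be overridden with a YAML document passed via
`--config`, e.g.:

```yaml
settings:
  horizon: 40
  perspective: societal
costs:
  vial_price:
    brolucizumab: 700.0
baseline:
  occupancy: [0.03, 0.20, 0.42, 0.29, 0.06, 0.004]
```

## Synthetic stand-ins

Two model inputs are not available in machine-readable form and ship as
documented synthetic stand-ins in `ocumark.synthetic`:

* the baseline visual-acuity distribution
  (`STANDIN_BASELINE_OCCUPANCY`, a discretized Normal(60.6, 13.2) letter
  score) — override it via the config if you have the trial values;
* the 2018 Italian life table, emulated by a Gompertz–Makeham hazard
  calibrated to the observed life expectancies at age 75.8 (12.9 y
  women, 10.8 y men). A real table can be supplied as CSV
  (`age,sex,qx`) through `--life-table`.

The same module provides the individual-level Monte-Carlo oracle used to
validate the parametric transition estimator.

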