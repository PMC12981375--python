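# scmpanel

Synthetic-control analysis of multi-brand weekly retail sales panels, with
placebo-based permutation inference and a synthetic-data generator so the
full pipeline is testable without licensed scanner data.

Given a long-format table of weekly equivalized unit sales for ~52 brands
over a year, the pipeline:

1. **Standardizes** each brand's series using pre-intervention statistics
   (z-score by default; min-max and robust/IQR rescaling as sensitivity
   checks), keeping the affine parameters for exact back-transformation.
2. **Fits synthetic-control weights** for the treated brand — a convex
   combination of donor brands minimizing pre-intervention discrepancy
   (non-negative weights summing to 1, solved by penalized NNLS with an
   exact active-set polish).
3. **Runs placebo inference**: every brand is refit as if treated, the
   post/pre MSE ratios are ranked, and Fisher-exact-style overall and
   week-specific p-values are the share of units at least as extreme as
   the treated one.
4. **Back-transforms** standardized gaps into unit-scale effects
   (cumulative equivalized-unit reduction, final-week percent reduction)
   and assembles a cross-method sensitivity table.

## CLI

```bash
# generate a synthetic 52-brand x 52-week panel with a 68.5% ramped effect
scmpanel generate --out panel.csv --truth truth.json --seed 7

# full pipeline, one standardization method
scmpanel run --panel panel.csv --treated TREATED --method zscore --out results/run

# compare all three standardization methods
scmpanel sensitivity --panel panel.csv --treated TREATED --out results/sens
```

`run` writes gap series, donor weights, placebo MSE-ratio ranks, weekly
p-values, and a JSON manifest; `sensitivity` writes the one-row-per-method
comparison table. Study windows default to weeks 1–19 (pre), 20–30
(intervention), 31–52 (post) and can be overridden through a YAML config
(`pre_end`, `intervention_end`, `treated_id`, `schema`, `exclusions`).

## Library

```python
from scmpanel import (
    GeneratorConfig, generate_panel, StudyWindows,
    standardize_panel, placebo_analysis, effect_summary, effect_window,
)

cfg = GeneratorConfig(seed=7)
panel, truth = generate_panel(cfg)
std = standardize_panel(panel, cfg.windows, method="zscore")
placebos = placebo_analysis(std, cfg.windows)
effect = effect_summary(placebos.treated_fit, std, panel, effect_window(cfg.windows))
print(placebos.rank_of_treated, placebos.p_overall, effect.cumulative_units)
```

## Layout

```
src/scmpanel/
  panel_io.py        # read/validate/filter/write panels, study windows
  standardize.py     # zscore / minmax / robust rescaling, back-transform
  scm_core.py        # simplex-constrained least squares, synthetic series
  inference.py       # placebo analysis, MSE ratios, permutation p-values
  effects.py         # unit-scale cumulative and percent effects
  sensitivity.py     # cross-method orchestration
  synthetic_data.py  # seeded panel generator with ground-truth record
  cli.py             # click command group
tests/               # unit, property, and acceptance tests
scripts/acceptance.py
```
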