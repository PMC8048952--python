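# pyrograss

Fire-regime statistics and phylogenetic comparative models for fire-prone
grasses.

Grasses persist through fire either by resprouting from protected buds or by
re-seeding after adult death. Which strategy wins is expected to depend on
the fire regime a species actually experiences — how often fire returns, how
intense it is — and on drought, which shapes both fuels and recruitment.
`pyrograss` implements the full analysis chain needed to test these ideas
from occurrence records and satellite burn histories:

- **Occurrence QC** (`pyrograss.occurrence_qc`): coordinate validity and
  precision filters, human-influence (HII > 30) exclusion with a
  protected-area exemption, pre-1980 date filter, minimum-sampling filter,
  and optional spatial thinning, with per-step attrition reporting.
- **Fire return interval** (`pyrograss.fire_frequency`): burn-date series in
  a fixed observation window give complete inter-fire intervals plus two
  open tails per burnt pixel. A Weibull interval distribution is fitted by
  maximum likelihood with the open tails treated as censored observations
  (the leading tail as a forward recurrence time of the stationary renewal
  process), and the median fire return interval is

      FRI = b (ln 2)^(1/c)

  with scale *b* and shape *c*. Species are classed fire-prone by a
  break-point regression threshold on the proportion of records in burnt
  pixels, and FRIs outside 1–100 yr are treated as unresolved.
- **Fire intensity** (`pyrograss.fire_intensity`): per-species 95th quantile
  of fire radiative power (FRP, MW) after discarding detections below 50%
  confidence.
- **Drought** (`pyrograss.drought_index`): Foley's drought index,
  FDI(m) = (Σ rain over the 36 months ending at m − 3·MAP) / MAP, with MAP
  from a 1901–2003 baseline.
- **Comparative models** (`pyrograss.phylo_models`): phylogenetic logistic
  regression of strategy (0 = seeder, 1 = resprouter) on log-transformed
  fire variables and drought, with a Firth-type penalty, a
  phylogenetic-signal parameter α (tip correlation exp(−2αt/T) in divergence
  time t), and parametric-bootstrap confidence intervals; PGLS under
  Brownian covariance; leaf-trait PCA with a fixed sign convention; and the
  mortality-based strategy classifier (<30% mortality at full scorch →
  resprouter, >70% → seeder).
- **Synthetic data** (`pyrograss.synthetic_data`): seed-deterministic
  generators for window-truncated Weibull renewal fire histories, seasonal
  rainfall with drought episodes, birth–death phylogenies, logistic binary
  traits with tunable phylogenetic signal, and a full benchmark bundle with
  a ground-truth manifest.
- **Pipeline & CLI** (`pyrograss.pipeline`, `pyrograss` command): QC →
  FRI/FRP/FDI → fire-prone filter → comparative fits, end to end.

Model-like components are scikit-learn-style estimators
(`CensoredWeibull`, `BreakpointRegression`, `PhyloLogisticRegression`,
`PGLS`, `LeafTraitPCA`) with `fit`, fitted attributes (`coef_`,
`median_fri_`, …) and `get_params`/`set_params`; the module-level functions
are thin wrappers.

## Worked example

```python
import numpy as np
from pyrograss import (
    CensoredWeibull, FireHistory, extract_intervals,
    SimulationConfig, make_benchmark_bundle,
    PipelineConfig, run_pipeline,
)

# one pixel observed April 2000 - January 2020
h = FireHistory("px1", 2000.25, 2020.08, burn_dates=[2005.0, 2010.0, 2018.0])
iv = extract_intervals(h)
print(list(iv.complete), list(iv.recurrence), list(np.round(iv.censored, 2)))
# [5.0, 8.0] [4.75] [2.08]

# a full synthetic study and the comparative model
bundle = make_benchmark_bundle(SimulationConfig(seed=1))
res = run_pipeline(bundle, PipelineConfig(seed=1))
prof = res["profiles"]
print(len(prof), round(prof["median_fri"].median(), 2))
# 80 7.38
tab = res["fits"]["frequency"]["table"]
print(tab.loc[tab.term == "log_fri", "estimate"].round(3).iloc[0])
# 0.878
```

The first block splits one burn history into its two complete inter-fire
intervals (5 and 8 yr) and the two open tails (4.75 yr before the first
fire, 2.08 yr after the last). The pipeline run derives per-species
profiles for 80 synthetic species (median FRI here 7.38 yr, generated
around 7 yr) and fits strategy ~ log FRI + FDI; the positive
fire-frequency coefficient (0.878, generated at 0.84) means resprouters
sit at longer fire return intervals, the direction the generator encodes.

The same stages are available from the shell:

```bash
pyrograss simulate --out bundle/ --seed 1
pyrograss run --bundle bundle/ --out results/ --seed 1
```

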