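# manihotsim

Calibration and diagnosis of a daily cassava (*Manihot esculenta*) growth
model against multi-environment breeding-trial data.

Breeding programmes measure fresh root yield, aboveground biomass and a few
phenology traits across many location-years, but crop growth models need
cultivar-specific physiological parameters that those trials never measure
directly. This package closes that gap: it screens trials for usable genetic
signal, converts routine field measurements into the model's state variables,
estimates cultivar parameters with a staged calibration protocol, quantifies
model fit, and diagnoses where the remaining error lives (environment,
genotype, or their interaction).

## What is in the box

| Module | Purpose |
| --- | --- |
| `manihotsim.growth_model` | Daily radiation-use-efficiency crop simulator: thermal time, branching phenology, leaf canopy with cohort senescence, single-bucket water balance, demand-first assimilate allocation with storage roots as the residual sink |
| `manihotsim.field_traits` | Field measurements to model quantities: leaf-lobe allometry, LAI, fresh-to-dry conversions, phyllochron, back-estimation of fork dates from internode counts |
| `manihotsim.trial_qc` | Per-trial mixed model (harvested-proportion covariate, replicate and cultivar effects), broad-sense heritability, reliability, and the retention filter |
| `manihotsim.calibration` | Staged protocol: phenology/leaf grid search, GLUE (generalised likelihood uncertainty estimation) over the growth parameters, and a final yield-bias match |
| `manihotsim.evaluation` | Agreement statistics: Pearson r, RMSE, normalised RMSE with quality classes, Willmott's index of agreement, grouped evaluation and paired before/after tests |
| `manihotsim.gxe_deviation` | Genotype x environment analysis of observed minus simulated deviations: additive imputation, AMMI decomposition with an ANOVA table, environmental covariate correlations |
| `manihotsim.synthetic_data` | Seeded generators for weather, soils, cultivars, trials, leaf scans, phenology observations and deviation-matrix fixtures |

## Worked example

Generate a small synthetic study, screen the trials, calibrate every
cultivar, and diagnose the residual error:

```python
import pandas as pd

from manihotsim import synthetic_data as syn
from manihotsim.calibration import PriorSpec, full_protocol
from manihotsim.field_traits import dry_aboveground, storage_root_dry_weight
from manihotsim.trial_qc import qc_report

# 1. a synthetic multi-environment study: 6 location-years, 8 cultivars
envs = syn.make_study_environments(6, seed=0)
cultivars = syn.gen_cultivars(8, seed=1, priors=PriorSpec())
design = syn.StudyDesign(n_cultivars=8, n_environments=6)
plots, _ = syn.gen_trials(cultivars, envs, design, seed=2)

# 2. trial quality control
report = qc_report(plots, method="moments")
print(report[report["trait"] == "fresh_root"]
      [["trial", "H2", "reliability", "retained"]].round(2).to_string(index=False))
```

```
   trial   H2  reliability  retained
 Abuja17 0.91         0.91      True
AgoOwu17 0.92         0.92      True
Ibadan17 0.84         0.84      True
Ikenne17 0.79         0.79      True
 Mokwa17 0.94         0.94      True
  Onne17 0.90         0.90      True
```

```python
# 3. fresh plot weights -> dry per-cell observations
plots = plots.dropna(subset=["fresh_root", "fresh_aboveground"]).assign(
    storage_dry=lambda d: [storage_root_dry_weight(f, c)
                           for f, c in zip(d["fresh_root"], d["dmc"])],
    aboveground_dry=lambda d: [dry_aboveground(f) for f in d["fresh_aboveground"]],
)
obs = (plots.groupby(["cultivar", "environment"])[["storage_dry", "aboveground_dry"]]
       .mean().reset_index().rename(columns={"environment": "env"}))

# 4. staged calibration for all cultivars
result = full_protocol(obs, envs, n_draws=500, seed=0)
print(result.after[["cultivar", "r", "rmse", "nrmse", "d"]].round(2).to_string(index=False))
print("paired before/after tests:",
      {k: round(v["p"], 4) for k, v in result.paired_tests.items()})
```

```
cultivar    r  rmse  nrmse    d
   CV001 0.95  0.26  20.84 0.96
   CV002 0.78  0.46  44.56 0.87
   CV003 0.70  1.57  27.59 0.74
   CV004 0.93  0.50  30.34 0.88
   CV005 0.54  1.16  39.32 0.65
   CV006 0.95  1.48  27.20 0.80
   CV007 0.45  1.12  38.88 0.55
   CV008 0.61  1.16  25.76 0.78
paired before/after tests: {'r': 0.0008, 'rmse': 0.0254, 'd': 0.0055}
```

```python
# 5. where does the remaining error live?  AMMI on observed - simulated
import manihotsim
from manihotsim.calibration import simulate_targets
from manihotsim.gxe_deviation import build_deviation_matrix, fit_ammi

sims = []
for cultivar, row in result.params.iterrows():
    p = manihotsim.CultivarParams.default().replace(**row.to_dict())
    t = simulate_targets(p, envs).reset_index()
    t["cultivar"] = cultivar
    sims.append(t)
sim = pd.concat(sims, ignore_index=True)

dm = build_deviation_matrix(obs, sim)
print(fit_ammi(dm, n_components=3).anova.round(2).to_string())
```

```
              df  sum_sq  mean_sq     F     p  pct_total_ss  cum_interaction_pct
source
Environment    5    7.83     1.57  2.62  0.04         15.53                  NaN
Genotype       7   21.71     3.10  5.20  0.00         43.07                  NaN
Interactions  35   20.88     0.60  4.43  0.02         41.41                  NaN
PC1           11   10.78     0.98  7.28  0.00           NaN                51.66
PC2            9    7.24     0.80  5.98  0.01           NaN                86.35
PC3            7    1.77     0.25  1.88  0.20           NaN                94.84
Residuals      8    1.08     0.13   NaN   NaN           NaN                  NaN
```

The same pipeline is available from the command line:

```bash
manihotsim generate --n-cultivars 8 --n-environments 6 --seed 0 --out study/
manihotsim qc study/plots.csv --method moments
manihotsim calibrate full study/ --n-draws 500 --seed 0
manihotsim ammi deviation_matrix.csv --components 3
```

## Reproduction

Run the full test suite (the acceptance tests are in
`tests/test_acceptance.py`, one per headline requirement):

```bash
python -m pytest -o addopts= -p no:cacheprovider -q tests/
```

Recompute the numeric acceptance targets from fresh seeded data:

```bash
python scripts/acceptance.py --seed 1 --out targets.json
```

which writes, for any seed, the index-of-agreement identity (`t3`, exactly
1.0) and the mean environment and genotype shares of total sum of squares
across 20 replicates of the study-sized deviation fixture (`t5` near 70%,
`t6` near 2%).

### Known limitation

One acceptance test,
`test_glue_recovers_growth_parameters_from_16_environments`, currently
fails, and deliberately so: with a season-end aboveground-biomass likelihood
alone, the five growth parameters are not jointly identifiable. The stem
node weight and the node production slope enter yield almost exclusively
through their product, the petiole fraction's two effects on biomass nearly
cancel, and the internode-length parameter has no effect on biomass at all
(it only shapes plant architecture). The posterior therefore concentrates on
a ridge rather than on the generating point, and no amount of draws or
environments resolves it. See `docs/methods.md` for the quantitative
sensitivity analysis and what extra observations would fix it.

## Layout

```
src/manihotsim/   the package
tests/            pytest suite (unit, property, oracle and acceptance tests)
scripts/          acceptance-target recomputation
docs/methods.md   model assumptions, numerical choices, limitations
```
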