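# Methods

Assumptions, parameters, generator scope, numerical choices and limitations
of the `manihotsim` toolkit. Everything here describes what the code does —
the package is self-contained and verifiable from its own test suite.

## 1. Growth model

A daily, single-plant-scaled, radiation-use-efficiency (RUE) model of cassava
growth from planting of a stem cutting to harvest.

### Thermal time and phenology

Daily thermal time uses a trapezoidal response of the daily mean temperature
`(tmin + tmax) / 2`: zero at or below the base temperature (12 °C), linear up
to the optimum (30 °C), declining linearly to zero at the upper limit
(42 °C). Development is driven entirely by cumulative thermal time.

The shoot apex forks into `br{k}fx` branches when cumulative thermal time
passes the running sum of the branching thresholds `b01nd, b12nd, b23nd,
b34nd` (up to four forks). The branch level on any day is the number of
thresholds passed; the shoot count is the product of the branch numbers at
each passed fork.

### Canopy and assimilation

Fractional light interception follows Beer's law,
`1 - exp(-kcan * LAI)`, using the LAI of the *previous* day (explicit daily
time stepping; no within-day iteration). Daily assimilate supply is
`PARUE * par_fraction * srad * interception * stress`, converted to grams per
occupied ground area, with `stress` the water-supply/demand ratio from the
soil bucket.

### Node production and organ demands

New nodes per day are `shoots * (dtt / node_tt) * lnslp * exp(-cum_tt /
node_decay_tt) / occupied_area`; the exponential term makes node production
slow down as the plant ages. Organ demands per day:

- **Leaf**: per-node leaf area `laxs * min(1, cum_tt / 450) *
  leaf_taper^branch_level * stress` (cm²), converted to mass with the
  specific leaf area `slas` (cm²/g).
- **Stem**: `nodes * nodwt * min(1, cum_tt / 3400) *
  node_taper^branch_level`.
- **Petiole**: `lpefr / (1 - lpefr)` times the leaf demand.
- **Fibrous roots**: a fixed 15% tax on aboveground allocation.

Allocation is demand-first with proportional scaling when supply is short; a
15 g per plant cutting reserve tops up early shortfalls; any surplus after
demands spills into the storage-root pool (the residual sink). Mass balance
(sum of all pools plus senesced matter minus cumulative supply and initial
reserve) holds to better than 1e-6 t/ha and is asserted in the tests.

Leaves senesce by cohort when their age exceeds the leaf lifetime `llifa`
(°Cd); senesced mass leaves the live canopy but stays in the mass-balance
ledger.

### Water balance

A single plant-available bucket with capacity from the soil profile's
drained-upper-limit minus lower-limit water over the rooted depth. Daily
rain is capped at an infiltration limit of 50 mm; excess runs off.
Transpiration demand is proportional to intercepted radiation
(0.3 mm per MJ/m² intercepted); the stress factor is the ratio of what the
bucket can supply to that demand.

### Cultivar parameters

| Name | Meaning | Prior range |
| --- | --- | --- |
| `b01nd`–`b34nd` | branching thresholds (°Cd) | 231–1200, 80–344, 101–286, 100–250 |
| `br1fx`–`br4fx` | branches per fork | 2.0–3.8, 2.0–4.0, 1.0–3.0, 1.4–2.0 |
| `laxs` | maximum leaf area per node (cm²) | 401–920 |
| `llifa` | leaf lifetime (°Cd) | 600–1800 |
| `slas` | specific leaf area (cm²/g) | 149–280 |
| `lpefr` | petiole fraction of leaf+petiole mass | 0.2–0.3 |
| `lnslp` | node-production slope | 0.7–1.7 |
| `nodwt` | stem weight per node (g) | 1.7–6.0 |
| `nodlt` | internode length (cm) | 1.0–4.0 |
| `parue` | radiation-use efficiency (g/MJ PAR) | 1.4–2.6 |
| `kcan` | canopy extinction coefficient | 0.5–0.8 |

Species-level constants (thermal-time cardinal temperatures, tapers, node
decay scale, infiltration cap, transpiration coefficient, cutting reserve)
live in `SpeciesConfig` and are shared across cultivars.

## 2. Field-trait transforms

- **Leaf allometry**: ordinary least squares of measured single-leaf area on
  `lobe_length * lobe_width * n_lobes`; needs at least three measured scans
  and a non-constant predictor. On noise-free data the generating
  coefficients are recovered to machine precision (tested).
- **LAI** from leaf count, mean leaf area (cm²) and occupied ground area (m²)
  with the 1e-4 cm²→m² factor.
- **Dry weights**: storage roots as fresh weight times measured dry-matter
  content; aboveground dry weight as exactly one third of fresh weight.
- **Phyllochron** from two node counts and the thermal time between them;
  **fork-date back-estimation** divides the stem-section height by the
  internode length (or uses a direct internode count) and multiplies by the
  phyllochron.

## 3. Trial quality control

Per trial and trait, a mixed model `y = mu + beta*H + R + G + e` with the
harvested proportion H fixed and replicate and cultivar random. Two
estimators are provided and agree to numerical precision on balanced data
(tested at 1e-6):

- **REML** via `statsmodels` MixedLM with variance components, run at tight
  optimizer tolerances (`pgtol=1e-12, factr=10`);
- **method of moments** from the balanced-ANOVA expected mean squares after
  covariate adjustment, with negative estimates truncated at zero.

Entry-mean heritability is `var_G / (var_G + var_e / n_rep)`; reliability
uses the balanced shrinkage formula, which coincides with entry-mean
heritability under balance. A trial is retained iff at least one yield trait
has H² > 0.25 **and** reliability > 0.40, both strict.

## 4. Calibration protocol

Four stages per cultivar, seeded via spawned `SeedSequence` children so the
whole protocol is reproducible from one seed:

1. **Phenology/leaf grid search** on fork dates, branch counts and LAI
   trajectories (branching thresholds at 10 °Cd resolution, `laxs` at
   20 cm²; a one-day fork-date quantization adds roughly one day of thermal
   time to the attainable accuracy).
2. **GLUE** over the five growth parameters (`slas, lpefr, lnslp, nodwt,
   nodlt`): uniform prior draws, Gaussian likelihood on season-end
   aboveground biomass computed in the log domain (logsumexp
   normalisation, so weight underflow cannot produce NaN). The likelihood
   scale defaults to the standard deviation of the observations across
   environments, floored at 0.5 t/ha. The point estimate is the
   weighted posterior mean, clipped to the prior bounds.
3. **GLUE on storage yield** with the same machinery.
4. **Yield match**: a final bisection on `parue` (falling back to `kcan` at
   the bounds) that removes the mean storage-yield bias; it never increases
   the absolute bias (tested).

## 5. Evaluation

Pearson r, RMSE, normalised RMSE (percent of the observed mean) with
half-open quality bins (<10 excellent, 10–20 good, 20–30 fair, ≥30 poor),
and Willmott's index of agreement `d = 1 - SSE / sum((|s - ō| + |o - ō|)²)`,
which is exactly 1.0 on identical vectors. Undefined cases (single pair,
constant vectors, zero observed mean) return NaN with an explicit flag
rather than raising. Paired before/after comparisons use a paired t-test
across cultivars and require at least three pairs.

## 6. Genotype x environment deviation analysis

Observed minus simulated storage yield per cultivar-environment cell.
Genotypes missing more than 10% of environments are excluded; remaining
holes are filled by iterating the additive fit `mu + G + E` to a 1e-6 fixed
point. AMMI then double-centres the complete matrix and takes its SVD:

- ANOVA sums of squares partition the total exactly (environment + genotype
  + interaction); the interaction SS equals the sum of squared singular
  values.
- Component degrees of freedom follow Gollob: `g + e - 1 - 2m` for the m-th
  component. Main effects are F-tested against the interaction mean square,
  components against the residual interaction.
- Environmental covariates (seasonal windows of rain, radiation and
  temperature) are correlated with environment means and component loadings,
  with Benjamini–Hochberg control across the covariate family; constant
  covariates are flagged, not dropped silently.

## 7. Synthetic data generators

All generators take explicit seeds and are bit-reproducible. Scope: they
produce data *from the package's own model and noise assumptions* — they are
fixtures for testing and demonstration, not emulations of any particular
field dataset.

- **Weather**: eight West-African-style archetypes with monthly wet-season
  weights; annual rain totals land within ~15% of the archetype's target.
- **Soils**: three texture classes with seeded jitter on the water limits.
- **Cultivars**: uniform draws within the prior ranges.
- **Trials**: RCBD plot tables built from simulated cell means plus replicate
  effects, a harvested-proportion covariate effect, plot noise, per-plot
  dry-matter content and missingness. With all noise terms zero the plot
  values are exact functions of the simulated truth (tested).
- **Leaf scans**: recorded lobe dimensions are rounded to the measurement
  resolution *first* and the area generated from the rounded values, so a
  noise-free table is exactly consistent with its own predictors.
- **Deviation fixture**: an exact-orthogonality construction that hits
  prescribed environment/genotype/interaction SS shares to machine precision
  in every seed.

## 8. Numerical choices

- Explicit daily time stepping; yesterday's LAI drives today's interception.
- All stochastic code uses `numpy.random.default_rng` /
  `SeedSequence.spawn`; no global RNG state.
- GLUE weights are computed and normalised in the log domain.
- REML is run at tight tolerances so that balanced-data results match the
  closed-form ANOVA estimators (verified at 1e-6 in tests, observed ~1e-14).
- The whole pipeline is deterministic given its seeds; simulations are
  bit-identical on reruns (tested).

## 9. Limitations

**GLUE identifiability (the one failing acceptance test).** A likelihood on
season-end aboveground biomass alone cannot pin down all five growth
parameters, for structural reasons measurable in this codebase:

- `nodlt` (internode length) does not enter any mass demand or supply term
  — perturbing it across its full prior range changes simulated biomass by
  exactly 0. It is only recoverable from architecture observations (the
  fork-date back-estimation path), never from yield.
- `lpefr` raises petiole demand but lowers the leaf share of the combined
  pool; the two channels nearly cancel, leaving ~0.03 t/ha of signal across
  its prior range — far below the likelihood scale (≥0.5 t/ha).
- `slas` moves biomass by only ~0.26 t/ha across its range, also below the
  resolvable level at realistic observation spread.
- `lnslp` and `nodwt` each have strong signal (2–3 t/ha), but they enter
  stem growth almost exclusively through their product, so the posterior
  concentrates on a hyperbola-shaped ridge: the product is well identified,
  the factors are not.

The weaker property that *does* hold, and is tested, is consistency: the
normalised error of the identifiable parameters decreases when environments
and posterior draws increase. Resolving the full criterion would require
either additional observation types in the likelihood (LAI trajectories,
node counts, stem fractions) or a reparameterisation to the identifiable
combinations — both are API extensions, not tuning.

**Other limitations.**

- The water balance is a single bucket: no drainage dynamics, layered
  extraction, or evaporation from bare soil.
- No nutrient limitation, pests, or photoperiod response.
- The aboveground fresh-to-dry ratio is a fixed 1/3; real trials vary.
- The trial generator draws dry-matter content independently per plot, which
  slightly inflates fresh-weight variance relative to a shared cultivar DMC.
- AMMI significance tests assume homoscedastic cell errors; the
  Gollob df approximation is liberal for the leading components.
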