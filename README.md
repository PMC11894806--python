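# zsustain

Subtype and stage inference for regional grey-matter volumes.

Neurodegenerative syndromes such as corticobasal syndrome (CBS) are
pathologically heterogeneous: clinically similar patients may harbour
corticobasal degeneration, progressive supranuclear palsy or Alzheimer
pathology, and no imaging biomarker separates them reliably in life.
`zsustain` implements a complete, tested analysis pipeline that addresses
this with a z-score event-based subtype-and-stage mixture model: starting
from per-scan regional volumes (mm³) and covariates, it

1. **harmonizes** volumes by per-region least squares on controls
   (field strength, manufacturer, sex, age, TIV), propagated unchanged to
   cases;
2. **selects regions of interest** by case–control effect size
   (pooled-SD Cohen's *d* ≥ 0.6 by default) and converts adjusted volumes to
   atrophy-positive z-scores, `z = (μ_ctrl − x) / σ_ctrl`;
3. **fits a mixture of event sequences**: each subtype *c* is an ordering
   `S_c` of all threshold-crossing events (biomarker *i* reaches z-scores
   `z_{i1} < z_{i2} < …`), defining piecewise-linear expected trajectories;
   a subject at stage *k* of subtype *c* is modelled as
   `x_i ~ N(g_{S_c,i}(k), σ_i²)` with a uniform prior over the N+1 stages,
   so the data likelihood is
   `∏_j Σ_c f_c · (N+1)⁻¹ Σ_k ∏_i N(x_ij ; g_{S_c,i}(k), σ_i²)`.
   Sequences are found by greedy coordinate ascent with random restarts,
   the mixture grown hierarchically with EM, uncertainty quantified by
   Metropolis–Hastings MCMC (positional variance diagrams), and the number
   of subtypes chosen by CVIC = Σ_folds −2·(out-of-sample log-likelihood);
4. **assigns** any scan — baseline or follow-up — to its maximum-likelihood
   subtype and stage (stage 0 = "normal appearing", no subtype reported);
5. **validates and characterizes**: subtype stability and stage progression
   at follow-up, pathology-by-subtype χ² enrichment, per-region and
   laterality-index comparisons with Bonferroni correction.

A synthetic-cohort generator with known ground truth (default ≈252 controls
and 135 cases, two latent atrophy subtypes, uniform stage occupancy, ~1-year
follow-ups) makes every stage testable without any data download.

## Worked example

```python
import numpy as np
from zsustain import (
    default_settings, generate_cohort, default_schema,
    combine_hemispheres, fit_covariate_model, apply_harmonization,
    select_rois, to_zscores, fit_subtypes, assign_cohort,
    EventGrid, NoiseModel, FitSettings,
)

schema = default_schema()
settings = default_settings(n_controls=120, n_cases=100, seed=7)
scans, truth = generate_cohort(settings)

combined = combine_hemispheres(scans, schema)
controls = combined[combined["group"] == "control"]
hmodel = fit_covariate_model(controls, schema)
adjusted = apply_harmonization(combined, hmodel, schema)
rois, d = select_rois(adjusted, schema, threshold=0.6)
print(len(rois), "regions selected")          # -> 19 regions selected
z = to_zscores(adjusted, hmodel, rois)

grid = EventGrid.create(rois, thresholds=(2.0,), z_max=5.0)
cases = z[z["group"] == "case"]
X = cases[rois].to_numpy()
model = fit_subtypes(X, grid, NoiseModel.default(len(rois)), 2,
                     FitSettings(n_random_starts=4, seed=7))
print(np.round(model.fractions, 2))           # -> [0.48 0.52]

assignments = assign_cohort(cases, model)
print(sum(a.normal_appearing for a in assignments), "normal appearing")
# -> 3 normal appearing
```

The selected region count reflects the generator's injected case–control
effect sizes; the fitted mixture fractions approximate the generating
proportions (0.46/0.54 by default); scans whose maximum-likelihood stage is
0 show no detectable atrophy relative to controls and carry no subtype.

The same pipeline runs from a shell:

```sh
zsustain simulate --seed 7 --out-dir cohort
zsustain harmonize --scans cohort/scans.csv --out zscores.csv
zsustain fit --zscores zscores.csv --subtypes 2 --seed 7 --out model.json
zsustain assign --model model.json --zscores zscores.csv --out assignments.csv
zsustain validate --assignments assignments.csv --out report.json
# or everything at once, with artifacts stamped by config hash + seed:
zsustain run --seed 7 --out-dir run
```

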