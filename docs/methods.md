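# Methods

## Model

### Events, sequences, trajectories

The unit of progression is a *z-score event*: biomarker *i* (a
hemisphere-combined regional volume, z-scored against controls with an
atrophy-positive sign) crossing a fixed threshold `z_{i,j}`. An *event grid*
lists, per biomarker, strictly increasing thresholds `z_{i,1} < … < z_{i,R_i}`
and a ceiling `z_max_i ≥ z_{i,R_i}`; the total number of events is
`N = Σ_i R_i`.

A *subtype* is an ordering S of all N events, constrained so that a
biomarker's thresholds occur in increasing order. The expected z of
biomarker *i* at integer stage `t ∈ {0..N}` is piecewise-linear through the
anchors `(0, 0)`, `(pos(i,j), z_{i,j})` for each of the biomarker's events,
and `(N, z_max_i)` when its last event sits before stage N; if the last
event occupies stage N itself the curve is capped at that threshold. This
makes every trajectory non-decreasing, zero at stage 0, and bounded by
`z_max_i`.

### Likelihood

Observed z-vectors get independent Gaussian noise per biomarker
(`σ_i = 1` by default — natural for z-scored inputs) around the stage-t
trajectory value, a uniform prior over the N+1 stages, and a categorical
mixture over C subtypes with fractions `f_c`:

    p(x) = Σ_c f_c · (N+1)⁻¹ Σ_k ∏_i N(x_i ; g_{S_c,i}(k), σ_i²)

Trajectories are evaluated at integer stages only (no within-stage
integration). All sums of densities are accumulated in log-space with
log-sum-exp; a subject's log-likelihood is finite for any finite z-vector.

### Fitting

* **Sequence search.** Greedy coordinate ascent: from a random valid
  ordering, each event is removed and re-inserted at the valid position that
  maximizes the responsibility-weighted log-likelihood, repeating passes
  until none improves; the best of `n_random_starts` (default 25) restarts
  is kept. For N ≤ 5 the result provably matches exhaustive enumeration in
  our acceptance checks.
* **Mixture growth.** The C-subtype model grows hierarchically from the
  (C−1)-model: one cluster's mixture mass is split in half and the two
  children are seeded with *independent random valid sequences*, then the
  full mixture is refined by EM (E: responsibilities ∝ f_c × subject
  likelihood; M: per-cluster greedy re-optimization under its
  responsibilities, fractions = mean responsibility). The best of
  `n_split_attempts` (default 5) seeds per parent is kept, and a final joint
  EM runs at the target C. We deliberately do *not* seed children by fitting
  the two halves of a random bisection of the parent's members: both halves
  of a mixed cluster contain the same blend of subtypes, so their fitted
  orderings come out nearly identical and EM cannot break the symmetry —
  measured on the recovery benchmark, bisection seeding converges to a
  local optimum several log-likelihood units below both the random-sequence
  seeding and the ground-truth initialization. EM stops on a relative
  log-likelihood change below 1e-6 or 100 iterations; a cluster whose total
  responsibility collapses below one subject is re-seeded from the
  worst-fit 5% of subjects (logged).
* **Uncertainty.** Metropolis–Hastings over model space: with probability
  0.9 one random event of one random subtype is relocated to a uniformly
  random valid position (the valid-slot count for an event does not depend
  on its current position, so the move is symmetric); otherwise the
  fractions receive Gaussian jitter (step 0.01) and are renormalized.
  Acceptance probability is min(1, exp(Δ log-likelihood)). The first 10% of
  iterations are burn-in; retained samples (thinned to at most 10,000) yield
  per-subtype positional-variance matrices, P(event e at position p), whose
  rows sum to 1.
* **Model selection.** Seeded K-fold cross-validation (default K = 10): for
  each fold and each C in 1..C_max the model is fitted on the training fold
  and scored on the held-out fold; CVIC(C) = Σ_folds −2·loglik_test, and
  the C minimizing CVIC is selected.

Ties anywhere resolve to the first-encountered maximum in deterministic
iteration order. All randomness flows from one integer seed; the pipeline
fans a global seed out to per-stage seeds by fixed offsets (simulate +0,
fit +1000, MCMC +2000, CV +3000) so a single stage can be re-run
reproducibly.

### Staging and the normal-appearing rule

A scan's subtype is `argmax_c f_c · p(x|S_c)` and its stage is the argmax of
the stage posterior *conditional on that subtype* (sequential, not joint,
argmax; ties break toward the lower index/stage). Stage-0 scans are
*normal appearing* — indistinguishable from controls — and carry no subtype
label in reports or post-hoc comparisons, though they remain in staging
outputs. Follow-up scans are z-scored with the baseline-fitted
harmonization model (never refit) and assigned by the identical trained
model.

## Harmonization

Per-region ordinary least squares of hemisphere-combined volume on scanner
field strength, manufacturer, sex (0/1 indicators, control-majority level as
reference), age at scan and TIV, fitted on controls only. The adjusted
volume is `raw − (fitted − control grand mean)` — residual plus grand mean —
keeping values on an interpretable mm³ scale; by least-squares orthogonality
the adjusted control volumes are exactly uncorrelated with every modelled
covariate in-sample. A rank-deficient design (e.g. single-manufacturer
controls) raises an error naming the degenerate column. ROI selection uses
baseline scans only and pooled-SD Cohen's d with n−1 weights (the
atrophy-positive convention: d > 0 when cases are smaller); hemisphere
combination precedes both d computation and z-scoring. The laterality index
of a raw scan is |Σ left − Σ right| over paired regions divided by total
brain volume (the sum of all 24 regional volumes) × 100.

## Synthetic cohorts

The generator emulates a multi-site volumetric MRI study of corticobasal
syndrome: 252 controls and 135 cases by default; ages ≈ N(66, 8²) years,
TIV ≈ N(1.4×10⁶, 1.3×10⁵) mm³, 70% 3T scans, two manufacturers; linear
covariate effects per region (age −0.3%/year of the region mean, sex −6%,
TIV slope 0.4·mean/TIV_ref, +2% at 3T, +1% on one manufacturer — magnitudes
in the range reported for volumetric covariate adjustments). Cases draw a
latent subtype from the mixture fractions (0.46/0.54 by default, echoing the
published two-subtype split) and a stage uniform on {0..N}; their z-scores
are the subtype trajectory at that stage plus N(0, noise_sd²) noise
(controls: noise only). Volumes are `control mean − z·control SD` plus
covariate effects, and paired regions split left/right with a configurable
per-subtype asymmetry fraction plus a small split jitter (SD 0.01), so
laterality indices are positive but near-symmetric by default. Pathology
labels (CBD/PSP/AD/IDT at the published marginals 12/6/34/83 of 135) are
drawn conditionally on subtype so that P(subtype|pathology) matches the
published assignment proportions — enabling end-to-end enrichment tests.
Follow-ups (default half of cases; 1–3 visits with probabilities
0.39/0.58/0.03; interval 1.04 years) advance the latent stage by
non-negative draws, Poisson(1.5) capped at N by default. No study reports a
per-year stage-increment distribution; Poisson is a pragmatic choice for a
non-negative count of threshold crossings, fully configurable.

What the generator does **not** emulate: voxel-level anatomy, segmentation
error, scanner drift, longitudinal covariance beyond the shared scanner,
non-linear age effects, or missing data. Tests passing on these cohorts
demonstrate the estimator's correctness and identifiability under the
model's own assumptions, not performance on real MRI.

## Numerical choices and degenerate inputs

* Log-space likelihoods throughout; stage posteriors normalized within
  1e-12.
* Greedy improvements require a gain above 1e-12 to avoid tie cycling.
* `combine_hemispheres` is exact (sums), conserving total volume to the
  float unit.
* Zero control SD, zero pooled SD, dimension mismatches, unseen categorical
  levels, follow-ups without baselines, and degenerate contingency tables
  all raise explicit errors; zero-variance regions and groups smaller than
  two scans are skipped with a warning in post-hoc tests.
* χ² enrichment uses Pearson's statistic without continuity correction;
  small expected counts warn but never switch the method. Pairwise t-tests
  are pooled-variance by default (Welch available); all multiplicity
  corrections are Bonferroni.
* Stage progression compares consecutive visits by default; a
  baseline-vs-each-follow-up view is available (`from_baseline=True`).
  Denominators count follow-up comparisons (scans, not subjects); pairs
  normal-appearing at both visits are excluded.

## Problem sizes in the shipped checks

The acceptance script and test suite favour small, seeded experiments: the
brute-force search oracle uses 100 random grids with at most 5 events; the
recovery benchmark uses 300 cases, 6 biomarkers × 2 thresholds (z ∈ {2, 4},
z_max 5 — events comparable to or above the σ = 1 noise floor, so the two
reversed orderings are genuinely separable), fractions 0.6/0.4, medians
over 5 seeds; model selection uses 3-fold CVIC at reduced restarts over 10
seeds; longitudinal logic uses a noise-free cohort of 120 cases. The default
pipeline configuration in the tests uses a single-threshold grid over the 19
selected regions.

## Known limitations

* Subtype recovery accuracy is intrinsically bounded when stage occupancy is
  uniform over {0..N}: all subtypes share the stage-0 trajectory (all
  zeros) and converge to the same z_max vector at stage N, so subjects near
  either end of the timeline are ambiguous by construction — the
  Bayes-optimal assignment under the recovery benchmark's conditions
  misclassifies 12–18% of subjects depending on threshold placement. Stage
  and sequence recovery do not suffer this bound.
* The greedy search is exact on small grids but only locally optimal in
  general; restarts and MCMC mitigate, not eliminate, this.
* Mixture fractions estimated by EM shrink slightly toward 1/C because
  early-stage subjects contribute nearly flat responsibilities.
* No missing-biomarker marginalization: scans must carry every modelled ROI.
* Fold assignment in CV is by subject without stratification.
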