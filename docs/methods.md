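# Methods

This note documents the models, priors, numerical choices, and limitations
of the package. Everything stated here is computed by the test suite or the
acceptance script; nothing is an empirical claim beyond what the code
produces.

## Synthetic data: what it emulates and what it does not

The pipeline was designed around four kinds of restricted data: a large
opt-in morality survey with strong demographic self-selection, per-county
joint demographic tables, county counts of hate groups with population
exposure, and panel/crowdsourced vignette experiments with a continuous
mediator (perceived moral wrongness, PMW) and four 7-point justification
items. The generators reproduce the *structural* features the estimators
must cope with:

- **Geography.** A rook-adjacency rectangular lattice with contiguous
  region bands stands in for the county/state map. This reproduces the one
  property that drives the fixed-effects discussion — low within-region
  variance of smooth spatial fields — but not the irregular degree
  distribution or islands of real county maps (islands are supported by the
  graph type and the ICAR code, just not produced by the lattice
  generator).
- **Demographics.** Six variables with (2, 3, 4, 3, 3, 3) levels — 648
  cells — with a national joint built as a product of plausible margins
  perturbed by a seeded log-linear interaction (the real external joint is
  unavailable). Per-area joints are Dirichlet perturbations of the national
  joint (`concentration` controls heterogeneity; 300 in the default study
  conditions, i.e. modest between-area composition differences), converted
  to integers by largest-remainder rounding so populations are conserved
  exactly.
- **Selection bias.** Default opt-in weights overrepresent liberal
  respondents 6:1 versus conservatives and college-educated 4:1 versus
  high-school-or-less, mimicking a self-selected morality website panel.
  Bias acts only through the six modeled demographics; real opt-in surveys
  also select on unmodeled traits, so passing recovery tests here shows the
  estimator corrects *modeled* selection, not arbitrary selection.
- **Latent surface.** `latent = rho * spatial + (1 - rho) * iid`, the
  spatial part drawn from a variance-scaled ICAR distribution
  (sum-to-zero per connected component). Defaults for the study conditions:
  spatial_sd 0.5, iid_sd 0.15, rho 0.85 on a roughly 1–6 moral-value scale
  — strong but not total spatial structure.
- **Counts.** Negative-binomial with log link, exposure = population /
  10,000 (rates per 10,000 inhabitants), dispersion 2 by default; mean
  count near one per area matches the sparsity of hate-group counts.
- **Experiments.** PMW means by arm are calibrated to the published
  descriptive pattern (control ≈ 2.15, violation arms ≈ 5.55 / 5.48 on the
  1–7 scale, residual sd 1.7); justification items use six cutpoints chosen
  to give right-skewed responses (control-arm medians 1–2). PMW is left
  continuous and unclipped so the linear mediator model is well specified;
  clipping to the printed scale would truncate the tails and is not
  emulated. The latent justification scale applies the b path to
  sample-standardized PMW — the same standardization the analysis models
  use. The instrument's response scale bounds are configuration, not fact:
  published means near 4.1–4.6 suggest a 1–6 scale for the value subscales,
  and the generators treat scale location as arbitrary.

Every generator returns a `TruthRecord` (latent fields, effect values,
path coefficients, seed) and is byte-reproducible from (config, seed).

## Small-area model

Gaussian response model on the continuous subscale scores (the individual
items are never modeled here; whether the original response model was
Gaussian on subscale means or ordinal on items is not documented — Gaussian
is assumed because the scores are means of many items). Priors: N(0, 10)
intercept, half-normal(1) on all hierarchical SDs, N(0, 1) on standardized
area-covariate slopes, half-normal(2) on the residual SD. The area effect
is ICAR + iid; the graph Laplacian is rescaled per connected component so
the ICAR marginal variances have geometric mean 1 (BYM2-style scaling),
making `sd_spatial` and `sd_iid` comparable; `spatial_mix =
sd_s^2/(sd_s^2+sd_u^2)` is reported per draw. The ICAR part carries a soft
sum-to-zero constraint per component (sum ~ N(0, (0.001 |c|)^2)); singleton
components are pinned at zero.

Fitting is blocked Gibbs: every location block (intercept, each
demographic factor, regions, slopes, spatial, iid) has a conjugate Gaussian
conditional; scale parameters are updated by stepping-out slice sampling on
the log scale. Two implementation details matter:

- **Translation moves.** The likelihood identifies only the sum of the
  intercept and the block means, so plain Gibbs random-walks along that
  ridge. After each sweep the sampler draws the exact Gaussian conditional
  of a joint shift (block minus m, intercept plus m) for every additive
  block, which restored split R-hat from ~2 to ~1.1–1.2 at the default
  problem sizes.
- **Identifiability of effects.** Demographic effects are reported and
  tested as within-factor contrasts (centered); their absolute levels trade
  off against the intercept by construction.

`pooling="none"` replaces the additive demographic effects with a single
flat-prior cell factor, which makes the poststratified estimate equal the
direct cell-stratified weighted mean (the oracle used in the tests).
Prediction for demographic levels never seen in the survey draws from the
pooled prior N(0, sd_v) per posterior draw rather than erroring, since a
synthetic frame can contain cells a biased survey missed. Default sampler
settings are 4 chains × 1000 draws after 1000 warmup; the tests and
acceptance script use 2 × 300/300, which suffices for posterior means of
linear functionals at these problem sizes.

Poststratification weights are the frame cell counts normalized within
area; areas with zero population are an explicit error. Validation reports
Pearson r, t = r sqrt(df)/sqrt(1-r^2) on df = n-2, and RMSE.

### Synthetic joint by IPF

`synthesize_joint_ipf` is classic iterative proportional fitting: start
from the external joint, rescale along each variable to match that
variable's margin, and iterate until the largest margin deviation is below
`tol` (relative to the area total). Margins whose totals disagree across
variables, required mass on zero-support slices, and non-convergence are
explicit, area-named errors. Output cell counts are real-valued (they are
poststratification weights, not people).

## Spatially filtered count model

The Moran basis is the eigendecomposition of `M = (I - 11'/n) A
(I - 11'/n)`; vectors are returned in decreasing-eigenvalue order with each
vector's Moran's I. Only positive-eigenvalue vectors (positive spatial
autocorrelation) are used; if a degenerate graph has none, the remaining
nonzero-eigenvalue vectors are returned with a warning. The default basis
size is the number of vectors with Moran's I > 0.25, capped at n/10 — the
basis size used originally is not documented, and this default keeps the
filter well below the sample size.

Likelihood: NB2 with log link and log-exposure offset. Priors: N(0, 5)
intercept, N(0, 1) per-SD covariate slopes, gamma_j = lambda *
gamma_tilde_j with gamma_tilde ~ N(0, 1) and lambda ~ half-normal(1) (a
shared, estimated shrinkage scale — the filter coefficients vanish when
the data carry no spatial residual), log(phi) ~ N(0, 1.5). Covariates are
z-scored inside the fit and the transform is stored with the draws.
Sampling is NUTS (below). Intervals are central 2.5/97.5 percentiles and
are labelled as such; the exponentiated coefficient is labelled a *rate
ratio* (the original write-up calls it an odds ratio, but the model is a
rate model).

The published outcome was an *average* count over several years, which is
non-integer; this implementation requires integer counts and documents
sum-then-offset (sum the counts, multiply the exposure by the number of
years) as the supported translation.

The ML fixed-effects variant uses the standard NB2 maximum-likelihood
regression with optional region dummies; singleton regions are dropped with
a warning (they contribute no within-region contrast), and rank-deficient
designs fail naming the offending column. Under a region-confounded
covariate with low within-region variance the FE coefficient attenuates
and its standard error inflates — the qualitative behavior is asserted in
the tests; magnitudes are data-specific.

## Ordinal outcome model

Cumulative logit with 7 categories and 6 cutpoints, parameterized as a free
first cutpoint plus five positive log-gaps (ordering holds by
construction). Priors: N(0, 5) on fixed effects and the first cutpoint,
N(0, 1.5) on log-gaps, half-normal(2) on all random-effect SDs;
participant and item intercepts and item slopes are non-centered standard
normals. Interval probabilities are evaluated tail-stably (complementary
sigmoids in the far tail) and gradients are analytic.

Category probabilities and exceedance probabilities marginalize the
participant intercept by Monte Carlo over fresh N(0, sd_p) draws (default
200 per posterior draw) because the quantities of interest are
population-level; conditioning on a typical participant (`re_policy="zero"`)
is available. "At least slightly justified" maps to response >= 2 on the
1–7 scale by default (the category index is not documented; it is a config
default here). Cronbach's alpha uses the classical formula with the Feldt
F-distribution interval and is cross-checked against an independent
implementation in the tests.

## Mediation

The mediator model is a Gaussian linear regression of z-scored PMW on
treatment, values, interactions, and covariates, sampled exactly under the
reference prior (normal–inverse-gamma posterior) — conjugacy makes MCMC
unnecessary and removes one source of Monte Carlo error. Fitting the model
to the z-scored mediator is equivalent to standardizing counterfactual
mediator values with the observed mean/SD, and the outcome model consumes
the same column.

Counterfactual units are the observed participant covariate profiles.
Per posterior draw, mediator residual noise is shared across treatment
levels (common random numbers), and because every model term is a product
of columns, the outcome linear predictor is linear in the mediator —
`eta = A_t + B_t m` — which lets the four p(t, m) surfaces be computed
with two design evaluations per treatment arm. Effects are averaged over
treatment arms (½[e(0)+e(1)]; the reporting convention was not stated) and
`total = ACME + ADE` holds to machine precision per draw because all three
average the same simulated units. The mediation is full-Bayesian (effects
computed per posterior draw); a quasi-Bayesian normal approximation was the
other defensible reading and is not implemented. `scale="latent"` reports
effects on the latent justification scale, where a no-interaction model
reduces ACME to the product of coefficients (used as a closed-form oracle).
`proportion_mediated` is ACME/total per draw, summarized over draws where
the total is nonzero.

Moderated mediation pins the moderator at −1 and +1 SD in the mediator and
outcome models *simultaneously*, reuses the same posterior draws and the
same simulated noise at both levels, and reports the per-draw high-minus-low
ACME contrast with a central interval. Treatment is a named column with
configurable endpoint values, so the observational studies (a 1-SD increase
in binding values) and the randomized designs (0/1 condition dummy) share
one code path.

No sensitivity analysis for sequential ignorability is provided; the
computed decomposition is a statistical one and carries no identification
claim beyond it.

## Samplers

- **NUTS**: recursive No-U-Turn sampler (slice variant) with dual-averaging
  step-size adaptation (target acceptance 0.85–0.9), a diagonal mass matrix
  estimated from a middle warmup window (variance regularized toward a
  small constant), a generous terminal window for step-size
  re-equilibration, and max tree depth 8. Energy errors above 1000 are
  divergences; non-finite log densities or gradients in the tails are
  treated as divergent transitions (never as acceptances), and the initial
  step-size search is capped — both guards exist because overflow-induced
  NaN energies otherwise corrupt the dual-averaging statistics.
- **Gibbs** for the Gaussian multilevel model, as above.
- **Slice sampling** (univariate, stepping-out) for scale hyperparameters.
- Split R-hat and bulk ESS are computed with `arviz` for every stored
  parameter; divergence counts are recorded on every NUTS fit. Posterior
  draws are stored as (chain, draw, ...) arrays in a `PosteriorDraws`
  container shared by all stages.

## Problem sizes and numerical choices

The tests and the acceptance script run deliberately small configurations
chosen to keep full replication loops cheap while leaving the recovery
margins wide: 25-area lattices with n = 2000 surveys and 2 × 300/300 Gibbs
chains for small-area recovery (20 replicates); 200-area count simulations
with a true rate ratio of 1.3 and 2 × 300/300 NUTS chains (20 replicates);
240-participant three-arm experiments with 2 × 200/200 chains for the
moderated-mediation loops. Replicate-rate assertions use binomial
thresholds (17/20 or 18/20) rather than single-interval checks, since one
95% interval misses 5% of data realizations by construction. Coefficient
tables round to 2 decimals; raw draws are written at full precision.

## Known limitations

- The lattice geography has no irregular adjacency, and the region bands
  are deterministic; real state nesting is messier.
- Selection bias operates only through modeled demographics (see above).
- The Gaussian small-area model does not propagate ordinal item structure
  into the subscale scores.
- The NB spatial filter can tension with a covariate of interest that is
  itself spatially smooth (e.g., an MrsP estimate): with few areas the
  basis and the covariate compete, and accidental spatial confounding in a
  given data realization is reported faithfully rather than removed.
- Mediation draws require the mediator and outcome fits to carry the same
  number of posterior draws; the pipeline presets guarantee this.
- No category-specific (non-proportional-odds) effects; no CAR-error NB
  variant; no raking beyond the supplied margins.
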