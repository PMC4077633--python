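# Methods

## Normative model

Each voxel (and each global tissue volume) is modeled independently as a
zero-mean Gaussian process over covariate space with a squared-exponential
ARD kernel plus i.i.d. Gaussian observation noise:

    y_i = g(x_i) + eps_i,  eps_i ~ N(0, sigma^2),  g ~ GP(0, k),
    k(x_p, x_q) = a * exp(-1/2 * sum_k (x_pk - x_qk)^2 / l_k^2)

Hyperparameters `(a, l_1..l_m, sigma^2)` are selected per target by
maximizing the log marginal likelihood

    log p(y|X) = -1/2 y'C^-1 y - 1/2 log|C| - n/2 log 2pi,   C = K + sigma^2 I

in log-parameter space with analytic gradients
(`grad_j = 1/2 tr((aa' - C^-1) dC/dtheta_j)`, `a = C^-1 y`). The zero-mean
prior is imposed on mean-centered targets; the training mean is restored
at prediction. The predictive distribution for a new subject is the
standard conditional Gaussian; the reported z-score
`delta = (y* - mean)/u` uses the *observation* variance
`u^2 = latent posterior variance + sigma^2`, so that delta is standard
normal for subjects drawn from the training population. Negative delta
means less volume than predicted (atrophy).

Assumptions: smooth latent trajectories in covariate space (SE kernel);
Gaussian residuals (motivating the Box–Cox step); voxelwise independence
(no spatial model); covariates observed without error and identically
distributed between training and test samples.

## Tunable parameters

| Parameter | Default | Meaning / rationale |
|---|---|---|
| `FitConfig.n_restarts` | 3 | Multi-restart L-BFGS in log space; first start is data-driven, later starts add N(0, 0.5^2) jitter to the log parameters. The evidence surface can be multimodal; one start is often enough at n in the hundreds and is used in the bulk experiments. |
| initialization | `log a = log var(y)`, `log sigma^2 = log(var(y)/2)`, `log l = 0` | Splits observed variance evenly between signal and noise; unit length scale is natural because covariates are z-standardized. |
| jitter | `1e-8 * a`, escalate x10 to `1e-2 * a` | Cholesky safeguard; failure after escalation reports an ill-conditioned kernel. |
| Box–Cox `lambda` | ML in [-3, 3] | Bounded scalar search of the profile likelihood; boundary solutions are flagged, not rejected. |
| Box–Cox shift | `1e-4 - min(y)` when `min(y) <= 0` | Modulated volume data may contain zeros in-mask; the shift is stored in the model and reused at test time (test values are clipped to the positive domain rather than rejected). |
| mask threshold | mean volume > 0.05 | Auto-derivation of the analysis mask when none is supplied. |
| covariate standardization | per-column z-score, training statistics | Makes ARD length scales comparable; binary columns (sex, fstr in {0,1}) are standardized like the rest. Test data always use the training shift/scale. |

Units: ages in years; volumes in milliliters for real data, in the
simulator's modulated-volume units (around 1) for synthetic data.

## Numerical choices

* Evidence and prediction reuse one cached Cholesky factor per model;
  latent variances are clipped at 0 from below (they can round negative
  at machine precision for training-point queries).
* The Box–Cox forward map uses `expm1(lambda*log y)/lambda`, which is
  exact in the small-lambda limit and continuous at `lambda = 0`; the
  profile likelihood uses the ML (1/n) residual variance about the
  transformed mean (intercept-only residual model — the transform is an
  independent preprocessing step before the GP, so no covariate
  regression enters its likelihood). A zero residual variance returns
  `-inf` rather than raising.
* The Taylor rescale divides transformed data by
  `f_lambda'(mu) = mu^(lambda-1)` with `mu` the training mean, restoring
  the raw-data variance to first order so voxelwise scales remain
  comparable after transformation.
* Per-voxel seeds are `master_seed XOR linear_voxel_index` (masked to
  31 bits), making each voxel's fit a pure function of its data and seed;
  chunked and single-pass training agree bit-for-bit.
* Naive-Bayes posteriors are computed in log space with
  log-sum-exp normalization; any non-finite per-voxel likelihood is a
  hard error (no silent marginalization).
* Degenerate constant targets: the evidence is evaluated with variance
  floored at 1e-12, yielding a finite optimum with near-zero `a + sigma^2`.

## Simulator

`gpnorm.simulate` draws ensembles of individual quadratic lifespan
trajectories from a two-level mixed-effects model: per-subject parameters
`theta ~ N(theta_mean, diag(theta_var))`, a single observation per
subject at an age uniform on [20, 90] years, and Gaussian measurement
noise. Presets:

* `fig2_large` — `theta_mean = [0.92, 4e-3, 1e-4]`,
  `theta_var = [6e-3, 1e-6, 2e-10]`, noise variance 0.01 (large
  individual differences, large noise);
* `fig2_small` — `theta_var = [6e-4, 1e-7, 2e-11]`, noise 6e-6;
* `fig3_disease` — healthy law plus `theta_3 * max(0, t - theta_4)` with
  mean slope -0.02/yr, mean onset 65 yr, slope variance 1e-4, onset
  variance 20 yr^2 (the onset spread is read as a variance, SD ~4.5 yr;
  onsets outside the age range are permitted — the hinge is simply never
  or always active), noise 2e-5.

Covariates supplied to the models are
`x_k = r * z(theta_k) + sqrt(1-r^2) * N(0,1)` with `z(.)` standardized by
the ensemble's *population* moments, so the theta-to-covariate map is a
fixed property of a subject and identical across independently drawn
cohorts (cohort-level standardization would inject spurious
between-cohort prediction offsets that are visible at correlation 1 with
small noise). At `r = 1` the standardized parameter is used exactly.

What the simulator emulates: age-structured between-subject variance,
informative-but-noisy covariates, cross-sectional sampling, additive
disease decline, and (via `export_cohort_as_images`) tiny NIfTI phantoms
with signal and pure-noise voxels. What it does not emulate: spatial
covariance between voxels, site/scanner effects, segmentation and
registration artifacts, non-Gaussian noise, and realistic covariate
distributions. Passing tests therefore demonstrate the statistical
machinery (calibration, relative method ordering, scaling behavior), not
performance on real MRI.

## Experiment problem sizes

The replicated comparisons use ensembles of 640 training and 640 test
subjects with 20 replicate seeds (medians reported), single-restart fits;
the uncertainty-versus-sample-size profile uses training subsamples
{40, 80, 160, 320, 640} with 3 repeats against 100 test subjects; the
held-out calibration check accumulates 10,000 z-scores from 100
replicate draws of 50 training and 100 test points at fixed true
hyperparameters. These sizes give Monte-Carlo error comfortably below
the assertion margins (e.g. variance-of-variance relative SD
`sqrt(2/n) ~ 5.6%` at n = 640 against 20% bands).

## Design choices on genuinely open points

* The Box–Cox profile likelihood uses an intercept-only residual model
  (see above) rather than residuals about a covariate regression.
* Global tissue-volume models are fit without a Box–Cox transform by
  default (global volumes are near-Gaussian aggregates); configurable.
* Disease-state likelihoods other than "healthy" are user-supplied
  density maps — the package provides the healthy GP predictive density
  and the combination rule, not disease generative models.
* Clinician disease priors are required inputs to the posterior; no
  elicitation scheme is imposed.
* ROC orientation is pinned to "larger score = more diseased", with
  explicit sign flips for delta (atrophy-negative) documented at the
  call sites.
* Onset-locked profiles use 2-year bins over [-20, 20] years since
  onset.
* Pre-onset comparisons between diseased and healthy cohorts are
  age-matched by giving healthy subjects pseudo-onsets from the same
  onset law; without this the raw t statistic differs purely through the
  age composition of the groups.

## Known limitations

* Exact GP inference is O(n^3) per voxel; no sparse approximations are
  provided, so realistic database sizes (n ~ 1000+) are slow at full
  brain resolution. The model container also stores training data per
  voxel, which duplicates covariates across voxels; acceptable at
  phantom scale, wasteful at brain scale.
* NPM companion volumes (predicted, error) are on the Box–Cox-transformed
  scale of each voxel, not raw milliliters.
* Amplitude `a` is weakly identified relative to length scales and noise;
  its recovery error in simulations is several times larger than for the
  other hyperparameters.
* The `corr = 0` covariate columns are pure noise, yet remain in the
  design; ARD handles them but does not remove them.
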