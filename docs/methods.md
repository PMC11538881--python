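# Methods

This note documents the model, its defaults, the synthetic-data generator,
the numerical choices, and what the test suite does and does not establish.

## Model

The inferential target is the mitotic count on the surgical specimen,
$M^S$, expressed per 5 mm² of tumor tissue.  It is a count, so the
likelihood is Poisson with rate $\lambda_i$ per patient and a log link:

$$\log \lambda_i = \alpha + \beta_{L_i} d_i + \gamma_{L_i} s_i
  + \bigl[(1-R_i)\delta + R_i\varepsilon\bigr] m_i .$$

The covariate set comes from a causal diagram of the biopsy process: site
$L$ influences both tumor size at diagnosis (some sites become symptomatic
later) and the tissue surface obtainable at biopsy (some sites are harder
to reach); the specimen count drives the biopsy count, which is additionally
thinned by the surface examined.  Site therefore indexes both the size
coefficient $\beta_L$ and the surface coefficient $\gamma_L$, and both are
partially pooled across the four sites (colon-rectum, duodenum, small
intestine, stomach) through normal hyper-priors — a multilevel structure
that regularizes the sparsely observed sites toward the population mean.

The response flag $R$ is operational, not radiological: a pre-treated tumor
whose specimen count fell below its biopsy count.  Such cases switch the
biopsy-count coefficient from $\delta$ to a separate $\varepsilon$, so they
still inform $\alpha$, $\beta$, $\gamma$ without contaminating $\delta$.
Forecasts for new tumors always use the $\delta$ arm: the question a
forecast answers is "what would the specimen show absent therapy response",
and $\varepsilon$ exists only to absorb the treated cases during fitting.

### Covariate transforms

The source analysis does not pin down covariate scaling, so the transforms
are explicit, configurable, and stored with every fit:

* **size**: z-score of `size_mm` over the training cohort (default), or
  identity in cm;
* **surface**: identity in mm² (default; the 0–5 mm² range is already
  unit-scale), or z-score;
* **biopsy count**: $\log(1+M^B)$ (default), raw count, or
  $\log(1+\text{rate per 5 mm}^2)$.

The `log1p` default makes $\delta \approx 1$ read as "specimen rate
proportional to biopsy count", which is the natural null expectation.

### Priors

Defaults (all overridable through `PriorConfig`):

| parameter | prior | note |
| --- | --- | --- |
| $\alpha$ | Normal(1, 1) | $e^\alpha \approx 2.7$ baseline mitoses / 5 mm² |
| $\delta, \varepsilon$ | Normal(0, 0.5) | count-coefficient scale |
| $\mu_\beta$ | Normal(0, 0.5) | size hyper-mean (z-scored covariate) |
| $\sigma_\beta$ | Exponential(2) | size hyper-scale, mean 0.5 |
| $\mu_\gamma$ | Normal(0, 0.2) | surface hyper-mean (mm² covariate) |
| $\sigma_\gamma$ | Exponential(5) | surface hyper-scale, mean 0.2 |

The surface-coefficient priors are tighter than the size ones by design:
the surface covariate spans 0–5 mm² rather than unit scale, so a coefficient
of the same magnitude moves the log-rate several times more.  The widths
were calibrated by prior-predictive simulation against two pieces of field
knowledge — most GISTs are mitotically quiet (rate < 5 / 5 mm²), and rates
above 50 are biologically implausible in more than a small minority — until
the simulated rates satisfied both (the package enforces: ≥ 50% of
prior-predictive rates below 5, ≤ 10% above 50, share above 50 nonzero).
With Normal(0, 0.5)/Exponential(2) surface priors the linear predictor's
prior sd is ≈ 2.7 and about 14% of rates exceed 50, which fails the second
constraint; the tighter defaults give ≈ 67% below 5 and ≈ 3% above 50.

### Variants compared

Five structures, compared out-of-sample:

| name | linear predictor | hierarchy |
| --- | --- | --- |
| `full` | size + surface + count | $\beta_L, \gamma_L$ |
| `hier-delta` | size + surface + count | $\beta_L, \gamma_L, \delta_L$ |
| `size-hier` | size + surface | $\beta_L, \gamma_L$ |
| `size-no-surface` | size only | $\beta_L$ |
| `flat-no-size` | surface + count | none (independent fixed-width site priors) |

The variant equations are reconstructed from prose descriptions; only their
structure (which terms, which pooled) is asserted anywhere.

## Inference

Posterior sampling is adaptive Hamiltonian Monte Carlo over the
unconstrained space (hierarchical scales on the log scale with the
exponential-prior Jacobian).  The model's gradients are closed-form — a
Poisson GLM — so each leapfrog step is one cheap analytic evaluation; the
gradients are verified against finite differences for every variant in the
test suite.  The sampler uses dual-averaging step-size adaptation toward a
0.9 acceptance target, a diagonal mass matrix estimated from the middle
half of warmup, trajectory lengths jittered uniformly up to 48 leapfrog
steps (guards against resonance), and Stan-style divergence flagging
(energy error > 1000 or a non-finite density).  Defaults: 4 chains,
1000 warmup + 1000 retained draws each.

Hierarchical site coefficients use the **noncentered** form
$\beta_L = \mu_\beta + \sigma_\beta z_L$, $z_L \sim \mathcal N(0,1)$ by
default; the centered form is available and defines the same posterior (the
test suite checks the density Jacobian identity and the agreement of
posterior means).  On mock cohorts the centered form produces markedly more
divergent transitions (the funnel at small $\sigma$), which is why
noncentered is the default.

Diagnostics follow current practice: rank-normalized split R-hat (not the
classic Gelman–Rubin statistic), bulk effective sample size, divergence
counts, the energy/BFMI summary, and trace-rank ("trankplot") exports.  A
fit whose R-hat exceeds 1.01 or whose ESS degenerates is *flagged* on the
returned object, never silently passed.

## Model comparison

WAIC and PSIS-LOO are computed from the pointwise log-likelihood matrix
retained with every fit, reported on the deviance scale ($-2\,$elpd).
PSIS smoothing fits a generalized Pareto distribution (Zhang–Stephens
posterior-mean estimator) to the largest 20% of importance weights (at
least 5), replaces them with expected order statistics, truncates at the
raw maximum, and reports per-observation $\hat k$ with warnings above 0.7;
with fewer than 5 tail draws it falls back to truncated importance
sampling and says so.  Contrasts against the best model use paired
pointwise differences; intervals on deviances use a normal approximation
at 89% — the compatibility-interval mass used throughout the package
(HDPIs are reported at 89% too).

A caveat established during validation: when two variants are nearly tied
in elpd (the `hier-delta` structure nests `full`'s fit, so on
`full`-generated data they differ by well under one elpd unit), WAIC and
PSIS-LOO can order that pair differently — their penalties are different
estimators and the discrepancy does not vanish with more draws.  The two
criteria reliably agree on the clearly separated part of the ranking.

## Synthetic-data generator

Two modes:

* **model-faithful** — covariates drawn from plausible clinical
  distributions, specimen counts Poisson at the model's own linear
  predictor with known parameters.  Used for parameter-recovery validation:
  with truth drawn from the priors each replicate, 89% HDPIs must cover
  the truth at the simulation-based-calibration rate.
* **dag-faithful** — a latent per-tumor rate drives both counts, the biopsy
  count thinned by surface/5.  This encodes the sampling-bias mechanism
  independently of the inferential model: biopsy rates correlate with
  specimen counts, more strongly when more surface was examined.

Covariate defaults: site probabilities (0.10, 0.10, 0.20, 0.60) reflecting
gastric predominance; log-normal sizes, median 50 mm gastric / 35 mm
elsewhere, log-sd 0.5; surface $0.05 + 4.95\cdot\mathrm{Beta}(2,2)$ mm²;
15% therapy-response rate; biopsy counts Poisson at a log-normal latent
rate thinned by surface.  These are plausibility choices, not estimates of
any real cohort — the real cohort is not public — and nothing downstream
depends on their exact values.

What passing tests therefore show: the machinery is self-consistent (it
recovers what it simulates, its criteria match exact oracles, its forecasts
match closed forms).  What they cannot show: that the model is well
specified for real GIST cohorts, whose covariate distributions, overdispersion
and measurement quirks the generator does not claim to reproduce.

## Risk stratification

The Miettinen–Lasota (AFIP) lookup ships as an editable YAML configuration
(site group × four size bands × two mitotic bands, 32 cells), with
"insufficient data" cells preserved as such rather than coerced.  Band
edges are closed above (≤2, >2–5, >5–10, >10 cm; ≤5 vs >5 mitoses).  Two
mapping choices the source material leaves open: colon-rectum tumors use
the rectum column (the classification has no colon column) and
small-intestine tumors the jejunum/ileum column; both are remappable in
the config.  `predictive_risk` pushes the forecast pmf through the lookup,
so classes inherit exactly the forecast's uncertainty.

The preoperative clinical types 0–4 combine resectability, metastatic
status, site, size and forecast risk.  The published row list does not
resolve overlaps, so precedence here is highest-severity-first
(unresectable → metastatic → any locally-advanced trigger → the low-risk
gastric types); input combinations matching no row return an explicit
"unclassified" outcome.  Clinical judgment (resectability, rupture risk,
mutilating-resection need) enters as caller-supplied flags — the package
never computes it.

## Problem sizes and determinism

Validation runs use cohorts of n = 100 (recovery, selection, mock
diagnostics), n = 60 (shared unit-test fixture) and n = 20 (exact-LOO
oracle, where 20 brute-force refits are needed), with reduced MCMC
schedules (4 × 500 or 2 × 800 retained draws) for replicated experiments;
these sizes were chosen so the whole suite replicates the qualitative
findings at desk scale.  Every stochastic step takes an explicit seed;
identical seeds reproduce fits bit-for-bit on one machine.

## Known limitations

* The Poisson likelihood has no overdispersion term; a negative-binomial
  extension is deliberately out of scope.
* Static-trajectory HMC with jitter, not NUTS; adequate for this 15-ish
  dimensional GLM posterior (verified by R-hat/ESS), but trajectory length
  is not locally adapted.
* Forecasts condition on the fitted cohort's covariate transforms; a new
  tumor far outside the training size distribution extrapolates.
* The hosted interactive application is out of scope; the CLI `predict`
  subcommand reproduces its computation (count forecast + risk-class
  probabilities) without the UI.
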