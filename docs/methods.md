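# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the design decisions taken where the design was genuinely open.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design being emulated

The package targets paired-design camera-trap studies of an invasive plant:
each 500 × 500 m grid square holds two cameras, the first at visibly high
invader density and the second 50–70 m away in a random direction at
strictly lower density, so that within-pair contrasts are informative about
the invader while habitat confounders are nearly shared. Two survey seasons
(January–April and October–November) are treated as a site-level attribute —
each site is surveyed in one season — and effects are season-specific
throughout. The generator always emits exactly two sites per square; real
deployments lose cameras, which is why the field counterpart of this design
had 101 + 27 sites rather than 92 + 28. The number of survey days per camera
is a free parameter (default 60): deployment lengths are study-specific.

## Consensus classification

Votes are aggregated per image. A species is present when
`votes_s / n_volunteers ≥ 0.66` (inclusive). The Shannon entropy of the full
vote distribution (natural log by default, base 2 available; the worked
6/6 → ln 2 and 4/4/4 → ln 3 examples straddle the discard threshold of 1
identically in both bases) measures volunteer disagreement; `H > 1`
(strictly) discards the image. An expert label overrides everything.

Open choices, resolved as follows:

* **Denominator of the 66% rule** — the number of volunteers who classified
  the image, not the number of species tags, so multi-species images can
  pass the threshold for several species at once. Configurable.
* **Accuracy audit** — images whose consensus status is `expert` are
  excluded from the audit (no self-comparison). A species with zero expert
  positives reports missing sensitivity, never 0/0.
* **Night boundary** — a detection at exactly dawn or dusk counts as day;
  night is strictly after dusk and strictly before dawn. Dawn/dusk are civil
  twilight (sun altitude −6°), the convention of the suncalc family of
  tools; sunrise/sunset (−0.833°) is a parameter away.
* **Day binning** uses the site's local civil date (UTC+3 for the study
  region), configurable.

## Solar and lunar computations

Twilight times come from the NOAA low-accuracy solar-position equations
(fractional-year series for declination and the equation of time), good to
about ±2 minutes at tropical latitudes; polar latitudes (|lat| ≥ 66°) are
rejected explicitly. The lunar illuminated fraction is
`(1 + cos i)/2` with the phase angle `i` computed from truncated solar and
lunar ecliptic longitudes (the moon series keeps the evection, variation and
annual-equation terms), accurate to about ±0.02. The test suite checks the
sun against an independently coded Meeus-style oracle and the moon against
frozen almanac full/new-moon instants. For day-level model covariates the
lunar fraction is evaluated at local midnight of the date — the choice of
per-night rather than per-detection evaluation is a documented default, and
per-timestamp evaluation is available.

## Distance sampling

Counts per distance bin, square and size class (S < 1 m, M 1–2 m, L > 2 m
stand height) follow a Poisson-thinned multinomial: with N ~ Poisson(λ)
stands uniform in [0, B] and half-normal detection, each cell count is
marginally independent Poisson(λ·π_c), with π_c computed in closed form via
the error function. The factorized form is numerically convenient; its exact
equivalence to explicit marginalisation over N is asserted in tests
(tolerance 1e-8, N summed to 500).

* **Bins and truncation** — unstated in the source design; defaults are
  1 m bins to B = 10 m, fully configurable.
* **σ per size class** — visibility plausibly increases with stand height,
  so σ is fitted per class; classes with zero detections are rejected as
  unidentifiable rather than silently fitted.
* **Priors** — σ ~ half-Normal(5 m), log λ ~ Normal(0, 2): weakly
  regularising on the scales of the design.
* **Volume constants** — per-stand volumes are hemispheres at representative
  heights 0.5 / 1.5 / 2.5 m. The stored constants are the printed values
  0.260 / 7.070 / 32.725 m³. The formula (2/3)πh³ reproduces the large
  constant exactly at 3 dp but gives 0.2618 and 7.0686 for the small and
  medium classes — agreement at 2 dp only. The printed constants are treated
  as authoritative for the volume pipeline and the discrepancy is documented
  here rather than "corrected".
* **Transects** are assumed walked once per square.
* **Per-square abundance** in the pipeline's `square_opuntia.csv` is
  Horvitz–Thompson style: observed detections divided by the posterior
  detection probability p̄(σ), propagating σ uncertainty through the
  posterior draws.

## Causal adjustment

The causal assumptions live in an editable edge-list file
(`src/invade/data/habitat_use.dag`), never hard-wired in code. Human use of
the landscape is latent: it may never enter an adjustment set (attempting to
condition on it raises, signalling a design error rather than returning
`False`). The transcription encodes human use as affecting the outcome only
through observed mediators (livestock activity, road proximity), which makes
the confounding resolvable: the unique minimal total-effect back-door set is
{distance to river, distance to road, livestock} — exactly the covariate
block the habitat models adjust for, and the test suite fails loudly if the
file and the models ever disagree. The native-plant block (grass, shrub,
forb, succulent cover, tree count) lies on the directed exposure → outcome
path, so total-effect sets exclude it; the "with native plants" model
variant adds it deliberately to probe the mediated pathway. d-separation is
delegated to networkx and verified against a brute-force path-enumeration
oracle; back-door validity and minimal-set enumeration are implemented here
and verified against subset enumeration on 1000 random DAGs.

## Habitat-use models

All covariates are standardized to mean 0, sd 1 (sample sd, n−1), except
lunar illumination, which keeps its natural [0, 1] scale. Slopes are
season-specific vectors indexed by the site's season. Priors: slopes
Normal(0, 1); intercepts Normal(0, 1.5); GP amplitude η half-Normal(1); GP
length-scale ρ half-Normal(half the study extent); log φ Normal(0, 1.5);
camera-model intercepts hierarchical Normal(a₀, 1) with a₀ ~ Normal(0, 1.5).
The hierarchical (rather than fixed-offset) camera intercept is the safer
reading with few camera models and is switchable. The GP kernel is the
exponentiated quadratic; the kernel family is a documented choice, not a
claim that alternatives (e.g. Matérn) would behave differently at these
inter-site distances.

* **Occupancy** marginalises the latent use indicator analytically:
  sites with a detection contribute log ψ + Σ log Bern(y|p); all-zero sites
  contribute logaddexp(log ψ + Σ log(1−p), log(1−ψ)). NA days (camera
  inactive) are skipped. Daily mean temperature enters the detection
  sub-model only.
* **Counts** are site-day observations with a shared site-level mean — the
  daily observation unit is chosen because temperature and lunar covariates
  are daily. NB2 parameterisation: variance μ + μ²/φ, Poisson recovered as
  φ → ∞ (verified against the Poisson limit and against scipy's nbinom).
* **Night proportion** uses site-day (k of n) observations so the lunar
  covariate varies within sites; rows with n = 0 contribute exactly zero.
* **Exposure scales** (site cover vs square volume) are always separate
  models, never joint. Sites whose square lacks a volume estimate (squares
  can go unsampled in the field) are dropped from square-scale models;
  imputation is deliberately not attempted.

### Sampling

`sample_posterior` runs plain Hamiltonian Monte Carlo with analytic
gradients (verified against finite differences at 1e-4 relative tolerance),
dual-averaging step-size adaptation targeting 0.8 acceptance, a diagonal
mass matrix estimated from the middle warmup window, and leapfrog trajectory
lengths jittered uniformly in [8, 32] steps. The GP hyperparameters (η, ρ)
enter the likelihood through a Cholesky factor, so they are updated by
log-scale random-walk Metropolis-within-Gibbs with Robbins–Monro scale
adaptation instead of carrying awkward Cholesky derivatives; the GP field
itself uses the non-centred parameterisation f = η L(ρ) u with u ~ N(0, I)
and jitter 1e-6 on the correlation diagonal (configurable). Default
protocol: 4 chains × 2000 sampling iterations, warmup 4000 (occupancy,
night) or 7000 (counts). Non-convergence (split-R̂ > 1.01 on any
interpretable parameter; the per-site field coordinates are exempt as they
mix more slowly by construction) raises a warning, never a silent success.
Degenerate logits are capped at ±35, which preserves probabilities 0/1 to
double precision while keeping gradients finite.

### Reporting

Draws are pooled across chains post-warmup. P(+ve effect) uses strict
inequality (exact zeros count as not positive, so the three sign
probabilities partition). Compatibility intervals are central quantile
intervals at 95/89/80/70/60/50%, nested by construction. Marginal effect
curves are conditional-at-means: the exposure varies over a grid
(standardized via the fit's scaling record), all other covariates sit at 0
(their standardized mean), the GP term at 0, detection/camera nuisance at
reference, and the night model's lunar covariate at 0.5; each draw passes
through the inverse link, and curves are summarised by the median and the
six interval levels. Grid points beyond ±3 sd of the observed exposure are
flagged as extrapolation but still computed. Curves condition on the
season-specific slope of the requested season, matching per-season panels.

## Synthetic-data generator

The generator inverts exactly the models fitted: GP field draws (independent
per response, shared hyperparameters), Bernoulli occupancy and daily
detection, NB2 counts, binomial night counts with the exposure × lunar
interaction, half-normal thinned transect counts, and per-image volunteer
votes drawn iid from the confusion row of the true label (default: 0.9
correct, 0.1 "empty"). Temperature is a sinusoidal annual mean with Gaussian
daily noise; only daily means are emitted. Site-level cover is the
generative exposure; square-level volume is correlated with mean site cover
through a Gaussian copula (configurable r, default 0.6). Everything is
deterministic given a seed, byte-identical on re-run.

What the generator does **not** emulate — and hence what passing recovery
tests do not show about field data: animal movement and home-range overlap
between paired sites (observations are conditionally independent given the
GP), camera failures beyond simple random inactive days, seasonal turnover
in occupancy (no colonisation/extinction dynamics), volunteer heterogeneity
(a single confusion matrix for all volunteers), and any real-image
properties. Recovery results validate the estimation machinery, not the
field study's substantive conclusions.

## Problem sizes used in checks

The recovery studies run at 80 sites × 60 days (occupancy; slope +1, GP
η = 0.5, ρ = 1000 m) and 50 squares (distance sampling; σ = 4 m, 30
stands/square), with 2 chains × 500 warmup + 500 sampling iterations — the
package's chosen reporting sizes for calibration studies, with 20 replicates
in the test suite and 6 in the acceptance script. Coverage targets are 16/20
for nominal-90% intervals (a ≥ 0.8 observed rate is within binomial noise of
0.9 at n = 20).

## Known limitations

* The HMC sampler is deliberately minimal (no NUTS tree building, no
  Riemannian adaptation); very ill-conditioned posteriors may need longer
  warmup than the defaults.
* Metropolis updates for (η, ρ) mix more slowly than gradient updates;
  length-scale posteriors are often broad at these design sizes, which is
  honest uncertainty rather than a sampler defect, but worth inspecting.
* The distance-sampling likelihood is binned; continuous-distance
  likelihoods and alternative detection functions (hazard-rate, uniform)
  are out of scope.
* Back-door enumeration is exponential in the number of candidate nodes;
  fine for the bundled 7-node graph, not for large learned graphs.
* Multi-species joint modelling, dynamic occupancy and model comparison
  (WAIC/LOO) are out of scope.
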