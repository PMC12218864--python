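# invade

Bayesian estimation of the effects of an invasive plant (*Opuntia* spp.,
prickly pear) on mammal occupancy and activity, from camera-trap data
classified by citizen-science volunteers.

The package is aimed at ecologists running paired-design camera-trap studies:
it covers the full inferential chain from raw volunteer votes and detector
scores to posterior effect estimates, and ships a synthetic-study generator
with known ground truth so every stage can be validated by parameter
recovery before being pointed at field data.

## What it computes

**Consensus classification.** Each image is classified by ≥ 12 volunteers.
A species is accepted when ≥ 66% of volunteers voted for it; images whose
vote distribution has Shannon entropy H = −Σ qₗ log qₗ > 1 are discarded as
ambiguous; an expert label, where present, overrides the volunteers.
Accuracy is audited against the expert-labelled subset (per-species
sensitivity and specificity).

**Distance sampling.** Invader abundance per 500 × 500 m grid square is
estimated from line-transect counts binned by perpendicular distance,
separately for three stand-height classes, under a Poisson–multinomial model
with half-normal detection g(x) = exp(−x²/2σ²). Class abundances are
converted to volume using hemisphere-based per-stand constants
(0.260 / 7.070 / 32.725 m³ for small/medium/large stands) and expressed per
metre of transect (× 500 for the square total).

**Causal adjustment.** Covariates for the effect models are selected with
the back-door criterion on a DAG in which human use of the landscape is a
latent node. Adjustment sets preserve the *total* effect: nodes on directed
exposure → outcome paths (the native plant community) are never conditioned
on. The bundled graph file is editable text.

**Habitat-use models.** Three models per species, season and exposure scale
(site-level % cover vs square-level volume), all with season-specific slopes,
standardized covariates (lunar illumination excepted) and a spatial Gaussian
process f ~ GP(0, η² exp(−d²/2ρ²)) over site coordinates:

* occupancy: zᵢ ~ Bernoulli(ψᵢ), logit ψᵢ = α + xᵢ'β + fᵢ, with daily
  detections yᵢⱼ ~ Bernoulli(zᵢ pᵢⱼ), logit pᵢⱼ = a_cam + γ·tempᵢⱼ, and the
  latent zᵢ marginalised analytically;
* daily counts: nᵢⱼ ~ NegBin(μᵢ, φ) (NB2, variance μ + μ²/φ), log μᵢ = α +
  xᵢ'β + fᵢ;
* night activity: kᵢⱼ ~ Binomial(nᵢⱼ, πᵢⱼ), logit πᵢⱼ including lunar
  illumination and an exposure × lunar interaction.

Posteriors are sampled with Hamiltonian Monte Carlo (analytic gradients,
dual-averaging step size, diagonal mass adaptation; GP hyperparameters by
Metropolis-within-Gibbs), with rank-normalised split-R̂ and bulk-ESS
convergence checks. Effects are reported as P(+ve effect) — the posterior
probability the exposure slope is positive — plus nested 95/89/80/70/60/50%
compatibility intervals and marginal effect curves on the response scale.

## Worked example

Simulate a single-season study (40 squares × 2 paired sites, 60 survey
days) with a known positive exposure effect (+1 on the standardized cover
scale, logit) and spatial autocorrelation, then refit it:

```python
from invade import (TrueParameters, generate_design, simulate_site_covariates,
                    simulate_observations, ModelSpec, build_model_data,
                    sample_posterior, p_positive, compatibility_intervals)

params = TrueParameters(occ_opuntia=(1.0, 1.0), gp_eta=0.5, gp_rho=1000.0)
design = generate_design(n_squares_s1=40, n_squares_s2=0, days=60, seed=1)
sites = simulate_site_covariates(design, params, seed=1)
obs, truth = simulate_observations(sites, params, days=60, seed=1)

spec = ModelSpec(response="occupancy", exposure="opuntia_cover_pct",
                 covariates=(), gp=True)
data = build_model_data(sites, obs, spec)
draws = sample_posterior(spec, data, chains=2, warmup=500, iters=500, seed=1)

name = "beta[opuntia_cover_pct,s1]"
print(f"P(+ve effect) = {p_positive(draws, name):.3f}")
print(compatibility_intervals(draws, name).round(3).to_string(index=False))
```

Output:

```
P(+ve effect) = 1.000
 level  lower  upper
    95  0.425  1.621
    89  0.504  1.465
    80  0.609  1.357
    70  0.694  1.290
    60  0.748  1.225
    50  0.797  1.167
```

The posterior puts essentially all mass on a positive effect and every
compatibility interval comfortably contains the generating slope of 1.0:
the occupancy model recovers the known truth through the full chain of
imperfect detection and spatial correlation.

The same workflow is available from the shell:

```sh
invade simulate --out run --seed 1 --squares-s1 20 --days 30
invade run-all  --out run --seed 1
invade adjust                      # prints {dist_river, dist_road, livestock}
```

`invade run-all` writes `sites.csv`, `observations.csv`, `transects.csv`,
`votes.csv`, `detections.csv`, `square_opuntia.csv`, per-model posterior
draws, `effects.csv` and an `effect_matrix.csv` of P(+ve effect) per
season × scale × model, with a `manifest.json` that lets reruns skip
up-to-date stages.

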