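# snelicit

Expert prior elicitation as a skew-normal distribution: convert
trial-roulette chip placements or a location-plus-bounds judgment into a
fully specified prior, harmonize a panel of experts elicited on different
scales, and update or score the elicited prior against observed data.

## Who this is for

Applied Bayesian analysts — in psychology, epidemiology, business
forecasting — who need a prior for a mean parameter from domain experts
rather than from data. Experts are unreliable when asked for a full
distribution in one step, so the elicitation is decomposed: first the
location (where they think the value is), then the uncertainty (how far off
they could reasonably be), with each stage fit, shown back, and re-fit until
accepted.

## The model

Beliefs are represented as a skewed normal in the Fernandez–Steel form: a
standard-normal base density f made asymmetric by a shape parameter
γ > 0 that allocates mass around the mode M,

    p(ε | γ) = 2/(γ + 1/γ) · { f(ε/γ)·1[ε ≥ M] + f(γε)·1[ε < M] }

with γ = 1 exactly normal, γ > 1 right-skewed, and the density for 1/γ the
mirror image of the one for γ. The package uses a **moment-standardized**
parameterization `SkewNormal(mean, sd, shape)`: the declared mean and sd are
the true first two moments for every shape, so fitting can pin them to data
and optimize only γ.

The elicitation pipeline:

1. **Chips** — the expert places ≥ 7 chips on a 600-column grid spanning
   their stated reasonable range; each chip carries 1/n of the probability
   mass (5% at 20 chips). Chip columns map to an equally spaced value axis.
2. **Location fit** — a skew normal is fit to the chip values with mean and
   sd pinned to the sample moments and γ chosen by maximum likelihood; the
   fitted mean becomes the location estimate μ₀.
3. **Bounds** — the expert states reasonable lower/upper bounds for μ₀.
   A weighted sample is built: μ₀ × 100, lower × 10, upper × 10.
4. **Scale/shape fit** — (σ, γ) maximize the likelihood of the 120-value
   sample with the mean constrained to μ₀ exactly, giving the prior
   π(θ) ~ SN(μ₀, σ₀², γ₀).
5. **Use** — update the prior with data on a θ grid (normal likelihood for
   the mean), summarize the posterior in the same SN(μ₁, σ₁², γ₁) form, or
   compute a prior-data conflict score (a two-sided prior-predictive
   p-value of the observed sample mean; small = conflict).

Experts on different scales (per product, per region, totals) are made
comparable through the affine map θ* = aθ + b, which sends
SN(μ, σ², γ) to SN(aμ + b, (aσ)², γ) for a > 0.

## Worked example

An expert estimates the average quarterly turnover per professional at 2.25
(hundred k€), with reasonable bounds 1.9 and 2.8:

```sh
snelicit fit-bounds --mu0 2.25 --lower 1.9 --upper 2.8
```

```json
{
 "prior": {
  "mean": 2.25,
  "sd": 0.18267073338943338,
  "shape": 1.1422779687196287
 }
}
```

The mean is constrained to the stated 2.25; the sd ≈ 0.18 reflects the
bound spread, and shape ≈ 1.14 > 1 encodes the longer upper tail (2.8 is
further from 2.25 than 1.9 is). Updating with 12 observed quarterly
averages (sample sd 0.35 plugged in as the likelihood sd):

```python
from snelicit import (BoundsElicitation, fit_from_bounds, posterior_on_grid,
                      summarize_posterior, prior_data_conflict)

prior = fit_from_bounds(BoundsElicitation(2.25, 1.9, 2.8))
obs = [2.85, 2.31, 2.99, 1.81, 2.4, 2.19, 2.6, 1.97,
       2.7, 2.34, 2.75, 2.28]
gp = posterior_on_grid(prior, obs, likelihood_sd=0.35)
print(summarize_posterior(gp))
print(prior_data_conflict(prior, obs, 0.35, n_sim=100_000, seed=1))
```

```
SkewNormal(mean=2.389780675597572, sd=0.09056794613929395, shape=1.0014509787677583)
0.38344
```

The posterior mean 2.39 sits between the prior mean (2.25) and the data
mean (2.43), the posterior sd shrinks to 0.09, and the conflict score 0.38
is far from 0: the data give no evidence against the elicited prior.

Harmonizing a four-expert panel where two experts reasoned per product and
two per product type (a store selling 104 products of 9 types):

```python
from snelicit import ScaleSpec, harmonize_panel
per_product = ScaleSpec(1/104, 0, "per-product")
per_type    = ScaleSpec(1/9,   0, "per-type")
total       = ScaleSpec(1,     0, "total")
panel = [(1.8, per_product), (2.1, per_product),
         (23.0, per_type), (24.5, per_type)]
print([r["value"] for r in harmonize_panel(panel, total)])
# [187.20000000000002, 218.4, 207.0, 220.5]
```

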