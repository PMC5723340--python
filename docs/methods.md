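# Methods

## The distribution

The skew-normal family used throughout is the Fernandez–Steel construction:
a standard-normal base density f, a mode M, and a shape γ > 0 that rescales
the argument by 1/γ above the mode and by γ below it,

    p(ε | γ) = 2/(γ + 1/γ) · { f(ε/γ)·1[ε ≥ M] + f(γε)·1[ε < M] },

taking M = 0 for the raw form. Both branches agree at ε = M, so the density
is continuous there and the branch tie needs no special handling. Closed
forms used internally (standard-normal base):

- mass below the mode: 1/(1 + γ²);
- raw mean: √(2/π)·(γ − 1/γ); raw second moment: (γ³ + γ⁻³)/(γ + 1/γ);
- CDF: piecewise in the normal CDF Φ — 2Φ(γε)/(1+γ²) below the mode,
  1/(1+γ²) + (2γ²/(1+γ²))(Φ(ε/γ) − ½) above.

**Moment standardization.** The public `SkewNormal(mean, sd, shape)` shifts
and scales the raw form by its own moments, so the declared mean and sd are
the true moments for every shape. This is the parameterization forced by
the fitting procedure: it pins mean and sd to the data and optimizes only
γ, which is only coherent if those two numbers really are the moments
regardless of γ. A consequence worth knowing: the mode is *not* the mean
for γ ≠ 1 — it sits at mean − sd·raw_mean/raw_sd, below the mean for
right-skewed distributions.

**Quantiles and sampling.** The piecewise CDF inverts in closed form
(scipy's `ndtri` on each branch), so quantiles are exact rather than
root-found; the CDF∘quantile round trip is tested to 1e-9. Sampling is
inverse-CDF on seeded uniform draws — exact, reproducible, and equivariant
under affine maps at matched seeds (a property the scale-transform tests
exploit).

## The roulette grid

Chips are single-cell activations on a 600 × 300 grid; the 600 columns form
an equally spaced axis from the stated reasonable lower bound to the upper
bound, endpoints inclusive, so the two range-defining chips map exactly to
the bounds. Rows only stack chips visually and carry no value; duplicate
cells are rejected. A chip's mass is 1/n of the total — the value vector
repeats a column's axis value once per chip there, making weights integral.
A grid is fit-ready with at least 7 chips (the minimum under the continuous
re-fit procedure this package adopts) and chips in both end columns.

## Fitting

**Shape-only fit (chip values).** Mean and sd are the sample moments
(n − 1 denominator for sd; any consistent convention is absorbed by the
standardization) and γ maximizes the log-likelihood over
log γ ∈ [log 0.01, log 100] with a bounded scalar minimizer (tolerance
1e-8). Symmetric data recover γ = 1 to 1e-2; negating the data reciprocates
γ; affinely mapping the data maps the fit componentwise.

**Bounds fit (the 120-value sample).** The location estimate μ₀ is repeated
100 times and each reasonable bound 10 times — the center-to-bound weight
ratio 100:10:10 is what makes the bounds "reasonable extremes" rather than
hard limits. The mean is constrained to μ₀ exactly and (log σ, log γ) are
jointly optimized by L-BFGS-B from three shape starts (symmetric, right-,
left-skewed), keeping the best. Symmetric bounds give γ ≈ 1; lengthening
the upper bound never decreases γ (tested).

*Boundary behavior.* For strongly asymmetric bounds the constrained-mean
likelihood is monotone in γ: it increases toward the γ → ∞ limit of the
family (a shifted half-normal-like shape whose short side abuts the mode),
so the joint MLE lands on the γ = 100 search cap. This is the genuine
optimum of the stated estimation problem — an exhaustive 2-D grid search
finds the same point — and the cap acts as the regularizer. Users who want
the milder shapes typical of real elicitations should state bounds whose
asymmetry reflects honest uncertainty (ratios of upper-gap to lower-gap
below about 3) rather than order-of-magnitude-lopsided ranges.

**Feedback loops.** "Show the fit, let the expert adjust" is modeled as
pure re-invocation: the caller edits inputs and re-fits; each fit is
appended to the record's iteration log; acceptance is a flag. No hidden
state.

## Scale harmonization

A `ScaleSpec(a, b, label)` is an affine map θ* = aθ + b from a common base
scale; panel harmonization converts a record from its own scale to the
target via spec_to ∘ spec_from⁻¹. For distributions, mean ↦ a·mean + b,
sd ↦ |a|·sd, and shape is unchanged for a > 0 and reciprocated for a < 0 —
the family is closed under affine maps because skewing acts on the
standardized argument. Negative a is supported for completeness (e.g. a
cost stated as a saving). Stored values keep full precision; only reports
round to 2 decimals.

## Bayesian use of the prior

**Likelihood.** Normal for the mean with a user-supplied sd (plug in the
sample sd when nothing better is available). This is the minimal model for
"the expert predicted the average"; it keeps the posterior one-dimensional.

**Posterior.** Computed on a deterministic equally spaced θ grid (default
4001 points) rather than by sampling, so results are exactly reproducible.
A pilot pass over a wide bracket (prior ±10 sd ∪ data mean ±10 se) locates
the posterior mean and sd; the final axis spans ±8 posterior sds, leaving
truncated tail mass below 1e-8. With a shape-1 prior the grid reproduces
the closed-form normal-normal posterior to ~1e-14, the margin behind the
1e-6 contract.

**Posterior summary.** The posterior is reported in the same
three-hyperparameter form as the prior: mean and sd are the grid moments
(trapezoid rule), and γ minimizes the integrated squared deviation between
the skew-normal density at those moments and the gridded density.
Moment-matching plus least-squares shape was chosen over a full
minimum-distance fit of all three parameters so that the reported mean and
sd are always the exact posterior moments, whatever the shape fit does.

**Prior-data conflict.** Operationalized as a two-sided prior-predictive
p-value of the observed sample mean: simulate θ from the prior, then a
sample mean from the likelihood, and report 2·min(P(sim ≤ obs),
P(sim ≥ obs)). Monte-Carlo with n_sim ≥ 1000 (default 1e5), all driven by
the caller's seed. When data really come from the prior predictive the
score is approximately uniform, so conflict flags at the 0.05 level occur
in ≲ 10% of replicates (tested over 500 seeded replicates).

## Synthetic experts

The generator emulates a coherent expert: n chips whose columns are seeded
draws from a known skew-normal binned to the axis, with the first two chips
forced into the end columns (the range-defining chips placed first). The
stated range must cover ≥ 99% of the generating distribution's mass —
wildly over-wide ranges would place the forced end chips at implausible
values and bias the moment fit, which is a property of careless bounds, not
of the method.

What the generator does *not* emulate: rounding to psychologically salient
values, anchoring on earlier questions, overconfidence (bounds tighter than
beliefs), or chip counts chosen adaptively. Passing recovery tests
therefore shows the computational pipeline is unbiased for an idealized
expert, not that human elicitations are well calibrated.

**Recovery is a panel-level property.** A single 100-chip elicitation
estimates the generating mean with sampling error σ/√100 = 0.1σ, so no
correct implementation can put every replicate within 0.1σ. The recovery
contract is therefore stated at panel level: across 10 seeded synthetic
experts (shapes spanning 0.5–2, bounds at the true 5th/95th percentiles)
the mean recovery error stays within 0.1σ, and each individual pipeline
within 3.5 sampling SEs.

## Problem sizes and numerical defaults

| quantity | default | why |
|---|---|---|
| grid columns | 600 | axis resolution ≈ 0.17% of the stated range |
| minimum chips | 7 | fewest placements that still shape a histogram |
| bounds weights | 100/10/10 | center-dominant; bounds as reasonable extremes |
| γ search range | [0.01, 100] | 4 decades; covers any plausible asymmetry |
| optimizer tolerance | 1e-8 | parameters stable to ~1e-4 relative |
| posterior grid | 4001 points, ±8 sd | trapezoid error ≪ 1e-6 contract |
| conflict n_sim | 1e5 | MC se of a mid-range p ≈ 0.0016 |

Test and acceptance runs use 5000 draws for shape recovery, 10 random
configurations for the conjugate limit, and 10 pipelines of 100 chips for
end-to-end recovery — sizes at which the Monte-Carlo error is an order of
magnitude inside each stated tolerance.

## Known limitations

- Quantile-based elicitation (thirds, quartiles) is not implemented; the
  bounds construction is deliberately simple.
- One parameter per expert; no multivariate or dependent-parameter
  elicitation, and no pooling of experts into a consensus prior — panels
  are compared, not aggregated.
- The conflict score is a prior-predictive p-value on the sample mean only;
  it will not detect variance or shape conflicts.
- The γ = 100 cap is reported as-is when the bounds fit pins at the
  boundary; see the fitting section.
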