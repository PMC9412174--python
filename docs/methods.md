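# Methods

## The Cmax error-distribution model

All modelling happens on the base-10 logarithm of concentration in µM. For
chemical *i* under exposure *j*, ζ<sub>i,j</sub> denotes the true (unobserved)
population-average log₁₀ C<sub>max</sub>, and ζ̂ the observed quantities. The
model is a Gaussian chain over PBK parameterization levels:

| layer | distribution | interpretation |
|---|---|---|
| clinical | ζ̂_clinical ~ N(ζ, σ_clinical) | a clinical study measures ζ with small noise |
| L3 | ζ̂_L3 ~ N(ζ + α_L3, σ_L3,pop) | the clinically calibrated PBK estimate scatters around ζ with bias α_L3 |
| L2 | ζ̂_L2 ~ N(ζ̂_L3 + α_L2, σ·f_L2L3/(β+f_L2L3)) | the L2→L3 gap grows with the fraction f of re-parameterized inputs |
| L1 | ζ̂_L1 ~ N(ζ̂_L2 + α_L1, σ·f_L1L2/(β+f_L1L2)) | same saturating gap law between L1 and L2 |

Assumptions worth making explicit: the prediction-error distributions are
chemical- and exposure-agnostic (only the level matters); biases α_k are
nonnegative (half-normal priors — the chain can overpredict systematically but
not underpredict); and the gap standard deviation `σ·f/(β+f)` is exactly zero
when no parameters change (f = 0), increases monotonically in f, and saturates
at σ. When a scenario's f is unknown it defaults to 0.5 for the L2–L3 gap
(slightly above the largest fraction seen in practice, ≈0.38) and 1.0 for the
L1–L2 gap, maximizing the implied uncertainty.

Priors: σ_clinical ~ InverseGamma(4.6, 0.22) (shape/scale convention,
density ∝ x^(−a−1)·e^(−b/x)), placing ≈95% of its mass on [0.0225, 0.155]
log₁₀ units — between a 1.1-fold and a 2-fold measurement error at 95%
probability; α_k, β ~ HalfNormal(0, 0.5); σ_L3,pop, σ ~ HalfNormal(0, 1);
ζ ~ N(0, 10), effectively flat over the 0.004–4000 µM range the workflow
operates in.

### Posterior computation

Every layer is Gaussian, so the latent ζ and any missing L3/clinical
observations can be marginalized in closed form: per scenario, the observed
vector is multivariate normal with a nested covariance (shared variance τ²
from the ζ prior plus cumulative chain variances) and mean offsets given by
the cumulative biases. This reduces the problem to a 7-dimensional posterior
over (σ_clinical, α_L1, α_L2, α_L3, σ_L3,pop, σ, β), which is sampled with
the affine-invariant ensemble sampler (emcee) in log-parameter space with a
vectorized likelihood (scenarios grouped by missingness pattern, batched
linear algebra). Latent ζ values and missing observations are reinstated
afterwards by exact conditional-normal draws, so the joint posterior is
identical to sampling the full hierarchy directly — at a fraction of the
cost, which is what makes the repeated-refit calibration checks practical.

Numerical choices: a diagonal nugget of `1e-8 + 1e-9·diag` keeps the marginal
covariance nonsingular in the f → 0 limit (its effect on predictive quantiles
is below 10⁻⁶ log₁₀ units); log-parameters are clipped to |x| ≤ 20; walkers
whose prior log-density is −∞ skip the likelihood. Defaults: 32 walkers
(8 per nominal chain), 1000 warmup + 1000 retained ensemble steps, seed 1234,
`chains × samples` draws retained by even thinning. Convergence is summarized
by split-R-hat after thinning each walker series by its integrated
autocorrelation time and concatenating walkers into 4 pseudo-chains; R-hat
above 1.01 for any hyperparameter sets a warning flag (`converged=False`)
rather than raising, since short exploratory runs are legitimate.

### Prediction

Predictive distributions are equally weighted normal mixtures with one
conditional-normal component per posterior draw; quantiles invert the exact
mixture CDF (Brent's method, xtol 10⁻¹²), so they are monotone, nested, and
collapse to closed-form normal quantiles for degenerate single-draw fits.
Population-average prediction conditions on whatever observations a scenario
has; withheld-measurement prediction conditions only on PBK levels ≤ the
requested context and convolves with the clinical noise draw-by-draw. New
scenarios use the same code path as training scenarios because the likelihood
factorizes per scenario.

## Leave-one-exposure-out calibration

For every scenario with a measured C<sub>max</sub> and every PBK level X it
carries, the measurement and all levels above X are removed for that scenario
only, the model refit (seed derived deterministically from the base seed,
scenario key and level), and the withheld value compared against the
predictive. Central intervals are equal-tailed quantile intervals. Fold
exceedance is 10^(q95 − measured), computed once in log space; folds below 1
are included unclipped in the geometric mean by default (configurable),
because clipping would overstate how conservative the upper bounds are.

## POD estimation

The pharmacological-profiling workflow implements the screening rule (follow
up a target iff specific binding strictly exceeds 50% of control), the
screening-concentration choice (10 µM default; 100 µM when cytotoxicity is
absent or appears only above 100 µM), and a Bayesian Hill fit

`response = low + (high − low)·c^h/(xc50^h + c^h)` (decreasing form for
antagonist mode), with priors log₁₀(xc50) ~ N(log₁₀ median tested
concentration, 1), h ~ LogNormal(0, 0.5), low ~ N(0, 5)%, high ~ N(100, 5)%,
noise ~ HalfNormal(0, 10)%. Only the prior centers were externally specified;
the families and widths are this package's choices. Replicates are pooled; at
least 4 distinct concentrations are required (designs typically use 8 × 2
replicates).

Flat data (response span < 20%) are a special case: because the `high` prior
pins the amplitude near 100%, a no-response dataset would push the xc50
posterior arbitrarily far beyond the tested range instead of leaving it
unchanged. Since such data carry no information about the half-maximal
concentration, the fit returns the prior itself and sets the `uninformative`
flag; a fit whose xc50 posterior remains nearly as wide as the prior is
flagged the same way.

The minimum POD over a platform subset is a plain minimum and therefore
monotone under subset inclusion; BIFROST- and BMDL-derived PODs enter as
precomputed inputs.

## BER distributions and the decision model

BER draws are B = P/10^ζ with ζ drawn from the relevant C<sub>max</sub>
predictive; the point estimate is the geometric mean (equal to P divided by
the geometric-mean C<sub>max</sub>), and BER quantiles are defined through
the ζ draw set by q_p(BER) = P/10^(q_(1−p)(ζ)), which makes the quantile
identity exact on any draw set. Decisions at a PBK level condition only on
PBK estimates at that level and below (no clinical value), mirroring what an
ab initio assessment would actually have.

Consistent thresholds are derived top-down. At the highest level the
threshold BER solves `E_posterior[Φ((log₁₀T − dev)/sd)] = p_top` where (dev,
sd) are the per-draw conditional mean-deviation and sd of ζ for a reference
scenario observed only at that level — the mean deviations, driven by the
posterior spread of the bias terms, matter: without them the threshold rule
and the probability rule disagree systematically near the boundary. For each
lower level, the boundary scenario's point estimate shifts at the next level
by the gap noise ε ~ N(0, σ·f/(β+f)) (posterior-mixed, Monte-Carlo sampled
with the unknown-fraction defaults), and the smallest threshold keeping the
overturn probability ≤ 0.1 is `log₁₀T_lower = log₁₀T_upper − Q_0.1(ε)`. The
equivalent confidence threshold is the boundary scenario's Prob(BER > 1).
Strict inequalities are used throughout ("exceeds").

Protectiveness is the fraction of high-risk benchmark scenarios *not* called
low risk; utility is the fraction of low-risk scenarios called low risk; the
only alternative decision is "uncertain risk" — the workflow is deliberately
not a binary classifier. The point-biserial correlation between BER and the
binary label is computed per posterior draw on log₁₀ BER (raw BER spans six
orders of magnitude and would be outlier-dominated) using each draw's latent
ζ, then summarized by mean and central 95% interval.

## Synthetic data

The generator draws portfolios from exactly the generative chain above: ζ
uniform over log₁₀ [−3, 4] (0.004–4000 µM), f_L2L3 ~ U(0.05, 0.38), f_L1L2 ~
U(0.5, 1.0), clinical measurements present with probability 11/30, L3
estimates missing with probability 6/30, one minimum POD per chemical
log-uniform over [10⁻³, 10³] µM, and the risk label "high" iff the true BER
is below 1. Default true parameters: σ_clinical 0.07, α_L1 0.2, α_L2 0.15,
α_L3 0.1, σ_L3,pop 0.3, σ 0.6, β 0.3 — mid-prior values producing realistic
fold-errors (L3 estimates within ~2-fold, L1 estimates within ~10-fold of
truth most of the time). Concentration-response fixtures come from the Hill
equation plus Gaussian noise (default 8 concentrations spanning 4 decades,
2 replicates, 5% noise).

What the generator does *not* emulate: real portfolios share chemicals across
exposure scenarios (errors may correlate within a chemical), routes may have
different error structures, PODs correlate with chemical potency rather than
being independent of ζ, and benchmark labels come from expert judgement with
ambiguity near the boundary rather than from a sharp BER cut. Passing the
synthetic checks therefore demonstrates the statistical machinery is
self-consistent and well-calibrated *under the model's own assumptions*, not
that those assumptions hold for any particular real dataset.

## Problem sizes and reproducibility

Default study conditions use 30-scenario portfolios; the predictive
calibration benchmark uses a 100-scenario training portfolio (so parameter
uncertainty does not inflate the intervals being audited) and 200 withheld
measurements; parameter-recovery checks use 20 independent
simulate-fit replicates; Hill-fit recovery uses 20 curves. These sizes give
binomial tolerances tight enough to detect miscalibration while keeping the
full suite and the acceptance script fast on a single CPU. Every stochastic
step is driven by an explicit seed (fits derive substream seeds from the base
seed plus a stable context tag), so all outputs are bit-reproducible.

## Known limitations

- σ_clinical is only weakly identified by single measurements per scenario;
  its posterior is largely the informative prior, by design.
- The ensemble sampler's R-hat is computed over walker groups, which share an
  ensemble; the thinning step makes this a reasonable but not iron-clad
  diagnostic.
- The overturn-probability construction treats the boundary scenario's point
  estimate as exactly at threshold (worst admissible case) and uses the
  unknown-fraction defaults for the gap noise; scenarios with known, smaller
  f values overturn less often, so the guarantee is conservative for them.
- No route-specific error variances, no alternative likelihoods, and no
  population-variability layer; C_max is the sole exposure metric.
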