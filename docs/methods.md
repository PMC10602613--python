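# Methods

## Observation model

All analysis happens on y = ln(locule count). Natural log is used throughout
("mean log locule number" always means base e): effect *ratios* are
base-invariant, and base e keeps the likelihood algebra clean. Fruits are
modelled as independent draws y ~ Normal(μ(g), σ²) with one residual σ shared
across genotypes. σ is profiled out, so the maximized log-likelihood of any
mean structure is

    loglik = −(n/2) · (ln(2π·RSS/n) + 1),

a monotone function of the residual sum of squares; maximum likelihood is
least squares, and the linear families are exact OLS. A heteroscedastic
per-genotype σ was considered and rejected for the default: shared σ makes
the likelihood-ratio degrees of freedom well-defined (the σ parameter cancels
in every comparison) and the linear fits closed-form.

Plant-level clustering is deliberately *not* in the default likelihood — the
genotype mean structure is the estimand, and with balanced fruits per plant
the point estimates are unchanged by clustering. The synthetic generator can
inject plant random effects (τ > 0) precisely so the cost of ignoring them is
measurable, and a cluster-aware check is available through the parametric
bootstrap by simulating with τ > 0. Replicated field trials are pooled by
default (genotype identity keys on the three loci, not the trial);
`PhenotypeTable.split_by_trial()` supports stratified reanalysis.

## The model family

With background b (reference "WT" first) and focal indicator m:
μ(b, 0) = β_b, μ(b, 1) = β_b + E(b).

- **additive**: E(b) = δ.
- **constant**: E(WT) = δ_WT, E(b ≠ WT) = δ_mut.
- **proportional** (multilinear): E(b) = δ0·(1 + ε·(β_b − β_WT)). The
  strength covariate is the *centered fitted* background mean, so ε is a
  dimensionless slope per unit log-count and δ0 is the effect in the
  reference background.
- **sigmoid**: E(b) = A/(1 + exp(−(β_b − x0)/r)), r > 0. The covariate is
  β_b itself (matching the effect-vs-background-mean plots); the lower
  asymptote is fixed at 0, encoding an effect that is negligible in weak
  backgrounds — a modelling assumption, not a fitted quantity. A is the
  saturated effect, x0 the threshold (in mean-log units), r the transition
  width.
- **idiosyncratic**: E(b) = δ_b free — the saturated model; its fitted
  genotype means are exactly the per-genotype sample means of log counts.

Nesting is strict for additive ⊂ {constant, proportional} ⊂ idiosyncratic and
sigmoid ⊂ idiosyncratic. The sigmoid only reaches a constant or additive
effect in boundary limits (r → 0 with x0 below every background, or A → 0),
so comparisons of sigmoid against additive/constant/proportional are flagged
*approximate*: the χ² reference is reported, and a parametric-bootstrap
p-value (simulating under the small model's fit, p = (1 + #{stat_b ≥
stat_obs})/(B + 1)) is the recommended headline for those pairs. An
approximately nested pair can legitimately produce a negative LRT statistic
(e.g. a constant fit with nonzero reference effect lies outside the sigmoid
family); that is clipped to zero evidence. For strictly nested pairs a
negative statistic beyond tolerance is raised as an optimization failure.
Degrees of freedom are differences in mean-parameter counts: K+1 backgrounds
plus {1, 2, 2, 3, K+1} focal parameters. The scan reports raw p-values, with
AIC per family alongside; no multiplicity correction is applied by default.

## Fitting

Because every mean structure is constant within a (background, focal) cell,
fits operate on per-cell sufficient statistics (count, mean, within-cell sum
of squares); the within-cell scatter is an additive constant in the RSS, so
fitting cost is independent of the number of fruits.

Additive, constant and idiosyncratic fits are closed-form weighted least
squares on the cell means. Proportional and sigmoid involve the β's
nonlinearly (the strength covariate is itself fitted), so **all** parameters
are optimized jointly by multi-start bounded L-BFGS-B. Starts: a two-stage
estimate (β̂ = sample means of the m = 0 cells; focal parameters fit to the
observed per-background effect estimates), two deterministic boundary starts
for the sigmoid (the constant-effect corner x0 = min β̂ − 1, r ≈ 10⁻³, where
every background is saturated, and the no-effect start A = 0 — these make the
additive limit exactly reachable), and seeded jitter around the two-stage
point (32 starts by default). Bounds: r ∈ [10⁻³, 10], |A| ≤ 5, x0 within
[min β̂ − 1, max β̂ + 1], β within ±1.5 of the two-stage values. Ties within
tolerance in log-likelihood are broken toward the smaller focal-parameter
norm, making the reported fit deterministic for a fixed seed. A two-stage
variant (β frozen at sample means) is exposed as `method="two-stage"` for
comparison. Zero-RSS (interpolating) fits are floored at σ = 10⁻⁸ and flagged
degenerate; degenerate-vs-degenerate comparisons carry zero evidence.

Standard errors are Gauss–Newton: cov(θ̂) = s²(JᵀWJ)⁻¹ with J the numerical
Jacobian of the cell means in the parameters, W the cell counts, and
s² = RSS/(n − k).

One caveat discovered while validating the variance decomposition: because
the proportional and sigmoid families fit β jointly, their curved manifolds
can absorb some genuinely idiosyncratic structure (the absorbed
log-likelihood grows roughly like n·e⁴ for perturbations of size e). This is
a property of joint maximum likelihood, not an optimizer artifact; the
two-stage variant does not show it.

## Effects, variance decomposition, prediction

Background-specific effects are model-free: Δ̂(b) = mean log locule number of
the focal mutant minus that of its background genotype, with SE the
quadrature sum of the two genotype SEs (sd/√n each). These equal the
saturated model's fitted-mean differences exactly. Percent change is
computed on arithmetic means of raw counts by default (the scale of the
familiar percent-change axis); a log-scale alternative
(100·(exp Δ − 1)) is available via `log_scale_percent`.

The epistatic-variance fraction of family M is
(RSS_additive − RSS_M)/(RSS_additive − RSS_idiosyncratic), computed from
fruit-level RSS. An n-weighted genotype-mean version is algebraically
identical (the within-cell scatter cancels from both differences), so the
only distinct option offered is unweighted genotype means
(`level="genotype"`). The fraction is exactly 1 for the saturated family and
exactly 0 for additive; for the approximately nested sigmoid it can in
principle fall outside [0, 1] if the sigmoid fits worse than additive, in
which case it is reported as computed.

Saturated-effect prediction from a converged sigmoid fit returns Â, and
`predict_effect_at(x)` evaluates the fitted curve at any background strength
— used to ask whether triple-mutant effects approach the level predicted from
the pairwise series.

Triple-mutant (three-locus) data reuse the two-locus machinery with compound
backgrounds: background = (CLV3 allele, WUS state), focal locus CLE9, so a
6 × 2 × 2 factorial becomes 12 backgrounds × 2. Sign reversals in specific
compound backgrounds appear directly as negative effect estimates.

## Synthetic data

The generator mirrors the observation model: per genotype, N plants with
plant effects ~ Normal(0, τ²), n fruits per plant with residual Normal(0,
σ²) on the log scale. Defaults: τ = 0 (matching the default likelihood),
σ = 0.2 (a typical within-genotype log-scale spread for locule counts),
N = 5 plants, n = 10 fruits. The default background grid spans ln 2 ≈ 0.69
(wild-type fruits with ~2 locules) to ln 15 ≈ 2.7 (near-null promoter
alleles), the phenotypic range of the allelic series. Discretization
(count = max(2, round-half-even(exp y))) is available but off by default:
rounding plus the 2-locule floor biases the mean log of small-count genotypes
upward, and that generator artifact would masquerade as epistasis at large n.
Recovery and calibration studies therefore run on the continuous scale; the
bias is a documented limitation, not hidden. Consequently, passing tests
demonstrate correctness of the estimator under its assumed observation model;
they do not certify behaviour under count discreteness, overdispersion, or
trial-by-genotype interactions, none of which the generator emulates.

`simulate_study_standin` builds a *synthetic* study-scale dataset (46
genotypes, ~40,000 fruit records): a two-trial 2 × 12 factorial whose focal
effects are additive plus idiosyncratic perturbations (RMS 0.06)
Gram-Schmidt-orthogonalized against the constant and proportional contrasts
(so those comparisons are genuinely null while the saturated model is
overwhelmingly favored — the perturbation size is capped because of the
curvature-absorption effect noted above); a three-trial 2 × 12 factorial with
sigmoid effects (A = 0.4, x0 = 1.5, r = 0.2) plus small idiosyncratic
residuals (SD 0.02); a 6 × 2 × 2 triple factorial with a sign reversal in the
Pro-11/wus-lc cell; and four stand-alone single mutants. It exists so the
full pipeline can be exercised end-to-end at realistic scale without any
external data; it is a stand-in, not a reconstruction of any real dataset.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` use: 2,000 replicates for the
type-I calibration of the additive-vs-idiosyncratic LRT (6 backgrounds, 50
fruits/genotype, σ = 0.2; the observed rejection rate is compared with the
99% binomial interval around 0.05); 100 replicates at 500 fruits/genotype for
sigmoid parameter recovery, plus 30 replicates each at 50/200/800
fruits/genotype for the RMSE-consistency check; grid-oracle comparisons on
3-background instances; and the study stand-in at full scale for the
pipeline checks. These sizes give Monte-Carlo error comfortably inside each
check's tolerance.

## Known limitations

- The Gaussian-on-log model ignores count discreteness; no Poisson or
  negative-binomial variant is provided (deliberately out of scope).
- The sigmoid's lower asymptote is fixed at zero; series whose focal effect
  is nonzero even in the weakest backgrounds will push the fit toward the
  boundary starts.
- χ² reference distributions for the approximately nested sigmoid
  comparisons are heuristic; use the bootstrap p for headline claims.
- The LRT assumes independent fruits; strong plant effects (τ > 0) inflate
  type-I error, which can be quantified with the generator's τ scenarios.
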