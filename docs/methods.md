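# Methods

## The model

A model assumption is formulated as a hypothesis H₀ about a parameter — in
the shipped two-group setting, equality of variances, H₀: δ = 1 with
δ = σ₁²/σ₂². A rational analyst holds a prior plausibility
p₀ = P(H₀) strictly inside (0, 1): an analyst certain either way would
regard checking as redundant, and the Bayesian update degenerates at the
boundary, so boundary priors raise a hard error rather than a warning.

The assumption check is a significance test applied at level α with the
convention that H₀ is rejected when p < α and retained when p ≥ α (the
boundary retains). Conditional on a violation, the probability that the
check misses it depends on *which* violation is true, so the Type II error
entering the update is the catch-all average

β = Σᵢ P(¬R | Hᵢ) P(Hᵢ) / Σᵢ P(Hᵢ),

over the analyst's prior on specific alternatives. Bayes' rule then gives
the posterior plausibility after a nonrejection,

P(H₀ | ¬R) = p₀(1 − α) / (p₀(1 − α) + (1 − p₀)β),

equivalently posterior odds = prior odds × (1 − α)/β. Three consequences
drive the package's outputs:

- the check confirms H₀ (posterior > prior) precisely when α < 1 − β;
  with α = 1 − β the posterior equals the prior exactly;
- the *wrong-acceptance proportion* 1 − P(H₀ | ¬R) — the expected
  fraction of false assumptions among accepted ones — depends strongly on
  p₀; no power level short of 1 rescues an a-priori implausible
  assumption;
- with β = 0 and α < 1, survival of the check proves the assumption; the
  posterior is returned as exactly 1 with an `infinite_evidence` flag, and
  the odds factor as `inf`, rather than dividing by zero — the limit is
  well defined.

A parallel pathway updates with a Bayes factor for H₀ against its
complement (BF > 1 favours H₀): posterior odds = prior odds × BF.
Sequential updates compose multiplicatively.

## Parameters that matter

| parameter | meaning | default | rationale |
|---|---|---|---|
| p₀ | prior plausibility of the assumption | none (required) | elicitation is the analyst's job |
| α | level of the assumption check | 0.05 | conventional pretest level |
| effect prior on δ | plausibility of violation sizes | lognormal, median 1, log-sd 0.7 | symmetric in log δ (δ and 1/δ are the same violation relabelled); ~90% of mass on ratios between 1/3 and 3, the range a two-group study plausibly meets |
| quadrature grid | discretisation of the continuous prior | 81 trapezoid nodes on log δ ∈ [−4.6, 4.6] | covers ratios 1/100…100; spacing 0.115 makes the discretisation error of smooth power curves ≲ 10⁻³, far below Monte-Carlo bands |
| group sizes n₁, n₂ | per-scenario | 50/50 | a typical two-group study; size checks use 200/200 (below) |
| nsim | replicates per scenario | 10⁴–2×10⁴ | binomial SE ≲ .01 on cell rates |

All probabilities are decimal fractions; the CLI rejects percentage
strings outright to avoid α = 5 class errors.

## Power curves and the catch-all β

For the variance-ratio F test the power is exact: under δ the sample
variance ratio is δ times a central F(n₁−1, n₂−1) variate, and the
two-sided acceptance region takes equal tail areas α/2 (the standard
convention). For Levene's test — whose null distribution is only
asymptotically F — power is estimated by seeded Monte Carlo. The
`PowerCurve.levene_mc` estimator draws one block of standard normals and
rescales it for every δ queried (common random numbers), which makes the
estimated curve smooth and monotone in δ and therefore safe to bisect when
inverting power to an effect size (`match_power`, tolerance .005 on
power).

The catch-all β is the power curve integrated against the effect prior on
the violation region; any point mass at δ = 1 belongs to the null and is
excluded. Aggregation against a discrete alternative set is the weighted
mean of per-alternative miss probabilities and always stays inside their
convex hull.

## The tests

Levene's statistic is the one-way ANOVA F on absolute deviations from the
per-group mean (the classical form; median centering — the Brown–Forsythe
variant — is available via a flag). It is implemented as a vectorised
batch operation so that 10⁵-replicate power and size studies run in
seconds; the scalar path is the batch path with one replicate, and the
test suite cross-checks it against an independent reference
implementation. Degenerate-data convention: if both groups are constant
there is no spread information and an error is raised; identical nonzero
deviation patterns give F = 0, p = 1; zero within-group scatter with
between-group spread gives F = +∞, p = 0.

Student's and Welch's t are the standard pooled-variance and
Satterthwaite forms, two-sided.

The equal-variances Bayes factor is a deliberately minimal
sufficient-statistic computation: each sample variance is modelled as a
scaled chi-square with its group's degrees of freedom, σ₁² = δσ₂², the
common scale σ₂² carries a Jeffreys prior and integrates out in closed
form, and the marginal likelihood at δ = 1 is compared with its average
over the effect prior (log-sum-exp on the quadrature grid). It is
invariant to rescaling both groups by a common constant and — for a
log-symmetric prior — to swapping the groups, for any group sizes (the
substitution δ → 1/δ maps the swapped marginal onto the original). It is
*not* a general or default-prior Bayes-factor method for variance
hypotheses; it exists so the Bayes-factor pathway can be exercised end to
end on real data.

## Simulation designs

**Truth-then-data sampling.** Each replicate first draws the truth — H₀
with probability p₀, otherwise δ from the effect prior — then generates
Gaussian two-group data and applies the check. This hierarchical scheme is
the one under which the closed-form wrong-acceptance proportion is an
expected error rate, which is exactly the claim being validated.
Continuous priors are sampled from the *continuous* family, not from the
quadrature grid, so agreement between simulation and quadrature also
bounds the discretisation error.

**Power-matched cell validation.** The wrong-acceptance grid is indexed by
power, not by effect size, so validating a cell requires finding the δ
whose Levene power equals the column label at the scenario's n; this is
done by bisection on the common-random-numbers Monte-Carlo power curve
(tolerance .005). The empirical rate is compared with the *unrounded*
closed-form value within 3 binomial SE; separately the closed form is
checked to round to the published-style 2-decimal cell (within half a
printing unit). Comparing simulation directly against a 2-decimal rounded
value would conflate Monte-Carlo error with quantisation error and fail
more often the *more* replicates one runs.

**Gated two-stage procedure.** The everyday practice — Levene at level
α₁, then Student's t if the gate passes and Welch's t if it fails — is
simulated under equal means to measure its realised size, overall and per
truth arm. Under equal variances and balanced groups the realised size
sits at the nominal level; under unequal variances with unequal group
sizes the pooled t is anticonservative and the gate's routing to Welch is
what keeps the realised size in check — the per-arm report makes this
visible.

**Seeding.** Every scenario carries an integer seed; a master seed spawns
independent substreams (numpy `SeedSequence`) for the power curve and each
simulated cell, so results are bit-reproducible and independent of
execution order. Identical scenario specs produce byte-identical record
files.

## Problem sizes

Closed-form checks run on dense grids (50³ parameter combinations) in
milliseconds. Stochastic validations use 20 000 replicates per
wrong-acceptance cell at n = 50/50, 10⁵ replicates for size checks, and
10⁵ hierarchical draws for quadrature-vs-simulation agreement; these sizes
put 3-SE bands at a few times 10⁻³, tight enough to detect any defect that
would matter at the precision the closed forms are quoted to.

Size checks use n = 200 per group. The mean-centred Levene statistic is
only asymptotically F-distributed, and its finite-sample size at α = .05
is measurably liberal: ≈ .052 at n = 50, .0507 at n = 100, .0505 at
n = 200 (2×10⁶-replicate measurements). At n = 200 the residual deviation
is well inside a 3-SE band at 10⁵ replicates, so the nominal-size property
is tested where the approximation it asserts actually holds; the n = 50
liberality is documented and asserted as such in the unit suite.

## What the generator does and does not emulate

The synthetic-data module generates independent Gaussian samples with
specified means and variances — the exact setting in which the two-group
theory is derived. It does not emulate skewed or heavy-tailed responses
(e.g. raw reaction times), unequal-shape alternatives, or dependence
within groups. Passing tests therefore certify the probability
calculus and the operating characteristics of the tests *under
Gaussianity*; they say nothing about Levene's robustness to
non-normality, which is a property of the test, not of the updating
framework.

## Known limitations

- One assumption at a time: no joint updating across several assumptions
  of the same model.
- The shipped power curves cover the two variance tests only; other
  checks require a user-supplied curve.
- The Bayes factor is the minimal two-group construction described above;
  analysts with more than two groups or informed variance priors should
  compute a Bayes factor elsewhere and feed it to the updating pathway.
- Posterior-after-rejection is provided for completeness of the Bayes
  complement; published wrong-acceptance analyses condition on
  nonrejection, and no external anchor exists for the rejection branch.
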