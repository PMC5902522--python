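# plausitest

**How plausible is a statistical model assumption after you have "checked" it?**

Before running a Student's *t* test, a careful analyst checks the
equal-variances assumption with Levene's test; a nonsignificant result is
then routinely read as licensing the assumption. `plausitest` quantifies
what that nonrejection is actually worth. It treats the assumption as a
hypothesis H₀ with a prior plausibility *p*₀ = P(H₀) ∈ (0, 1), the check as
a diagnostic instrument with level α = P(R | H₀) and *catch-all* Type II
error

β = P(¬R | ¬H₀) = Σᵢ P(¬R | Hᵢ) P(Hᵢ) / Σᵢ P(Hᵢ),

the miss probability averaged over the analyst's prior on specific
violations Hᵢ — and applies Bayes' rule:

P(H₀ | ¬R) = p₀(1 − α) / (p₀(1 − α) + (1 − p₀)β).

The complement 1 − P(H₀ | ¬R) is the **wrong-acceptance proportion**: the
long-run fraction of accepted-but-false assumptions among all acceptances —
the error rate that actually determines how often an inappropriate model
ends up in use. A nonrejection raises plausibility only when the check is
*informative* (α < 1 − β), and never to certainty: with a prior of .10 and
power .90 at α = .05, roughly half of all acceptances are still wrong.
The same update can be driven directly by a Bayes factor: posterior odds =
prior odds × BF.

The package covers, for the two-group equal-variances setting
(δ = σ₁²/σ₂², H₀: δ = 1):

- closed-form posterior plausibility, odds-update factors, and
  wrong-acceptance tables (`plausitest.core`);
- exact and Monte-Carlo power curves (variance-ratio F test, Levene's
  test), priors over δ, and their aggregation into β (`plausitest.power`);
- Levene / Student / Welch tests, CSV input, and a minimal
  sufficient-statistic Bayes factor for equal variances
  (`plausitest.twogroup`);
- seeded truth-then-data simulations validating the closed forms,
  including the common Levene-gated Student/Welch workflow
  (`plausitest.simulate`);
- a command-line interface (`plausitest update | table | check | simulate`).

## Worked example

A skeptical analyst (prior plausibility .10 that the variances are equal)
obtains a Bayes factor of 1.070 for equality — essentially no evidence
either way:

```
$ plausitest update --prior 0.1 --bf 1.070
plausibility update
===================

inputs:
  prior: 0.1
  decimals: 4
  pathway: bayes_factor
  bayes_factor: 1.07
results:
  posterior: 0.1063
  posterior_odds: 0.1189
```

The posterior (.106) barely moves: skepticism before, skepticism after —
even though a conventional pretest would have "accepted" the assumption.

The `check` command runs the whole workflow on data. Here the file was
generated with a true variance ratio of 2.5 at n = 50 per group:

```
$ plausitest check speed.csv --prior 0.1 --with-bf --seed 0
two-group assumption check
==========================
...
results:
  levene_F: 8.93674
  levene_p: 0.00353346
  student_t: -1.75157
  student_p: 0.0829756
  welch_t: -1.75157
  welch_p: 0.083644
  gated_choice: welch_t
  variance_ratio: 2.71882
  assessed_power: 0.426096
  posterior_equal_variances: 0.0128704
  bayes_factor: 0.0174968
  posterior_from_bf: 0.00194032
```

Levene's test fires (p = .0035), so the gate routes to Welch's *t*; the
posterior plausibility of equal variances drops from .10 to .013 through
the significance pathway and to .002 through the Bayes-factor pathway.
`assessed_power` is the Levene power averaged over the default lognormal
prior on δ (median 1, log-sd 0.7) at these group sizes.

The wrong-acceptance grid (α = .05) ships as `plausitest table`; the cell
for prior .10 and power .90 reads .49 — about half of such acceptances are
expected to be wrong.

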