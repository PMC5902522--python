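"""Monte-Carlo validation of the plausibility framework.

Two study designs are simulated, both fully seeded and reproducible:

* **Wrong-acceptance runs** — for each replicate, nature first draws the
  truth (the equal-variance null with probability ``p0``, otherwise a
  variance ratio from the effect prior), then Gaussian two-group data are
  generated and Levene's test applied.  Among replicates where the check
  does not fire, the fraction whose null was actually false is the
  empirical wrong-acceptance rate; the closed-form posterior from
  :mod:`plausitest.core` predicts it.  Truth-then-data sampling is the
  scheme under which that prediction is an expected error rate.

* **Gated t-test runs** — the common two-stage practice: Levene first,
  then Student's t if the check passes and Welch's t if it fails.  With
  equal group means, the rejection rate of the chosen test is the realised
  size of the two-stage procedure, reported separately for equal- and
  unequal-variance truth arms.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import PlausibilityPrior, OperatingCharacteristics, posterior_after_nonrejection
from .errors import DomainError, UndefinedRateError
from .power import EffectPrior, PowerCurve, integrate_power_over_prior
from .twogroup import TwoGroupSample, _levene_f_batch, levene_test, student_t, welch_t

__all__ = [
    "ScenarioSpec",
    "SimulationSummary",
    "GatedRecord",
    "generate_two_group",
    "run_gated_ttest",
    "estimate_wrong_acceptance_rate",
    "estimate_gated_type1",
    "validate_table1",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Complete description of a simulation scenario.

    ``p0`` is the probability with which nature makes the equal-variance
    null true in a replicate; when it is false, the variance ratio is drawn
    from ``effect_prior``.  Group 1 receives variance ``delta *
    base_variance``, group 2 ``base_variance``.  ``fixed_truth`` permits
    the degenerate frequencies 0 and 1 for runs that pin the truth (e.g. a
    pure size check); otherwise the prior must be strictly interior, as in
    the belief-updating framework.
    """

    p0: float
    effect_prior: EffectPrior
    n1: int = 50
    n2: int = 50
    mu1: float = 0.0
    mu2: float = 0.0
    base_variance: float = 1.0
    alpha_assumption: float = 0.05
    alpha_primary: float = 0.05
    nsim: int = 10_000
    seed: int = 0
    fixed_truth: bool = False

    def __post_init__(self) -> None:
        if self.fixed_truth:
            if not 0.0 <= self.p0 <= 1.0:
                raise DomainError("p0 must lie in [0, 1]")
        elif not 0.0 < self.p0 < 1.0:
            raise DomainError(
                "p0 must lie strictly in (0, 1); set fixed_truth=True to pin the truth"
            )
        if self.n1 < 2 or self.n2 < 2:
            raise DomainError("group sizes must be at least 2")
        if self.base_variance <= 0:
            raise DomainError("base_variance must be positive")
        for name in ("alpha_assumption", "alpha_primary"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise DomainError(f"{name} must lie in (0, 1), got {a!r}")
        if self.nsim < 100:
            raise DomainError("nsim must be at least 100")

    def to_dict(self) -> dict:
        d = {
            "p0": self.p0,
            "effect_prior": self.effect_prior.to_dict(),
            "n1": self.n1,
            "n2": self.n2,
            "mu1": self.mu1,
            "mu2": self.mu2,
            "base_variance": self.base_variance,
            "alpha_assumption": self.alpha_assumption,
            "alpha_primary": self.alpha_primary,
            "nsim": self.nsim,
            "seed": self.seed,
        }
        if self.fixed_truth:
            d["fixed_truth"] = True
        return d

    @classmethod
    def from_dict(cls, spec: dict) -> "ScenarioSpec":
        spec = dict(spec)
        known = {
            "p0", "effect_prior", "n1", "n2", "mu1", "mu2", "base_variance",
            "alpha_assumption", "alpha_primary", "nsim", "seed", "fixed_truth",
        }
        unknown = set(spec) - known
        if unknown:
            raise DomainError(f"unknown scenario keys: {sorted(unknown)}")
        if "effect_prior" not in spec or "p0" not in spec:
            raise DomainError("scenario requires at least 'p0' and 'effect_prior'")
        spec["effect_prior"] = EffectPrior.from_dict(spec["effect_prior"])
        return cls(**spec)

    def digest(self) -> str:
        """Stable hash of the scenario for provenance sidecars."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class GatedRecord:
    """One pass through the Levene-gated t-test workflow."""

    levene_p: float
    test_used: str  # "student_t" when the gate passes, "welch_t" otherwise
    primary_p: float
    reject: bool
    alpha_levene: float
    alpha_t: float


@dataclass(frozen=True)
class SimulationSummary:
    """Aggregated outcome of a seeded scenario run.

    ``records`` holds one row per replicate (truth delta, Levene p, chosen
    test, primary p, decisions), so every headline rate can be recomputed
    from it.  Counts always sum to ``nsim``.
    """

    spec: ScenarioSpec
    n_reject: int
    n_nonreject: int
    n_wrong_acceptances: int
    empirical_wrong_acceptance_rate: float | None
    wrong_acceptance_se: float | None
    analytic_prediction: float | None
    gated_rejection_rate: float
    gated_rejection_se: float
    arm_rates: dict = field(default_factory=dict)
    records: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    def write(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write per-replicate records as CSV plus a JSON metadata sidecar."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        csv_path = prefix.with_suffix(".csv")
        json_path = prefix.with_suffix(".json")
        self.records.to_csv(csv_path, index=False)
        meta = {
            "spec": self.spec.to_dict(),
            "spec_digest": self.spec.digest(),
            "n_reject": self.n_reject,
            "n_nonreject": self.n_nonreject,
            "n_wrong_acceptances": self.n_wrong_acceptances,
            "empirical_wrong_acceptance_rate": self.empirical_wrong_acceptance_rate,
            "wrong_acceptance_se": self.wrong_acceptance_se,
            "analytic_prediction": self.analytic_prediction,
            "gated_rejection_rate": self.gated_rejection_rate,
            "gated_rejection_se": self.gated_rejection_se,
            "arm_rates": self.arm_rates,
        }
        json_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
        return csv_path, json_path


def generate_two_group(
    n1: int,
    n2: int,
    mu1: float,
    mu2: float,
    var1: float,
    var2: float,
    rng: np.random.Generator,
) -> TwoGroupSample:
    """Independent Gaussian two-group sample with the given means and variances."""
    if var1 <= 0 or var2 <= 0:
        raise DomainError("variances must be positive")
    g1 = rng.normal(mu1, math.sqrt(var1), size=n1)
    g2 = rng.normal(mu2, math.sqrt(var2), size=n2)
    return TwoGroupSample(g1, g2)


def run_gated_ttest(
    sample: TwoGroupSample, alpha_levene: float = 0.05, alpha_t: float = 0.05
) -> GatedRecord:
    """Run the two-stage workflow on one sample.

    Levene's test gates the choice of the primary test: Student's t when
    its p-value is at least ``alpha_levene`` (no detected violation),
    Welch's t otherwise.
    """
    lev = levene_test(sample)
    if lev.p_value >= alpha_levene:
        primary = student_t(sample)
    else:
        primary = welch_t(sample)
    return GatedRecord(
        levene_p=lev.p_value,
        test_used=primary.test_name,
        primary_p=primary.p_value,
        reject=primary.p_value < alpha_t,
        alpha_levene=alpha_levene,
        alpha_t=alpha_t,
    )


# ---------------------------------------------------------------------------
# Vectorised batch machinery


def _t_batch(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Student and Welch p-values over a batch, shape (reps, n) each."""
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1, v2 = x1.var(axis=1, ddof=1), x2.var(axis=1, ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    t_s = (m1 - m2) / np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    p_student = 2.0 * stats.t.sf(np.abs(t_s), n1 + n2 - 2)
    se2 = v1 / n1 + v2 / n2
    t_w = (m1 - m2) / np.sqrt(se2)
    df_w = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p_welch = 2.0 * stats.t.sf(np.abs(t_w), df_w)
    return p_student, p_welch


def _simulate_records(spec: ScenarioSpec) -> pd.DataFrame:
    """Run all replicates of a scenario and return the per-replicate table."""
    rng = np.random.default_rng(spec.seed)
    nsim = spec.nsim
    null_true = rng.random(nsim) < spec.p0
    deltas = np.ones(nsim)
    n_false = int((~null_true).sum())
    if n_false:
        deltas[~null_true] = spec.effect_prior.sample(rng, n_false)
    sd1 = np.sqrt(deltas * spec.base_variance)
    sd2 = math.sqrt(spec.base_variance)
    x1 = spec.mu1 + sd1[:, None] * rng.standard_normal((nsim, spec.n1))
    x2 = spec.mu2 + sd2 * rng.standard_normal((nsim, spec.n2))

    f, df1, df2 = _levene_f_batch(x1, x2)
    levene_p = stats.f.sf(f, df1, df2)
    gate_welch = levene_p < spec.alpha_assumption
    p_student, p_welch = _t_batch(x1, x2)
    primary_p = np.where(gate_welch, p_welch, p_student)

    return pd.DataFrame(
        {
            "null_true": null_true,
            "truth_delta": deltas,
            "levene_p": levene_p,
            "levene_reject": gate_welch,
            "test_used": np.where(gate_welch, "welch_t", "student_t"),
            "primary_p": primary_p,
            "primary_reject": primary_p < spec.alpha_primary,
        }
    )


def _wrap_summary(
    spec: ScenarioSpec, records: pd.DataFrame, analytic: float | None
) -> SimulationSummary:
    nonreject = ~records["levene_reject"]
    n_nonreject = int(nonreject.sum())
    n_reject = spec.nsim - n_nonreject
    wrong = nonreject & ~records["null_true"]
    n_wrong = int(wrong.sum())
    if n_nonreject > 0:
        rate = n_wrong / n_nonreject
        se = math.sqrt(rate * (1.0 - rate) / n_nonreject)
    else:
        rate = se = None
    gated = float(records["primary_reject"].mean())
    gated_se = math.sqrt(gated * (1.0 - gated) / spec.nsim)
    arms = {}
    for truth, name in ((True, "equal_variance"), (False, "unequal_variance")):
        mask = records["null_true"] == truth
        n_arm = int(mask.sum())
        if n_arm:
            r = float(records.loc[mask, "primary_reject"].mean())
            arms[name] = {
                "n": n_arm,
                "rejection_rate": r,
                "se": math.sqrt(r * (1.0 - r) / n_arm),
            }
    return SimulationSummary(
        spec=spec,
        n_reject=n_reject,
        n_nonreject=n_nonreject,
        n_wrong_acceptances=n_wrong,
        empirical_wrong_acceptance_rate=rate,
        wrong_acceptance_se=se,
        analytic_prediction=analytic,
        gated_rejection_rate=gated,
        gated_rejection_se=gated_se,
        arm_rates=arms,
        records=records,
    )


def _analytic_wrong_acceptance(spec: ScenarioSpec, power_nsim: int = 20_000) -> float | None:
    """Closed-form prediction of the wrong-acceptance rate for a scenario.

    The catch-all Type II error is the Levene power curve (Monte-Carlo,
    common random numbers, its own seeded stream) integrated against the
    scenario's effect prior; the posterior then comes from the closed-form
    nonrejection update.
    """
    if not 0.0 < spec.p0 < 1.0:
        return 0.0 if spec.p0 == 1.0 else 1.0
    curve = PowerCurve.levene_mc(
        spec.n1, spec.n2, spec.alpha_assumption, nsim=power_nsim, seed=spec.seed + 101
    )
    expected_power = integrate_power_over_prior(curve, spec.effect_prior)
    post = posterior_after_nonrejection(
        PlausibilityPrior(spec.p0),
        OperatingCharacteristics(alpha=spec.alpha_assumption, beta=1.0 - expected_power),
    )
    return post.complement


def estimate_wrong_acceptance_rate(
    spec: ScenarioSpec, power_nsim: int = 20_000
) -> SimulationSummary:
    """Empirical wrong-acceptance rate of the Levene check under a scenario.

    Runs the truth-then-data simulation and compares the observed fraction
    of false nulls among nonrejections with the closed-form posterior
    prediction (``analytic_prediction``).
    """
    records = _simulate_records(spec)
    analytic = _analytic_wrong_acceptance(spec, power_nsim=power_nsim)
    summary = _wrap_summary(spec, records, analytic)
    if summary.n_nonreject == 0:
        raise UndefinedRateError(
            "no nonrejections in this run; the wrong-acceptance rate is undefined"
        )
    return summary


def estimate_gated_type1(spec: ScenarioSpec) -> SimulationSummary:
    """Realised size of the Levene-gated t procedure under equal means.

    Requires ``mu1 == mu2`` so that every rejection of the chosen t test is
    a Type I error.  Rates are reported overall and per truth arm; the
    deviation from the nominal level under unequal variances with unequal
    group sizes is the quantity of interest.
    """
    if spec.mu1 != spec.mu2:
        raise DomainError("estimate_gated_type1 requires mu1 == mu2 (size under the null)")
    records = _simulate_records(spec)
    return _wrap_summary(spec, records, None)


def validate_table1(
    priors: list[float],
    powers: list[float],
    alpha: float = 0.05,
    nsim: int = 20_000,
    seed: int = 0,
    n1: int = 50,
    n2: int = 50,
    power_nsim: int = 20_000,
    power_tol: float = 0.005,
) -> pd.DataFrame:
    """Empirically validate wrong-acceptance cells by power-matched simulation.

    For each (prior, power) cell, a variance ratio delta >= 1 is tuned by
    bisection on the Monte-Carlo Levene power curve until the test's power
    matches the column label; the scenario is then simulated with a point
    mass at that delta and the empirical wrong-acceptance rate compared
    with the closed-form cell value.  Cells whose power is unattainable at
    the given group sizes are flagged rather than simulated.
    """
    ss = np.random.SeedSequence(seed)
    curve_seed, *cell_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(1 + len(priors) * len(powers))
    ]
    curve = PowerCurve.levene_mc(n1, n2, alpha, nsim=power_nsim, seed=curve_seed)
    rows = []
    k = 0
    for p0 in priors:
        for pw in powers:
            cell_seed = cell_seeds[k]
            k += 1
            analytic = (
                posterior_after_nonrejection(
                    PlausibilityPrior(p0), OperatingCharacteristics(alpha, 1.0 - pw)
                ).complement
            )
            try:
                delta = curve.match_power(pw, tol=power_tol)
            except DomainError:
                rows.append(
                    dict(prior=p0, power=pw, attainable=False, delta=np.nan,
                         empirical=np.nan, se=np.nan, analytic=analytic,
                         n_nonreject=0, abs_error=np.nan, within_3se=False)
                )
                continue
            spec = ScenarioSpec(
                p0=p0,
                effect_prior=EffectPrior.point_mass(delta),
                n1=n1,
                n2=n2,
                alpha_assumption=alpha,
                nsim=nsim,
                seed=cell_seed,
            )
            records = _simulate_records(spec)
            summary = _wrap_summary(spec, records, analytic)
            rate, se = summary.empirical_wrong_acceptance_rate, summary.wrong_acceptance_se
            rows.append(
                dict(
                    prior=p0,
                    power=pw,
                    attainable=True,
                    delta=delta,
                    empirical=rate,
                    se=se,
                    analytic=analytic,
                    n_nonreject=summary.n_nonreject,
                    abs_error=abs(rate - analytic),
                    within_3se=abs(rate - analytic) <= 3.0 * se,
                )
            )
    return pd.DataFrame(rows)
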