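"""Two-group assumption and mean tests: Levene, Student t, Welch t, variance BF.

These are the ingredients of the everyday "gated" workflow: check equal
variances with Levene's test, then run Student's t if the check does not
fire and Welch's t if it does.  A small marginal-likelihood Bayes factor
for equality of two variances is included so the plausibility update can
be driven by the evidence in the data rather than by a thresholded
p-value.  The Bayes factor here is a deliberately minimal sufficient-
statistic computation for two groups, not a general Bayes-factor method
for variance hypotheses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .errors import DegenerateDataError, DomainError
from .power import EffectPrior

__all__ = [
    "TwoGroupSample",
    "TestResult",
    "levene_test",
    "student_t",
    "welch_t",
    "bf_equal_variances",
    "read_two_group",
]


@dataclass(frozen=True)
class TwoGroupSample:
    """Two independent samples of real observations."""

    group1: np.ndarray
    group2: np.ndarray
    labels: tuple[str, str] = ("group1", "group2")

    def __post_init__(self) -> None:
        g1 = np.asarray(self.group1, dtype=float)
        g2 = np.asarray(self.group2, dtype=float)
        for g, lab in ((g1, self.labels[0]), (g2, self.labels[1])):
            if g.ndim != 1 or g.size < 2:
                raise DomainError(f"group {lab!r} needs at least 2 observations")
            if not np.all(np.isfinite(g)):
                raise DomainError(f"group {lab!r} contains non-finite values")
        object.__setattr__(self, "group1", g1)
        object.__setattr__(self, "group2", g2)

    @property
    def n1(self) -> int:
        return self.group1.size

    @property
    def n2(self) -> int:
        return self.group2.size

    def swapped(self) -> "TwoGroupSample":
        return TwoGroupSample(self.group2, self.group1, (self.labels[1], self.labels[0]))


@dataclass(frozen=True)
class TestResult:
    """Outcome of a frequentist test: statistic, degrees of freedom, p-value."""

    statistic: float
    df1: float
    df2: float | None
    p_value: float
    test_name: str


def read_two_group(
    path: str | Path,
    value_col: str = "value",
    group_col: str = "group",
    sep: str | None = None,
) -> TwoGroupSample:
    """Load a two-group sample from a CSV/TSV file.

    The file must contain one numeric value column and one group column
    with exactly two distinct labels.  ``sep=None`` sniffs comma vs tab.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    for col in (value_col, group_col):
        if col not in df.columns:
            raise DomainError(
                f"column {col!r} not found in {path} (columns: {list(df.columns)})"
            )
    values = pd.to_numeric(df[value_col], errors="raise")
    groups = df[group_col].astype(str)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise DomainError(
            f"group column {group_col!r} must have exactly 2 distinct labels, "
            f"found {len(labels)}: {labels}"
        )
    return TwoGroupSample(
        values[groups == labels[0]].to_numpy(),
        values[groups == labels[1]].to_numpy(),
        (labels[0], labels[1]),
    )


# ---------------------------------------------------------------------------
# Levene's test


def _levene_f_batch(
    x1: np.ndarray, x2: np.ndarray, center: str = "mean"
) -> tuple[np.ndarray, int, int]:
    """Levene F statistic for a batch of replicates, shape (reps, n) per group.

    One-way ANOVA F on absolute deviations from the per-group center
    (mean, or median for the Brown–Forsythe variant), df (1, n1+n2-2).
    """
    if center not in ("mean", "median"):
        raise DomainError(f"center must be 'mean' or 'median', got {center!r}")
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    loc = np.mean if center == "mean" else np.median
    z1 = np.abs(x1 - loc(x1, axis=1, keepdims=True))
    z2 = np.abs(x2 - loc(x2, axis=1, keepdims=True))
    n1, n2 = z1.shape[1], z2.shape[1]
    m1 = z1.mean(axis=1)
    m2 = z2.mean(axis=1)
    grand = (n1 * m1 + n2 * m2) / (n1 + n2)
    ssb = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
    ssw = ((z1 - m1[:, None]) ** 2).sum(axis=1) + ((z2 - m2[:, None]) ** 2).sum(axis=1)
    df2 = n1 + n2 - 2
    # NaN only when both groups are constant (no deviation information at
    # all); identical nonzero deviations give SSB = 0 hence F = 0, and a
    # zero within-group SS with spread between groups gives F = +inf.
    all_const = (np.ptp(z1, axis=1) == 0) & (np.ptp(z2, axis=1) == 0) & (z1[:, 0] == 0) & (
        z2[:, 0] == 0
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(
            ssw > 0,
            ssb / (ssw / df2),
            np.where(ssb > 0, np.inf, 0.0),
        )
    f = np.where(all_const, np.nan, f)
    return f, 1, df2


def levene_test(sample: TwoGroupSample, center: str = "mean") -> TestResult:
    """Levene's test for equality of the two group variances.

    Mean centering is the classical form; ``center='median'`` gives the
    Brown–Forsythe variant.  The statistic is the one-way ANOVA F on
    absolute deviations from the center, df (1, n1+n2-2), upper-tail p.
    """
    f, df1, df2 = _levene_f_batch(sample.group1, sample.group2, center=center)
    f = float(f[0])
    if math.isnan(f):
        raise DegenerateDataError(
            "Levene statistic undefined: zero spread of absolute deviations in both groups"
        )
    p = float(stats.f.sf(f, df1, df2))
    return TestResult(f, float(df1), float(df2), p, f"levene[{center}]")


# ---------------------------------------------------------------------------
# t tests (thin wrappers over scipy)


def student_t(sample: TwoGroupSample) -> TestResult:
    """Two-sided pooled-variance (Student) t test, df n1+n2-2."""
    v1 = sample.group1.var(ddof=1)
    v2 = sample.group2.var(ddof=1)
    if ((sample.n1 - 1) * v1 + (sample.n2 - 1) * v2) == 0:
        raise DegenerateDataError("pooled variance is zero; t statistic undefined")
    res = stats.ttest_ind(sample.group1, sample.group2, equal_var=True)
    return TestResult(float(res.statistic), float(res.df), None, float(res.pvalue), "student_t")


def welch_t(sample: TwoGroupSample) -> TestResult:
    """Two-sided Welch t test with Welch–Satterthwaite fractional df."""
    if sample.group1.var(ddof=1) == 0 or sample.group2.var(ddof=1) == 0:
        raise DegenerateDataError("a group has zero variance; Welch statistic undefined")
    res = stats.ttest_ind(sample.group1, sample.group2, equal_var=False)
    return TestResult(float(res.statistic), float(res.df), None, float(res.pvalue), "welch_t")


# ---------------------------------------------------------------------------
# Bayes factor for equal variances


def _log_marginal_variance_ratio(
    s1: float, s2: float, nu1: int, nu2: int, delta: np.ndarray
) -> np.ndarray:
    """Log marginal density of the two sample variances given a variance ratio.

    Model: nu_k * s_k^2 / sigma_k^2 ~ chi-square(nu_k) with sigma1^2 =
    delta * sigma2^2; the shared scale sigma2^2 carries the Jeffreys prior
    1/sigma^2 and integrates out in closed form (inverse-gamma conjugacy).
    Terms constant in delta are dropped — they cancel in the Bayes factor.
    """
    a1, a2 = nu1 / 2.0, nu2 / 2.0
    delta = np.asarray(delta, dtype=float)
    return -a1 * np.log(delta) - (a1 + a2) * np.log(a1 * s1 / delta + a2 * s2)


def bf_equal_variances(sample: TwoGroupSample, prior: EffectPrior | None = None) -> float:
    """Bayes factor for equal variances (H0: delta = 1) against the catch-all.

    The marginal likelihood of the sufficient statistics (the two sample
    variances) at delta = 1 is compared with its average over the prior on
    the violation ratios: BF = m(delta=1) / integral m(delta) dPrior.
    Values above 1 favour equality.  Invariant to rescaling both groups by
    a common constant and, for a log-symmetric prior, to swapping groups.
    """
    if prior is None:
        prior = EffectPrior.lognormal()
    s1 = float(sample.group1.var(ddof=1))
    s2 = float(sample.group2.var(ddof=1))
    if s1 <= 0 or s2 <= 0:
        raise DegenerateDataError("both sample variances must be positive for the BF")
    nu1, nu2 = sample.n1 - 1, sample.n2 - 1
    log_m0 = float(_log_marginal_variance_ratio(s1, s2, nu1, nu2, np.array([1.0]))[0])
    log_mi = _log_marginal_variance_ratio(s1, s2, nu1, nu2, prior.deltas)
    log_m1 = float(logsumexp(log_mi, b=prior.weights))
    bf = math.exp(log_m0 - log_m1)
    if not math.isfinite(bf):
        raise DomainError(
            f"non-finite Bayes factor (log m0={log_m0!r}, log m1={log_m1!r}); "
            "check the prior grid against the data scale"
        )
    return bf
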