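"""Prior-to-posterior updating of assumption plausibility.

A model assumption (equal variances, normality, ...) is routinely checked
with a null-hypothesis significance test in which the assumption itself is
the null hypothesis H0.  A nonsignificant result is then commonly read as
licensing the assumption.  This module quantifies what such a nonrejection
is actually worth: starting from an analyst's prior plausibility
``p0 = P(H0)`` and the operating characteristics of the check — its level
``alpha = P(reject | H0)`` and its catch-all Type II error
``beta = P(not reject | H0 false)`` — Bayes' rule gives the posterior
plausibility of the assumption after a nonrejection,

    P(H0 | not reject) = p0 (1 - alpha) / (p0 (1 - alpha) + (1 - p0) beta),

the multiplicative odds-update factor ``(1 - alpha) / beta``, and the
complement quantity of practical interest: the expected proportion of
accepted-but-false assumptions among all acceptances (the wrong-acceptance
proportion).  A parallel update from a Bayes factor is provided for
workflows that quantify the evidence directly instead of thresholding a
p-value.

All probabilities are decimal fractions in [0, 1], never percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Sequence

import numpy as np

from .errors import DegeneratePriorError, DomainError

__all__ = [
    "PlausibilityPrior",
    "OperatingCharacteristics",
    "Decision",
    "DecisionOutcome",
    "Conditioning",
    "PosteriorPlausibility",
    "WrongAcceptanceTable",
    "decide",
    "posterior_after_nonrejection",
    "posterior_after_rejection",
    "odds_update_factor_nonrejection",
    "wrong_acceptance_proportion",
    "build_wrong_acceptance_table",
    "posterior_from_bayes_factor",
    "round_half_up",
]


def _check_probability(x: float, name: str, *, strict: bool = False) -> float:
    x = float(x)
    if not math.isfinite(x):
        raise DomainError(f"{name} must be finite, got {x!r}")
    if strict:
        if not 0.0 < x < 1.0:
            raise DomainError(f"{name} must lie strictly in (0, 1), got {x!r}")
    elif not 0.0 <= x <= 1.0:
        raise DomainError(f"{name} must lie in [0, 1], got {x!r}")
    return x


def round_half_up(x: float, decimals: int) -> float:
    """Round with ties away from zero (school rounding), not banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PlausibilityPrior:
    """An analyst's prior degree of belief that the assumption (H0) holds.

    The prior must be strictly between 0 and 1: an analyst who is certain
    either way would consider testing the assumption redundant, and the
    Bayesian update degenerates at the boundary.
    """

    p0: float
    label: str = ""

    def __post_init__(self) -> None:
        p0 = float(self.p0)
        if not math.isfinite(p0) or not 0.0 < p0 < 1.0:
            raise DegeneratePriorError(
                "prior plausibility must lie strictly between 0 and 1 "
                f"(got {self.p0!r}); a prior of exactly 0 or 1 makes testing "
                "the assumption redundant"
            )
        object.__setattr__(self, "p0", p0)

    @property
    def odds(self) -> float:
        """Prior odds of H0 against its complement."""
        return self.p0 / (1.0 - self.p0)


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Level and catch-all Type II error of an assumption check.

    ``alpha`` is the Type I error rate P(reject | H0).  ``beta`` is the
    analyst's catch-all Type II error: the prior-weighted probability of
    failing to reject across all specific violations of the assumption
    (see :mod:`plausitest.power` for how to assemble it from a prior over
    effect sizes).  The check is *informative* — a nonrejection counts as
    evidence for H0 — precisely when ``alpha < 1 - beta``, i.e. when the
    expected power exceeds the level.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        a = float(self.alpha)
        b = float(self.beta)
        if not math.isfinite(a) or not 0.0 <= a < 1.0:
            raise DomainError(f"alpha must lie in [0, 1), got {self.alpha!r}")
        _check_probability(b, "beta")
        object.__setattr__(self, "alpha", a)
        object.__setattr__(self, "beta", b)

    @property
    def power(self) -> float:
        """Catch-all power 1 - beta."""
        return 1.0 - self.beta

    @property
    def informative(self) -> bool:
        """True iff a nonrejection raises the plausibility of H0 (alpha < 1 - beta)."""
        return self.alpha < 1.0 - self.beta


class Decision(str, Enum):
    REJECT = "reject"
    NONREJECT = "nonreject"


@dataclass(frozen=True)
class DecisionOutcome:
    """Outcome of the significance decision rule at level alpha."""

    outcome: Decision
    p_value: float
    alpha: float


class Conditioning(str, Enum):
    NONREJECTION = "nonrejection"
    REJECTION = "rejection"
    BAYES_FACTOR = "bayes_factor"


@dataclass(frozen=True)
class PosteriorPlausibility:
    """Posterior plausibility of the assumption after an update.

    ``infinite_evidence`` flags the limit case beta = 0 under nonrejection:
    a check that detects every violation with certainty leaves no doubt
    when it does not fire, so the posterior is exactly 1.
    """

    value: float
    conditioned_on: Conditioning
    infinite_evidence: bool = False

    def __post_init__(self) -> None:
        _check_probability(self.value, "posterior plausibility")

    @property
    def complement(self) -> float:
        """Posterior plausibility of the catch-all alternative."""
        return 1.0 - self.value


def decide(p_value: float, alpha: float) -> DecisionOutcome:
    """Apply the standard significance decision rule.

    H0 is rejected when ``p_value < alpha`` and retained when
    ``p_value >= alpha`` (the boundary retains).
    """
    p = _check_probability(p_value, "p_value")
    a = _check_probability(alpha, "alpha", strict=True)
    outcome = Decision.REJECT if p < a else Decision.NONREJECT
    return DecisionOutcome(outcome=outcome, p_value=p, alpha=a)


def posterior_after_nonrejection(
    prior: PlausibilityPrior | float, oc: OperatingCharacteristics
) -> PosteriorPlausibility:
    """Posterior plausibility of the assumption after a nonsignificant check.

    Computes ``p0 (1 - alpha) / (p0 (1 - alpha) + (1 - p0) beta)``.  With
    ``beta = 0`` and ``alpha < 1`` every violation would have been caught,
    so surviving the check proves the assumption; the result is 1 with the
    ``infinite_evidence`` flag set.
    """
    prior = _as_prior(prior)
    num = prior.p0 * (1.0 - oc.alpha)
    den = num + (1.0 - prior.p0) * oc.beta
    if den == 0.0:  # alpha = 1 and beta = 0 simultaneously
        raise DomainError(
            "posterior undefined: nonrejection has probability zero under "
            "both hypotheses (alpha = 1 and beta = 0)"
        )
    if oc.beta == 0.0:
        return PosteriorPlausibility(1.0, Conditioning.NONREJECTION, infinite_evidence=True)
    return PosteriorPlausibility(num / den, Conditioning.NONREJECTION)


def posterior_after_rejection(
    prior: PlausibilityPrior | float, oc: OperatingCharacteristics
) -> PosteriorPlausibility:
    """Posterior plausibility of the assumption after a significant check.

    Bayes complement of the nonrejection update:
    ``p0 alpha / (p0 alpha + (1 - p0)(1 - beta))``.
    """
    prior = _as_prior(prior)
    num = prior.p0 * oc.alpha
    den = num + (1.0 - prior.p0) * (1.0 - oc.beta)
    if den == 0.0:  # alpha = 0 and beta = 1: rejection is impossible
        raise DomainError(
            "posterior undefined: rejection has probability zero under both "
            "hypotheses (alpha = 0 and beta = 1)"
        )
    return PosteriorPlausibility(num / den, Conditioning.REJECTION)


def odds_update_factor_nonrejection(oc: OperatingCharacteristics) -> float:
    """Factor by which the odds of H0 increase after a nonrejection.

    Returns ``(1 - alpha) / beta``.  When ``beta = 0`` the evidence is
    infinite and ``math.inf`` is returned explicitly; callers that need a
    finite posterior should use :func:`posterior_after_nonrejection`, which
    handles the limit.
    """
    if oc.beta == 0.0:
        return math.inf
    return (1.0 - oc.alpha) / oc.beta


def wrong_acceptance_proportion(
    prior: PlausibilityPrior | float, alpha: float, power: float
) -> float:
    """Expected proportion of accepted assumptions that are actually false.

    Among occasions on which the check does not fire and the assumption is
    therefore accepted, the long-run fraction of false acceptances is
    ``1 - P(H0 | not reject)``.  This — not alpha or beta — is the error
    rate that determines how often an inappropriate model ends up in use.
    """
    power = _check_probability(power, "power")
    oc = OperatingCharacteristics(alpha=alpha, beta=1.0 - power)
    return posterior_after_nonrejection(prior, oc).complement


@dataclass(frozen=True)
class WrongAcceptanceTable:
    """Grid of wrong-acceptance proportions over priors (rows) and powers (columns)."""

    priors: tuple[float, ...]
    powers: tuple[float, ...]
    alpha: float
    decimals: int
    cells: np.ndarray = field(repr=False)

    def to_frame(self):
        """Return the table as a pandas DataFrame (priors as index, powers as columns)."""
        import pandas as pd

        return pd.DataFrame(
            self.cells,
            index=pd.Index(self.priors, name="prior"),
            columns=pd.Index(self.powers, name="power"),
        )

    def cell(self, prior: float, power: float) -> float:
        i = self.priors.index(prior)
        j = self.powers.index(power)
        return float(self.cells[i, j])


def build_wrong_acceptance_table(
    priors: Sequence[float],
    powers: Sequence[float],
    alpha: float = 0.05,
    decimals: int = 2,
) -> WrongAcceptanceTable:
    """Tabulate wrong-acceptance proportions for a grid of priors and powers.

    Each cell is :func:`wrong_acceptance_proportion` rounded half-up to
    ``decimals`` places.  Rows where the check is informative decrease as
    the prior grows: the more plausible the assumption was to begin with,
    the less often its acceptance is a mistake.
    """
    if len(priors) == 0 or len(powers) == 0:
        raise DomainError("priors and powers must be non-empty")
    if decimals < 0:
        raise DomainError("decimals must be non-negative")
    cells = np.empty((len(priors), len(powers)))
    for i, p0 in enumerate(priors):
        for j, pw in enumerate(powers):
            cells[i, j] = round_half_up(
                wrong_acceptance_proportion(PlausibilityPrior(p0), alpha, pw), decimals
            )
    return WrongAcceptanceTable(
        priors=tuple(float(p) for p in priors),
        powers=tuple(float(p) for p in powers),
        alpha=float(alpha),
        decimals=int(decimals),
        cells=cells,
    )


def posterior_from_bayes_factor(
    prior: PlausibilityPrior | float, bf: float
) -> PosteriorPlausibility:
    """Update the prior plausibility with a Bayes factor for H0 over its complement.

    ``bf > 1`` favours the assumption.  Posterior odds are prior odds times
    ``bf``; the returned value is the corresponding probability.
    """
    prior = _as_prior(prior)
    bf = float(bf)
    if not math.isfinite(bf) or bf <= 0.0:
        raise DomainError(f"Bayes factor must be a positive finite real, got {bf!r}")
    post_odds = prior.odds * bf
    return PosteriorPlausibility(post_odds / (1.0 + post_odds), Conditioning.BAYES_FACTOR)


def _as_prior(prior: PlausibilityPrior | float) -> PlausibilityPrior:
    if isinstance(prior, PlausibilityPrior):
        return prior
    return PlausibilityPrior(float(prior))
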