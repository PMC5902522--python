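"""Catch-all Type II error from a prior over assumption violations.

The Type II error of an assumption check is not a single number: it depends
on which violation is true.  A coherent analyst therefore averages the
per-violation miss probabilities over their prior plausibilities,

    beta_j = sum_i (1 - power_i) w_i / sum_i w_i,

which is the catch-all Type II error fed into the plausibility update in
:mod:`plausitest.core`.  For the equal-variances assumption the violation
is parameterised by the variance ratio delta = var1 / var2 (delta = 1 is
the null), and this module supplies:

* an exact power curve for the two-sided variance-ratio F test,
* a seeded Monte-Carlo power estimator for Levene's test,
* continuous priors over delta discretised by trapezoid quadrature on the
  log-delta axis (log scale respects the 1/delta relabelling symmetry),
* the aggregation of a power curve against such a prior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .errors import DomainError

__all__ = [
    "Alternative",
    "AlternativeSet",
    "EffectPrior",
    "PowerCurve",
    "mixture_type2_error",
    "f_test_variance_power",
    "levene_power_mc",
    "integrate_power_over_prior",
    "region_prior_mass",
]

#: Default grid for continuous priors on log delta: 81 trapezoid nodes on
#: [-4.6, 4.6], i.e. variance ratios from ~1/100 to ~100.
DEFAULT_SPAN = 4.6
DEFAULT_NODES = 81


@dataclass(frozen=True)
class Alternative:
    """One specific violation: a variance ratio with its power and prior weight."""

    effect: float
    power: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.effect) and self.effect > 0):
            raise DomainError(f"effect (variance ratio) must be positive, got {self.effect!r}")
        if not 0.0 <= self.power <= 1.0:
            raise DomainError(f"power must lie in [0, 1], got {self.power!r}")
        if not (math.isfinite(self.weight) and self.weight >= 0):
            raise DomainError(f"weight must be non-negative, got {self.weight!r}")


@dataclass(frozen=True)
class AlternativeSet:
    """A discrete set of mutually exclusive violations with prior weights."""

    alternatives: tuple[Alternative, ...]

    def __post_init__(self) -> None:
        alts = tuple(self.alternatives)
        if not alts:
            raise DomainError("alternative set must be non-empty")
        effects = [a.effect for a in alts]
        if len(set(effects)) != len(effects):
            raise DomainError("alternatives must have distinct effects")
        if sum(a.weight for a in alts) <= 0:
            raise DomainError("total prior weight over alternatives must be positive")
        object.__setattr__(self, "alternatives", alts)

    @property
    def weights(self) -> np.ndarray:
        w = np.array([a.weight for a in self.alternatives])
        return w / w.sum()

    @property
    def powers(self) -> np.ndarray:
        return np.array([a.power for a in self.alternatives])

    @property
    def effects(self) -> np.ndarray:
        return np.array([a.effect for a in self.alternatives])


def mixture_type2_error(alts: AlternativeSet) -> float:
    """Catch-all Type II error: prior-weighted average miss probability.

    Always lies between the smallest and largest per-alternative miss
    probability (the mixture is convex).
    """
    return float(np.sum((1.0 - alts.powers) * alts.weights))


@dataclass(frozen=True)
class EffectPrior:
    """Discretised prior over the variance ratio delta.

    ``nodes`` are strictly increasing points on the log-delta axis and
    ``weights`` are normalised quadrature weights (trapezoid rule times the
    density, for a continuous family).  An optional point mass at delta = 1
    is carried separately — it belongs to the null, not to the violation
    region, and is excluded from power aggregation.
    """

    nodes: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)
    point_mass_on_null: float = 0.0
    family: str = "custom"
    params: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.ndim != 1 or nodes.shape != weights.shape or nodes.size == 0:
            raise DomainError("nodes and weights must be equal-length non-empty 1-d arrays")
        if not np.all(np.diff(nodes) > 0):
            raise DomainError("nodes must be strictly increasing")
        if np.any(weights < 0) or weights.sum() <= 0:
            raise DomainError("weights must be non-negative with positive sum")
        if not 0.0 <= self.point_mass_on_null <= 1.0:
            raise DomainError("point_mass_on_null must lie in [0, 1]")
        weights = weights / weights.sum()
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)

    # ---- constructors -------------------------------------------------

    @classmethod
    def lognormal(
        cls,
        median: float = 1.0,
        sigma_log: float = 0.7,
        n_nodes: int = DEFAULT_NODES,
        span: float = DEFAULT_SPAN,
    ) -> "EffectPrior":
        """Lognormal prior on delta, discretised on a symmetric log grid.

        ``median`` is the prior median of delta and ``sigma_log`` the
        standard deviation on the log scale.  The default (median 1,
        sigma_log 0.7) puts roughly 90% of its mass on variance ratios
        between 1/3 and 3: violations of the size a two-group study
        plausibly encounters.
        """
        if median <= 0 or sigma_log <= 0:
            raise DomainError("median and sigma_log must be positive")
        if n_nodes < 3:
            raise DomainError("need at least 3 quadrature nodes")
        grid = np.linspace(-span, span, n_nodes)
        dens = stats.norm.pdf(grid, loc=math.log(median), scale=sigma_log)
        w = dens * _trapezoid_weights(grid)
        return cls(
            nodes=grid, weights=w, family="lognormal", params=(float(median), float(sigma_log))
        )

    @classmethod
    def point_mass(cls, delta: float) -> "EffectPrior":
        """All violation mass on a single variance ratio."""
        if delta <= 0:
            raise DomainError("delta must be positive")
        return cls(
            nodes=np.array([math.log(delta)]),
            weights=np.array([1.0]),
            family="point",
            params=(float(delta),),
        )

    @classmethod
    def from_nodes(
        cls, nodes: Sequence[float], weights: Sequence[float], point_mass_on_null: float = 0.0
    ) -> "EffectPrior":
        """Prior from explicit log-delta nodes and weights."""
        return cls(
            nodes=np.asarray(nodes, dtype=float),
            weights=np.asarray(weights, dtype=float),
            point_mass_on_null=point_mass_on_null,
        )

    # ---- queries ------------------------------------------------------

    @property
    def deltas(self) -> np.ndarray:
        """Variance-ratio values at the nodes."""
        return np.exp(self.nodes)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw delta values from the prior over violations.

        Continuous families are sampled exactly (not from the grid), so a
        Monte-Carlo estimate built from these draws is an independent check
        on the quadrature, discretisation error included.
        """
        if self.family == "lognormal":
            median, sigma = self.params
            return np.exp(rng.normal(math.log(median), sigma, size=size))
        idx = rng.choice(self.nodes.size, size=size, p=self.weights)
        return self.deltas[idx]

    def mass_in(self, lower: float, upper: float) -> float:
        """Prior mass on delta in [lower, upper], point mass at 1 included if covered."""
        return region_prior_mass(self, lower, upper)

    def to_dict(self) -> dict:
        """Serialisable description (named family or explicit nodes/weights)."""
        if self.family in ("lognormal", "point"):
            return {"family": self.family, "params": list(self.params)}
        return {
            "family": "custom",
            "nodes": self.nodes.tolist(),
            "weights": self.weights.tolist(),
            "point_mass_on_null": self.point_mass_on_null,
        }

    @classmethod
    def from_dict(cls, spec: dict) -> "EffectPrior":
        spec = dict(spec)
        family = spec.pop("family", "custom")
        if family == "lognormal":
            median, sigma = spec.pop("params", (1.0, 0.7))
            if spec:
                raise DomainError(f"unknown effect-prior keys: {sorted(spec)}")
            return cls.lognormal(median=median, sigma_log=sigma)
        if family == "point":
            (delta,) = spec.pop("params")
            if spec:
                raise DomainError(f"unknown effect-prior keys: {sorted(spec)}")
            return cls.point_mass(delta)
        known = {"nodes", "weights", "point_mass_on_null"}
        unknown = set(spec) - known
        if unknown:
            raise DomainError(f"unknown effect-prior keys: {sorted(unknown)}")
        return cls.from_nodes(
            spec["nodes"], spec["weights"], spec.get("point_mass_on_null", 0.0)
        )


def _trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    w = np.empty_like(grid)
    w[1:-1] = (grid[2:] - grid[:-2]) / 2.0
    w[0] = (grid[1] - grid[0]) / 2.0
    w[-1] = (grid[-1] - grid[-2]) / 2.0
    return w


def region_prior_mass(prior: EffectPrior, lower: float, upper: float) -> float:
    """Prior mass assigned to delta in [lower, upper].

    For a named lognormal family the mass is the exact CDF difference; for
    explicit node/weight priors it is the sum of weights whose node falls
    in the region.  Any point mass at delta = 1 is added when the region
    covers 1.  Useful for asking how much prior plausibility an approximate
    null region — e.g. "variances differ by less than a factor 10" —
    carries before any data are seen.
    """
    if not (0 < lower < upper):
        raise DomainError(f"need 0 < lower < upper, got [{lower!r}, {upper!r}]")
    scale = 1.0 - prior.point_mass_on_null
    if prior.family == "lognormal":
        median, sigma = prior.params
        dist = stats.lognorm(s=sigma, scale=median)
        mass = scale * float(dist.cdf(upper) - dist.cdf(lower))
    else:
        lo, hi = math.log(lower), math.log(upper)
        inside = (prior.nodes >= lo) & (prior.nodes <= hi)
        mass = scale * float(prior.weights[inside].sum())
    if lower <= 1.0 <= upper:
        mass += prior.point_mass_on_null
    return mass


# ---------------------------------------------------------------------------
# Power curves


def f_test_variance_power(delta: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Exact power of the two-sided variance-ratio F test against delta.

    Under variance ratio delta, the sample variance ratio s1^2/s2^2 is
    delta times a central F(n1-1, n2-1) variate.  The equal-tail acceptance
    region [F_{alpha/2}, F_{1-alpha/2}] of the central F gives

        power(delta) = F_cdf(lo / delta) + 1 - F_cdf(hi / delta).

    At delta = 1 the power equals the level alpha; the curve is symmetric
    under (delta, n1, n2) -> (1/delta, n2, n1).
    """
    if n1 < 2 or n2 < 2:
        raise DomainError("group sizes must be at least 2")
    if not 0 < alpha < 1:
        raise DomainError("alpha must lie in (0, 1)")
    delta = np.asarray(delta, dtype=float)
    if np.any(delta <= 0):
        raise DomainError("delta must be positive")
    d1, d2 = n1 - 1, n2 - 1
    lo = stats.f.ppf(alpha / 2.0, d1, d2)
    hi = stats.f.isf(alpha / 2.0, d1, d2)
    power = stats.f.cdf(lo / delta, d1, d2) + stats.f.sf(hi / delta, d1, d2)
    return float(power) if power.ndim == 0 else power


def _levene_reject(
    x1: np.ndarray, x2: np.ndarray, alpha: float, center: str = "mean"
) -> np.ndarray:
    """Vectorised Levene rejection indicator over a batch of replicates.

    ``x1``/``x2`` have shape (reps, n); the statistic is the one-way ANOVA
    F on absolute deviations from the per-group center.
    """
    from .twogroup import _levene_f_batch

    f, df1, df2 = _levene_f_batch(x1, x2, center=center)
    return stats.f.sf(f, df1, df2) < alpha


def levene_power_mc(
    delta: float,
    n1: int,
    n2: int,
    alpha: float = 0.05,
    nsim: int = 10_000,
    seed: int | np.random.Generator = 0,
    center: str = "mean",
) -> tuple[float, float]:
    """Monte-Carlo power of Levene's test against a variance ratio delta.

    Simulates ``nsim`` Gaussian two-group datasets with var1/var2 = delta,
    applies the test at level ``alpha`` and returns the rejection rate with
    its binomial standard error.  Seeded and fully reproducible.
    """
    if nsim < 100:
        raise DomainError("nsim must be at least 100 for a meaningful estimate")
    if delta <= 0:
        raise DomainError("delta must be positive")
    if n1 < 2 or n2 < 2:
        raise DomainError("group sizes must be at least 2")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x1 = rng.standard_normal((nsim, n1)) * math.sqrt(delta)
    x2 = rng.standard_normal((nsim, n2))
    rate = float(_levene_reject(x1, x2, alpha, center=center).mean())
    se = math.sqrt(rate * (1.0 - rate) / nsim)
    return rate, se


@dataclass(frozen=True)
class PowerCurve:
    """Power of an assumption test as a function of the variance ratio delta."""

    test_name: str
    n1: int
    n2: int
    alpha: float
    evaluator: Callable[[np.ndarray], np.ndarray] = field(repr=False)

    @classmethod
    def f_test(cls, n1: int, n2: int, alpha: float = 0.05) -> "PowerCurve":
        """Exact curve for the two-sided variance-ratio F test."""

        def evaluator(delta):
            return f_test_variance_power(delta, n1, n2, alpha)

        return cls("variance_ratio_F", n1, n2, alpha, evaluator)

    @classmethod
    def levene_mc(
        cls,
        n1: int,
        n2: int,
        alpha: float = 0.05,
        nsim: int = 20_000,
        seed: int = 0,
        center: str = "mean",
    ) -> "PowerCurve":
        """Monte-Carlo curve for Levene's test with common random numbers.

        One block of standard normals is drawn once and rescaled for every
        delta queried, so the estimated curve is a smooth, monotone-in-delta
        function of the same underlying randomness — well suited to
        bisection (power matching) and quadrature.
        """
        rng = np.random.default_rng(seed)
        z1 = rng.standard_normal((nsim, n1))
        z2 = rng.standard_normal((nsim, n2))

        def evaluator(delta):
            delta = np.atleast_1d(np.asarray(delta, dtype=float))
            out = np.empty(delta.shape)
            for i, d in enumerate(delta):
                out[i] = _levene_reject(z1 * math.sqrt(d), z2, alpha, center=center).mean()
            return out if out.size > 1 else float(out[0])

        return cls("levene", n1, n2, alpha, evaluator)

    def __call__(self, delta) -> float | np.ndarray:
        return self.evaluator(delta)

    def match_power(
        self, target: float, lo: float = 1.0, hi: float = 400.0, tol: float = 0.005
    ) -> float:
        """Find delta >= 1 whose power matches ``target`` by bisection.

        Raises if the target is unattainable on [lo, hi].
        """
        if not self.alpha <= target <= 1.0:
            raise DomainError(f"target power {target!r} below the level {self.alpha}")
        p_lo, p_hi = float(self(lo)), float(self(hi))
        if not p_lo <= target <= p_hi:
            raise DomainError(
                f"power {target} not attainable on delta in [{lo}, {hi}] "
                f"(curve spans [{p_lo:.4f}, {p_hi:.4f}]) at n=({self.n1},{self.n2})"
            )
        a, b = math.log(lo), math.log(hi)
        for _ in range(60):
            m = (a + b) / 2.0
            pm = float(self(math.exp(m)))
            if abs(pm - target) <= tol / 2.0:
                return math.exp(m)
            if pm < target:
                a = m
            else:
                b = m
        return math.exp((a + b) / 2.0)


def integrate_power_over_prior(curve: PowerCurve, prior: EffectPrior) -> float:
    """Expected power of a check, averaged over the prior on violations.

    Returns 1 - beta_j for the violation region: the quadrature sum of the
    power curve against the prior weights.  Mass at delta = 1 is excluded —
    it belongs to the null hypothesis, not the catch-all.
    """
    powers = np.asarray(curve(np.exp(prior.nodes)), dtype=float)
    if np.any(~np.isfinite(powers)):
        raise DomainError("power curve returned non-finite values on the prior grid")
    return float(np.sum(powers * prior.weights))
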