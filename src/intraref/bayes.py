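"""Empirical-Bayes personal reference intervals via normal–normal shrinkage.

The model behind the fourth estimator.  A measurement of subject i at
visit j decomposes as

    X_ij = mu_i + t_j + e_ij,

with subject means mu_i ~ N(mu0, sigma0^2) (between-subject), shared
visit effects t_j (fixed, sum to zero) and within-subject noise e_ij of
variance sigma^2 (temporal + analytical, not separately identifiable
from one series per visit).

Given n observations of a new individual, the conjugate posterior of
their personal mean is N(mu_n, sigma_n^2) with

    mu_n      = w*mu0 + (1-w)*xbar,   w = sigma^2 / (n*sigma0^2 + sigma^2)
    sigma_n^2 = sigma^2*sigma0^2 / (sigma^2 + n*sigma0^2)

and the personal reference range is mu_n ± z*sqrt(sigma_n^2 + sigma^2):
posterior-mean uncertainty plus irreducible within-subject scatter.  At
n = 0 this is the population range mu0 ± z*total SD; as n grows it
narrows to the within-subject floor mu_i ± z*sigma.

Variance components are estimated from a balanced reference panel by
closed-form method-of-moments ANOVA after removing visit means; in a
balanced design this coincides with the likelihood solution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .intervals import ReferenceInterval
from .panel import LongitudinalPanel

__all__ = [
    "VarianceComponents",
    "PriorParams",
    "PosteriorParams",
    "estimate_components",
    "posterior",
    "bayes_interval",
]


@dataclass(frozen=True)
class VarianceComponents:
    """Between/within decomposition of a panel's dispersion.

    between_var : sigma0^2, variance of true subject means (units^2).
    within_var  : sigma^2 = tau^2 + sigma_eps^2, within-subject variance
                  (temporal + measurement, reported only as their sum).
    visit_effects : estimated shared visit shifts, mean-centered.
    """

    between_var: float
    within_var: float
    visit_effects: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.between_var < 0 or self.within_var < 0:
            raise ValueError("variance components must be >= 0")
        if self.visit_effects and abs(sum(self.visit_effects)) > 1e-8 * (
            1.0 + max(abs(v) for v in self.visit_effects)
        ):
            raise ValueError("visit_effects must sum to 0")

    @property
    def between_sd(self) -> float:
        return math.sqrt(self.between_var)

    @property
    def within_sd(self) -> float:
        return math.sqrt(self.within_var)

    @property
    def total_sd(self) -> float:
        return math.sqrt(self.between_var + self.within_var)


@dataclass(frozen=True)
class PriorParams:
    """Population prior for a subject's personal mean: N(mu0, sigma0_sq)."""

    mu0: float
    sigma0_sq: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.sigma0_sq) or self.sigma0_sq < 0:
            raise ValueError("sigma0_sq must be finite and >= 0")


@dataclass(frozen=True)
class PosteriorParams:
    """Posterior N(mu_n, sigma_n_sq) of the personal mean after n observations.

    shrinkage_weight is the weight the posterior mean puts on the
    population mean mu0; it is 1 at n = 0 and decays like 1/n.
    """

    mu_n: float
    sigma_n_sq: float
    n: int
    shrinkage_weight: float

    def __post_init__(self) -> None:
        if self.sigma_n_sq < 0 or not 0.0 <= self.shrinkage_weight <= 1.0:
            raise ValueError("invalid posterior parameters")


def estimate_components(panel: LongitudinalPanel) -> VarianceComponents:
    """Method-of-moments variance components from a balanced panel.

    Visit (fixed) effects are the visit means minus the grand mean.  On
    visit-centered data the balanced one-way random-effects decomposition
    gives

        within_var  = residual SS / ((S-1)(T-1))
        between_var = max(0, (MS_between - within_var) / T)

    with MS_between = T * var(subject means).  The (S-1)(T-1) divisor
    keeps within_var unbiased after estimating the T visit means.
    Negative between-subject moment estimates truncate to 0 with a
    warning.
    """
    if not panel.is_balanced():
        raise ValueError("estimate_components requires a balanced panel")
    wide = panel.wide()
    S, T = wide.shape
    if S < 2 or T < 2:
        raise ValueError("need >= 2 subjects and >= 2 visits")
    X = wide.to_numpy()
    grand = X.mean()
    visit_effects = X.mean(axis=0) - grand
    subj_means = X.mean(axis=1)

    resid = X - subj_means[:, None] - visit_effects[None, :]
    within = float((resid**2).sum() / ((S - 1) * (T - 1)))
    ms_between = float(T * np.var(subj_means, ddof=1))
    between = (ms_between - within) / T
    if between < 0:
        if between < -1e-12 * max(within, 1.0):
            warnings.warn(
                f"negative between-subject moment estimate ({between:.4g}) truncated to 0",
                stacklevel=2,
            )
        between = 0.0
    if within == 0.0 and between == 0.0 and np.ptp(X) == 0:
        warnings.warn("panel has zero total variance; all components 0", stacklevel=2)
    return VarianceComponents(
        between_var=between,
        within_var=within,
        visit_effects=tuple(float(v) for v in visit_effects),
    )


def posterior(
    prior: PriorParams, within_var: float, observations: Sequence[float]
) -> PosteriorParams:
    """Conjugate normal–normal update of the personal-mean distribution.

    ``within_var`` (sigma^2) is treated as known — the plug-in of a
    panel estimate ignores its sampling uncertainty.
    """
    x = np.asarray(observations, dtype=float)
    n = int(x.size)
    if n == 0:
        return PosteriorParams(
            mu_n=prior.mu0, sigma_n_sq=prior.sigma0_sq, n=0, shrinkage_weight=1.0
        )
    if not within_var > 0:
        raise ValueError("within_var must be > 0 when observations are present")
    if not np.isfinite(x).all():
        raise ValueError("observations must be finite")
    s0 = prior.sigma0_sq
    denom = n * s0 + within_var
    w = within_var / denom
    mu_n = w * prior.mu0 + (s0 / denom) * float(x.sum())
    sigma_n_sq = within_var * s0 / denom
    return PosteriorParams(mu_n=mu_n, sigma_n_sq=sigma_n_sq, n=n, shrinkage_weight=w)


def bayes_interval(
    post: PosteriorParams, within_var: float, z: float = 1.96
) -> ReferenceInterval:
    """Personal reference range mu_n ± z·√(sigma_n² + sigma²).

    The width combines remaining uncertainty about the personal mean with
    the irreducible within-subject scatter; it is decreasing in n and
    bounded below by 2·z·within SD.
    """
    if within_var < 0:
        raise ValueError("within_var must be >= 0")
    if z <= 0:
        raise ValueError("z must be positive")
    h = z * math.sqrt(post.sigma_n_sq + within_var)
    return ReferenceInterval("bayes", post.mu_n - h, post.mu_n + h, post.mu_n, post.n)
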