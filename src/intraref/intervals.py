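"""Closed-form personal reference intervals from a subject's own history.

Three estimators of the range a healthy individual's next measurement
should fall in, given n past measurements:

* **naive** — mean ± z·S, treating the sample mean and SD as if they were
  the true ones.  Anticonservative at small n.
* **rcv** — mean ± mean·RCV/100, where the reference change value
  RCV = √2·z·√(CVa² + CVi²) combines analytical (CVa) and within-subject
  biological (CVi) coefficients of variation.
* **tango** (prediction interval) — mean ± Cn·S with
  Cn = t_{n−1}(α/2)·√((n+1)/n), the exact acceptance region of the
  one-new-observation t test; calibrated 95% coverage at every n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ReferenceInterval",
    "RcvParams",
    "naive_interval",
    "rcv",
    "rcv_interval",
    "cn",
    "tango_interval",
]


@dataclass(frozen=True)
class ReferenceInterval:
    """A symmetric reference range with method provenance.

    ``n_used`` records how many observations the interval consumed
    (0 for a configured population range).
    """

    method: str
    lower: float
    upper: float
    center: float
    n_used: int = 0

    def __post_init__(self) -> None:
        if not (self.lower <= self.center <= self.upper):
            raise ValueError(
                f"malformed interval: lower {self.lower} <= center {self.center} "
                f"<= upper {self.upper} violated"
            )

    @property
    def half_width(self) -> float:
        return (self.upper - self.lower) / 2.0

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        """Closed-interval membership (boundary values count as inside)."""
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class RcvParams:
    """Inputs of the reference-change-value formula, all in percent.

    cva_percent : analytical (assay) CV.
    cvi_percent : within-subject biological CV.
    z_value     : normal quantile; 1.96 for 95%, 2.58 for 99%.
    """

    cva_percent: float
    cvi_percent: float
    z_value: float = 1.96

    def __post_init__(self) -> None:
        for name in ("cva_percent", "cvi_percent", "z_value"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite")
        if self.cva_percent < 0 or self.cvi_percent < 0:
            raise ValueError("CVs must be non-negative")
        if self.z_value <= 0:
            raise ValueError("z_value must be positive")


def naive_interval(
    mean: float, sd: float, z: float = 1.96, n_used: int = 0
) -> ReferenceInterval:
    """mean ± z·sd with the sample SD plugged in as if known."""
    if not math.isfinite(sd) or sd < 0:
        raise ValueError(f"sd must be finite and >= 0, got {sd}")
    if z <= 0:
        raise ValueError("z must be positive")
    h = z * sd
    return ReferenceInterval("naive", mean - h, mean + h, mean, n_used)


def rcv(params: RcvParams) -> float:
    """Reference change value in percent: √2 · z · √(CVa² + CVi²)."""
    return math.sqrt(2.0) * params.z_value * math.hypot(params.cva_percent, params.cvi_percent)


def rcv_interval(mean: float, rcv_percent: float, n_used: int = 0) -> ReferenceInterval:
    """mean ± mean·RCV/100 — the RCV expressed as an absolute half-width."""
    if not mean > 0:
        raise ValueError(f"mean must be positive for a percent-based interval, got {mean}")
    if rcv_percent < 0:
        raise ValueError("rcv_percent must be >= 0")
    h = mean * rcv_percent / 100.0
    return ReferenceInterval("rcv", mean - h, mean + h, mean, n_used)


def cn(n: int, alpha: float = 0.05) -> float:
    """Prediction-interval half-width multiplier t_{n−1}(α/2)·√((n+1)/n).

    The √((n+1)/n) factor accounts for the variance of (new draw − sample
    mean); the t quantile for estimating σ by S.  Strictly decreasing in
    n, → z_{α/2} as n → ∞.  Equals 3.041 at n = 5, α = 0.05.
    """
    if n < 2:
        raise ValueError("cn requires n >= 2 (no SD estimate below that)")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    return float(stats.t.ppf(1.0 - alpha / 2.0, n - 1) * math.sqrt((n + 1) / n))


def tango_interval(values: Sequence[float], alpha: float = 0.05) -> ReferenceInterval:
    """Exact prediction interval X̄ ± Cn·S for one future observation.

    Equivalent to the acceptance region of the t statistic
    T = (X − X̄)/(S·√(1 + 1/n)) at level α.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("tango_interval requires >= 2 observations")
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    mean = float(x.mean())
    s = float(x.std(ddof=1))
    h = cn(int(x.size), alpha) * s
    return ReferenceInterval("tango", mean - h, mean + h, mean, int(x.size))
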