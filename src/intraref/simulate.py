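"""Synthetic longitudinal panels with the generative structure X_ij = mu_i + t_j + e_ij.

Subject means mu_i are drawn around a population mean mu0 with
between-subject SD sigma0; optional fixed visit effects t_j shift every
subject equally at a visit; within-subject noise e_ij is i.i.d. normal
with variance tau^2 + sigma_eps^2 (temporal + analytical — only their
sum is identifiable, so the split is a simulation convenience).

``study_like_bundle`` packages the four-analyte, 20-subject x 5-visit
cohort design used throughout the test-suite, with mixed-model variance
components and cohort means at realistic serum-marker scales.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import LongitudinalPanel

__all__ = ["SimulationParams", "generate_panel", "study_like_bundle", "STUDY_COMPONENTS"]


@dataclass(frozen=True)
class SimulationParams:
    """Generative settings for one synthetic panel.

    mu0, sigma0      : population mean and between-subject SD (units).
    tau, sigma_eps   : temporal and analytical within-subject SDs; noise
                       variance is tau^2 + sigma_eps^2.
    visit_effects    : optional shared per-visit shifts summing to 0
                       (length n_visits); None means no visit effect.
    sex_ratio        : fraction of female subjects (remainder male).
    """

    mu0: float
    sigma0: float
    tau: float = 0.0
    sigma_eps: float = 0.0
    visit_effects: tuple[float, ...] | None = None
    n_subjects: int = 20
    n_visits: int = 5
    sex_ratio: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma0", "tau", "sigma_eps"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if self.n_subjects < 2 or self.n_visits < 2:
            raise ValueError("need n_subjects >= 2 and n_visits >= 2")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")
        if self.visit_effects is not None:
            ve = tuple(float(v) for v in self.visit_effects)
            if len(ve) != self.n_visits:
                raise ValueError("visit_effects must have length n_visits")
            if abs(sum(ve)) > 1e-9 * (1.0 + max(abs(v) for v in ve)):
                raise ValueError("visit_effects must sum to 0")
            object.__setattr__(self, "visit_effects", ve)

    @property
    def within_sd(self) -> float:
        return math.hypot(self.tau, self.sigma_eps)


def generate_panel(
    params: SimulationParams, analyte: str = "SYN", units: str = ""
) -> LongitudinalPanel:
    """Draw one panel; deterministic for a fixed seed.

    Values are floored at 0 with a warning if truncation occurs (analyte
    concentrations are non-negative; at realistic settings the floor
    never triggers).
    """
    rng = np.random.default_rng(params.seed)
    S, T = params.n_subjects, params.n_visits
    mu_i = rng.normal(params.mu0, params.sigma0, size=S)
    noise = rng.normal(0.0, params.within_sd, size=(S, T))
    v = np.zeros(T) if params.visit_effects is None else np.asarray(params.visit_effects)
    X = mu_i[:, None] + v[None, :] + noise
    if (X < 0).any():
        warnings.warn(
            f"{int((X < 0).sum())} simulated value(s) truncated at 0", stacklevel=2
        )
        X = np.clip(X, 0.0, None)

    n_female = int(round(params.sex_ratio * S))
    sexes = np.array(["female"] * n_female + ["male"] * (S - n_female))
    sexes = sexes[rng.permutation(S)]

    df = pd.DataFrame(
        {
            "subject_id": np.repeat([f"S{i + 1:02d}" for i in range(S)], T),
            "sex": np.repeat(sexes, T),
            "visit_index": np.tile(np.arange(1, T + 1), S),
            "value": X.ravel(),
        }
    )
    return LongitudinalPanel(analyte=analyte, units=units, data=df)


# Per-analyte generative settings of the study-like cohort: population mean,
# between-subject variance, within-subject variance (units^2).  ALB and TTR
# within-variances are implied by total_sd^2 - between_var.
STUDY_COMPONENTS: dict[str, dict[str, float]] = {
    "TRF": {"mu0": 280.0, "between_var": 770.96, "within_var": 165.95, "units_decimals": 0},
    "ALB": {"mu0": 4.7, "between_var": 0.05, "within_var": 0.0284, "units_decimals": 1},
    "RBP": {"mu0": 3.5, "between_var": 1.13, "within_var": 0.10, "units_decimals": 1},
    "TTR": {"mu0": 29.8, "between_var": 47.29, "within_var": 3.6896, "units_decimals": 1},
}

_STUDY_UNITS = {"TRF": "mg/dL", "ALB": "g/dL", "RBP": "mg/dL", "TTR": "mg/dL"}


def study_params(
    analyte: str, seed: int, n_subjects: int = 20, n_visits: int = 5
) -> SimulationParams:
    """SimulationParams for one study-like analyte at a given seed.

    The within-subject SD is split evenly (in variance) between the
    temporal and analytical terms; only the sum affects the data.
    """
    c = STUDY_COMPONENTS[analyte]
    half = math.sqrt(c["within_var"] / 2.0)
    return SimulationParams(
        mu0=c["mu0"],
        sigma0=math.sqrt(c["between_var"]),
        tau=half,
        sigma_eps=half,
        n_subjects=n_subjects,
        n_visits=n_visits,
        sex_ratio=0.45,
        seed=seed,
    )


def study_like_bundle(seed: int) -> dict[str, LongitudinalPanel]:
    """Four 20x5 panels (TRF, ALB, RBP, TTR) from one master seed.

    Child seeds are spawned deterministically per analyte, so panels are
    independent yet the whole bundle reproduces byte-identically from the
    master seed.
    """
    children = np.random.SeedSequence(seed).spawn(len(STUDY_COMPONENTS))
    out: dict[str, LongitudinalPanel] = {}
    for child, analyte in zip(children, STUDY_COMPONENTS):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        params = study_params(analyte, seed=child_seed)
        out[analyte] = generate_panel(params, analyte=analyte, units=_STUDY_UNITS[analyte])
    return out
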