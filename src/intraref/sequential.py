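"""Cumulative re-estimation of personal reference ranges as visits accrue.

Two evaluation modes:

* **prospective** — the interval judging visit k is built from visits
  1..k-1 only: the clinical "alarm" semantics (would this new result have
  been flagged?).
* **retrospective** — the interval at step k uses visits 1..k: the
  cumulative trajectory of the range estimate itself.

At step 1 (prospective) no SD exists yet, so the naive, RCV and
prediction-interval methods judge the first measurement against the
routine population range; the Bayesian method uses its prior predictive,
which equals the population-style range built from mixed-model
components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from . import intervals as iv
from .bayes import PosteriorParams, PriorParams, VarianceComponents, bayes_interval, estimate_components, posterior
from .descriptive import panel_summary, subject_summary
from .panel import AnalyteConfig, LongitudinalPanel

__all__ = [
    "METHODS",
    "TrajectoryStep",
    "IntervalTrajectory",
    "flag_observation",
    "cumulative_trajectory",
    "comparison_report",
    "trajectory_table",
]

METHODS = ("naive", "rcv", "tango", "bayes", "population")

Mode = Literal["prospective", "retrospective"]


def flag_observation(value: float, interval: iv.ReferenceInterval) -> str:
    """Classify a value against a closed interval: within / below / above."""
    if value < interval.lower:
        return "below"
    if value > interval.upper:
        return "above"
    return "within"


@dataclass(frozen=True)
class TrajectoryStep:
    """One visit in a trajectory: the interval in force and the verdict.

    ``interval`` is None when the method cannot be evaluated at this step
    (flag ``not_evaluable``); when the population range stands in for a
    not-yet-available personal method, the interval's method tag says so.
    """

    k: int
    observation: float
    interval: iv.ReferenceInterval | None
    flag: str


@dataclass(frozen=True)
class IntervalTrajectory:
    subject_id: str
    method: str
    mode: str
    steps: tuple[TrajectoryStep, ...]


def _interval_from_history(
    method: str,
    history: np.ndarray,
    *,
    config: AnalyteConfig,
    sex: str,
    prior: PriorParams | None,
    within_var: float | None,
    cvi_percent: float | None,
    alpha: float,
) -> iv.ReferenceInterval | None:
    """Build one method's interval from a subject's past values, or None."""
    n = len(history)
    z = config.z_value
    if method == "population":
        lo, hi = config.range_for(sex)
        return iv.ReferenceInterval("population", lo, hi, (lo + hi) / 2.0, 0)
    if method == "bayes":
        if prior is None or within_var is None:
            raise ValueError("bayes method requires variance components or a configured prior")
        return bayes_interval(posterior(prior, within_var, history), within_var, z)
    if n < 2:  # naive/rcv/tango need an SD (or a cumulative CV)
        return None
    mean = float(history.mean())
    if method == "naive":
        return iv.naive_interval(mean, float(history.std(ddof=1)), z, n_used=n)
    if method == "tango":
        return iv.tango_interval(history, alpha)
    if method == "rcv":
        if cvi_percent is None:
            if mean <= 0:
                return None
            cvi_percent = 100.0 * float(history.std(ddof=1)) / mean
        pct = iv.rcv(iv.RcvParams(config.cva_percent, cvi_percent, z))
        out = iv.rcv_interval(mean, pct, n_used=n)
        return out
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def cumulative_trajectory(
    panel: LongitudinalPanel,
    subject_id: str,
    method: str,
    config: AnalyteConfig,
    components: VarianceComponents | None = None,
    *,
    prior: PriorParams | None = None,
    mode: Mode = "prospective",
    alpha: float = 0.05,
    cvi_percent: float | None = None,
) -> IntervalTrajectory:
    """Re-estimate one subject's interval at every visit.

    Parameters
    ----------
    components :
        Mixed-model variance components of the reference panel; required
        for the Bayesian method unless ``prior`` (and its within-variance
        via components) is supplied.  When given without ``prior``, the
        prior mean defaults to the panel grand mean and the prior
        variance to the between-subject component.
    cvi_percent :
        Fix the RCV method's CVi instead of the subject's own cumulative
        CV (e.g. the cohort mean CV(intra)).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if mode not in ("prospective", "retrospective"):
        raise ValueError(f"unknown mode {mode!r}")
    values = panel.subject_values(subject_id)
    sex = panel.subject_sex(subject_id)

    within_var: float | None = None
    if method == "bayes":
        if components is None and prior is None:
            raise ValueError("bayes method requires components or a prior")
        if components is not None:
            within_var = components.within_var
            if prior is None:
                grand = float(
                    panel.data.groupby("subject_id", sort=False)["value"].mean().mean()
                )
                prior = PriorParams(mu0=grand, sigma0_sq=components.between_var)
        if within_var is None:
            raise ValueError("bayes method needs a within-subject variance (components)")

    pop_lo, pop_hi = config.range_for(sex)
    pop = iv.ReferenceInterval("population", pop_lo, pop_hi, (pop_lo + pop_hi) / 2.0, 0)

    steps: list[TrajectoryStep] = []
    for k in range(1, len(values) + 1):
        obs = float(values[k - 1])
        hist = values[:k] if mode == "retrospective" else values[: k - 1]
        interval = _interval_from_history(
            method,
            np.asarray(hist, dtype=float),
            config=config,
            sex=sex,
            prior=prior,
            within_var=within_var,
            cvi_percent=cvi_percent,
            alpha=alpha,
        )
        if interval is None:
            # first measurement judged against the routine population range
            interval = pop
        steps.append(TrajectoryStep(k=k, observation=obs, interval=interval, flag=flag_observation(obs, interval)))
    return IntervalTrajectory(
        subject_id=str(subject_id), method=method, mode=mode, steps=tuple(steps)
    )


def trajectory_table(trajectories: list[IntervalTrajectory]) -> pd.DataFrame:
    """Flatten trajectories into a tidy per-step table."""
    rows = []
    for tr in trajectories:
        for st in tr.steps:
            rows.append(
                {
                    "subject_id": tr.subject_id,
                    "method": tr.method,
                    "mode": tr.mode,
                    "k": st.k,
                    "observation": st.observation,
                    "interval_method": st.interval.method if st.interval else "",
                    "lower": st.interval.lower if st.interval else math.nan,
                    "upper": st.interval.upper if st.interval else math.nan,
                    "flag": st.flag,
                }
            )
    return pd.DataFrame(rows)


def comparison_report(
    panel: LongitudinalPanel,
    config: AnalyteConfig,
    *,
    alpha: float = 0.05,
    components: VarianceComponents | None = None,
) -> dict:
    """Panel-level comparison of all four personal-range methods vs the population range.

    Returns a dict with: the cohort summary block; panel-level ranges for
    the naive, RCV and prediction-interval constructions (the latter is
    this package's grand_mean ± Cn(T)·SD analog); the mixed-model
    components; the count of subjects whose CV(intra) is below the cohort
    CV(inter); and each method's mean per-subject interval width against
    the population-range width.
    """
    ps = panel_summary(panel)
    comp = components if components is not None else estimate_components(panel)
    z = config.z_value
    T = panel.n_visits

    naive_panel = iv.naive_interval(ps.grand_mean, ps.sd_of_subject_means, z)
    rcv_pct = iv.rcv(iv.RcvParams(config.cva_percent, ps.mean_cv_intra_percent, z))
    rcv_panel = iv.rcv_interval(ps.grand_mean, rcv_pct)
    tango_h = iv.cn(T, alpha) * ps.sd_of_subject_means
    tango_panel = iv.ReferenceInterval(
        "tango", ps.grand_mean - tango_h, ps.grand_mean + tango_h, ps.grand_mean, T
    )

    prior = PriorParams(mu0=ps.grand_mean, sigma0_sq=comp.between_var)
    pop_lo, pop_hi = config.population_range
    pop_width = pop_hi - pop_lo

    n_below = 0
    widths: dict[str, list[float]] = {m: [] for m in ("naive", "rcv", "tango", "bayes")}
    for sid in panel.subject_ids:
        ss = subject_summary(panel, sid)
        if ss.cv_percent is not None and ss.cv_percent < ps.cv_inter_percent:
            n_below += 1
        vals = panel.subject_values(sid)
        widths["naive"].append(iv.naive_interval(ss.mean, ss.sd, z, n_used=ss.n).width)
        widths["tango"].append(iv.tango_interval(vals, alpha).width)
        pct = iv.rcv(iv.RcvParams(config.cva_percent, ss.cv_percent, z))
        widths["rcv"].append(iv.rcv_interval(ss.mean, pct, n_used=ss.n).width)
        if comp.within_var > 0:
            post = posterior(prior, comp.within_var, vals)
        else:
            post = PosteriorParams(prior.mu0, 0.0, len(vals), 1.0)
        widths["bayes"].append(bayes_interval(post, comp.within_var, z).width)

    return {
        "analyte": panel.analyte,
        "units": panel.units,
        "panel_summary": ps,
        "components": comp,
        "rcv_percent": rcv_pct,
        "panel_intervals": {
            "naive": naive_panel,
            "rcv": rcv_panel,
            "tango": tango_panel,
        },
        "population_range": (pop_lo, pop_hi),
        "population_width": pop_width,
        "n_subjects_cv_intra_below_cv_inter": n_below,
        "mean_method_widths": {m: float(np.mean(w)) for m, w in widths.items()},
    }
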