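"""Per-subject and cohort summaries of a longitudinal panel.

The central quantities are the two coefficients of variation that
motivate personal reference ranges:

* CV(inter) — the CV of subject means across people, capturing
  between-subject biology;
* CV(intra) — a person's CV across their own repeat visits, capturing
  within-subject (biological + analytical) noise.

When CV(intra) << CV(inter), an individual's healthy values occupy a
narrow band inside the population range and a personal range is far more
sensitive to change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import LongitudinalPanel

__all__ = [
    "SubjectSummary",
    "PanelSummary",
    "subject_summary",
    "panel_summary",
    "subject_vs_grand_tests",
    "summary_table",
]


@dataclass(frozen=True)
class SubjectSummary:
    """Mean, sample SD (n−1) and CV% of one subject's repeat measurements.

    ``sd`` and ``cv_percent`` are ``None`` (undefined-flagged) when they
    cannot be computed: sd needs n >= 2, cv needs a positive mean.
    """

    subject_id: str
    n: int
    mean: float
    sd: float | None
    cv_percent: float | None


@dataclass(frozen=True)
class PanelSummary:
    """Cohort-level block: subject-mean dispersion and the two CVs.

    ``grand_mean`` and ``sd_of_subject_means`` are computed over subject
    means (each person weighted equally), so on a balanced panel the grand
    mean also equals the mean of all observations.  ``max_value`` /
    ``min_value`` run over all observations; the subject-mean extrema are
    exposed separately.
    """

    n_subjects: int
    grand_mean: float
    sd_of_subject_means: float
    max_value: float
    min_value: float
    max_subject_mean: float
    min_subject_mean: float
    cv_inter_percent: float
    mean_cv_intra_percent: float
    sd_cv_intra_percent: float


def subject_summary(panel: LongitudinalPanel, subject_id: str) -> SubjectSummary:
    """Summary statistics for one subject's series (sample SD, n−1)."""
    x = panel.subject_values(subject_id)
    n = len(x)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if n >= 2 else None
    cv = 100.0 * sd / mean if (sd is not None and mean > 0) else None
    return SubjectSummary(subject_id=str(subject_id), n=n, mean=mean, sd=sd, cv_percent=cv)


def _subject_frame(panel: LongitudinalPanel) -> pd.DataFrame:
    g = panel.data.groupby("subject_id", sort=False)["value"]
    return pd.DataFrame({"n": g.size(), "mean": g.mean(), "sd": g.std(ddof=1)})


def panel_summary(panel: LongitudinalPanel) -> PanelSummary:
    """Cohort summary; every subject must have at least two visits."""
    per = _subject_frame(panel)
    short = per.index[per["n"] < 2].tolist()
    if short:
        raise ValueError(f"subject(s) with < 2 records: {short}")
    means = per["mean"].to_numpy()
    grand = float(means.mean())
    sd_means = float(np.std(means, ddof=1)) if len(means) >= 2 else 0.0
    cvs = 100.0 * per["sd"].to_numpy() / means
    return PanelSummary(
        n_subjects=len(per),
        grand_mean=grand,
        sd_of_subject_means=sd_means,
        max_value=float(panel.data["value"].max()),
        min_value=float(panel.data["value"].min()),
        max_subject_mean=float(means.max()),
        min_subject_mean=float(means.min()),
        cv_inter_percent=100.0 * sd_means / grand if grand > 0 else math.nan,
        mean_cv_intra_percent=float(np.mean(cvs)),
        sd_cv_intra_percent=float(np.std(cvs, ddof=1)) if len(cvs) >= 2 else 0.0,
    )


def subject_vs_grand_tests(panel: LongitudinalPanel, alpha: float = 0.05) -> pd.DataFrame:
    """Per-subject tests of location and spread against the cohort.

    For each subject: a one-sample two-sided t test of their visits
    against the cohort grand mean, and a variance-ratio F test of their
    visit variance against the pooled within-subject variance.  Degenerate
    statistics (zero SD or zero pooled variance) are reported as NaN with
    ``undefined=True``.

    Returns a DataFrame indexed by subject with columns
    ``t_stat, t_p, t_flag, f_stat, f_p, f_flag, undefined``.
    """
    if not panel.is_balanced():
        raise ValueError("subject_vs_grand_tests requires a balanced panel")
    wide = panel.wide()
    S, T = wide.shape
    if S < 2 or T < 2:
        raise ValueError("need >= 2 subjects and >= 2 visits")
    grand = float(wide.to_numpy().mean())
    sds = wide.std(axis=1, ddof=1)
    means = wide.mean(axis=1)
    pooled_var = float((sds**2).mean())  # balanced: simple average of subject variances

    rows = []
    for sid in wide.index:
        s, m = float(sds[sid]), float(means[sid])
        if s == 0.0:
            t_stat = t_p = math.nan
            undef_t = True
        else:
            t_stat = (m - grand) / (s / math.sqrt(T))
            t_p = 2.0 * stats.t.sf(abs(t_stat), T - 1)
            undef_t = False
        if pooled_var == 0.0:
            f_stat = f_p = math.nan
            undef_f = True
        else:
            f_stat = s**2 / pooled_var
            # two-sided variance-ratio p with T-1 and S(T-1) df
            cdf = stats.f.cdf(f_stat, T - 1, S * (T - 1))
            f_p = 2.0 * min(cdf, 1.0 - cdf)
            undef_f = False
        rows.append(
            {
                "subject_id": sid,
                "t_stat": t_stat,
                "t_p": t_p,
                "t_flag": (not undef_t) and t_p < alpha,
                "f_stat": f_stat,
                "f_p": f_p,
                "f_flag": (not undef_f) and f_p < alpha,
                "undefined": undef_t or undef_f,
            }
        )
    return pd.DataFrame(rows).set_index("subject_id")


def summary_table(panel: LongitudinalPanel) -> pd.DataFrame:
    """Tidy table: one row per subject plus a final cohort row.

    Columns: ``subject_id, n, mean, sd, cv_percent``; the cohort row uses
    subject-mean statistics and CV(inter)/mean CV(intra).
    """
    subs = [subject_summary(panel, sid) for sid in panel.subject_ids]
    rows = [
        {
            "subject_id": s.subject_id,
            "n": s.n,
            "mean": s.mean,
            "sd": s.sd,
            "cv_percent": s.cv_percent,
        }
        for s in subs
    ]
    ps = panel_summary(panel)
    rows.append(
        {
            "subject_id": "__panel__",
            "n": ps.n_subjects,
            "mean": ps.grand_mean,
            "sd": ps.sd_of_subject_means,
            "cv_percent": ps.cv_inter_percent,
        }
    )
    return pd.DataFrame(rows)
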