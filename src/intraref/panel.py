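"""Data model and I/O for longitudinal laboratory panels.

A panel holds repeated measurements of one analyte on a cohort of
subjects: one row per (subject, visit), long format.  Validation enforces
the invariants every downstream estimator relies on — unique
(subject, visit) pairs, contiguous visit numbering from 1, finite
non-negative values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LongitudinalPanel",
    "AnalyteConfig",
    "ValidationReport",
    "PanelError",
    "SchemaError",
    "PanelValidationError",
    "read_panel",
    "write_panel",
    "validate_panel",
    "load_analyte_configs",
    "default_analyte_configs",
    "round_display",
]

REQUIRED_COLUMNS = ("subject_id", "sex", "visit_index", "analyte", "value")

SEX_CODES = {"M": "male", "F": "female", "U": "unspecified"}
SEX_LABELS = {v: k for k, v in SEX_CODES.items()}
_VALID_SEX = frozenset(SEX_CODES.values())


class PanelError(Exception):
    """Base class for panel construction and I/O failures."""


class SchemaError(PanelError):
    """The input file is missing a required column."""


class PanelValidationError(PanelError):
    """The data violate a panel invariant (duplicates, gaps, bad values)."""


def round_display(x: float, decimals: int) -> float:
    """Round half away from zero at ``decimals`` places.

    Used only when formatting results for display; computations always run
    at full precision.
    """
    if not math.isfinite(x):
        return x
    q = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * q + 0.5), x) / q


@dataclass(frozen=True)
class LongitudinalPanel:
    """Repeated measurements of one analyte, one row per (subject, visit).

    Parameters
    ----------
    analyte : str
        Analyte identifier (e.g. ``"TRF"``).
    units : str
        Measurement units (e.g. ``"mg/dL"``).
    data : pandas.DataFrame
        Columns ``subject_id`` (str), ``sex`` (one of ``male``, ``female``,
        ``unspecified``), ``visit_index`` (int, 1-based) and ``value``
        (float).  Sorted by (subject_id, visit_index) at construction.
    """

    analyte: str
    units: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True)
        missing = [c for c in ("subject_id", "sex", "visit_index", "value") if c not in df.columns]
        if missing:
            raise SchemaError(f"panel data missing column(s): {', '.join(missing)}")
        df = df.assign(
            subject_id=df["subject_id"].astype(str),
            sex=df["sex"].astype(str),
            visit_index=df["visit_index"].astype(int),
            value=df["value"].astype(float),
        ).sort_values(["subject_id", "visit_index"], kind="mergesort").reset_index(drop=True)
        _check_invariants(df)
        object.__setattr__(self, "data", df)

    # -- accessors ---------------------------------------------------------

    @property
    def subject_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["subject_id"]))

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    @property
    def n_records(self) -> int:
        return len(self.data)

    def visit_counts(self) -> dict[str, int]:
        return self.data.groupby("subject_id", sort=False)["visit_index"].size().to_dict()

    def is_balanced(self) -> bool:
        counts = set(self.visit_counts().values())
        return len(counts) <= 1

    @property
    def n_visits(self) -> int:
        """Common number of visits; raises on an unbalanced panel."""
        counts = set(self.visit_counts().values())
        if len(counts) != 1:
            raise PanelValidationError("panel is unbalanced; no common visit count")
        return counts.pop()

    def subject_values(self, subject_id: str) -> np.ndarray:
        sub = self.data[self.data["subject_id"] == str(subject_id)]
        if sub.empty:
            raise KeyError(f"unknown subject: {subject_id!r}")
        return sub["value"].to_numpy()

    def subject_sex(self, subject_id: str) -> str:
        sub = self.data[self.data["subject_id"] == str(subject_id)]
        if sub.empty:
            raise KeyError(f"unknown subject: {subject_id!r}")
        return sub["sex"].iloc[0]

    def wide(self) -> pd.DataFrame:
        """Subjects × visits matrix (only meaningful for balanced panels)."""
        return self.data.pivot(index="subject_id", columns="visit_index", values="value")


def _check_invariants(df: pd.DataFrame) -> None:
    if df["value"].isna().any() or not np.isfinite(df["value"]).all():
        bad = df.index[~np.isfinite(df["value"].fillna(np.inf))].tolist()
        raise PanelValidationError(f"non-finite value(s) at row(s) {bad}")
    if (df["value"] < 0).any():
        bad = df.loc[df["value"] < 0, ["subject_id", "visit_index"]].to_records(index=False).tolist()
        raise PanelValidationError(f"negative value(s) at {bad}")
    bad_sex = sorted(set(df["sex"]) - _VALID_SEX)
    if bad_sex:
        raise PanelValidationError(f"invalid sex value(s): {bad_sex}; expected male/female/unspecified")
    dup = df.duplicated(subset=["subject_id", "visit_index"], keep=False)
    if dup.any():
        offenders = (
            df.loc[dup, ["subject_id", "visit_index"]].drop_duplicates().to_records(index=False).tolist()
        )
        raise PanelValidationError(f"duplicate (subject, visit) pair(s): {offenders}")
    for sid, grp in df.groupby("subject_id", sort=False):
        visits = grp["visit_index"].tolist()
        if visits != list(range(1, len(visits) + 1)):
            raise PanelValidationError(
                f"subject {sid!r}: visit indices {visits} are not contiguous from 1 "
                "(pass reindex_visits=True to renumber observed visits)"
            )
        if (grp["sex"].nunique()) != 1:
            raise PanelValidationError(f"subject {sid!r} has inconsistent sex codes")


# -- file I/O --------------------------------------------------------------


def read_panel(
    path: str | Path,
    analyte: str,
    *,
    units: str = "",
    reindex_visits: bool = False,
) -> LongitudinalPanel:
    """Read a long-format delimited file and return the panel for one analyte.

    The file must be UTF-8 with a header row and columns
    ``subject_id,sex,visit_index,analyte,value``; comma or tab delimited
    (sniffed).  ``sex`` uses the codes M/F/U.

    Parameters
    ----------
    reindex_visits : bool
        When True, each subject's observed visits are renumbered 1..k in
        their original order instead of rejecting gaps.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = pd.read_csv(path, sep=None, engine="python", dtype=str, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")

    rows = raw[raw["analyte"].astype(str) == str(analyte)].copy()
    values = pd.to_numeric(rows["value"], errors="coerce")
    bad = values.isna() & rows["value"].notna()
    if bad.any():
        # +2: header line plus 1-based numbering
        lineno = int(bad.idxmax()) + 2
        raise PanelError(f"{path}:{lineno}: non-numeric value {rows.loc[bad.idxmax(), 'value']!r}")
    visits = pd.to_numeric(rows["visit_index"], errors="coerce")
    if visits.isna().any():
        lineno = int(visits.isna().idxmax()) + 2
        raise PanelError(f"{path}:{lineno}: non-integer visit_index")

    df = pd.DataFrame(
        {
            "subject_id": rows["subject_id"].astype(str),
            "sex": rows["sex"].str.strip().str.upper().map(SEX_CODES).fillna("unspecified"),
            "visit_index": visits.astype(int),
            "value": values.astype(float),
        }
    )
    if reindex_visits:
        df = df.sort_values(["subject_id", "visit_index"], kind="mergesort")
        df["visit_index"] = df.groupby("subject_id", sort=False).cumcount() + 1
    return LongitudinalPanel(analyte=str(analyte), units=units, data=df)


def write_panel(panel: LongitudinalPanel, path: str | Path) -> Path:
    """Write a panel back to the long delimited format read by read_panel."""
    path = Path(path)
    out = panel.data.assign(
        sex=panel.data["sex"].map(SEX_LABELS),
        analyte=panel.analyte,
    )[["subject_id", "sex", "visit_index", "analyte", "value"]]
    out.to_csv(path, index=False)
    return path


# -- validation report -----------------------------------------------------


@dataclass(frozen=True)
class ValidationReport:
    passed: bool
    n_subjects: int
    visit_counts: Mapping[str, int]
    issues: tuple[str, ...] = ()

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        head = "PASS" if self.passed else "FAIL"
        lines = [f"{head}: {self.n_subjects} subject(s)"]
        lines += [f"  - {msg}" for msg in self.issues]
        return "\n".join(lines)


def validate_panel(
    panel: LongitudinalPanel, min_subjects: int = 2, min_visits: int = 2
) -> ValidationReport:
    """Check cohort-size requirements on an already invariant-clean panel.

    Structural invariants (duplicates, gaps, finiteness) are enforced at
    construction, so this reports only count shortfalls — it never raises.
    """
    counts = panel.visit_counts()
    issues: list[str] = []
    if panel.n_records == 0:
        issues.append("no records")
    if panel.n_subjects < min_subjects:
        issues.append(f"only {panel.n_subjects} subject(s); need >= {min_subjects}")
    short = {s: c for s, c in counts.items() if c < min_visits}
    for sid, c in sorted(short.items()):
        issues.append(f"subject {sid!r} has {c} visit(s); need >= {min_visits}")
    return ValidationReport(
        passed=not issues,
        n_subjects=panel.n_subjects,
        visit_counts=counts,
        issues=tuple(issues),
    )


# -- analyte configuration -------------------------------------------------


@dataclass(frozen=True)
class AnalyteConfig:
    """Per-analyte constants: routine population range, assay CV, display.

    ``population_range`` is the conventional (inter-individual) reference
    range for unspecified sex; ``sex_ranges`` optionally overrides it per
    sex.  ``cva_percent`` is the analytical (assay) coefficient of
    variation consumed by the RCV method.
    """

    analyte: str
    units: str
    population_range: tuple[float, float]
    cva_percent: float
    display_decimals: int = 1
    z_value: float = 1.96
    sex_ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.population_range
        if not lo < hi:
            raise ValueError(f"{self.analyte}: population_range lower must be < upper")
        for sex, (slo, shi) in self.sex_ranges.items():
            if not slo < shi:
                raise ValueError(f"{self.analyte}/{sex}: range lower must be < upper")
        if not math.isfinite(self.cva_percent) or self.cva_percent < 0:
            raise ValueError(f"{self.analyte}: cva_percent must be finite and >= 0")
        if self.z_value <= 0:
            raise ValueError("z_value must be positive")

    def range_for(self, sex: str = "unspecified") -> tuple[float, float]:
        """Population range for a record's sex; falls back to the overall range."""
        return tuple(self.sex_ranges.get(sex, self.population_range))

    def fmt(self, x: float) -> float:
        return round_display(x, self.display_decimals)


def _config_from_dict(analyte: str, d: Mapping) -> AnalyteConfig:
    sex_ranges = {s: tuple(map(float, r)) for s, r in (d.get("sex_ranges") or {}).items()}
    return AnalyteConfig(
        analyte=analyte,
        units=str(d.get("units", "")),
        population_range=tuple(map(float, d["population_range"])),
        cva_percent=float(d["cva_percent"]),
        display_decimals=int(d.get("display_decimals", 1)),
        z_value=float(d.get("z_value", 1.96)),
        sex_ranges=sex_ranges,
    )


def load_analyte_configs(path: str | Path) -> dict[str, AnalyteConfig]:
    """Load a YAML (or JSON — YAML is a superset) analyte-config document."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise SchemaError(f"{path}: expected a mapping analyte -> config")
    return {a: _config_from_dict(a, d) for a, d in doc.items()}


def default_analyte_configs() -> dict[str, AnalyteConfig]:
    """Shipped defaults for the four serum nutrition markers.

    Routine reference ranges and assay CVs are those in routine clinical
    use for transferrin, albumin, retinol-binding protein and
    transthyretin.
    """
    here = Path(__file__).with_name("analytes.yaml")
    return load_analyte_configs(here)
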