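"""End-to-end report generation: panel in, per-analyte tables + manifest out.

Outputs per analyte: the cohort summary table, the mixed-model
components table, per-subject intervals for every requested method,
per-step sequential trajectories and a JSON comparison summary.  A
manifest records every file with its SHA-256 checksum so that seeded
runs can be verified bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import intervals as iv
from .bayes import PriorParams, estimate_components, posterior, bayes_interval
from .descriptive import subject_summary, summary_table
from .panel import AnalyteConfig, LongitudinalPanel, default_analyte_configs
from .sequential import METHODS, comparison_report, cumulative_trajectory, trajectory_table

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("intraref")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class RunConfig:
    """Pipeline settings; defaults mirror the library defaults.

    methods : subset of {naive, rcv, tango, bayes, population}.
    mode    : prospective (interval from visits 1..k-1 judges visit k) or
              retrospective (cumulative interval at k uses visits 1..k).
    """

    analytes: dict[str, AnalyteConfig] = field(default_factory=default_analyte_configs)
    methods: tuple[str, ...] = ("naive", "rcv", "tango", "bayes")
    alpha: float = 0.05
    z_value: float = 1.96
    mode: str = "prospective"
    out_dir: Path = Path("intraref_out")
    seed: int | None = None
    log_level: str = "info"

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("method list must be non-empty")
        bad = [m for m in self.methods if m not in METHODS]
        if bad:
            raise ValueError(f"unknown method(s): {bad}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.mode not in ("prospective", "retrospective"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("methods", "alpha", "z_value", "mode", "out_dir", "seed", "log_level"):
            if key in doc:
                kwargs[key] = tuple(doc[key]) if key == "methods" else doc[key]
        if "analytes" in doc:
            from .panel import _config_from_dict

            kwargs["analytes"] = {a: _config_from_dict(a, d) for a, d in doc["analytes"].items()}
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def _subject_intervals(
    panel: LongitudinalPanel, cfg: AnalyteConfig, config: RunConfig
) -> pd.DataFrame:
    comp = estimate_components(panel) if "bayes" in config.methods else None
    prior = None
    if comp is not None:
        grand = float(panel.data.groupby("subject_id", sort=False)["value"].mean().mean())
        prior = PriorParams(mu0=grand, sigma0_sq=comp.between_var)
    rows = []
    for sid in panel.subject_ids:
        vals = panel.subject_values(sid)
        ss = subject_summary(panel, sid)
        for method in config.methods:
            if method == "population":
                lo, hi = cfg.range_for(panel.subject_sex(sid))
                interval = iv.ReferenceInterval("population", lo, hi, (lo + hi) / 2.0, 0)
            elif method == "naive":
                interval = iv.naive_interval(ss.mean, ss.sd, cfg.z_value, n_used=ss.n)
            elif method == "tango":
                interval = iv.tango_interval(vals, config.alpha)
            elif method == "rcv":
                pct = iv.rcv(iv.RcvParams(cfg.cva_percent, ss.cv_percent, cfg.z_value))
                interval = iv.rcv_interval(ss.mean, pct, n_used=ss.n)
            else:  # bayes
                post = posterior(prior, comp.within_var, vals)
                interval = bayes_interval(post, comp.within_var, cfg.z_value)
            rows.append(
                {
                    "subject_id": sid,
                    "method": method,
                    "n_used": interval.n_used,
                    "center": interval.center,
                    "lower": interval.lower,
                    "upper": interval.upper,
                    "half_width": interval.half_width,
                }
            )
    return pd.DataFrame(rows)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def run_pipeline(config: RunConfig, panels: dict[str, LongitudinalPanel]) -> dict:
    """Run every stage for every analyte panel and write the report bundle.

    Returns the manifest (also written to ``manifest.json``): per analyte
    the list of outputs with checksums, plus a ``failed`` marker naming
    the stage if one raised.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"outputs": {}, "failed": None, "seed": config.seed}
    try:
        for analyte, panel in panels.items():
            stage = f"{analyte}"
            cfg = config.analytes.get(analyte)
            if cfg is None:
                raise PipelineError(f"stage {analyte}/config: no analyte config for {analyte!r}")
            files: list[Path] = []
            adir = out / analyte
            adir.mkdir(exist_ok=True)

            stage = f"{analyte}/summary"
            files.append(_write_csv(summary_table(panel), adir / "summary.csv"))

            stage = f"{analyte}/components"
            comp = estimate_components(panel)
            comp_df = pd.DataFrame(
                [
                    {
                        "analyte": analyte,
                        "between_var": comp.between_var,
                        "between_sd": comp.between_sd,
                        "within_var": comp.within_var,
                        "within_sd": comp.within_sd,
                        "total_sd": comp.total_sd,
                    }
                ]
            )
            files.append(_write_csv(comp_df, adir / "components.csv"))

            stage = f"{analyte}/intervals"
            files.append(_write_csv(_subject_intervals(panel, cfg, config), adir / "intervals.csv"))

            stage = f"{analyte}/sequential"
            trajs = [
                cumulative_trajectory(
                    panel, sid, m, cfg, comp, mode=config.mode, alpha=config.alpha
                )
                for sid in panel.subject_ids
                for m in config.methods
            ]
            files.append(_write_csv(trajectory_table(trajs), adir / "sequential.csv"))

            stage = f"{analyte}/comparison"
            report = comparison_report(panel, cfg, alpha=config.alpha, components=comp)
            cmp_path = adir / "comparison.json"
            cmp_path.write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))
            files.append(cmp_path)

            manifest["outputs"][analyte] = {
                str(p.relative_to(out)): _sha256(p) for p in files
            }
    except Exception as exc:  # partial outputs retained, stage recorded
        manifest["failed"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        log.error("pipeline failed at stage %s: %s", stage, exc)
        raise PipelineError(f"stage {stage}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
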