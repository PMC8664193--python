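"""Config-driven end-to-end runner: region in, access table + statistics out.

Stages: load or generate a region, build the travel-time graph, snap
facilities and population-weighted area centroids to junctions, route
closest station / emergency department per area, compose RT/TT/TPT with
golden-hour and quintile classification, and run the comparative (Pearson,
ANOVA + Tukey) and disparity (NB2 regression) statistics. Border-buffer
areas stay routable but are excluded from every reported statistic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import shapely
import yaml

from . import __version__
from .accessibility import (
    AREA_TYPES,
    MEASURES,
    TimeConstants,
    compute_access_table,
)
from .inference import (
    AnovaResult,
    ModelSpec,
    NBModelResult,
    anova_by_area_type,
    correlation_rt_tt,
    fit_disparity_models,
)
from .region import SyntheticRegion, areas_frame
from .region_io import read_region, write_region
from .road_network import snap_to_junction, weighted_centroid
from .synthetic_data import RegionConfig, generate_region

logger = logging.getLogger(__name__)

DEFAULT_MODEL_SPECS = [
    ModelSpec(m, with_interaction=i, subset=s)
    for m in MEASURES
    for i, s in ((False, "all"), (True, "all"), (False, "quintile5"))
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything one pipeline run needs; YAML/JSON-serializable."""

    seed: int = 0
    input_dir: str | None = None            # region files, or ...
    synthetic: RegionConfig | None = None   # ... a generator config
    constants: TimeConstants = field(default_factory=TimeConstants)
    n_quantiles: int = 5
    model_specs: list[ModelSpec] = field(default_factory=lambda: list(DEFAULT_MODEL_SPECS))
    income_scale: float = 1.0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.input_dir is None and self.synthetic is None:
            self.synthetic = RegionConfig(seed=self.seed)

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs: dict[str, Any] = {}
        for key in ("seed", "input_dir", "n_quantiles", "income_scale", "out_dir"):
            if key in raw:
                kwargs[key] = raw[key]
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            if "covariate_gradients" in syn:
                syn["covariate_gradients"] = {
                    k: tuple(v) for k, v in syn["covariate_gradients"].items()
                }
            if "speed_classes" in syn:
                syn["speed_classes"] = [tuple(v) for v in syn["speed_classes"]]
            syn.setdefault("seed", kwargs.get("seed", 0))
            kwargs["synthetic"] = RegionConfig(**syn)
        if "constants" in raw and raw["constants"] is not None:
            kwargs["constants"] = TimeConstants(**raw["constants"])
        if "model_specs" in raw and raw["model_specs"] is not None:
            kwargs["model_specs"] = [ModelSpec(**m) for m in raw["model_specs"]]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d: dict[str, Any] = {
            "seed": self.seed,
            "input_dir": self.input_dir,
            "n_quantiles": self.n_quantiles,
            "income_scale": self.income_scale,
            "constants": dataclasses.asdict(self.constants),
            "model_specs": [dataclasses.asdict(m) for m in self.model_specs],
        }
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    """Summary of one pipeline run (mirrors a descriptives-plus-models
    results section)."""

    descriptives: pd.DataFrame
    golden_hour: pd.DataFrame      # per area type: within / outside counts
    correlation_rt_tt: tuple[float, float]
    anova: dict[str, AnovaResult]
    models: list[NBModelResult]
    n_areas: int
    n_reportable: int
    provenance: dict

    def to_json_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "n_areas": self.n_areas,
            "n_reportable": self.n_reportable,
            "descriptives": self.descriptives.to_dict(orient="records"),
            "golden_hour": self.golden_hour.to_dict(orient="records"),
            "correlation_rt_tt": {
                "r": self.correlation_rt_tt[0], "p": self.correlation_rt_tt[1],
            },
            "anova": {
                m: {
                    "F": a.F, "df_between": a.df_between, "df_within": a.df_within,
                    "p": a.p,
                    "groups": a.group_stats.to_dict(orient="records"),
                    "tukey": [
                        {"pair": list(k), "mean_diff": v[0], "p_adj": v[1]}
                        for k, v in a.tukey.items()
                    ],
                }
                for m, a in self.anova.items()
            },
            "models": [
                {
                    "label": r.label, "n": r.n, "alpha": r.alpha,
                    "log_likelihood": r.log_likelihood, "aic": r.aic, "bic": r.bic,
                    "terms": {t: {"estimate": e, "se": s, "p": p}
                              for t, (e, s, p) in r.coefficients.items()},
                }
                for r in self.models
            ],
        }

    def to_text(self) -> str:
        lines = [
            f"ehc-access run (config {self.provenance['config_hash']}, "
            f"seed {self.provenance['seed']})",
            f"areas: {self.n_areas} total, {self.n_reportable} reportable",
            "",
            "Golden hour (TPT < %.0f min):" % self.provenance["golden_hour_min"],
        ]
        for rec in self.golden_hour.to_dict(orient="records"):
            lines.append(
                f"  {rec['area_type']:>18}: {rec['within']:4d} within / "
                f"{rec['outside']:4d} outside ({rec['share_within'] * 100:5.1f}% within)"
            )
        lines.append("")
        lines.append("Measure means by area type (minutes):")
        for rec in self.descriptives.to_dict(orient="records"):
            lines.append(
                f"  {rec['measure'].upper():>3} {rec['area_type']:>18}: "
                f"mean {rec['mean']:6.1f}  median {rec['median']:6.1f}  "
                f"min {rec['min']:6.1f}  max {rec['max']:6.1f}  (n={rec['n']})"
            )
        r, p = self.correlation_rt_tt
        lines.append("")
        lines.append(f"Pearson r(RT, TT) = {r:.3f} (p = {p:.2e})")
        for m, a in self.anova.items():
            lines.append(
                f"ANOVA {m.upper()}: F({a.df_between}, {a.df_within}) = {a.F:.1f}, "
                f"p = {a.p:.2e}"
            )
        lines.append("")
        lines.append("Disparity models (NB2):")
        for res in self.models:
            lines.append(
                f"  {res.label:<22} n={res.n:<5d} alpha={res.alpha:.4f} "
                f"llf={res.log_likelihood:9.1f} AIC={res.aic:9.1f} BIC={res.bic:9.1f}"
            )
        return "\n".join(lines) + "\n"


def summarize_by_area_type(access: pd.DataFrame, areas: pd.DataFrame) -> pd.DataFrame:
    """Mean/median/min/max of each measure, overall and per area type."""
    if access.empty:
        raise ValueError("no access records to summarize")
    data = access.merge(areas[["area_id", "area_type"]], on="area_id")
    rows = []
    groups = [("all", data)] + [
        (t, data[data["area_type"] == t]) for t in AREA_TYPES
        if (data["area_type"] == t).any()
    ]
    for label, sub in groups:
        for m in MEASURES:
            x = sub[f"{m}_min"]
            rows.append({
                "measure": m, "area_type": label, "n": len(sub),
                "mean": float(x.mean()), "median": float(x.median()),
                "min": float(x.min()), "max": float(x.max()),
                "share_within_golden_hour": float(sub["within_golden_hour"].mean()),
            })
    return pd.DataFrame(rows)


def _golden_hour_table(access: pd.DataFrame, areas: pd.DataFrame) -> pd.DataFrame:
    data = access.merge(areas[["area_id", "area_type"]], on="area_id")
    rows = []
    for label, sub in [("all", data)] + [
        (t, data[data["area_type"] == t]) for t in AREA_TYPES
        if (data["area_type"] == t).any()
    ]:
        within = int(sub["within_golden_hour"].sum())
        rows.append({
            "area_type": label,
            "within": within,
            "outside": len(sub) - within,
            "share_within": within / len(sub) if len(sub) else float("nan"),
        })
    return pd.DataFrame(rows)


def prepare_region(config: RunConfig) -> SyntheticRegion:
    if config.input_dir is not None:
        return read_region(config.input_dir)
    return generate_region(config.synthetic)


def compute_access(region: SyntheticRegion, constants: TimeConstants) -> pd.DataFrame:
    """Snap centroids/facilities and build the per-area access table."""
    cells = [((x, y), c) for x, y, c in np.asarray(region.population_grid)]
    tree = shapely.STRtree([shapely.points(x, y) for (x, y), _ in cells])
    centroid_nodes: dict[str, int] = {}
    area_types: dict[str, str] = {}
    for area in region.areas:
        idx = tree.query(area.polygon, predicate="intersects")
        wc = weighted_centroid(area.area_id, area.polygon, [cells[i] for i in sorted(idx)])
        node = snap_to_junction(wc.point, region.network)
        area.centroid = dataclasses.replace(wc, snapped_node=node)
        centroid_nodes[area.area_id] = node
        area_types[area.area_id] = area.area_type
    stations = [f.snapped(region.network) for f in region.stations]
    hospitals = [f.snapped(region.network) for f in region.hospitals]
    return compute_access_table(
        region.network, centroid_nodes, area_types, stations, hospitals, constants
    )


def run_pipeline(config: RunConfig) -> RunReport:
    """Run every stage; see the module docstring. Deterministic for a fixed
    config (all randomness flows from the region seed)."""
    try:
        region = prepare_region(config)
    except Exception as exc:
        raise PipelineError("load_region", exc) from exc

    areas = areas_frame(region.areas)
    try:
        access = compute_access(region, config.constants)
    except Exception as exc:
        raise PipelineError("accessibility", exc) from exc

    reportable_ids = set(areas.loc[areas["reportable"], "area_id"])
    reported = access[access["area_id"].isin(reportable_ids)].reset_index(drop=True)
    rep_areas = areas[areas["area_id"].isin(set(reported["area_id"]))]

    try:
        descriptives = summarize_by_area_type(reported, rep_areas)
        golden = _golden_hour_table(reported, rep_areas)
        corr = correlation_rt_tt(reported)
        merged = reported.merge(rep_areas[["area_id", "area_type"]], on="area_id")
        anova = {
            m: anova_by_area_type(merged[f"{m}_min"], merged["area_type"])
            for m in MEASURES
            if merged["area_type"].nunique() >= 2
        }
    except Exception as exc:
        raise PipelineError("comparative_statistics", exc) from exc

    models: list[NBModelResult] = []
    for spec in config.model_specs:
        try:
            models.append(
                fit_disparity_models(rep_areas, reported, spec,
                                     income_scale=config.income_scale)
            )
        except Exception as exc:
            raise PipelineError(f"model_{spec.label}", exc) from exc

    provenance = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "package_version": __version__,
        "golden_hour_min": config.constants.golden_hour,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    report = RunReport(
        descriptives=descriptives,
        golden_hour=golden,
        correlation_rt_tt=corr,
        anova=anova,
        models=models,
        n_areas=len(areas),
        n_reportable=len(reported),
        provenance=provenance,
    )

    if config.out_dir is not None:
        write_outputs(config, region, access, report)
    return report


def write_outputs(
    config: RunConfig,
    region: SyntheticRegion,
    access: pd.DataFrame,
    report: RunReport,
) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    access.to_csv(out / "access.csv", index=False)

    rows = []
    fit_rows = []
    for res in report.models:
        for term, (e, s, p) in res.coefficients.items():
            rows.append({"model": res.label, "term": term,
                         "estimate": e, "se": s, "p": p})
        fit_rows.append({"model": res.label, "n": res.n, "alpha": res.alpha,
                         "loglik": res.log_likelihood, "aic": res.aic, "bic": res.bic})
    pd.DataFrame(rows).to_csv(out / "models.csv", index=False)
    pd.DataFrame(fit_rows).to_csv(out / "model_fit.csv", index=False)

    full = report.to_json_dict()
    with open(out / "report.json", "w") as fh:
        json.dump(full, fh, indent=2)
    with open(out / "anova.json", "w") as fh:
        json.dump(full["anova"], fh, indent=2)
    with open(out / "correlations.json", "w") as fh:
        json.dump(full["correlation_rt_tt"], fh, indent=2)
    with open(out / "report.txt", "w") as fh:
        fh.write(report.to_text())
    logger.info("wrote outputs to %s", out)
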