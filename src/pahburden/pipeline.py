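"""End-to-end orchestration: synth → simulate → stats/cluster → burden.

`run_pipeline` executes the whole chain for each requested scenario and
writes every intermediate table (distribution CSV, summary JSON, cluster
CSV, burden JSON) plus a consolidated report, so each reported number is
traceable to a stage output file.  Configuration comes from a
`PipelineConfig`, loadable from YAML.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dist_stats import (
    kmeans2,
    kruskal_wallis,
    levene,
    mann_whitney_u,
    shapiro_wilk,
    summarize,
)
from .exposure_sim import (
    OPTIMISTIC,
    PESSIMISTIC,
    ExposureDistribution,
    Scenario,
    SimConfig,
    pah4_by_sample,
    simulate,
)
from .risk_burden import RiskParams, burden_chain
from .synthetic_tds import (
    SynthConfig,
    generate_catalog,
    generate_concentrations,
    generate_survey,
)
from .tds_data import (
    Catalog,
    ValidationError,
    read_catalog,
    read_concentration_table,
    read_survey,
    write_catalog,
    write_concentration_table,
    write_survey,
)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "cooking_method_table",
    "SCENARIOS",
]

logger = logging.getLogger(__name__)

SCENARIOS: dict[str, Scenario] = {
    "optimistic": OPTIMISTIC,
    "pessimistic": PESSIMISTIC,
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class PipelineConfig:
    """Configuration of an end-to-end run.

    Either ``synth`` (generate a synthetic TDS) or the three input paths
    (``catalog_path``, ``concentrations_path``, ``survey_path``) must be
    provided.  ``scenarios`` selects which substitution policies to run.
    """

    risk: RiskParams
    sim: SimConfig = field(default_factory=SimConfig)
    synth: Optional[SynthConfig] = None
    catalog_path: Optional[str] = None
    concentrations_path: Optional[str] = None
    survey_path: Optional[str] = None
    scenarios: tuple[str, ...] = ("optimistic", "pessimistic")
    cooking_category: str = "fish and seafood"
    output_dir: str = "pipeline_out"
    write_distributions: bool = True

    def __post_init__(self) -> None:
        if not self.scenarios:
            raise ValidationError("at least one scenario required")
        for s in self.scenarios:
            if s not in SCENARIOS:
                raise ValidationError(f"unknown scenario {s!r}")
        paths = (self.catalog_path, self.concentrations_path, self.survey_path)
        if self.synth is None:
            if not all(paths):
                raise ValidationError(
                    "either synth config or all three input paths must be given"
                )
            for p in paths:
                if not Path(p).exists():
                    raise ValidationError(f"input file not found: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kwargs = dict(raw)
        kwargs["risk"] = RiskParams.from_dict(raw["risk"])
        if "sim" in raw:
            kwargs["sim"] = SimConfig(**raw["sim"])
        if raw.get("synth") is not None:
            kwargs["synth"] = SynthConfig(**raw["synth"])
        if "scenarios" in raw:
            kwargs["scenarios"] = tuple(raw["scenarios"])
        return cls(**kwargs)


def cooking_method_table(
    records, catalog: Catalog, category: str = "fish and seafood"
) -> dict[str, np.ndarray]:
    """Group per-composite-sample PAH4 (µg/kg) by cooking method.

    Restricted to one food category; uses pessimistic (upper-bound)
    substitution so all-non-detect methods remain distinguishable rather
    than collapsing to identical zeros.  Methods with zero samples are
    excluded with a warning; fewer than two remaining methods is an error
    (no contrast to test).
    """
    cat_foods = {it.food_id: it for it in catalog if it.category == category}
    if not cat_foods:
        raise ValidationError(f"no foods in category {category!r}")
    per_food = pah4_by_sample(
        [r for r in records if r.food_id in cat_foods], PESSIMISTIC
    )
    groups: dict[str, list[float]] = {}
    for fid, values in per_food.items():
        method = cat_foods[fid].cooking_method
        groups.setdefault(method, []).extend(values.tolist())
    methods = {it.cooking_method for it in cat_foods.values()}
    for m in sorted(methods - set(groups)):
        logger.warning("cooking method %r has zero samples in %r; excluded", m, category)
    if len(groups) < 2:
        raise ValidationError(
            f"category {category!r} has a single cooking method: no contrast"
        )
    return {m: np.asarray(groups[m]) for m in sorted(groups)}


def _config_hash(cfg: PipelineConfig) -> str:
    blob = repr(cfg).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""
    class _Ctx:
        def __init__(self, label: str):
            self.label = label
            self.t0 = 0.0

        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage {self.label!r} failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", self.label, time.perf_counter() - self.t0)
            return False

    return _Ctx(name)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage for each scenario and return the consolidated report.

    The report (also written to ``report.json``) carries, per scenario, the
    distribution summary, the cluster prevalence, the burden-chain result
    and the Mann-Whitney test between clusters (with Shapiro-Wilk/Levene
    assumption checks), plus the Kruskal-Wallis test across cooking methods
    and provenance (seeds, config hash, version).  Identical (cfg, seed)
    yields an identical report.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("load-data"):
        if cfg.synth is not None:
            catalog = generate_catalog(cfg.synth)
            records = generate_concentrations(catalog, cfg.synth)
            survey = generate_survey(catalog, cfg.synth)
            write_catalog(catalog, out / "catalog.csv")
            write_concentration_table(records, out / "concentrations.csv")
            write_survey(survey, out / "survey.csv")
        else:
            catalog = read_catalog(cfg.catalog_path)
            records = read_concentration_table(cfg.concentrations_path, catalog)
            survey = read_survey(cfg.survey_path, catalog)
        logger.info(
            "data: %d foods, %d concentration records, %d person-days",
            len(catalog), len(records), len(survey),
        )

    report: dict = {
        "scenarios": {},
        "provenance": {
            "package_version": __version__,
            "sim_seed": cfg.sim.seed,
            "synth_seed": cfg.synth.seed if cfg.synth is not None else None,
            "config_hash": _config_hash(cfg),
            "iterations": cfg.sim.iterations,
        },
    }

    for name in cfg.scenarios:
        scenario = SCENARIOS[name]
        with _stage(f"simulate[{name}]"):
            dist = simulate(survey, records, scenario, cfg.sim)
            if cfg.write_distributions:
                pd.DataFrame(
                    {
                        "iteration": np.arange(dist.iterations),
                        "scenario": name,
                        "exposure_mg_per_kg_bw_day": dist.values,
                    }
                ).to_csv(out / f"dist_{name}.csv", index=False)

        with _stage(f"stats[{name}]"):
            summary = summarize(dist)
            (out / f"summary_{name}.json").write_text(
                json.dumps(summary.to_dict(), indent=2)
            )

        with _stage(f"cluster[{name}]"):
            clusters = kmeans2(dist.values)
            if cfg.write_distributions:
                pd.DataFrame(
                    {
                        "exposure_mg_per_kg_bw_day": dist.values,
                        "label": clusters.labels,
                    }
                ).to_csv(out / f"clusters_{name}.csv", index=False)
            unexp = dist.values[~clusters.exposed]
            expd = dist.values[clusters.exposed]
            mw = mann_whitney_u(unexp, expd)
            checks = {}
            for label, grp in (("unexposed", unexp), ("exposed", expd)):
                try:
                    checks[f"shapiro_{label}"] = shapiro_wilk(grp, seed=cfg.sim.seed).p_value
                except ValidationError as exc:
                    logger.warning("shapiro-wilk (%s) skipped: %s", label, exc)
                    checks[f"shapiro_{label}"] = None
            try:
                checks["levene"] = levene(unexp, expd).p_value
            except ValidationError as exc:
                logger.warning("levene skipped: %s", exc)
                checks["levene"] = None

        with _stage(f"burden[{name}]"):
            burden = burden_chain(summary.median, clusters.prevalence, cfg.risk)
            (out / f"burden_{name}.json").write_text(
                json.dumps(burden.to_dict(), indent=2)
            )

        report["scenarios"][name] = {
            "summary": summary.to_dict(),
            "cluster": {
                "prevalence": clusters.prevalence,
                "threshold": clusters.threshold,
                "means": list(clusters.means),
            },
            "mann_whitney": {"statistic": mw.statistic, "p_value": mw.p_value},
            "assumption_checks": checks,
            "burden": burden.to_dict(),
        }

    with _stage("cooking-methods"):
        try:
            groups = cooking_method_table(records, catalog, cfg.cooking_category)
            kw = kruskal_wallis(list(groups.values()))
            report["cooking_methods"] = {
                "category": cfg.cooking_category,
                "group_sizes": {m: int(g.size) for m, g in groups.items()},
                "kruskal_wallis": {"statistic": kw.statistic, "p_value": kw.p_value},
            }
        except ValidationError as exc:
            logger.warning("cooking-method analysis skipped: %s", exc)
            report["cooking_methods"] = {"skipped": str(exc)}

    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
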