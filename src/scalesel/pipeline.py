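"""Configuration and end-to-end orchestration.

A single YAML config declares where the data comes from (a synthetic
scenario or CSV files), the selection tuning parameters, and which analysis
stages to run.  ``run_pipeline`` executes the full workflow — simulate (or
load), filter, standardize, select, refit, compare scales, mixed models,
interactions — and writes one CSV report per table of the analysis, plus a
manifest recording the seed, config hash, and versions so a run can be
reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_filter import apply_exclusions
from .data_model import standardize_full, standardize_gelman
from .inference_ols import refit_ols, scale_comparison_table
from .interactions import (
    DEFAULT_INTERACTION_CONCEPTS,
    build_interaction_design,
    final_interaction_models,
    prune_to_significant,
    resolve_interactions,
)
from .mixed_models import compare_re_specs
from .ss_select import ALGORITHMS, SSConfig, final_model
from .synthetic import SyntheticScenario, scenario_design, simulate_study

FLOAT_FORMAT = "%.6g"


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "scalesel_run"
    scenario: SyntheticScenario | None = None
    selection: SSConfig = field(default_factory=SSConfig)
    algorithms: tuple[str, ...] = ("stepwise", "stagewise", "lars", "lasso")
    run_mixed: bool = True
    run_interactions: bool = True
    interaction_concepts: tuple[tuple[str, str], ...] = DEFAULT_INTERACTION_CONCEPTS
    raw: dict = field(default_factory=dict, repr=False)

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML pipeline config.

    Selection tuning defaults to the study's values (epsilon 1, step size
    0.001, tolerance 0.01, alpha 0.05).  Unknown algorithm names and missing
    required fields raise a :class:`ConfigError` naming the field.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if "seed" not in doc:
        raise ConfigError("missing required field: seed")
    sel = doc.get("selection", {})
    unknown = set(sel) - {"epsilon", "step_size", "tolerance", "alpha", "max_steps"}
    if unknown:
        raise ConfigError(f"unknown selection fields: {sorted(unknown)}")
    try:
        ss_cfg = SSConfig(**sel)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid selection config: {exc}") from exc
    algos = tuple(doc.get("algorithms", ("stepwise", "stagewise", "lars", "lasso")))
    bad = set(algos) - set(ALGORITHMS)
    if bad:
        raise ConfigError(f"unknown algorithms: {sorted(bad)}")
    scen_doc = dict(doc.get("scenario", {}))
    scen_doc.setdefault("seed", doc["seed"])
    if "effects" in scen_doc:
        scen_doc["effects"] = {
            k: (v[0], float(v[1])) for k, v in scen_doc["effects"].items()
        }
    if "area_concepts" in scen_doc:
        scen_doc["area_concepts"] = {
            k: tuple(v) for k, v in scen_doc["area_concepts"].items()
        }
    try:
        scenario = SyntheticScenario(**scen_doc)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid scenario: {exc}") from exc
    pairs = tuple(
        (p[0], p[1]) for p in doc.get("interactions", DEFAULT_INTERACTION_CONCEPTS)
    )
    return PipelineConfig(
        seed=int(doc["seed"]),
        output_dir=str(doc.get("output_dir", "scalesel_run")),
        scenario=scenario,
        selection=ss_cfg,
        algorithms=algos,
        run_mixed=bool(doc.get("mixed_models", True)),
        run_interactions=bool(doc.get("run_interactions", True)),
        interaction_concepts=pairs,
        raw=doc,
    )


def write_report(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a report CSV with stable column order and 6-significant-digit
    floats."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def path_to_frame(path) -> pd.DataFrame:
    rows = []
    for i, step in enumerate(path.steps):
        for col, val in step.coef.items():
            rows.append(
                {
                    "step": i,
                    "event": step.event,
                    "knot_column": step.column or "",
                    "column": col,
                    "coefficient": val,
                    "aic": step.aic,
                }
            )
        if not step.coef:
            rows.append(
                {
                    "step": i,
                    "event": step.event,
                    "knot_column": step.column or "",
                    "column": "",
                    "coefficient": 0.0,
                    "aic": step.aic,
                }
            )
    return pd.DataFrame(
        rows, columns=["step", "event", "knot_column", "column", "coefficient", "aic"]
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis on the configured scenario and write all
    reports under ``config.output_dir``.  Returns the run directory."""
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def clock(stage: str) -> None:
        timings[stage] = round(time.time() - t0, 3)

    scenario = config.scenario or SyntheticScenario(seed=config.seed)
    geo, tables, cohort, raw, truth = simulate_study(scenario)
    clock("simulate")

    filtered, report = apply_exclusions(raw)
    write_report(
        pd.DataFrame(
            {
                "rule": ["input", "underweight", "race", "missing", "retained"],
                "count": [
                    report.n_input,
                    report.n_underweight,
                    report.n_race_excluded,
                    report.n_missing,
                    report.n_retained,
                ],
            }
        ),
        out / "exclusions.csv",
    )
    clock("filter")

    # the clean cohort is the modeling input; the raw table exercises the filter
    design = scenario_design(scenario, cohort, tables)
    y_raw = cohort["BMIZ"].to_numpy(dtype=float)
    Xs, ys, recipe = standardize_full(design, y_raw)
    groups = cohort[["cbg_id", "ct_id"]]
    clock("standardize")

    for algo in config.algorithms:
        path = ALGORITHMS[algo](Xs, ys, config.selection)
        write_report(path_to_frame(path), out / f"path_{algo}.csv")
        selected = final_model(path, Xs, ys)
        fit = refit_ols(Xs, ys, list(selected.active))
        write_report(fit.to_frame(), out / f"selected_{algo}.csv")

        comp, fits = scale_comparison_table(selected, Xs, ys)
        write_report(comp, out / f"scale_coefs_{algo}.csv")
        write_report(
            pd.DataFrame(
                {"model": list(comp.attrs["aic"]), "aic": list(comp.attrs["aic"].values())}
            ),
            out / f"scale_aic_{algo}.csv",
        )

        if config.run_mixed:
            re_table, re_fits = compare_re_specs(
                Xs, ys, list(selected.active), groups
            )
            write_report(re_table, out / f"re_aic_{algo}.csv")
            ranef = pd.concat(
                [f.ranef for k, f in re_fits.items() if hasattr(f, "ranef")],
                ignore_index=True,
            ).drop_duplicates(subset=["unit_id", "scale"], keep="last")
            write_report(ranef, out / f"ranef_{algo}.csv")

        if config.run_interactions:
            main_concepts = [Xs.info(t).concept for t in selected.active]
            forced = [c for c in ("Male",) if c not in main_concepts]
            work_terms = list(selected.active) + forced
            raw_subset = design.subset(work_terms)
            gelman, _ = standardize_gelman(raw_subset)
            spec = resolve_interactions(gelman, config.interaction_concepts)
            ext = build_interaction_design(gelman, spec)
            full_fit = refit_ols(
                ext, y_raw, work_terms + spec.term_names, add_intercept=True
            )
            reduced = prune_to_significant(full_fit, spec, config.selection.alpha)
            final_fit, ia_table, _ = final_interaction_models(
                gelman,
                y_raw,
                work_terms,
                reduced,
                groups if config.run_mixed else None,
            )
            write_report(final_fit.to_frame(), out / f"interactions_{algo}.csv")
            if ia_table is not None:
                write_report(ia_table, out / f"interactions_re_aic_{algo}.csv")
        clock(algo)

    manifest = {
        "package": "scalesel",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_input": report.n_input,
        "n_retained": report.n_retained,
        "algorithms": list(config.algorithms),
        "timings_s": timings,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
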