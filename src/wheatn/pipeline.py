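"""End-to-end orchestration: data → indices → models → comparison report.

A :class:`RunConfig` defines the experimental grid — sensor families ×
targets (LNC, PNC, NNI) × stage groupings (each stage alone plus both stages
combined) × methods — and :func:`run_pipeline` attempts every cell,
isolating failures so one degenerate family cannot abort a run.  Methods:

* ``pr``        best-single-index parametric regression,
* ``mlr``       stepwise MLR on all family features,
* ``mlr_sel``   ordinary MLR on the SBBR-selected subset,
* ``gpr``       GP regression on all family features,
* ``gpr_sbbr``  GP regression on the SBBR-selected subset.

All methods are scored by seeded 10-fold cross-validation on pooled
out-of-fold predictions; the SBBR subset is selected once per cell.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import wheatn
from wheatn.evaluation import CVResult, comparison_report, kfold_cv, render_report, results_frame
from wheatn.indices import TARGETS, build_feature_table, family_names
from wheatn.models import (
    BestIndexRegressor,
    GPRegressor,
    StepwiseLinearRegressor,
    sbbr,
)
from wheatn.synthetic import ExperimentConfig, generate_experiment, read_dataset, write_dataset

logger = logging.getLogger(__name__)

METHODS = ("pr", "mlr", "mlr_sel", "gpr", "gpr_sbbr")
STAGE_GROUPINGS = ("Feekes5", "Feekes11", "combined")


@dataclass(frozen=True)
class RunConfig:
    """Grid definition and provenance for one pipeline run."""

    synthetic: ExperimentConfig | None = None  # generate data with this config
    input_dir: str | None = None  # ... or load a written dataset
    families: tuple[str, ...] = ("asd", "multiplex", "rgb", "dualex")
    targets: tuple[str, ...] = TARGETS
    stage_groupings: tuple[str, ...] = STAGE_GROUPINGS
    methods: tuple[str, ...] = METHODS
    k_folds: int = 10
    seed: int = 0
    gpr_restarts: int = 2

    def __post_init__(self) -> None:
        if not (self.families and self.targets and self.stage_groupings and self.methods):
            raise ValueError("grid must have at least one family, target, stage and method")
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}")
        for t in self.targets:
            if t not in TARGETS:
                raise ValueError(f"unknown target {t!r}")


def _stage_rows(table: pd.DataFrame, grouping: str) -> pd.DataFrame:
    if grouping == "combined":
        return table
    return table[table["stage"] == grouping]


def _cell_results(
    feats: pd.DataFrame,
    feature_cols: list[str],
    target: str,
    grouping: str,
    config: RunConfig,
) -> list[CVResult]:
    sub = _stage_rows(feats, grouping)
    cols = [c for c in feature_cols if c in sub.columns]
    sub = sub.dropna(subset=cols + [target])
    if len(sub) < config.k_folds:
        raise ValueError(f"only {len(sub)} complete rows for {target}/{grouping}")
    X = sub[cols]
    y = sub[target].to_numpy(dtype=float)
    seed = config.seed

    selected: list[str] | None = None
    if {"gpr_sbbr", "mlr_sel"} & set(config.methods):
        trace = sbbr(X, y, k_folds=config.k_folds, seed=seed, n_restarts=config.gpr_restarts)
        selected = trace.selected

    out: list[CVResult] = []
    common = dict(target=target, stage=grouping)
    for method in config.methods:
        if method == "pr":
            est, Xm, fs = BestIndexRegressor(seed=seed), X, "single"
        elif method == "mlr":
            est, Xm, fs = StepwiseLinearRegressor(), X, "all"
        elif method == "mlr_sel":
            est, Xm, fs = StepwiseLinearRegressor(), X[selected], "selected"
        elif method == "gpr":
            est, Xm, fs = GPRegressor(n_restarts=config.gpr_restarts, random_state=seed), X, "all"
        else:  # gpr_sbbr
            est = GPRegressor(n_restarts=config.gpr_restarts, random_state=seed)
            Xm, fs = X[selected], "selected"
        r = kfold_cv(
            est, Xm, y, k=config.k_folds, seed=seed, method=method, feature_set=fs, **common
        )
        if selected is not None and fs == "selected":
            r.extra["selected_features"] = ",".join(map(str, selected))
        r.extra["n"] = len(y)
        out.append(r)
    return out


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None):
    """Run the full grid; optionally write features, results, report, manifest.

    Returns ``(results_df, report_tables, cv_results)``.  Per-cell failures
    are logged and leave missing cells rather than aborting the run.
    """
    if config.input_dir is not None:
        dataset = read_dataset(config.input_dir)
    else:
        dataset = generate_experiment(config.synthetic or ExperimentConfig(seed=config.seed))

    all_results: list[CVResult] = []
    failures: list[str] = []
    for family in config.families:
        try:
            feats = build_feature_table(dataset, families=(family,))
        except Exception as e:  # crash isolation per family
            logger.error("family %s failed to featurize: %s", family, e)
            failures.append(f"{family}: {e}")
            continue
        fam_cols = [c for c in family_names(family) if c in feats.columns]
        for target in config.targets:
            for grouping in config.stage_groupings:
                try:
                    cell = _cell_results(feats, fam_cols, target, grouping, config)
                except Exception as e:
                    logger.warning(
                        "cell (%s, %s, %s) failed: %s", family, target, grouping, e
                    )
                    failures.append(f"{family}/{target}/{grouping}: {e}")
                    continue
                for r in cell:
                    r.extra["family"] = family
                    all_results.append(r)

    flat = results_frame(all_results)
    if not flat.empty:
        flat = flat[
            ["family", "target", "stage", "method", "feature_set", "R2", "RMSE", "MAE", "NSE"]
            + [c for c in flat.columns if c not in
               ("family", "target", "stage", "method", "feature_set", "R2", "RMSE", "MAE", "NSE")]
        ]
    tables = None
    if all_results:
        tables = {}
        for fam in config.families:
            fam_res = [r for r in all_results if r.extra.get("family") == fam]
            if fam_res:
                tables[fam] = comparison_report(fam_res)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if config.input_dir is None:
            write_dataset(dataset, out / "data")
        flat.to_csv(out / "results.csv", index=False)
        if tables:
            parts = []
            for fam, tabs in tables.items():
                parts.append(f"# Sensor family: {fam}\n")
                parts.append(render_report(tabs))
            (out / "report.md").write_text("\n".join(parts))
        manifest = {
            "config": dataclasses.asdict(config),
            "seed": config.seed,
            "package_version": wheatn.__version__,
            "config_hash": hashlib.sha256(
                json.dumps(dataclasses.asdict(config), sort_keys=True, default=list).encode()
            ).hexdigest(),
            "failures": failures,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list))

    return flat, tables, all_results
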