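"""End-to-end orchestration: simulate → rank → train → evaluate → report.

A run is described by a :class:`RunConfig`; :func:`run_pipeline` executes
the full chain deterministically and writes accuracy tables (one row per
nested model: feature number, newly retained feature, overall and
per-class accuracy), the per-split AUC long table, the ReliefF ranking,
the elimination record, best/optimal model selection with the ANOVA over
AUCs, and a machine-readable manifest embedding the seed and a config
hash, so reruns are reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ensemble import build_nested_models
from .evaluation import (CVScheme, anova_one_way, evaluate_model_series,
                         select_best_and_optimal)
from .relieff import relieff_rank, select_top_fraction
from .synthetic import (CLASS_NAMES, OUTCOME_COLUMN, attach_demographics,
                        cohort_spec, generate_feature_table, read_feature_table,
                        table1_spec)

log = logging.getLogger("tripgait")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``table_path`` selects feature-level input; when None the cohort is
    simulated from the configured spec.  ``cutoff_mode`` is "train"
    (honest: optimal cutoffs from the training split) or "test";
    ``tune_mode`` is "once" (default), "per_subset", "per_fold" or "none".
    """

    seed: int = 0
    out_dir: str = "tripgait_run"
    table_path: str | None = None
    spec_name: str = "cohort"          # "cohort" (40 features) or "table1" (20)
    separation_boost: float = 1.0
    with_demographics: bool = False
    select_fraction: float = 0.5
    k_neighbors: int = 10
    hp_budget: int = 30
    tune_mode: str = "once"
    cutoff_mode: str = "train"
    n_folds: int = 5
    n_repeats: int = 10

    def __post_init__(self) -> None:
        if self.tune_mode not in ("once", "per_subset", "per_fold", "none"):
            raise ValueError(f"unknown tune_mode {self.tune_mode!r}")
        if self.cutoff_mode not in ("train", "test"):
            raise ValueError(f"unknown cutoff_mode {self.cutoff_mode!r}")
        if self.spec_name not in ("cohort", "table1"):
            raise ValueError(f"unknown spec_name {self.spec_name!r}")
        if self.table_path is not None and self.with_demographics:
            raise ValueError(
                "with_demographics applies only to simulated tables; "
                "supply a table that already carries demographics instead"
            )

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class SchemaReport:
    """Outcome of feature-table validation; violations, not exceptions."""

    n_rows: int
    n_feature_columns: int
    violations: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_table(path) -> SchemaReport:
    """Check a feature-table CSV: label vocabulary, numeric completeness."""
    table = pd.read_csv(path)
    violations: list[dict] = []
    feature_cols = [c for c in table.columns if c != OUTCOME_COLUMN]
    if OUTCOME_COLUMN not in table.columns:
        violations.append({"kind": "missing_column", "column": OUTCOME_COLUMN})
    else:
        bad = ~table[OUTCOME_COLUMN].isin(CLASS_NAMES)
        for row in np.flatnonzero(bad.to_numpy()):
            violations.append({
                "kind": "unknown_label", "row": int(row),
                "value": str(table[OUTCOME_COLUMN].iloc[row]),
            })
    for col in feature_cols:
        numeric = pd.to_numeric(table[col], errors="coerce")
        for row in np.flatnonzero(numeric.isna().to_numpy()):
            violations.append({"kind": "missing_or_non_numeric",
                               "row": int(row), "column": col})
    return SchemaReport(n_rows=len(table), n_feature_columns=len(feature_cols),
                        violations=violations)


def _load_or_simulate(config: RunConfig) -> pd.DataFrame:
    if config.table_path is not None:
        log.info("loading feature table from %s", config.table_path)
        return read_feature_table(config.table_path)
    spec = cohort_spec() if config.spec_name == "cohort" else table1_spec()
    if config.separation_boost != 1.0:
        spec = spec.with_boost(config.separation_boost)
    table = generate_feature_table(spec, seed=config.seed)
    if config.with_demographics:
        table = attach_demographics(table, seed=config.seed + 1)
    return table


def _accuracy_frame(evals, series) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Accuracy tables at both cutoffs, one row per nested model size.

    The "new_feature" of the k-feature model is the feature retained at
    size k but eliminated before size k-1 (for k = 1, the sole
    survivor), mirroring the additive reading of the nested series.
    """
    sizes = sorted(series.subsets)
    new_feature = {1: series.subsets[1][0]}
    for k in sizes[1:]:
        (extra,) = set(series.subsets[k]) - set(series.subsets[k - 1])
        new_feature[k] = extra
    rows_d, rows_o = [], []
    for ev in sorted(evals, key=lambda e: e.n_features):
        base = {"feature_number": ev.n_features,
                "new_feature": new_feature[ev.n_features]}
        rows_d.append({**base, "overall": ev.default_overall,
                       **{c: ev.default_tpr[c] for c in ev.default_tpr}})
        rows_o.append({**base, "overall": ev.optimal_overall,
                       **{c: ev.optimal_tpr[c] for c in ev.optimal_tpr}})
    return pd.DataFrame(rows_d), pd.DataFrame(rows_o)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain; returns the run report (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = _load_or_simulate(config)
    n_pool = table.shape[1] - 1
    log.info("feature pool: %d features, %d rows", n_pool, len(table))

    ranking = relieff_rank(table, k_neighbors=config.k_neighbors)
    selected = select_top_fraction(ranking, config.select_fraction)
    log.info("selected top %d of %d features", len(selected), n_pool)
    ranking.to_frame().to_csv(out / "relieff_ranking.csv", index=False,
                              float_format="%.6f")

    series = build_nested_models(table, selected, hp_budget=config.hp_budget,
                                 seed=config.seed,
                                 tune="once" if config.tune_mode != "none" else False)
    series.elimination_frame().to_csv(out / "elimination_record.csv",
                                      index=False, float_format="%.6f")

    scheme = CVScheme(n_folds=config.n_folds, n_repeats=config.n_repeats,
                      seed=config.seed)
    evals = evaluate_model_series(series, table, scheme, seed=config.seed,
                                  hp_budget=config.hp_budget,
                                  tune_mode=config.tune_mode,
                                  cutoff_mode=config.cutoff_mode)

    acc_default, acc_optimal = _accuracy_frame(evals, series)
    acc_default.to_csv(out / "accuracy_default_cutoff.csv", index=False,
                       float_format="%.1f")
    acc_optimal.to_csv(out / "accuracy_optimal_cutoff.csv", index=False,
                       float_format="%.1f")

    auc_long = pd.DataFrame([
        {"feature_number": ev.n_features, "split": i, "auc": float(a)}
        for ev in evals for i, a in enumerate(ev.auc_samples)
    ])
    auc_long.to_csv(out / "auc_per_split.csv", index=False, float_format="%.6f")

    f_stat, p_val = anova_one_way([ev.auc_samples for ev in evals])
    best, optimal = select_best_and_optimal(evals)
    report = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "versions": {"tripgait": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "n_rows": int(len(table)),
        "n_feature_pool": int(n_pool),
        "n_selected": len(selected),
        "n_models": len(evals),
        "n_auc_samples_per_model": int(len(evals[0].auc_samples)),
        "anova": {"F": f_stat, "p": p_val},
        "best_model_features": int(best),
        "optimal_model_features": int(optimal),
        "mean_auc_by_size": {ev.n_features: round(ev.mean_auc, 6)
                             for ev in evals},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    log.info("best model: %d features; optimal model: %d features",
             best, optimal)
    return report
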