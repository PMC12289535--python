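"""Tabular I/O, run configuration, and the end-to-end pipeline.

CSV conventions: comma separator, required header row, UTF-8, ``.`` decimal.
Every pipeline run writes its seed, fold-plan digest and backend settings to
the run log so any reported number can be recomputed from logged inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from .backends import BackendConfig
from .core import ClassificationRule
from .dataset import Dataset
from .exceptions import InputError
from .model import ICOLikeness, ICOResults

__all__ = ["RunConfig", "read_table", "write_dataset", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs, loadable from YAML and CLI flags."""

    input_path: str = ""
    output_dir: str = "icolike_out"
    id_column: str = "sample_id"
    target_column: str = "y"
    feature_columns: list[str] | None = None  # None -> all remaining columns
    backend: str = "gpr"
    n_restarts: int = 10
    noise_bounds: tuple[float, float] = (1e-8, 1e2)
    outer_k: int | str = "loo"
    seed: int = 0
    top_k: int | str = "all"
    rule_method: str = "robust_z"
    rule_multiplier: float = 3.0
    rule_threshold: float = 0.0

    def __post_init__(self) -> None:
        if isinstance(self.outer_k, str) and self.outer_k != "loo":
            self.outer_k = int(self.outer_k)
        if isinstance(self.top_k, str) and self.top_k != "all":
            self.top_k = int(self.top_k)
        if self.feature_columns is not None:
            if self.target_column in self.feature_columns:
                raise InputError("target column listed among feature columns")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise InputError(f"config file {path} is not a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def backend_config(self) -> BackendConfig:
        return BackendConfig(backend=self.backend, n_restarts=self.n_restarts,
                             seed=self.seed,
                             noise_bounds=tuple(self.noise_bounds))

    def classification_rule(self) -> ClassificationRule:
        return ClassificationRule(method=self.rule_method,
                                  multiplier=self.rule_multiplier,
                                  threshold=self.rule_threshold)


def read_table(path, config: RunConfig | None = None) -> Dataset:
    """Read and validate a samples CSV into a :class:`Dataset`.

    Rejects missing columns (naming them), non-numeric or blank cells
    (with row and column coordinates) and duplicate sample ids.
    """
    config = config or RunConfig()
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    df = pd.read_csv(path)
    if config.id_column not in df.columns:
        raise InputError(f"missing id column {config.id_column!r} in {path.name}")
    if config.target_column not in df.columns:
        raise InputError(
            f"missing target column {config.target_column!r} in {path.name}"
        )
    features = config.feature_columns
    if features is None:
        # "is_injected" is the simulator's bookkeeping flag, not a feature
        features = [c for c in df.columns
                    if c not in (config.id_column, config.target_column,
                                 "is_injected")]
    else:
        missing = [c for c in features if c not in df.columns]
        if missing:
            raise InputError(f"missing feature columns: {missing}")
    if not features:
        raise InputError("no feature columns found")
    ids = [str(v) for v in df[config.id_column]]
    numeric = df[features + [config.target_column]].apply(
        pd.to_numeric, errors="coerce"
    )
    bad = numeric.isna()
    if bad.to_numpy().any():
        rows, cols = bad.to_numpy().nonzero()
        cells = [
            f"row {r + 2} (id {ids[r]!r}), column {numeric.columns[c]!r}"
            for r, c in zip(rows, cols)  # row numbers count the header line
        ]
        raise InputError("non-numeric or blank cells: " + "; ".join(cells[:10]))
    return Dataset(
        ids=tuple(ids),
        X=numeric[features].to_numpy(dtype=float),
        y=numeric[config.target_column].to_numpy(dtype=float),
        feature_names=tuple(features),
    )


def write_dataset(dataset: Dataset, path, *, id_column: str = "sample_id",
                  target_column: str = "y") -> None:
    dataset.to_frame(id_column=id_column, target_column=target_column).to_csv(
        path, index=False
    )


def _write_log(path: Path, lines: list[str]) -> None:
    stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
    with path.open("a") as fh:
        for line in lines:
            fh.write(f"{stamp} INFO {line}\n")


def run_pipeline(config: RunConfig) -> ICOResults:
    """simulate-or-load -> DCV -> rank -> ICO-likeness -> classify -> report.

    Writes to ``config.output_dir``: ``candidates.csv`` (the labelled
    report), ``metrics.json`` (DCV MAE/R²), ``plot_data.csv`` (error vs
    ICO-likeness pairs) and ``run.log``.  Any stage failure halts with the
    stage name; partial outputs are flagged in the log.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    stage = "read_input"
    try:
        dataset = read_table(config.input_path, config)
        _write_log(log_path, [
            f"input={config.input_path} n={dataset.n_samples} "
            f"p={dataset.n_features}",
            f"seed={config.seed} outer_k={config.outer_k} "
            f"top_k={config.top_k}",
            f"backend={config.backend} n_restarts={config.n_restarts} "
            f"noise_bounds={tuple(config.noise_bounds)}",
            f"rule={config.rule_method} multiplier={config.rule_multiplier} "
            f"threshold={config.rule_threshold}",
        ])
        stage = "diagnose"
        model = ICOLikeness.from_dataset(
            dataset,
            backend=config.backend_config(),
            outer_k=config.outer_k,
            seed=config.seed,
            top_k=config.top_k,
            rule=config.classification_rule(),
        )
        results = model.fit()
        stage = "write_report"
        _write_log(log_path, [f"fold_plan_digest={results.fold_plan.digest()}"])
        results.to_frame().to_csv(out / "candidates.csv", index=False)
        metrics = {
            "mae": results.metrics.mae,
            "r2": results.metrics.r2,
            "n_evaluated": results.metrics.n_evaluated,
            "seed": config.seed,
            "fold_plan_digest": results.fold_plan.digest(),
        }
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2) + "\n")
        results.plot_frame().to_csv(out / "plot_data.csv", index=False)
        _write_log(log_path, [
            f"dcv_mae={results.metrics.mae!r} dcv_r2={results.metrics.r2!r}",
            f"n_candidates={len(results.records)} "
            f"ico={list(results.ico_ids)}",
            "status=complete",
        ])
        return results
    except Exception as exc:
        _write_log(log_path, [f"status=INCOMPLETE stage={stage} error={exc}"])
        raise
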