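"""End-to-end orchestration of the per-cell-line workflow.

One call runs: label assignment -> redundancy reduction -> length filter ->
stratified split -> featurization -> (optional) mRMR selection -> five-fold
CV -> hold-out evaluation -> best-model selection -> feature-CNRCI
correlation report.  Every output directory carries the serialized config,
its hash and the seed, and per-stage record counts are logged so dataset
attrition is auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import __version__
from .dataset import (
    CYTOPLASM,
    DEFAULT_IDENTITY_THRESHOLD,
    DEFAULT_MAX_LENGTH,
    DEFAULT_TEST_FRACTION,
    TRAIN,
    VALIDATION,
    assign_labels,
    build_cell_line_dataset,
    read_cnrci_table,
)
from .featurize import feature_matrix
from .models import ClassifierSpec, MetricSet, five_fold_cv, save_model, select_best, train_evaluate
from .selection import feature_label_correlation, mrmr_rank
from .seqio import read_fasta

logger = logging.getLogger("lncsubloc.pipeline")

DEFAULT_CLASSIFIERS = ["random_forest", "xgboost", "logistic_regression", "gaussian_nb"]


@dataclass
class PipelineConfig:
    """Settings for one pipeline run; defaults match the method's standard
    thresholds (length cap 10,000 nt, 90% identity, 80/20 split, 5 folds)."""

    fasta: Optional[str] = None
    cnrci_table: Optional[str] = None
    out_dir: str = "pipeline_out"
    cell_lines: Optional[List[str]] = None
    feature_families: str | List[str] = "correlation"
    mrmr_k: Optional[int] = None
    classifiers: List[str] = field(default_factory=lambda: list(DEFAULT_CLASSIFIERS))
    max_length: int = DEFAULT_MAX_LENGTH
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
    test_fraction: float = DEFAULT_TEST_FRACTION
    cv_folds: int = 5
    run_cv: bool = True
    seed: int = 42

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _metrics_row(metrics: MetricSet) -> dict:
    return {k: (v if v is not None else float("nan")) for k, v in metrics.as_dict().items()}


def run_pipeline(config: PipelineConfig) -> Dict[str, dict]:
    """Run the full workflow; returns a per-cell-line report dict.

    Writes, per cell line: the dataset manifest, the feature matrix, the
    mRMR ranking (when requested), a metrics table (one row per classifier,
    CV and validation), the best model file and the feature-CNRCI
    correlation profile.
    """
    if not config.fasta or not config.cnrci_table:
        raise ValueError("config.fasta and config.cnrci_table are required")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config": asdict(config), "config_hash": config.config_hash(), "version": __version__}
    (out / "run_config.json").write_text(json.dumps(meta, indent=2, default=str))

    seqs = read_fasta(config.fasta)
    table = read_cnrci_table(config.cnrci_table)
    cell_lines = config.cell_lines or sorted(table["cell_line"].unique())
    report: Dict[str, dict] = {}
    for cl in cell_lines:
        report[cl] = _run_cell_line(config, seqs, table, cl, out / cl)
    summary = pd.DataFrame(
        [
            {"cell_line": cl, "best_model": rep["best_model"], **rep["best_metrics"]}
            for cl, rep in report.items()
        ]
    )
    summary.to_csv(out / "best_models.tsv", sep="\t", index=False)
    return report


def _run_cell_line(
    config: PipelineConfig,
    seqs,
    table: pd.DataFrame,
    cell_line: str,
    out: Path,
) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    sub = table[table["cell_line"] == cell_line]
    records, dropped = assign_labels(
        list(zip(sub["gene_id"], sub["cnrci"])), cell_line=cell_line
    )
    logger.info(
        "%s: %d rows, %d labeled, %d dropped (zero/undefined CNRCI)",
        cell_line, len(sub), len(records), dropped,
    )
    ds = build_cell_line_dataset(
        seqs,
        records,
        cell_line,
        max_length=config.max_length,
        identity_threshold=config.identity_threshold,
        test_fraction=config.test_fraction,
        seed=config.seed,
    )
    manifest = ds.to_manifest()
    cnrci_of = {r.gene_id: r.cnrci for r in records}
    manifest["cnrci"] = manifest["id"].map(cnrci_of)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    logger.info(
        "%s: %d after redundancy+length, train %d / validation %d",
        cell_line,
        len(ds.entries),
        sum(1 for v in ds.split.values() if v == TRAIN),
        sum(1 for v in ds.split.values() if v == VALIDATION),
    )

    X = feature_matrix([s for s, _ in ds.entries], config.feature_families)
    X.to_csv(out / "features.tsv", sep="\t")
    labels = {s.id: lab for s, lab in ds.entries}
    y = (pd.Series(labels).loc[X.index] == CYTOPLASM).astype(int)
    train_ids = [i for i in X.index if ds.split[i] == TRAIN]
    val_ids = [i for i in X.index if ds.split[i] == VALIDATION]

    cols = list(X.columns)
    if config.mrmr_k:
        ranked = mrmr_rank(X.loc[train_ids], y.loc[train_ids], config.mrmr_k)
        ranked.to_frame().to_csv(out / "mrmr_ranking.tsv", sep="\t", index=False)
        cols = ranked.names

    rows = []
    candidates: List[Tuple[ClassifierSpec, MetricSet]] = []
    models = {}
    for name in config.classifiers:
        spec = ClassifierSpec(name)
        if config.run_cv:
            cv = five_fold_cv(
                X.loc[train_ids, cols], y.loc[train_ids], spec,
                seed=config.seed, n_folds=config.cv_folds,
            )
            rows.append({"classifier": name, "stage": "cv_mean", **_metrics_row(cv.mean)})
        model, val_metrics = train_evaluate(
            X.loc[train_ids, cols], y.loc[train_ids],
            X.loc[val_ids, cols], y.loc[val_ids],
            spec, seed=config.seed,
        )
        rows.append({"classifier": name, "stage": "validation", **_metrics_row(val_metrics)})
        candidates.append((spec, val_metrics))
        models[name] = model
    pd.DataFrame(rows).to_csv(out / "metrics.tsv", sep="\t", index=False)

    best_spec, best_metrics = select_best(candidates)
    best_model = models[best_spec.name]
    best_model.feature_families = (
        [config.feature_families]
        if isinstance(config.feature_families, str)
        else list(config.feature_families)
    )
    save_model(best_model, out / "best_model.joblib")

    r, _ = feature_label_correlation(X, manifest.set_index("id").loc[X.index, "cnrci"])
    r.sort_values(ascending=False).to_csv(out / "feature_cnrci_correlation.tsv", sep="\t")

    return {
        "n_labeled": len(records),
        "n_dropped": dropped,
        "n_final": len(ds.entries),
        "n_train": len(train_ids),
        "n_validation": len(val_ids),
        "best_model": best_spec.name,
        "best_metrics": _metrics_row(best_metrics),
    }
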