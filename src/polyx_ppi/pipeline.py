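"""End-to-end orchestration: detect -> build -> train -> predict.

A single :class:`RunConfig` (loadable from YAML) drives the whole run; one
seed governs every source of randomness, every intermediate table is
written to the output directory, and a manifest records the configuration
hash, stage file checksums and final metrics so identical configurations
reproduce byte-identical outputs.

Defaults follow the final per-repeat-type model choices: a symmetric
context of +/-6 positions without coiled-coil features for polyQ, and
+/-10 positions with coiled-coil features for polyA; paralogy imputation is
off by default (it adds little and complicates the positive set).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

from . import __version__
from . import io_formats
from .dataset import (
    build_context_rows,
    encode,
    impute_paralog_positives,
    restrict_window,
)
from .detection import DetectorConfig, detect_all
from .io_formats import RegionKind, load_config
from .models import (
    ModelSpec,
    cross_validate,
    evaluate_both_orientations,
    optimize_context_window,
    stratified_split,
    train_final,
    variable_importance,
)
from .scoring import predict_all, score_report, write_report

logger = logging.getLogger(__name__)

_DEFAULT_WINDOW = {"Q": 6, "A": 10}
_DEFAULT_USE_CC = {"Q": False, "A": True}


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    fasta: str
    interfaces: str
    out_dir: str
    repeat_type: str = "Q"
    coiled_coils: str | None = None
    paralogs: str | None = None
    min_count: int = 4
    window: int = 6
    n_context: int | None = None  # symmetric half-width; default per repeat type
    use_cc: bool | None = None  # default: False for Q, True for A
    use_paralogs: bool = False
    algorithms: list[str] = field(default_factory=lambda: ["random_forest"])
    grids: dict | None = None
    folds: int = 10
    repeats: int = 3
    train_frac: float = 0.7
    score_threshold: float = 0.7
    optimize_window: bool = False
    window_candidates: list[int] = field(default_factory=lambda: list(range(2, 11)))
    seed: int = 0

    def __post_init__(self) -> None:
        self.repeat_type = self.repeat_type.upper()
        if self.repeat_type not in _DEFAULT_WINDOW:
            raise ValueError("repeat_type must be Q or A")
        if self.n_context is None:
            self.n_context = _DEFAULT_WINDOW[self.repeat_type]
        if self.use_cc is None:
            self.use_cc = _DEFAULT_USE_CC[self.repeat_type]
        if self.use_cc and self.coiled_coils is None:
            raise ValueError("use_cc requires a coiled_coils annotation file")
        if self.use_paralogs and self.paralogs is None:
            raise ValueError("use_paralogs requires a paralogs file")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**load_config(path))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run manifest (also written to
    ``out_dir/manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- stage 1: inputs and detection -----------------------------------
    logger.info("stage detect: reading %s", config.fasta)
    records = io_formats.read_fasta(config.fasta)
    records_by_id = {r.protein_id: r for r in records}
    detector = DetectorConfig(
        config.repeat_type, min_count=config.min_count, window=config.window
    )
    regions = detect_all(records, detector)
    if not regions:
        raise RuntimeError("stage detect: no homorepeats found")
    _write_region_tsv(regions, out / "repeats.tsv")
    logger.info("stage detect: %d repeats", len(regions))

    # -- stage 2: build the labeled feature table ------------------------
    interfaces = io_formats.read_regions(config.interfaces, RegionKind.INTERACTION)
    cc_regions = (
        io_formats.read_regions(config.coiled_coils, RegionKind.COILED_COIL)
        if config.coiled_coils
        else None
    )
    rows = build_context_rows(
        records_by_id,
        regions,
        interfaces,
        n_before=config.n_context,
        n_after=config.n_context,
        cc_regions=cc_regions if config.use_cc else None,
    )
    n_imputed = 0
    if config.use_paralogs:
        pairs = io_formats.read_paralog_pairs(config.paralogs)
        n_imputed = impute_paralog_positives(rows, pairs, records_by_id)
        logger.info("stage build: %d paralog-imputed positives", n_imputed)
    io_formats.write_feature_table(rows, out / "table.tsv")
    n_pos = sum(r.is_positive for r in rows)
    logger.info("stage build: %d rows, %d positives", len(rows), n_pos)
    if n_pos < 2 or n_pos > len(rows) - 2:
        raise RuntimeError("stage build: need at least 2 rows of each class")

    # -- stage 3: train and select ---------------------------------------
    matrix = encode(rows)
    plan = stratified_split(
        matrix.y, config.train_frac, config.seed, config.folds, config.repeats
    )
    window_search = None
    if config.optimize_window:
        spec = _spec_for(config, "random_forest")
        mats = {}
        for n in config.window_candidates:
            rows_n = restrict_window(
                rows, records_by_id, n, cc_regions if config.use_cc else None
            )
            m = encode(rows_n)
            mats[n] = (m.X[plan.train_idx], m.y[plan.train_idx])
        window_search = optimize_context_window(
            mats, spec, folds=config.folds, repeats=config.repeats
        )
        logger.info("window search: best N=%d", window_search.best_n)
        if window_search.best_n != config.n_context:
            rows = restrict_window(
                rows,
                records_by_id,
                window_search.best_n,
                cc_regions if config.use_cc else None,
            )
            matrix = encode(rows)
            io_formats.write_feature_table(rows, out / "table.tsv")

    best = None
    metrics_rows = []
    for algorithm in config.algorithms:
        spec = _spec_for(config, algorithm)
        cv = cross_validate(
            spec,
            matrix.X[plan.train_idx],
            matrix.y[plan.train_idx],
            folds=config.folds,
            repeats=config.repeats,
        )
        clf = train_final(
            spec,
            matrix.X[plan.train_idx],
            matrix.y[plan.train_idx],
            cv.best_params,
            feature_names=matrix.feature_names,
        )
        test_metrics = evaluate_both_orientations(
            clf, matrix.X[plan.test_idx], matrix.y[plan.test_idx]
        )
        for params, m in cv.per_params:
            metrics_rows.append((algorithm, "cv", json.dumps(params), m))
        for ref, m in test_metrics.items():
            metrics_rows.append(
                (algorithm, f"test[{ref}]", json.dumps(cv.best_params), m)
            )
        cv_auc = cv.best_metrics.auc
        if best is None or cv_auc > best[1]:
            best = (algorithm, cv_auc, clf, cv, test_metrics)
    algorithm, _, classifier, cv, test_metrics = best
    logger.info(
        "stage train: selected %s %s (CV AUC %.4f)",
        algorithm,
        cv.best_params,
        cv.best_metrics.auc,
    )
    _write_metrics_tsv(metrics_rows, out / "metrics.tsv")
    classifier.save(out / "model")
    if algorithm == "random_forest":
        _write_importance_tsv(variable_importance(classifier), out / "importance.tsv")

    # -- stage 4: proteome-wide prediction -------------------------------
    predictions = predict_all(classifier, rows)
    io_formats.write_predictions(predictions, out / "predictions.tsv")
    report = score_report(predictions, threshold=config.score_threshold)
    write_report(report, out / "report.tsv")

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "n_proteins": len(records),
        "n_repeats": len(regions),
        "n_positive": int(n_pos),
        "n_paralog_imputed": int(n_imputed),
        "selected_algorithm": algorithm,
        "chosen_params": cv.best_params,
        "cv_auc": cv.best_metrics.auc,
        "test_metrics": {
            ref: m.as_dict() for ref, m in test_metrics.items()
        },
        "window_search": (
            {
                "best_n": window_search.best_n,
                "auc_by_n": window_search.auc_by_n,
            }
            if window_search
            else None
        ),
        "counts_above_threshold": report.counts_above_threshold,
        "stage_checksums": {
            name: _sha256(out / name)
            for name in (
                "repeats.tsv",
                "table.tsv",
                "metrics.tsv",
                "predictions.tsv",
                "report.tsv",
            )
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _spec_for(config: RunConfig, algorithm: str) -> ModelSpec:
    grid = (config.grids or {}).get(algorithm)
    return ModelSpec(algorithm, grid, seed=config.seed)


def _write_region_tsv(regions: Sequence, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\ttarget_aa\tstart\tend\tlength\tpurity\n")
        for r in sorted(regions, key=lambda r: (r.protein_id, r.start)):
            fh.write(
                f"{r.protein_id}\t{r.target_aa}\t{r.start}\t{r.end}\t"
                f"{r.length}\t{r.purity}\n"
            )


def _write_metrics_tsv(rows: Sequence, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "algorithm\tphase\tparams\tprecision\trecall\tf1\tauc\taccuracy\t"
            "reference_level\n"
        )
        for algorithm, phase, params, m in rows:
            fh.write(
                f"{algorithm}\t{phase}\t{params}\t{m.precision:.6f}\t"
                f"{m.recall:.6f}\t{m.f1:.6f}\t{m.auc:.6f}\t{m.accuracy:.6f}\t"
                f"{m.reference_level}\n"
            )


def _write_importance_tsv(importances: Sequence, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("feature\timportance\n")
        for name, value in importances:
            fh.write(f"{name}\t{value:.4f}\n")
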