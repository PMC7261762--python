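"""End-to-end pipeline: phantom cohort -> features -> grouped split ->
four classifier variants -> evaluation reports.

Everything is reproducible from (config, seed): each run writes its resolved
configuration next to the outputs, and the manifest carries content hashes.
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
import yaml

from . import nnet, phantom
from .contrasts import CLASSES
from .errors import ValidationError
from .evaluation import EvaluationReport, evaluate_predictions

log = logging.getLogger("dbsidnn")

VARIANTS = ("DBSI", "DTI", "MTR", "cMRI")


@dataclass
class PipelineConfig:
    """Resolved settings of one simulate/run invocation.

    ``size_scale`` shrinks lesion sizes (hence total voxels) for desk-scale
    runs; ``dbsi_source`` chooses whether the DBSI feature block comes from
    the generator's ground truth ("truth") or from the voxel-wise spectral
    fit on the noisy signals ("fit").
    """

    seed: int = 0
    snr: float = 30.0
    size_scale: float = 1.0
    composition: dict = field(default_factory=phantom.default_composition)
    n_directions: int = 99
    b_max: float = 1500.0
    n_b0: int = 1
    n_shells: int = 5
    dbsi_source: str = "truth"
    variants: tuple = VARIANTS
    n_hidden_layers: int = 10
    nodes_per_layer: int = 100
    max_epochs: int = 150
    learning_rate: float = 1.0e-3
    stop_at_val_accuracy: float | None = None
    n_bootstrap: int | None = None
    output_dir: str | None = None

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        mapping = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(mapping, dict):
            raise ValidationError(f"config file {path} must hold a mapping")
        return cls.from_mapping(mapping)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["variants"] = list(self.variants)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(directory, config: PipelineConfig):
    """Record the resolved config and the content hash of every artifact."""
    directory = Path(directory)
    (directory / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    files = sorted(
        p for p in directory.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "seed": config.seed,
        "files": {str(p.relative_to(directory)): _sha256(p) for p in files},
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def simulate_cohort(config: PipelineConfig) -> phantom.SyntheticCohort:
    """Generate the phantom cohort described by the config."""
    from .acquisition import make_default_scheme

    scheme = make_default_scheme(config.n_directions, config.b_max, config.n_b0, config.n_shells)
    log.info(
        "simulating cohort: %d lesion(s), snr=%s, seed=%d, size_scale=%.3g",
        sum(config.composition.values()), config.snr, config.seed, config.size_scale,
    )
    return phantom.generate_cohort(
        composition=config.composition,
        scheme=scheme,
        snr=config.snr,
        seed=config.seed,
        size_scale=config.size_scale,
    )


def run_pipeline(config: PipelineConfig, cohort: phantom.SyntheticCohort | None = None):
    """Train and evaluate all configured variants on one cohort.

    Returns ``(reports, summary)`` where ``reports`` maps variant name to its
    EvaluationReport and ``summary`` is a comparison table with the exact
    binomial CI band of the best model's error rate.
    """
    if cohort is None:
        cohort = simulate_cohort(config)
    log.info("building feature table (dbsi_source=%s)", config.dbsi_source)
    table = cohort.feature_table(dbsi_source=config.dbsi_source)
    labels = table["lesion_class"].to_numpy()
    parts = nnet.grouped_split(table["lesion_id"].to_numpy(), labels, seed=config.seed)
    log.info(
        "split: %d train / %d val / %d test voxels",
        len(parts.train_idx), len(parts.val_idx), len(parts.test_idx),
    )

    reports: dict[str, EvaluationReport] = {}
    for variant in config.variants:
        features = nnet.build_features(table, variant)
        dnn_config = nnet.DnnConfig(
            n_hidden_layers=config.n_hidden_layers,
            nodes_per_layer=config.nodes_per_layer,
            max_epochs=config.max_epochs,
            learning_rate=config.learning_rate,
            stop_at_val_accuracy=config.stop_at_val_accuracy,
            seed=config.seed,
            feature_variant=variant,
        )
        log.info("training %s variant (%d features)", variant, features.shape[1])
        model = nnet.train(dnn_config, parts, features, labels)
        probs = nnet.predict_proba(model, features[parts.test_idx])
        reports[variant] = evaluate_predictions(
            labels[parts.test_idx], probs,
            n_bootstrap=config.n_bootstrap, seed=config.seed,
        )
        log.info("%s test error rate: %.1f%%", variant, 100 * reports[variant].error_rate)

    best = min(reports, key=lambda v: reports[v].error_rate)
    summary = {
        "n_test": reports[best].n_test,
        "error_rates": {v: reports[v].error_rate for v in reports},
        "accuracies": {v: reports[v].accuracy for v in reports},
        "best_variant": best,
        "best_error_ci": list(reports[best].error_ci),
    }

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        for variant, report in reports.items():
            (outdir / f"report_{variant}.json").write_text(report.to_json())
            (outdir / f"report_{variant}.txt").write_text(report.to_text())
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
        write_manifest(outdir, config)
    return reports, summary


def export_metric_maps(metrics_rows: pd.DataFrame, directory, affine=None, shape=None):
    """Write fitted voxel metrics as a tidy CSV and, when voxel indices and a
    grid shape are available, one NIfTI map per metric."""
    from .acquisition import save_map

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    metrics_rows.to_csv(directory / "voxel_metrics.csv", index=False)
    if shape is None or not {"x", "y", "z"} <= set(metrics_rows.columns):
        return
    for col in metrics_rows.columns:
        if col in ("x", "y", "z", "quality"):
            continue
        vol = np.zeros(shape)
        vol[metrics_rows["x"], metrics_rows["y"], metrics_rows["z"]] = metrics_rows[col]
        save_map(vol, directory / f"{col}.nii.gz", affine)
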