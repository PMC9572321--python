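"""End-to-end pipeline: generate/load -> segment -> extract -> select -> train -> evaluate.

Every stage writes plain-text artifacts (CSV/JSON/PNG) when an output
directory is given, plus a manifest with a SHA-256 hash per file so reruns
can be compared byte-for-byte.  One seed drives every stochastic stage.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .discriminant import SplitConfig, fit_discriminant, split_indices
from .evaluate import EvaluationReport, evaluate_classifier
from .features import GlcmConfig, extract_table
from .neuralnet import StructureScanReport, TrainConfig, scan_structures
from .preprocess import MaskedImage, PreprocessConfig, preprocess_pipeline
from .selection import OPTIMUM_FEATURES, SelectionTrace, sfs_quadratic
from .synth import LabeledImageSet, SceneConfig, default_profiles, generate_dataset

log = logging.getLogger("ripegrade")


@dataclass
class PipelineConfig:
    """Configuration of one full run (synthetic generation by default)."""

    per_class: int = 40
    scene: SceneConfig | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    glcm: GlcmConfig = field(default_factory=GlcmConfig)
    # "optimum" = the fixed 16-feature registry list (skips selection);
    # None = run sequential selection; or an explicit list of names.
    feature_subset: str | list[str] | None = "optimum"
    selection_max_features: int | None = 16
    cv_folds: int = 5
    hidden_range: tuple[int, int] = (2, 20)
    train: TrainConfig | None = None
    seed: int = 0
    outdir: str | None = None
    save_images: bool = False


@dataclass
class PipelineResult:
    features: pd.DataFrame
    subset: list[str]
    trace: SelectionTrace | None
    models: dict
    reports: dict[str, EvaluationReport]
    scan: StructureScanReport
    manifest: dict


def write_png(path: Path, img: np.ndarray) -> None:
    """Write a [0,1] float image (RGB or boolean mask) as 8-bit PNG."""
    arr = np.asarray(img)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    else:
        arr = np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def read_image(path) -> np.ndarray:
    """Read a PNG/JPEG into an (H, W, 3) float array in [0, 1]."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=float) / 255.0


def save_image_set(imgset: LabeledImageSet, outdir: Path) -> None:
    """Write images as PNG plus a ``labels.csv`` and a JSON manifest."""
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for img, iid, lab in zip(imgset.images, imgset.image_ids, imgset.labels):
        fname = f"{iid}.png"
        write_png(outdir / fname, img)
        rows.append({"filename": fname, "class": lab})
    pd.DataFrame(rows).to_csv(outdir / "labels.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(
        {"n_images": len(imgset), "files": [r["filename"] for r in rows]},
        indent=2))


def preprocess_dataset(imgset: LabeledImageSet,
                       cfg: PreprocessConfig) -> list[MaskedImage]:
    masked = []
    for iid, img in zip(imgset.image_ids, imgset.images):
        try:
            m, _ = preprocess_pipeline(img, cfg)
        except Exception as exc:
            raise RuntimeError(f"preprocess failed for image {iid!r}: {exc}") from exc
        masked.append(m)
    return masked


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full grading pipeline on a synthetic dataset."""
    t0 = time.time()
    scene = cfg.scene or SceneConfig(seed=cfg.seed)
    train_cfg = cfg.train or TrainConfig(seed=cfg.seed)
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    log.info("generating %d images per class (seed=%d)", cfg.per_class, scene.seed)
    imgset = generate_dataset(default_profiles(), per_class=cfg.per_class,
                              scene=scene)
    if outdir and cfg.save_images:
        save_image_set(imgset, outdir / "images")

    log.info("segmenting %d images", len(imgset))
    masked = preprocess_dataset(imgset, cfg.preprocess)

    log.info("extracting features")
    table = extract_table(masked, imgset.labels, imgset.image_ids, cfg.glcm)

    trace = None
    if cfg.feature_subset is None:
        log.info("running sequential feature selection")
        trace = sfs_quadratic(table, max_features=cfg.selection_max_features,
                              cv_folds=cfg.cv_folds, seed=cfg.seed)
        subset = list(trace.selected)
    elif cfg.feature_subset == "optimum":
        subset = list(OPTIMUM_FEATURES)
    else:
        subset = list(cfg.feature_subset)

    log.info("training LDA/QDA (80:20) on %d features", len(subset))
    split2 = SplitConfig(ratios=(0.8, 0.2), seed=cfg.seed)
    tr2, te2 = split_indices(table["class"].to_numpy(), split2)
    models: dict = {}
    reports: dict[str, EvaluationReport] = {}
    for kind in ("lda", "qda"):
        model = fit_discriminant(table.iloc[tr2], subset, kind=kind)
        models[kind] = model
        reports[kind] = evaluate_classifier(model, table, subset, scope="all_data")
        reports[f"{kind}_test"] = evaluate_classifier(
            model, table, subset, scope="test_only", eval_index=te2)

    log.info("scanning ANN structures %s", cfg.hidden_range)
    split3 = SplitConfig(ratios=(0.6, 0.2, 0.2), seed=cfg.seed)
    scan = scan_structures(
        table, subset,
        hidden_range=range(cfg.hidden_range[0], cfg.hidden_range[1] + 1),
        split=split3, cfg=train_cfg)
    ann = scan.best_model
    models["ann"] = ann
    reports["ann"] = evaluate_classifier(ann, table, subset, scope="all_data")
    _, _, te3 = split_indices(table["class"].to_numpy(), split3)
    reports["ann_test"] = evaluate_classifier(
        ann, table, subset, scope="test_only", eval_index=te3)

    manifest: dict = {"seed": cfg.seed, "n_images": len(imgset),
                      "subset": subset, "elapsed_s": None, "files": {}}
    if outdir:
        table.to_csv(outdir / "features.csv", index=False)
        if trace is not None:
            (outdir / "selection.json").write_text(trace.to_json())
        scan.table.to_csv(outdir / "scan.csv", index=False)
        (outdir / "reports.json").write_text(json.dumps(
            {k: r.to_dict() for k, r in reports.items()}, indent=2))
        for kind in ("lda", "qda"):
            (outdir / f"model_{kind}.json").write_text(
                json.dumps(models[kind].to_dict()))
        (outdir / "model_ann.json").write_text(json.dumps(ann.to_dict()))
        (outdir / "config.yaml").write_text(yaml.safe_dump({
            "per_class": cfg.per_class, "seed": cfg.seed,
            "feature_subset": subset,
            "hidden_range": list(cfg.hidden_range),
            "scene": dataclasses.asdict(scene),
        }, default_flow_style=False))
        for p in sorted(outdir.glob("*")):
            if p.is_file():
                manifest["files"][p.name] = _sha256(p)
    manifest["elapsed_s"] = round(time.time() - t0, 2)
    if outdir:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("pipeline done in %.1fs", manifest["elapsed_s"])
    return PipelineResult(features=table, subset=subset, trace=trace,
                          models=models, reports=reports, scan=scan,
                          manifest=manifest)
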