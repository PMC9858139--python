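"""End-to-end orchestration: phantom generation / loading -> skull-strip ->
cross-validated classification (with fold-local augmentation) -> FL-MSCM
segmentation of abnormal slices -> evaluation, with a JSON run manifest.

Every stage is a pure function of (inputs, config, seed); the manifest
records the configs and seeds needed to re-run any stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import __version__
from .augment import AugmentConfig
from .cnn import CrossValResult, TrainConfig, build_architecture, train_and_evaluate
from .core_io import ABNORMAL, LabeledDataset, rescale_range, save_mask
from .flmscm import MSCMParams, run_fl_mscm
from .metrics import MetricsReport, segmentation_metrics, summarize_folds
from .phantoms import PhantomConfig, make_dataset
from .skullstrip import SkullStripConfig, skull_strip

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    n_normal: int = 60
    n_abnormal: int = 125
    seed: int = 0
    out_dir: str | None = None
    run_skullstrip: bool = True
    run_classification: bool = True
    run_segmentation: bool = True
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    skullstrip: SkullStripConfig = field(default_factory=SkullStripConfig)
    augment: AugmentConfig | None = None
    train: TrainConfig = field(default_factory=TrainConfig)
    log_level: str = "INFO"


@dataclass
class PipelineResult:
    classification: CrossValResult | None
    segmentation_reports: list[MetricsReport]
    segmentation_summary: dict
    manifest: dict


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return f"<array shape={obj.shape}>"
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(cfg: PipelineConfig,
                 dataset: LabeledDataset | None = None) -> PipelineResult:
    """Execute the enabled stages in order and return results + manifest.

    Segmentation runs only on samples the classifier flags abnormal (those
    with ground-truth masks are evaluated).  When ``dataset`` is None a
    phantom cohort of the configured size is generated.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    manifest: dict = {"version": __version__, "seed": cfg.seed,
                      "config": _jsonable(cfg), "stages": []}
    if dataset is None:
        ds = make_dataset(cfg.n_normal, cfg.n_abnormal,
                          replace(cfg.phantom, seed=cfg.seed))
        manifest["stages"].append({"stage": "phantom", "n": len(ds)})
    else:
        ds = dataset
    logger.info("pipeline dataset n=%d", len(ds))

    stripped = ds
    if cfg.run_skullstrip:
        images, reports = [], []
        for img in ds.images:
            res = skull_strip(img, cfg.skullstrip)
            images.append(res.stripped)
            reports.append(res.report)
        stripped = LabeledDataset(images=images, labels=ds.labels,
                                  masks=ds.masks, groups=ds.groups)
        manifest["stages"].append({
            "stage": "skullstrip", "n": len(images),
            "mean_Topt": float(np.mean([r.Topt for r in reports]))})

    classification: CrossValResult | None = None
    predicted_abnormal = [lab == ABNORMAL for lab in ds.labels]
    if cfg.run_classification:
        tcfg = replace(cfg.train, seed=cfg.seed, augment=cfg.augment)
        classification = train_and_evaluate(
            stripped, build_architecture(input_size=tcfg.input_size), tcfg)
        manifest["stages"].append({
            "stage": "classification",
            "summary": _jsonable(classification.summary),
            "folds": [_jsonable(r) for r in classification.fold_reports]})
        # out-of-fold predictions decide which slices get segmented; each
        # sample was a held-out test point for exactly one fold's model
        predicted_abnormal = (classification.oof_pred == 1).tolist()

    seg_reports: list[MetricsReport] = []
    seg_summary: dict = {}
    if cfg.run_segmentation:
        for i, (img, truth) in enumerate(zip(stripped.images, stripped.masks)):
            if not predicted_abnormal[i] or truth is None:
                continue
            S = rescale_range(img, (0.0, 1.0))
            res = run_fl_mscm(S, MSCMParams())
            seg_reports.append(segmentation_metrics(res.tumor_mask, truth))
            if cfg.out_dir:
                save_mask(res.tumor_mask,
                          os.path.join(cfg.out_dir, f"tumor_{i:04d}.png"))
        if seg_reports:
            seg_summary = summarize_folds(seg_reports)
        manifest["stages"].append({
            "stage": "segmentation", "n": len(seg_reports),
            "summary": _jsonable(seg_summary)})

    if cfg.out_dir:
        os.makedirs(cfg.out_dir, exist_ok=True)
        with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
    return PipelineResult(classification=classification,
                          segmentation_reports=seg_reports,
                          segmentation_summary=seg_summary,
                          manifest=manifest)
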