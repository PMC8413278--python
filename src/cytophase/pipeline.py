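"""End-to-end orchestration: captures → crops → SAD filter → train → evaluate.

The training flow mirrors the experimental protocol: segment every capture
into candidate crops, purify the condition labels with the SAD filter,
balance classes down to the smallest, split 80/20 stratified, train the
three-class network, and report validation metrics. Holdout evaluation
runs the same crop/filter/predict path on captures from experiments never
seen in training (enforced by capture-id disjointness), with labels used
only after prediction.

Every stage logs its input/output counts; discards plus kept always equal
the stage input.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classifier import (
    CLASS_ORDER,
    ClassifierModel,
    LabeledDataset,
    TrainConfig,
    balance_classes,
    build_model,
    predict,
    save_model,
    split_train_val,
    train_classifier,
)
from .evaluation import EvalReport, build_report
from .phase_optics import Condition, OpticalParams, PhaseCapture, read_capture
from .sad_filter import SADModel, apply_sad, get_extractor, save_sad, train_sad, verdicts_to_csv
from .segmentation import SegmentationParams, crop_cells, detect_cells
from .synthetic_data import MorphologyParams, SceneSpec, generate_capture, generate_labeled_dataset

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticConfig:
    """Synthetic-acquisition settings used when no capture directory is given."""

    n_captures_per_condition: int = 6
    cells_per_capture: int = 16
    impurity: float = 0.15  # fraction of still-alive cells in induced captures
    image_shape: tuple[int, int] = (440, 440)
    noise_sd_rad: float = 0.02


@dataclass(frozen=True)
class SADConfig:
    enabled: bool = True
    threshold: float = 0.01
    extractor: str = "phase-stats"
    n_alive: int = 200
    n_apoptotic: int = 100
    n_necroptotic: int = 100


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of a pipeline run, serializable to/from YAML."""

    seed: int = 0
    captures_dir: str | None = None
    out_dir: str | None = None
    optics: OpticalParams = field(default_factory=OpticalParams)
    # A fixed phase threshold (well above the background noise floor) is the
    # pipeline default: on captures mixing tall apoptotic and flat necroptotic
    # cells a global Otsu threshold drifts upward and underestimates the
    # footprint of the flat cells. Otsu remains available via the config.
    segmentation: SegmentationParams = field(
        default_factory=lambda: SegmentationParams(threshold_method="fixed", fixed_threshold=0.15)
    )
    sad: SADConfig = field(default_factory=SADConfig)
    backbone: str = "small_cnn"
    train: TrainConfig = field(default_factory=TrainConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"]["image_shape"] = list(self.synthetic.image_shape)
        return d

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "optics" in d:
            d["optics"] = OpticalParams(**d["optics"])
        if "segmentation" in d:
            seg = dict(d["segmentation"])
            d["segmentation"] = SegmentationParams(**seg)
        if "sad" in d:
            d["sad"] = SADConfig(**d["sad"])
        if "train" in d:
            d["train"] = TrainConfig(**d["train"])
        if "synthetic" in d:
            syn = dict(d["synthetic"])
            if "image_shape" in syn:
                syn["image_shape"] = tuple(syn["image_shape"])
            d["synthetic"] = SyntheticConfig(**syn)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    sad_model: SADModel | None
    classifier: ClassifierModel
    history: list[dict]
    report: EvalReport
    stage_counts: dict[str, int]
    train_capture_ids: set[str]


def _condition_mix(condition: Condition, impurity: float) -> dict[str, float]:
    if condition is Condition.ALIVE:
        return {"alive": 1.0}
    return {condition.value: 1.0 - impurity, "alive": impurity}


def generate_condition_captures(config: PipelineConfig, seed_offset: int = 0) -> list[PhaseCapture]:
    """Synthetic stand-in for the microscope: captures for all three conditions."""
    syn = config.synthetic
    captures = []
    for ci, condition in enumerate(Condition):
        for k in range(syn.n_captures_per_condition):
            spec = SceneSpec(
                image_shape=syn.image_shape,
                n_cells=syn.cells_per_capture,
                class_mix=_condition_mix(condition, syn.impurity),
                noise_sd_rad=syn.noise_sd_rad,
                seed=config.seed + seed_offset + 1000 * ci + k,
            )
            capture, _ = generate_capture(
                spec,
                optics=config.optics,
                condition=condition,
                capture_id=f"cap-{condition.value}-{seed_offset}-{k}",
            )
            captures.append(capture)
    return captures


def load_captures(captures_dir: str | Path) -> list[PhaseCapture]:
    paths = sorted(Path(captures_dir).glob("*.tif")) + sorted(Path(captures_dir).glob("*.tiff"))
    if not paths:
        raise FileNotFoundError(f"no TIFF captures in {captures_dir}")
    return [read_capture(p) for p in paths]


def _segment_all(captures: list[PhaseCapture], params: SegmentationParams, counts: dict) -> list:
    crops = []
    n_det = n_area = n_border = 0
    for capture in captures:
        detections = detect_cells(capture, params)
        kept, discards = crop_cells(capture, detections, params, return_discards=True)
        n_det += len(detections)
        n_area += sum(1 for _, r in discards if r == "area")
        n_border += sum(1 for _, r in discards if r == "border")
        crops.extend(kept)
    counts["detections"] = n_det
    counts["segmentation_discard_area"] = n_area
    counts["segmentation_discard_border"] = n_border
    counts["crops"] = len(crops)
    log.info("segmentation: %d detections -> %d crops (%d area, %d border discards)", n_det, len(crops), n_area, n_border)
    return crops


def _train_sad_stage(config: PipelineConfig) -> SADModel:
    sup = generate_labeled_dataset(
        max(config.sad.n_alive, config.sad.n_apoptotic, config.sad.n_necroptotic),
        optics=config.optics,
        seed=config.seed + 90001,
        noise_sd_rad=config.synthetic.noise_sd_rad,
        id_prefix="sadsup",
    ).by_class()
    return train_sad(
        sup["alive"][: config.sad.n_alive],
        sup["apoptosis"][: config.sad.n_apoptotic],
        sup["necroptosis"][: config.sad.n_necroptotic],
        extractor=get_extractor(config.sad.extractor, seed=config.seed),
        seed=config.seed,
        threshold=config.sad.threshold,
    )


def _sad_filter_stage(sad_model: SADModel, crops: list, counts: dict) -> tuple[list, list]:
    by_capture: dict[tuple[str, Condition], list] = {}
    for crop in crops:
        by_capture.setdefault((crop.capture_id, crop.condition), []).append(crop)
    kept, verdicts = [], []
    for (_, condition), group in sorted(by_capture.items(), key=lambda kv: kv[0][0]):
        vs = apply_sad(sad_model, group, condition)
        verdicts.extend(vs)
        kept.extend(c for c, v in zip(group, vs) if v.kept)
    counts["sad_input"] = len(crops)
    counts["sad_kept"] = len(kept)
    counts["sad_discard_class_mismatch"] = sum(1 for v in verdicts if v.reason == "class_mismatch")
    counts["sad_discard_below_threshold"] = sum(1 for v in verdicts if v.reason == "below_threshold")
    log.info("SAD: %d in -> %d kept", len(crops), len(kept))
    return kept, verdicts


def run_training_pipeline(
    config: PipelineConfig, captures: list[PhaseCapture] | None = None
) -> PipelineResult:
    """Run crop → SAD → balance → split → train and evaluate on validation.

    ``captures`` defaults to loading ``config.captures_dir``, or to
    synthetic generation when no directory is configured.
    """
    counts: dict[str, int] = {}
    if captures is None:
        if config.captures_dir:
            captures = load_captures(config.captures_dir)
        else:
            captures = generate_condition_captures(config, seed_offset=0)
    counts["captures"] = len(captures)
    present = {c.condition for c in captures}
    if len(present) < 3:
        raise ValueError(f"need captures of all three conditions, got {sorted(c.value for c in present)}")

    crops = _segment_all(captures, config.segmentation, counts)

    sad_model = None
    verdicts = []
    if config.sad.enabled:
        sad_model = _train_sad_stage(config)
        crops, verdicts = _sad_filter_stage(sad_model, crops, counts)
    for cls in CLASS_ORDER:
        if not any(c.condition.value == cls for c in crops):
            raise ValueError(f"no crops left for class {cls!r} after filtering")

    dataset = LabeledDataset(crops=crops)
    balanced = balance_classes(dataset, seed=config.seed)
    counts["balanced"] = len(balanced)
    train_set, val_set = split_train_val(balanced, config.train.val_fraction, seed=config.seed)
    counts["train"] = len(train_set)
    counts["val"] = len(val_set)
    log.info("dataset: %d balanced -> %d train / %d val", len(balanced), len(train_set), len(val_set))

    model = build_model(config.backbone, seed=config.seed)
    model, history = train_classifier(model, train_set, val_set, config.train)
    probs, labels = predict(model, val_set.crops)
    report = build_report(labels, probs, val_set.labels)

    result = PipelineResult(
        sad_model=sad_model,
        classifier=model,
        history=history,
        report=report,
        stage_counts=counts,
        train_capture_ids={c.capture_id for c in captures},
    )
    if config.out_dir:
        _write_artifacts(config, result, verdicts)
    return result


def run_holdout_evaluation(
    config: PipelineConfig,
    classifier: ClassifierModel,
    holdout_captures: list[PhaseCapture],
    train_capture_ids: set[str],
    sad_model: SADModel | None = None,
) -> EvalReport:
    """Evaluate on captures from experiments never used in training.

    The prediction path sees only pixels; condition labels enter only when
    the report is assembled. Raises on empty holdout or on any capture-id
    overlap with the training set.
    """
    if not holdout_captures:
        raise ValueError("empty holdout set")
    overlap = {c.capture_id for c in holdout_captures} & set(train_capture_ids)
    if overlap:
        raise ValueError(f"holdout captures overlap training experiments: {sorted(overlap)}")
    counts: dict[str, int] = {}
    crops = _segment_all(holdout_captures, config.segmentation, counts)
    if sad_model is not None:
        crops, _ = _sad_filter_stage(sad_model, crops, counts)
    if not crops:
        raise ValueError("no crops survived the holdout filters")
    crops = sorted(crops, key=lambda c: c.crop_id)
    probs, pred_labels = predict(classifier, crops)
    true_labels = np.array([c.condition.value for c in crops])
    return build_report(pred_labels, probs, true_labels)


def _write_artifacts(config: PipelineConfig, result: PipelineResult, verdicts) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    save_model(result.classifier, out / "classifier")
    if result.sad_model is not None:
        save_sad(result.sad_model, out / "sad_model")
    if verdicts:
        verdicts_to_csv(verdicts, out / "sad_verdicts.csv")
    pd.DataFrame(result.history).to_csv(out / "training_history.csv", index=False)
    result.report.to_json(out / "val_report.json")
    result.report.to_csv(out)
    (out / "stage_counts.json").write_text(json.dumps(result.stage_counts, indent=1, sort_keys=True))
    (out / "train_capture_ids.json").write_text(json.dumps(sorted(result.train_capture_ids)))
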