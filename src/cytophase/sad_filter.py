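"""Supervised anomaly detection (SAD): purify condition labels before training.

Bulk experiments are impure — an apoptosis-induced dish still contains cells
that look alive, and vice versa. The SAD filter is a two-class
(Alive vs Death) classifier, trained on a small hand-curated set of crops,
that discards every crop whose predicted appearance contradicts the
condition of its source experiment, or whose prediction score is not above
a cutoff T. Apoptotic and necroptotic morphologies are pooled into the
single Death class: the filter only decides alive vs dead, never the death
modality.

The embedding is pluggable. The default, :class:`PhaseStatsExtractor`,
computes deterministic classical features (intensity histogram + shape and
height moments); :class:`RandomCNNExtractor` embeds crops through a
seeded random-weight convolutional encoder instead. A deep pretrained
feature map can be slotted in through the same contract.

The "prediction score" is the probability gap of the predicted class
(p_predicted − p_other, clipped at zero; for two classes, 2·p_predicted − 1),
so scores live in [0, 1] and a small threshold such as T = 0.01 removes only
near-undecided crops. A raw SVM margin can be selected instead via
``score_kind="margin"``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol

import joblib
import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import config
from .classifier import build_model, preprocess_crop
from .phase_optics import Condition
from .segmentation import CellCrop

ALIVE, DEATH = "Alive", "Death"

#: Which SAD class "coordinates" with which experiment condition.
_COORDINATES = {
    Condition.ALIVE: ALIVE,
    Condition.APOPTOSIS: DEATH,
    Condition.NECROPTOSIS: DEATH,
}


class FeatureExtractor(Protocol):
    name: str
    embed_dim: int

    def extract(self, crops: list[CellCrop]) -> np.ndarray:
        """Embed crops into (n, embed_dim); bit-stable for a fixed instance."""
        ...


class PhaseStatsExtractor:
    """Classical per-crop features: normalized-intensity histogram, height
    statistics and shape moments of the above-threshold footprint.

    Fully deterministic; no trained weights.
    """

    name = "phase-stats"

    def __init__(self, n_bins: int = 16):
        self.n_bins = n_bins
        self.embed_dim = n_bins + 10

    def extract(self, crops: list[CellCrop]) -> np.ndarray:
        feats = np.empty((len(crops), self.embed_dim), dtype=np.float64)
        for i, crop in enumerate(crops):
            feats[i] = self._one(crop.pixels.astype(np.float64))
        return feats

    def _one(self, patch: np.ndarray) -> np.ndarray:
        ptp = np.ptp(patch)
        norm = (patch - patch.min()) / ptp if ptp > 0 else np.zeros_like(patch)
        hist, _ = np.histogram(norm, bins=self.n_bins, range=(0.0, 1.0))
        hist = hist / norm.size
        thr = threshold_otsu(norm) if ptp > 0 else 1.0
        mask = norm > thr
        area = mask.sum()
        if area > 0:
            rr, cc = np.nonzero(mask)
            r0, c0 = rr.mean(), cc.mean()
            mu_rr = np.mean((rr - r0) ** 2)
            mu_cc = np.mean((cc - c0) ** 2)
            spread = np.sqrt(mu_rr + mu_cc)
            fg = patch[mask]
            fg_mean, fg_max, fg_std = fg.mean(), fg.max(), fg.std()
        else:
            spread = fg_mean = fg_max = fg_std = 0.0
        # texture roughness: mean absolute Laplacian (bleb-sensitive)
        lap = (
            -4 * norm[1:-1, 1:-1]
            + norm[:-2, 1:-1]
            + norm[2:, 1:-1]
            + norm[1:-1, :-2]
            + norm[1:-1, 2:]
        )
        stats = np.array(
            [
                patch.mean(),
                patch.std(),
                patch.max(),
                float(fg_mean),
                float(fg_max),
                float(fg_std),
                area / norm.size,
                float(spread),
                float(np.abs(lap).mean()),
                float(np.abs(lap).max()),
            ]
        )
        return np.concatenate([hist, stats])


class RandomCNNExtractor:
    """Seeded random-weight convolutional encoder (random-projection features).

    Reuses the classifier's small conv stack with frozen seeded weights;
    deterministic for a fixed seed.
    """

    name = "random-cnn"

    def __init__(self, seed: int = 0):
        self.seed = seed
        self._model = build_model("small_cnn", seed=seed)
        self.embed_dim = 8 * 8 * 32

    def extract(self, crops: list[CellCrop]) -> np.ndarray:
        x = np.stack([preprocess_crop(c, self._model.input_shape[:2]) for c in crops])
        return self._model.backbone_forward(x).astype(np.float64)


def get_extractor(name: str, seed: int = 0) -> FeatureExtractor:
    if name == "phase-stats":
        return PhaseStatsExtractor()
    if name == "random-cnn":
        return RandomCNNExtractor(seed=seed)
    raise ValueError(f"unknown extractor {name!r}")


@dataclass
class SADModel:
    """Feature extractor + linear SVM over {Alive, Death} + score cutoff."""

    extractor: FeatureExtractor
    svm: "Pipeline"  # StandardScaler + linear SVC, fitted on {Alive, Death}
    threshold: float = config.SAD_THRESHOLD
    score_kind: str = "probability"  # "probability" | "margin"

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.score_kind not in ("probability", "margin"):
            raise ValueError(f"unknown score_kind {self.score_kind!r}")

    def predict_with_scores(self, crops: list[CellCrop]) -> tuple[np.ndarray, np.ndarray]:
        """Predicted class names and nonnegative prediction scores."""
        feats = self.extractor.extract(crops)
        if self.score_kind == "probability":
            probs = self.svm.predict_proba(feats)
            pred_idx = probs.argmax(axis=1)
            scores = np.clip(2.0 * probs.max(axis=1) - 1.0, 0.0, None)
        else:
            margin = self.svm.decision_function(feats)
            pred_idx = (margin > 0).astype(int)
            scores = np.abs(margin)
        classes = np.asarray(self.svm.classes_)
        return classes[pred_idx], scores


@dataclass(frozen=True)
class SADVerdict:
    """Outcome for one crop: prediction, score, and keep/discard reason."""

    crop_id: str
    predicted: str
    score: float
    kept: bool
    reason: str  # "kept" | "class_mismatch" | "below_threshold"

    def __post_init__(self) -> None:
        if self.kept != (self.reason == "kept"):
            raise ValueError("kept flag must agree with reason")


def train_sad(
    alive_crops: list[CellCrop],
    apoptotic_crops: list[CellCrop],
    necroptotic_crops: list[CellCrop],
    extractor: FeatureExtractor | None = None,
    seed: int = 0,
    threshold: float = config.SAD_THRESHOLD,
    score_kind: str = "probability",
    C: float = 1.0,
) -> SADModel:
    """Fit the Alive-vs-Death SVM on a hand-curated (or synthetic) crop set.

    Apoptotic and necroptotic crops are pooled into Death. Raises on any
    empty class; warns if the embedded classes are not separable at all
    (degenerate model, e.g. identical crops in both folders).
    """
    if not alive_crops:
        raise ValueError("alive class is empty")
    if not (apoptotic_crops or necroptotic_crops):
        raise ValueError("death class is empty")
    extractor = extractor or PhaseStatsExtractor()
    crops = list(alive_crops) + list(apoptotic_crops) + list(necroptotic_crops)
    y = np.array([ALIVE] * len(alive_crops) + [DEATH] * (len(apoptotic_crops) + len(necroptotic_crops)))
    feats = extractor.extract(crops)
    # features are standardized before the margin fit: histogram bins and
    # moment features live on very different scales
    svm = make_pipeline(StandardScaler(), SVC(kernel="linear", C=C, probability=True, random_state=seed))
    with warnings.catch_warnings():
        # sklearn 1.9 deprecates probability=True; Platt scaling here is
        # deliberate (the score is a probability gap) and seeded.
        warnings.simplefilter("ignore", FutureWarning)
        svm.fit(feats, y)
    train_acc = float(np.mean(svm.predict(feats) == y))
    if train_acc <= max(np.mean(y == ALIVE), np.mean(y == DEATH)) + 1e-12:
        warnings.warn(
            f"SAD classes are not separable in embedding space (training accuracy {train_acc:.2f}); "
            "the model is degenerate",
            UserWarning,
            stacklevel=2,
        )
    return SADModel(extractor=extractor, svm=svm, threshold=threshold, score_kind=score_kind)


def apply_sad(model: SADModel, crops: list[CellCrop], condition: Condition | str) -> list[SADVerdict]:
    """Filter crops from one experiment against its condition.

    A crop is kept iff its predicted class coordinates with the condition
    (Alive ↔ alive; Death ↔ apoptosis or necroptosis) AND its score is
    strictly above the threshold. A crop failing both checks is reported as
    class_mismatch (the mismatch is the decisive rejection).
    """
    condition = Condition(condition)
    if not crops:
        return []
    predicted, scores = model.predict_with_scores(crops)
    wanted = _COORDINATES[condition]
    verdicts = []
    for crop, pred, score in zip(crops, predicted, scores):
        if pred != wanted:
            kept, reason = False, "class_mismatch"
        elif score <= model.threshold:
            kept, reason = False, "below_threshold"
        else:
            kept, reason = True, "kept"
        verdicts.append(SADVerdict(crop_id=crop.crop_id, predicted=str(pred), score=float(score), kept=kept, reason=reason))
    return verdicts


def kept_fraction_over_time(model: SADModel, crops: list[CellCrop]) -> pd.DataFrame:
    """Fraction of crops classed Death per time-post-induction bin.

    Mirrors a fluorescence dead-cell time course: as induction progresses
    the Death-classed fraction should rise (a property of the data, not
    enforced here). Every crop must carry ``time_post_induction_min``.
    Returns a DataFrame with columns time_min, n, dead_fraction, sorted by
    time.
    """
    if not crops:
        raise ValueError("no crops")
    times = []
    for crop in crops:
        if crop.time_post_induction_min is None:
            raise ValueError(f"crop {crop.crop_id} lacks time_post_induction_min")
        times.append(float(crop.time_post_induction_min))
    predicted, _ = model.predict_with_scores(crops)
    df = pd.DataFrame({"time_min": times, "dead": (predicted == DEATH).astype(float)})
    out = (
        df.groupby("time_min")
        .agg(n=("dead", "size"), dead_fraction=("dead", "mean"))
        .reset_index()
        .sort_values("time_min", ignore_index=True)
    )
    return out


def verdicts_to_csv(verdicts: list[SADVerdict], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([v.__dict__ for v in verdicts]).to_csv(path, index=False)
    return path


def save_sad(model: SADModel, path: str | Path) -> Path:
    """Serialize the SVM (joblib) next to a JSON descriptor."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump(model.svm, path.with_suffix(".joblib"))
    descriptor = {
        "format_version": 1,
        "extractor": model.extractor.name,
        "embed_dim": model.extractor.embed_dim,
        "threshold": model.threshold,
        "score_kind": model.score_kind,
    }
    path.with_suffix(".json").write_text(json.dumps(descriptor, indent=1, sort_keys=True))
    return path.with_suffix(".joblib")


def load_sad(path: str | Path, extractor: FeatureExtractor | None = None) -> SADModel:
    path = Path(path)
    descriptor = json.loads(path.with_suffix(".json").read_text())
    svm = joblib.load(path.with_suffix(".joblib"))
    extractor = extractor or get_extractor(descriptor["extractor"])
    return SADModel(
        extractor=extractor,
        svm=svm,
        threshold=descriptor["threshold"],
        score_kind=descriptor["score_kind"],
    )
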