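"""Cell localization and 66×66 crop extraction.

Cells are located by thresholding the phase image (Otsu by default) and
labelling connected components (8-connectivity). From each component
centroid a square box is cut, and kept only if the component area is
strictly inside the configured bounds and the box lies entirely within the
capture. Discarded detections keep their reason for audit.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

from . import config
from .phase_optics import Condition, PhaseCapture

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholding, area-filter and crop-box settings.

    ``area_min_px`` / ``area_max_px`` are *strict* bounds: a component is
    kept only if area_min < area < area_max. ``connectivity`` is the
    connected-component neighbourhood (2 = 8-connectivity in 2-D).
    """

    crop_size_px: int = config.CROP_SIZE_PX
    area_min_px: int = config.AREA_MIN_PX
    area_max_px: int = config.AREA_MAX_PX
    threshold_method: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: float | None = None
    connectivity: int = 2

    def __post_init__(self) -> None:
        if self.crop_size_px < 1:
            raise ValueError("crop_size_px must be >= 1")
        if not (0 <= self.area_min_px < self.area_max_px):
            raise ValueError("need 0 <= area_min_px < area_max_px")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed_threshold required with threshold_method='fixed'")


@dataclass(frozen=True)
class Detection:
    """One connected component: integer centroid (row, col), pixel area, label id."""

    centroid_rc: tuple[int, int]
    area_px: int
    label_id: int


@dataclass
class CellCrop:
    """A crop_size×crop_size phase patch centred on a detection.

    ``condition`` is the source capture's experiment condition — the label the
    pipeline trains on; ``true_class`` is the planted ground truth on
    synthetic data, None on real data.
    """

    pixels: np.ndarray
    centroid_rc: tuple[int, int]
    area_px: int
    capture_id: str
    condition: Condition
    crop_id: str = ""
    true_class: str | None = None
    time_post_induction_min: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        self.condition = Condition(self.condition)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError(f"crop must be square 2-D, got {self.pixels.shape}")
        if not self.crop_id:
            r, c = self.centroid_rc
            self.crop_id = f"{self.capture_id}:r{r}c{c}"


def _threshold(capture: PhaseCapture, params: SegmentationParams) -> float:
    if params.threshold_method == "fixed":
        return float(params.fixed_threshold)
    phase = capture.phase
    if np.ptp(phase) == 0:  # constant image: Otsu undefined, nothing above threshold
        return float(np.inf)
    return float(threshold_otsu(phase))


def detect_cells(capture: PhaseCapture, params: SegmentationParams | None = None) -> list[Detection]:
    """Find candidate cells as connected components of the above-threshold mask.

    No area or border filtering happens here; every component becomes a
    Detection with its pixel-mean centroid rounded to the nearest integer.
    An all-background capture yields an empty list.
    """
    params = params or SegmentationParams()
    thr = _threshold(capture, params)
    mask = capture.phase > thr
    labels = cc_label(mask, connectivity=params.connectivity)
    detections = []
    for prop in regionprops(labels):
        r, c = prop.centroid
        detections.append(
            Detection(
                centroid_rc=(int(round(r)), int(round(c))),
                area_px=int(prop.area),
                label_id=int(prop.label),
            )
        )
    return detections


def crop_window(centroid_rc: tuple[int, int], crop_size: int) -> tuple[int, int, int, int]:
    """Half-open crop window (r0, r1, c0, c1) for a centroid.

    For even crop sizes "centred" is ambiguous; the convention here is rows
    [r − s//2, r + s − s//2) and likewise for columns, i.e. [r−33, r+33) at
    the default size 66.
    """
    r, c = centroid_rc
    half = crop_size // 2
    return r - half, r - half + crop_size, c - half, c - half + crop_size


def crop_cells(
    capture: PhaseCapture,
    detections: list[Detection],
    params: SegmentationParams | None = None,
    return_discards: bool = False,
):
    """Cut a crop for every detection that passes the area and border filters.

    A detection survives iff area_min < area < area_max (strict) and its
    crop box lies entirely inside the capture. Returns the list of
    :class:`CellCrop`; with ``return_discards=True`` also returns a list of
    ``(Detection, reason)`` with reason ``"area"`` or ``"border"``.
    """
    params = params or SegmentationParams()
    h, w = capture.shape
    crops: list[CellCrop] = []
    discards: list[tuple[Detection, str]] = []
    for det in detections:
        if not (params.area_min_px < det.area_px < params.area_max_px):
            discards.append((det, "area"))
            log.debug("discard %s: area %d outside (%d, %d)", det, det.area_px, params.area_min_px, params.area_max_px)
            continue
        r0, r1, c0, c1 = crop_window(det.centroid_rc, params.crop_size_px)
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
            discards.append((det, "border"))
            log.debug("discard %s: box (%d:%d, %d:%d) crosses border", det, r0, r1, c0, c1)
            continue
        crops.append(
            CellCrop(
                pixels=capture.phase[r0:r1, c0:c1].copy(),
                centroid_rc=det.centroid_rc,
                area_px=det.area_px,
                capture_id=capture.capture_id,
                condition=capture.condition,
                time_post_induction_min=capture.time_post_induction_min,
            )
        )
    if return_discards:
        return crops, discards
    return crops


def segment_capture(capture: PhaseCapture, params: SegmentationParams | None = None) -> list[CellCrop]:
    """detect_cells followed by crop_cells."""
    params = params or SegmentationParams()
    return crop_cells(capture, detect_cells(capture, params), params)


def write_crop_batch(
    crops: list[CellCrop],
    out_dir: str | Path,
    discards: list[tuple[Detection, str]] | None = None,
    capture_id: str | None = None,
) -> Path:
    """Write crops as float32 TIFF patches plus a CSV manifest.

    Manifest columns: capture_id, crop_id, row, col, area_px, condition,
    kept, discard_reason. Discarded detections (if given) appear as rows
    with kept=0 and no TIFF.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["capture_id", "crop_id", "row", "col", "area_px", "condition", "kept", "discard_reason"])
        for i, crop in enumerate(crops):
            fname = f"crop_{i:05d}.tif"
            tifffile.imwrite(out_dir / fname, crop.pixels)
            r, c = crop.centroid_rc
            writer.writerow([crop.capture_id, crop.crop_id, r, c, crop.area_px, crop.condition.value, 1, ""])
        for det, reason in discards or []:
            r, c = det.centroid_rc
            writer.writerow([capture_id or "", f"discard:{det.label_id}", r, c, det.area_px, "", 0, reason])
    return manifest
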