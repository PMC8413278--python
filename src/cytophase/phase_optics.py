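"""Quantitative phase images and the phase ↔ optical-height conversion.

A transparent cell delays transmitted light in proportion to its thickness
and its refractive-index contrast with the surrounding medium:

    Δφ = (2π / λ) · (η_i − η_media) · h

where Δφ is the per-pixel phase delay in radians, λ the illumination
wavelength, η_i the mean refractive index of the cell, η_media that of the
medium, and h the specimen height. Solving for h gives the "optical height"
h = Δφ · λ / (2π · (η_i − η_media)), an apparent height: it reflects
refractive-index changes (e.g. chromatin condensation, membrane pore
formation) as well as physical thickness.

Captures are stored as single-channel float32 TIFF plus a JSON sidecar
carrying condition and optics metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import tifffile

from . import config

#: Minimum capture side length: a capture must admit at least one crop box.
MIN_CAPTURE_SIDE = config.CROP_SIZE_PX


class Condition(str, Enum):
    """Experiment condition of a capture (one inducer per experiment)."""

    ALIVE = "alive"
    APOPTOSIS = "apoptosis"
    NECROPTOSIS = "necroptosis"


class DegenerateOpticsError(ValueError):
    """Raised when eta_cell == eta_media and the height conversion is undefined."""


@dataclass(frozen=True)
class OpticalParams:
    """Optical constants of the DHM setup.

    Parameters
    ----------
    wavelength_um
        Illumination wavelength λ in micrometres; must be positive.
    eta_cell
        Mean refractive index of the cell, η_i (dimensionless).
    eta_media
        Refractive index of the culture medium, η_media (dimensionless).
        Must differ from ``eta_cell``; the phase→height conversion divides
        by the contrast η_i − η_media.
    """

    wavelength_um: float = config.WAVELENGTH_UM
    eta_cell: float = config.ETA_CELL
    eta_media: float = config.ETA_MEDIA

    def __post_init__(self) -> None:
        if not np.isfinite(self.wavelength_um) or self.wavelength_um <= 0:
            raise ValueError(f"wavelength_um must be positive, got {self.wavelength_um}")
        if not (np.isfinite(self.eta_cell) and np.isfinite(self.eta_media)):
            raise ValueError("refractive indices must be finite")
        if self.eta_cell == self.eta_media:
            raise DegenerateOpticsError(
                "eta_cell == eta_media: zero refractive-index contrast, "
                "phase/height conversion undefined"
            )

    @property
    def contrast(self) -> float:
        """Refractive-index contrast η_i − η_media."""
        return self.eta_cell - self.eta_media


@dataclass
class PhaseCapture:
    """One full field-of-view phase-delay map with its experiment metadata.

    ``phase`` is a 2-D float array of unwrapped phase delays in radians; any
    2π ambiguity is assumed resolved upstream by the instrument software.
    """

    phase: np.ndarray
    condition: Condition
    capture_id: str
    optics: OpticalParams = field(default_factory=OpticalParams)
    time_post_induction_min: float | None = None

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=np.float32)
        self.condition = Condition(self.condition)
        if self.phase.ndim != 2:
            raise ValueError(f"phase must be 2-D, got shape {self.phase.shape}")
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("phase values must be finite")
        if min(self.phase.shape) < MIN_CAPTURE_SIDE:
            raise ValueError(
                f"capture shape {self.phase.shape} is below the croppable minimum "
                f"{MIN_CAPTURE_SIDE}x{MIN_CAPTURE_SIDE}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.phase.shape


@dataclass
class HeightMap:
    """Optical-height map (micrometres), same shape as its source phase grid."""

    height_um: np.ndarray
    optics: OpticalParams

    def __post_init__(self) -> None:
        self.height_um = np.asarray(self.height_um, dtype=np.float64)
        if self.height_um.ndim != 2:
            raise ValueError("height_um must be 2-D")


def phase_to_height(capture: PhaseCapture) -> HeightMap:
    """Convert a phase capture to optical height, h = Δφ·λ / (2π·(η_i − η_media)).

    Raises
    ------
    DegenerateOpticsError
        If the optics carry zero refractive-index contrast (guarded at
        ``OpticalParams`` construction, re-checked here for safety).
    """
    optics = capture.optics
    if optics.contrast == 0:
        raise DegenerateOpticsError("zero refractive-index contrast")
    h = capture.phase.astype(np.float64) * optics.wavelength_um / (2.0 * np.pi * optics.contrast)
    return HeightMap(height_um=h, optics=optics)


def height_to_phase(height_um: np.ndarray | HeightMap, optics: OpticalParams | None = None) -> np.ndarray:
    """Inverse conversion, Δφ = (2π/λ)·(η_i − η_media)·h.

    Accepts either a :class:`HeightMap` (optics taken from it unless
    overridden) or a bare 2-D array of heights in micrometres.
    """
    if isinstance(height_um, HeightMap):
        optics = optics or height_um.optics
        h = height_um.height_um
    else:
        if optics is None:
            raise ValueError("optics required when height is a bare array")
        h = np.asarray(height_um, dtype=np.float64)
    return 2.0 * np.pi / optics.wavelength_um * optics.contrast * h


# ---------------------------------------------------------------------------
# File I/O: float32 TIFF + JSON sidecar


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_capture(capture: PhaseCapture, path: str | Path) -> Path:
    """Write a capture as single-channel float32 TIFF plus a JSON sidecar.

    Returns the TIFF path. The sidecar lives next to it with a ``.json``
    suffix and carries capture_id, condition, optics and induction time.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, capture.phase.astype(np.float32))
    meta = {
        "capture_id": capture.capture_id,
        "condition": capture.condition.value,
        "wavelength_um": capture.optics.wavelength_um,
        "eta_cell": capture.optics.eta_cell,
        "eta_media": capture.optics.eta_media,
        "time_post_induction_min": capture.time_post_induction_min,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_capture(path: str | Path, metadata: dict | None = None) -> PhaseCapture:
    """Read a capture from TIFF (+ JSON sidecar, or an explicit metadata dict).

    Raises
    ------
    ValueError
        Missing/invalid metadata (unknown condition string), or an image
        smaller than the croppable minimum.
    TypeError
        Multi-channel image.
    """
    path = Path(path)
    phase = tifffile.imread(path)
    if phase.ndim != 2:
        raise TypeError(f"expected single-channel 2-D image, got shape {phase.shape}")
    if metadata is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValueError(f"metadata sidecar not found: {sidecar}")
        metadata = json.loads(sidecar.read_text())
    if "condition" not in metadata:
        raise ValueError("metadata must carry a 'condition'")
    try:
        condition = Condition(metadata["condition"])
    except ValueError as exc:
        raise ValueError(f"unknown condition {metadata['condition']!r}") from exc
    optics = OpticalParams(
        wavelength_um=metadata.get("wavelength_um", config.WAVELENGTH_UM),
        eta_cell=metadata.get("eta_cell", config.ETA_CELL),
        eta_media=metadata.get("eta_media", config.ETA_MEDIA),
    )
    return PhaseCapture(
        phase=phase,
        condition=condition,
        capture_id=str(metadata.get("capture_id", path.stem)),
        optics=optics,
        time_post_induction_min=metadata.get("time_post_induction_min"),
    )
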