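"""Seeded generator of synthetic DHM captures with planted cell-death morphologies.

The generator emulates what a digital holographic microscope sees in a
cell-death experiment, at the level the downstream pipeline cares about:

* **alive** cells — spread, irregular outline, smooth moderate elevation;
* **apoptotic** cells — shrunken bodies carrying a few small
  high-curvature blebs, with overall optical height scaled *up*
  (chromatin condensation raises the refractive index);
* **necroptotic** cells — large round smooth domes with optical height
  scaled *down* (membrane pores lower the index contrast);

plus background Gaussian phase noise and controllable cell density. Cells
are built as height patches (µm), placed without overlap, converted to
phase via the optics relation Δφ = (2π/λ)(η_i − η_media)·h, and noise is
added in phase space. All randomness flows from explicit seeds, so the
same seed yields a bit-identical capture.

Morphology magnitudes (radii, peak heights, scale factors) are invented,
chosen once to be class-separable and compatible with the segmentation
area filter (strict 80–600 px); they are not measured values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .classifier import CLASS_ORDER, LabeledDataset
from .phase_optics import Condition, OpticalParams, PhaseCapture, height_to_phase
from .segmentation import CellCrop


@dataclass(frozen=True)
class ClassMorphology:
    """Shape/height ranges for one class; ranges are inclusive uniform draws."""

    body_radius_px: tuple[float, float]
    peak_height_um: tuple[float, float]
    height_scale_factor: float
    profile: str  # "dome" | "spread"
    n_blebs: tuple[int, int] = (0, 0)
    bleb_radius_px: tuple[float, float] = (1.5, 2.5)
    boundary_modulation: float = 0.0  # fractional radius irregularity (spread profile)

    def __post_init__(self) -> None:
        if self.body_radius_px[0] <= 0 or self.peak_height_um[0] <= 0:
            raise ValueError("radii and heights must be positive")
        if self.height_scale_factor <= 0:
            raise ValueError("height_scale_factor must be positive")
        if self.profile not in ("dome", "spread"):
            raise ValueError(f"unknown profile {self.profile!r}")


@dataclass(frozen=True)
class MorphologyParams:
    """Morphology ranges for the three classes.

    The class ordering of optical-height scale factors is an invariant:
    apoptosis > alive > necroptosis.
    """

    alive: ClassMorphology = field(
        default_factory=lambda: ClassMorphology(
            body_radius_px=(7.0, 10.0),
            peak_height_um=(1.5, 2.5),
            height_scale_factor=1.0,
            profile="spread",
            boundary_modulation=0.15,
        )
    )
    apoptosis: ClassMorphology = field(
        default_factory=lambda: ClassMorphology(
            body_radius_px=(5.5, 7.5),
            peak_height_um=(1.5, 2.5),
            height_scale_factor=1.6,
            profile="dome",
            n_blebs=(3, 6),
            bleb_radius_px=(1.5, 2.5),
        )
    )
    necroptosis: ClassMorphology = field(
        default_factory=lambda: ClassMorphology(
            body_radius_px=(10.0, 13.0),
            peak_height_um=(1.5, 2.5),
            height_scale_factor=0.55,
            profile="dome",
        )
    )

    def __post_init__(self) -> None:
        if not (
            self.apoptosis.height_scale_factor
            > self.alive.height_scale_factor
            > self.necroptosis.height_scale_factor
        ):
            raise ValueError(
                "height scale factors must order apoptosis > alive > necroptosis"
            )

    def for_class(self, cls: str) -> ClassMorphology:
        return getattr(self, cls)


@dataclass(frozen=True)
class SceneSpec:
    """Layout of one synthetic capture."""

    image_shape: tuple[int, int] = (440, 440)
    n_cells: int = 12
    class_mix: dict = field(default_factory=lambda: {"alive": 1.0})
    noise_sd_rad: float = 0.02
    min_separation_px: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1, got {total}")
        for cls in self.class_mix:
            if cls not in CLASS_ORDER:
                raise ValueError(f"unknown class {cls!r}")


@dataclass(frozen=True)
class CellAnnotation:
    """Planted ground truth for one cell in a capture."""

    centroid_rc: tuple[int, int]
    true_class: str
    area_px: int


def generate_cell_height(
    cls: str, morph: MorphologyParams | None = None, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, int]:
    """Draw one cell as a height patch (µm) plus its ground-truth footprint area.

    The footprint is the strictly-positive support of the patch.
    """
    morph = morph or MorphologyParams()
    rng = rng if rng is not None else np.random.default_rng()
    if cls not in CLASS_ORDER:
        raise ValueError(f"unknown class {cls!r}")
    p = morph.for_class(cls)
    radius = rng.uniform(*p.body_radius_px)
    peak = rng.uniform(*p.peak_height_um) * p.height_scale_factor
    max_radius = radius * (1 + p.boundary_modulation) + p.bleb_radius_px[1] + 1
    half = int(np.ceil(max_radius)) + 1
    side = 2 * half + 1
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    dist = np.hypot(yy, xx)

    if p.profile == "spread":
        theta = np.arctan2(yy, xx)
        mod = np.zeros_like(theta)
        for k in (2, 3, 4):
            amp = rng.uniform(-1.0, 1.0) * p.boundary_modulation / 2
            phase = rng.uniform(0, 2 * np.pi)
            mod += amp * np.cos(k * theta + phase)
        r_theta = radius * (1.0 + np.clip(mod, -p.boundary_modulation, p.boundary_modulation))
        rel = np.clip(dist / r_theta, 0.0, 1.0)
        patch = peak * (1.0 - rel**2) ** 0.6
    else:
        rel = np.clip(dist / radius, 0.0, 1.0)
        exponent = 1.2 if cls == "apoptosis" else 1.5
        patch = peak * (1.0 - rel**2) ** exponent

    n_blebs = int(rng.integers(p.n_blebs[0], p.n_blebs[1] + 1)) if p.n_blebs[1] > 0 else 0
    for _ in range(n_blebs):
        ang = rng.uniform(0, 2 * np.pi)
        rad_pos = 0.85 * radius
        by, bx = rad_pos * np.sin(ang), rad_pos * np.cos(ang)
        rb = rng.uniform(*p.bleb_radius_px)
        amp = rng.uniform(0.4, 0.7) * peak
        db = np.hypot(yy - by, xx - bx)
        patch = patch + amp * np.clip(1.0 - (db / rb) ** 2, 0.0, None) ** 2

    area = int((patch > 1e-9).sum())
    return patch.astype(np.float64), area


def _class_counts(class_mix: dict, n: int) -> dict[str, int]:
    """Deterministic apportionment: floors, remainder by largest fraction."""
    raw = {c: class_mix.get(c, 0.0) * n for c in CLASS_ORDER}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    rem = n - sum(counts.values())
    order = sorted(CLASS_ORDER, key=lambda c: (counts[c] - raw[c], CLASS_ORDER.index(c)))
    for c in order[:rem]:
        counts[c] += 1
    return counts


def generate_capture(
    spec: SceneSpec,
    morph: MorphologyParams | None = None,
    optics: OpticalParams | None = None,
    condition: Condition | str = Condition.ALIVE,
    capture_id: str | None = None,
    time_post_induction_min: float | None = None,
    max_tries: int = 2000,
    return_height: bool = False,
) -> tuple[PhaseCapture, list[CellAnnotation]]:
    """Build one full-field capture with planted, annotated cells.

    Cells are placed by rejection sampling with pairwise centre distance
    ≥ ``min_separation_px`` and a border margin wide enough that every
    cell's crop box stays inside the image. Heights go through the
    phase relation; Gaussian phase noise is added on top.
    """
    morph = morph or MorphologyParams()
    optics = optics or OpticalParams()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    margin = 35  # keeps the 66x66 crop box of every planted cell inside the field
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise ValueError(f"image_shape {spec.image_shape} too small for placement margin {margin}")

    counts = _class_counts(spec.class_mix, spec.n_cells)
    classes = [c for c in CLASS_ORDER for _ in range(counts[c])]
    rng.shuffle(classes)

    centers: list[tuple[int, int]] = []
    tries = 0
    while len(centers) < spec.n_cells:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {spec.n_cells} cells with separation "
                f"{spec.min_separation_px} in {spec.image_shape} after {max_tries} tries"
            )
        r = int(rng.integers(margin, h - margin))
        c = int(rng.integers(margin, w - margin))
        if all(np.hypot(r - r0, c - c0) >= spec.min_separation_px for r0, c0 in centers):
            centers.append((r, c))

    canvas = np.zeros(spec.image_shape, dtype=np.float64)
    annotations: list[CellAnnotation] = []
    for (r, c), cls in zip(centers, classes):
        patch, area = generate_cell_height(cls, morph, rng)
        half = patch.shape[0] // 2
        canvas[r - half : r + half + 1, c - half : c + half + 1] += patch
        annotations.append(CellAnnotation(centroid_rc=(r, c), true_class=cls, area_px=area))

    phase = height_to_phase(canvas, optics)
    if spec.noise_sd_rad > 0:
        phase = phase + rng.normal(0.0, spec.noise_sd_rad, size=phase.shape)
    capture = PhaseCapture(
        phase=phase.astype(np.float32),
        condition=Condition(condition),
        capture_id=capture_id or f"synth-{Condition(condition).value}-{spec.seed}",
        optics=optics,
        time_post_induction_min=time_post_induction_min,
    )
    if return_height:
        return capture, annotations, canvas
    return capture, annotations


def generate_labeled_dataset(
    n_per_class: int,
    morph: MorphologyParams | None = None,
    optics: OpticalParams | None = None,
    seed: int = 0,
    crop_size: int = 66,
    noise_sd_rad: float = 0.02,
    area_bounds: tuple[int, int] = (80, 600),
    id_prefix: str = "synth",
) -> LabeledDataset:
    """Generate a balanced crop dataset with ground-truth classes.

    Each crop holds exactly one centred cell (with a small positional
    jitter). Draws whose footprint falls outside the strict area bounds are
    redrawn; if any redraw happened a warning reports the rejected
    fraction, since it means the morphology ranges brush against the
    segmentation filter.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    morph = morph or MorphologyParams()
    optics = optics or OpticalParams()
    rng = np.random.default_rng(seed)
    lo, hi = area_bounds
    crops: list[CellCrop] = []
    n_rejected = 0
    for cls in CLASS_ORDER:
        for i in range(n_per_class):
            for attempt in range(50):
                patch, area = generate_cell_height(cls, morph, rng)
                if lo < area < hi:
                    break
                n_rejected += 1
            else:
                raise RuntimeError(f"could not draw an in-filter {cls} cell in 50 tries")
            canvas = np.zeros((crop_size, crop_size), dtype=np.float64)
            half = patch.shape[0] // 2
            jr = int(rng.integers(-3, 4))
            jc = int(rng.integers(-3, 4))
            r0 = crop_size // 2 + jr
            c0 = crop_size // 2 + jc
            canvas[r0 - half : r0 + half + 1, c0 - half : c0 + half + 1] += patch
            phase = height_to_phase(canvas, optics)
            if noise_sd_rad > 0:
                phase = phase + rng.normal(0.0, noise_sd_rad, size=phase.shape)
            crops.append(
                CellCrop(
                    pixels=phase.astype(np.float32),
                    centroid_rc=(r0, c0),
                    area_px=area,
                    capture_id=f"{id_prefix}-{cls}-{i}",
                    condition=Condition(cls),
                    true_class=cls,
                )
            )
    if n_rejected:
        total = 3 * n_per_class + n_rejected
        warnings.warn(
            f"{n_rejected}/{total} cell draws fell outside the area filter "
            f"({n_rejected / total:.1%} rejected); morphology ranges brush the filter bounds",
            UserWarning,
            stacklevel=2,
        )
    return LabeledDataset(crops=crops)


def generate_time_course(
    bins: list[tuple[float, int, float]],
    morph: MorphologyParams | None = None,
    optics: OpticalParams | None = None,
    seed: int = 0,
    noise_sd_rad: float = 0.02,
) -> list[CellCrop]:
    """Crops for a death time course: ``bins`` is (time_min, n_cells, death_fraction).

    Dead cells alternate apoptotic/necroptotic morphology; every crop
    carries its time bin in ``time_post_induction_min``.
    """
    morph = morph or MorphologyParams()
    optics = optics or OpticalParams()
    crops: list[CellCrop] = []
    for b, (time_min, n, death_fraction) in enumerate(bins):
        n_dead = int(round(n * death_fraction))
        classes = ["apoptosis" if i % 2 == 0 else "necroptosis" for i in range(n_dead)]
        classes += ["alive"] * (n - n_dead)
        rng = np.random.default_rng(seed + 7919 * b)
        rng.shuffle(classes)
        for i, cls in enumerate(classes):
            ds = generate_labeled_dataset(
                1, morph, optics, seed=seed + 104729 * b + 31 * i + CLASS_ORDER.index(cls),
                noise_sd_rad=noise_sd_rad, id_prefix=f"tc{b}-{i}",
            )
            crop = next(c for c in ds.crops if c.true_class == cls)
            crop.time_post_induction_min = float(time_min)
            crops.append(crop)
    return crops
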