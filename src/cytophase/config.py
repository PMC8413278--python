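"""Package-wide defaults.

Optical constants are not universal — they depend on the microscope's laser
and on the cell line / medium — so every default lives here rather than being
buried in code, and every pipeline stage accepts explicit overrides.

Defaults:

* ``WAVELENGTH_UM`` — 0.532 µm, a common green DHM illumination wavelength.
* ``ETA_MEDIA`` — 1.333, refractive index of aqueous culture medium.
* ``ETA_CELL`` — 1.380, a typical mean cell refractive index; in practice it
  is fixed per cell line by calibration against cells with and without medium.
"""

WAVELENGTH_UM: float = 0.532
ETA_CELL: float = 1.380
ETA_MEDIA: float = 1.333

# Segmentation defaults: crop box side and the strict area filter bounds.
CROP_SIZE_PX: int = 66
AREA_MIN_PX: int = 80
AREA_MAX_PX: int = 600

# SAD score cutoff: crops whose (coordinating) prediction scores at or below
# this are discarded.
SAD_THRESHOLD: float = 0.01


def default_optics():
    """Return an :class:`~cytophase.phase_optics.OpticalParams` with the defaults above."""
    from .phase_optics import OpticalParams

    return OpticalParams(wavelength_um=WAVELENGTH_UM, eta_cell=ETA_CELL, eta_media=ETA_MEDIA)
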