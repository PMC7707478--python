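"""Core en face image container and shared enumerations.

An en face OCT angiography (OCTA) image is a frontal projection of the
decorrelation (flow) signal within one segmented retinal slab.  Three slabs
are handled here: the superficial capillary plexus (SCP), the deep capillary
plexus (DCP) and the choriocapillaris (CC).  Each slab can be acquired as a
single scan volume (``V1``) or as the merged average of four independently
acquired volumes (``V4``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

#: Default transverse sampling: a 3 x 3 mm field imaged at 304 x 304 pixels.
DEFAULT_IMAGE_SIZE = 304
DEFAULT_SCALE_MM_PER_PX = 3.0 / 304.0


class Plexus(str, Enum):
    """Vascular slab of an en face angiogram."""

    SCP = "SCP"
    DCP = "DCP"
    CC = "CC"


class AcquisitionMode(str, Enum):
    """Single-volume scan (V1) or merged average of four volumes (V4)."""

    V1 = "V1"
    V4 = "V4"


@dataclass
class EnFaceImage:
    """One grayscale en face angiogram with its acquisition metadata.

    Parameters
    ----------
    pixels:
        H x W array of intensities in ``[0, 255]`` (float or integer).
    plexus:
        Which vascular slab the image shows.
    acquisition_mode:
        ``V1`` (single volume) or ``V4`` (four-volume merge average).
    scale:
        Physical sampling in mm per pixel.
    eye_id:
        Free-text identifier of the imaged eye.
    """

    pixels: np.ndarray
    plexus: Plexus
    acquisition_mode: AcquisitionMode = AcquisitionMode.V1
    scale: float = DEFAULT_SCALE_MM_PER_PX
    eye_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.plexus = Plexus(self.plexus)
        self.acquisition_mode = AcquisitionMode(self.acquisition_mode)
        if self.pixels.ndim != 2:
            raise ValueError("en face image must be a 2-D grid")
        h, w = self.pixels.shape
        if h != w or h < 64:
            raise ValueError(
                f"en face image must be square with side >= 64 px, got {h}x{w}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image intensities must be finite")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("image intensities must lie in [0, 255]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape
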