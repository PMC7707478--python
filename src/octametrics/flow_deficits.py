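"""Choriocapillaris flow-deficit quantification.

A choriocapillaris en face angiogram is binarized with the Phansalkar local
threshold (designed for low-contrast, bright-background images): a pixel is
*flow* when its normalized intensity exceeds

    t = mu * (1 + p * exp(-q * mu) + k * (sigma / r - 1))

where mu and sigma are the mean and standard deviation of the normalized
intensities in a circular window around the pixel.  The complement of the
flow mask is the signal-void map; its 8-connected components are the flow
deficits (the ImageJ "Analyze Particles" convention), reported as a count,
per-deficit areas and the total void area as a percent of the frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import EnFaceImage, Plexus

__all__ = [
    "PhansalkarParams",
    "FlowDeficitResult",
    "phansalkar_threshold",
    "extract_flow_deficits",
    "compute_cc_metrics",
]

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class PhansalkarParams:
    """Phansalkar threshold constants (ImageJ Auto Local Threshold defaults)."""

    radius: int = 15
    k: float = 0.25
    r: float = 0.5
    p: float = 2.0
    q: float = 10.0

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.r <= 0:
            raise ValueError("r must be > 0")


@dataclass
class FlowDeficitResult:
    """Count, per-deficit areas, and total signal-void percentage."""

    n_deficits: int
    deficit_areas_px: list[int]
    deficit_areas_percent: list[float]
    total_fd_percent: float
    eye_id: str = ""
    acquisition_mode: str = ""

    def __post_init__(self) -> None:
        if self.n_deficits != len(self.deficit_areas_px):
            raise ValueError("n_deficits must equal len(deficit_areas_px)")
        if not (0.0 <= self.total_fd_percent <= 100.0):
            raise ValueError("total_fd_percent must lie in [0, 100]")


def _disk_footprint(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (yy**2 + xx**2 <= radius**2).astype(float)


def phansalkar_threshold(img: np.ndarray,
                         params: PhansalkarParams | None = None) -> np.ndarray:
    """Boolean flow mask: normalized pixel > Phansalkar local threshold.

    Intensities are normalized to [0, 1] by dividing by 255; window
    statistics use a circular footprint with edge-replicated borders.
    """
    if params is None:
        params = PhansalkarParams()
    x = np.asarray(img, dtype=float) / 255.0
    kern = _disk_footprint(params.radius)
    kern /= kern.sum()
    mean = ndimage.correlate(x, kern, mode="nearest")
    meansq = ndimage.correlate(x * x, kern, mode="nearest")
    sd = np.sqrt(np.clip(meansq - mean**2, 0.0, None))
    t = mean * (1.0 + params.p * np.exp(-params.q * mean)
                + params.k * (sd / params.r - 1.0))
    return x > t


def extract_flow_deficits(flow_mask: np.ndarray, *, eye_id: str = "",
                          acquisition_mode: str = "",
                          min_size_px: int = 0) -> FlowDeficitResult:
    """Label the void map (complement of flow) into 8-connected deficits.

    ``min_size_px`` optionally drops components below a size floor (for
    sensitivity analyses); by default every void component is counted.
    """
    flow = np.asarray(flow_mask, dtype=bool)
    void = ~flow
    labels, n = ndimage.label(void, structure=_EIGHT_CONNECTED)
    areas = ndimage.sum_labels(void, labels, index=np.arange(1, n + 1))
    areas = [int(a) for a in areas if a >= max(min_size_px, 1)]
    total_px = sum(areas)
    frame = flow.size
    return FlowDeficitResult(
        n_deficits=len(areas),
        deficit_areas_px=areas,
        deficit_areas_percent=[100.0 * a / frame for a in areas],
        total_fd_percent=100.0 * total_px / frame,
        eye_id=eye_id,
        acquisition_mode=acquisition_mode,
    )


def compute_cc_metrics(img: EnFaceImage,
                       params: PhansalkarParams | None = None,
                       min_size_px: int = 0) -> FlowDeficitResult:
    """Phansalkar binarization then particle analysis for a CC image."""
    if img.plexus is not Plexus.CC:
        raise ValueError("flow-deficit analysis applies to CC images only")
    flow = phansalkar_threshold(img.pixels, params)
    return extract_flow_deficits(flow, eye_id=img.eye_id,
                                 acquisition_mode=img.acquisition_mode.value,
                                 min_size_px=min_size_px)
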