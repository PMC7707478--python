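"""Dual-path binarization of SCP/DCP en face angiograms.

The chain reproduces the common ImageJ-style protocol for OCTA vessel
quantification: the image is background-flattened with a white top-hat,
duplicated, and binarized along two independent paths —

* path A: Frangi (Hessian-eigenvalue) vesselness, then a global threshold
  chosen by Huang's fuzzy-entropy criterion on the vesselness map;
* path B: local thresholding against the median of a square neighborhood —

and the two boolean maps are combined (pixelwise AND by default, so that a
pixel counts as vessel only when both paths agree; OR is available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import grey_opening, median_filter
from skimage.filters import frangi
from skimage.morphology import disk

from .image import EnFaceImage, Plexus

__all__ = [
    "BinarizationParams",
    "BinaryVesselMap",
    "top_hat",
    "hessian_vesselness",
    "huang_threshold",
    "median_local_threshold",
    "combine_masks",
    "binarize_plexus",
]


@dataclass(frozen=True)
class BinarizationParams:
    """Tunable parameters of the dual-path chain.

    Defaults: top-hat disk radius 12 px (just above the largest expected SCP
    caliber, so vessels survive the background flattening), vesselness scales
    0.5-3 px (the sub-pixel scale keeps capillary cores and, together with
    the coarser scales, large-vessel interiors above the global threshold),
    Huang threshold over 256 histogram levels, median-local radius 15 px
    with zero offset, AND combination.
    """

    tophat_radius: int = 12
    vesselness_scales: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0)
    huang_levels: int = 256
    local_radius: int = 15
    local_offset: float = 0.0
    combine_rule: str = "AND"

    def __post_init__(self) -> None:
        if self.tophat_radius < 1 or self.local_radius < 1:
            raise ValueError("radii must be >= 1")
        if len(self.vesselness_scales) == 0:
            raise ValueError("vesselness_scales must be non-empty")
        if self.combine_rule not in ("AND", "OR"):
            raise ValueError("combine_rule must be 'AND' or 'OR'")


@dataclass
class BinaryVesselMap:
    """A boolean vessel map plus the recorded processing chain."""

    mask: np.ndarray
    plexus: Plexus
    acquisition_mode: str = ""
    eye_id: str = ""
    method_chain: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.method_chain:
            raise ValueError("method_chain must be non-empty")


def top_hat(img: np.ndarray, radius: int) -> np.ndarray:
    """White top-hat: image minus its morphological opening by a disk.

    Flattens slowly varying background while keeping structures narrower
    than the disk.  Borders are edge-replicated.  Output is >= 0 and
    pointwise <= the input.
    """
    img = np.asarray(img, dtype=float)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if radius >= min(img.shape) / 2:
        raise ValueError(
            f"top-hat radius {radius} too large for image {img.shape}"
        )
    opened = grey_opening(img, footprint=disk(radius).astype(bool),
                          mode="nearest")
    return img - opened


def hessian_vesselness(img: np.ndarray, scales: tuple[float, ...] | list[float]
                       ) -> np.ndarray:
    """Frangi tubularity score, max over scales, rescaled to [0, 255].

    Bright ridges (vessels on dark background) score high; flat regions
    score ~0.  A constant image maps to all zeros.
    """
    scales = tuple(scales)
    if len(scales) == 0:
        raise ValueError("scales must be non-empty")
    img = np.asarray(img, dtype=float)
    v = frangi(img, sigmas=scales, beta=0.5, black_ridges=False)
    vmax = v.max()
    if vmax <= 0:
        return np.zeros_like(v)
    return 255.0 * v / vmax


def huang_threshold(img: np.ndarray, levels: int = 256) -> float:
    """Global threshold minimizing Huang-Wang fuzzy entropy.

    Intensities are binned into ``levels`` equal bins over [0, 255].  For a
    candidate threshold t, each gray level g gets a fuzzy membership to its
    class (below/above t), mu(g) = 1 / (1 + |g - m| / C), where m is the mean
    gray of g's class and C = g_max - g_min.  The score of t is the histogram-
    weighted Shannon pair entropy sum_g h(g) * S(mu(g)) with
    S(mu) = -mu ln mu - (1 - mu) ln(1 - mu); the threshold is the minimizer,
    ties broken toward the smallest t.  Pixels strictly above the returned
    value are foreground.
    """
    g = np.asarray(img, dtype=float).ravel()
    if not np.all(np.isfinite(g)):
        raise ValueError("image must be finite")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    # map [0, 255] onto integer bins; bin width w, centers i * w
    w = 255.0 / (levels - 1)
    idx = np.clip(np.rint(g / w).astype(int), 0, levels - 1)
    hist = np.bincount(idx, minlength=levels).astype(float)
    occupied = np.nonzero(hist)[0]
    if occupied.size < 2:
        raise ValueError("constant image: no threshold exists")
    gmin, gmax = occupied[0], occupied[-1]
    centers = np.arange(levels, dtype=float)  # work in bin units
    c_norm = float(gmax - gmin)

    csum_h = np.cumsum(hist)
    csum_gh = np.cumsum(centers * hist)
    tot_h, tot_gh = csum_h[-1], csum_gh[-1]

    # candidate thresholds: every level with non-empty classes on both sides
    cand = np.arange(gmin, gmax)
    w0 = csum_h[cand]
    m0 = csum_gh[cand] / w0
    m1 = (tot_gh - csum_gh[cand]) / (tot_h - w0)

    # membership matrix over (candidate, level)
    below = centers[None, :] <= cand[:, None]
    m = np.where(below, m0[:, None], m1[:, None])
    mu = 1.0 / (1.0 + np.abs(centers[None, :] - m) / c_norm)

    with np.errstate(divide="ignore", invalid="ignore"):
        s = -(mu * np.log(mu) + (1.0 - mu) * np.log(1.0 - mu))
    s[~np.isfinite(s)] = 0.0  # S(0) = S(1) = 0
    entropy = s @ hist
    t_star = cand[int(np.argmin(entropy))]  # argmin takes the first (smallest)
    return float(t_star * w)


def median_local_threshold(img: np.ndarray, radius: int,
                           offset: float = 0.0) -> np.ndarray:
    """Foreground where a pixel exceeds its local window median minus offset.

    The window is the (2r+1) x (2r+1) square around the pixel with
    edge-replicated borders.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    img = np.asarray(img, dtype=float)
    med = median_filter(img, size=2 * radius + 1, mode="nearest")
    return img > med - offset


def combine_masks(a: np.ndarray, b: np.ndarray, rule: str = "AND") -> np.ndarray:
    """Pixelwise AND (default) or OR of two boolean maps of equal shape."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if rule == "AND":
        return a & b
    if rule == "OR":
        return a | b
    raise ValueError("rule must be 'AND' or 'OR'")


def binarize_plexus(img: EnFaceImage,
                    params: BinarizationParams | None = None) -> BinaryVesselMap:
    """Run the full dual-path chain on an SCP or DCP en face image."""
    if params is None:
        params = BinarizationParams()
    if img.plexus not in (Plexus.SCP, Plexus.DCP):
        raise ValueError("binarize_plexus handles SCP/DCP images only")

    chain: list[dict] = []
    flat = top_hat(img.pixels, params.tophat_radius)
    chain.append({"step": "top_hat", "radius": params.tophat_radius})

    vness = hessian_vesselness(flat, params.vesselness_scales)
    chain.append({"step": "hessian_vesselness",
                  "scales": list(params.vesselness_scales)})
    t = huang_threshold(vness, params.huang_levels)
    mask_a = vness > t
    chain.append({"step": "huang_threshold", "levels": params.huang_levels,
                  "threshold": t})

    mask_b = median_local_threshold(flat, params.local_radius,
                                    params.local_offset)
    chain.append({"step": "median_local_threshold",
                  "radius": params.local_radius,
                  "offset": params.local_offset})

    mask = combine_masks(mask_a, mask_b, params.combine_rule)
    chain.append({"step": "combine", "rule": params.combine_rule})
    return BinaryVesselMap(mask=mask, plexus=img.plexus,
                           acquisition_mode=img.acquisition_mode.value,
                           eye_id=img.eye_id, method_chain=chain)
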