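"""Seeded synthetic en face OCTA phantoms with known ground truth.

Real en face angiograms of the three slabs look qualitatively different:

* **SCP** — a mixed network: a handful of large arterioles/venules
  (caliber well above capillary scale) plus a fine capillary mesh.
* **DCP** — a dense, homogeneous mesh of thin capillaries whose paths
  converge radially toward an epicenter (here: the image center).
* **CC** — a granular bright texture of tightly packed capillaries,
  interrupted by irregular dark signal-void patches (flow deficits).

The generator draws vessels as smooth random-walk tubes rendered with an
anti-aliased profile, then re-thresholds the rendered field at 0.5 to obtain
an unambiguous boolean ``vessel_mask``; the centerline ground truth is the
topological skeleton of that mask.  Acquisition is simulated as the pixelwise
mean of ``n_volumes`` independent noisy frames, which is exactly what a
four-volume merge average does to frame-independent noise: averaging four
frames halves the noise standard deviation.

All outputs are pure functions of (spec, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize

from .image import (
    DEFAULT_IMAGE_SIZE,
    DEFAULT_SCALE_MM_PER_PX,
    AcquisitionMode,
    EnFaceImage,
    Plexus,
)

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "NoiseModel",
    "CohortEye",
    "generate_plexus_phantom",
    "generate_cc_phantom",
    "simulate_acquisition",
    "generate_cohort",
    "render_tube_field",
    "tube_phantom_from_paths",
]

# Intensity convention: decorrelation (flow) signal bright on dark background.
_BG_LEVEL = 20.0
_VESSEL_LEVEL = 230.0

# CC texture: bright granular background around a mid-high mean level.
_CC_MEAN = 150.0
_CC_TEXTURE_SD = 30.0
_CC_VOID_ATTENUATION = 0.88


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic plexus phantom.

    ``capillary_density_target`` is the requested fraction of image area
    covered by the vessel mask (SCP/DCP); ``void_fraction_target`` is the
    requested fraction covered by flow-deficit patches (CC only).  Calibers
    are tube diameters in pixels; at the default 3/304 mm/px sampling one
    pixel is ~10 um, so capillaries of 1-3 px and large SCP vessels of
    6-12 px correspond to ~10-30 um and ~60-120 um vessels.
    """

    plexus: Plexus
    image_size: int = DEFAULT_IMAGE_SIZE
    scale: float = DEFAULT_SCALE_MM_PER_PX
    n_large_vessels: int = 0
    capillary_density_target: float = 0.30
    vessel_caliber_range: tuple[float, float] = (1.0, 3.0)
    large_caliber_range: tuple[float, float] = (6.0, 12.0)
    void_fraction_target: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "plexus", Plexus(self.plexus))
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")
        lo, hi = self.vessel_caliber_range
        if not (0 < lo <= hi):
            raise ValueError("vessel caliber range must satisfy 0 < min <= max")
        llo, lhi = self.large_caliber_range
        if not (0 < llo <= lhi):
            raise ValueError("large caliber range must satisfy 0 < min <= max")
        if not (0.0 < self.capillary_density_target < 1.0):
            raise ValueError("capillary_density_target must lie in (0, 1)")
        if not (0.0 <= self.void_fraction_target < 1.0):
            raise ValueError("void_fraction_target must lie in [0, 1)")

    # Per-plexus defaults used throughout the package and its tests.
    @classmethod
    def scp(cls, seed: int = 0, **kw) -> "PhantomSpec":
        kw.setdefault("n_large_vessels", 6)
        kw.setdefault("capillary_density_target", 0.30)
        return cls(plexus=Plexus.SCP, seed=seed, **kw)

    @classmethod
    def dcp(cls, seed: int = 0, **kw) -> "PhantomSpec":
        kw.setdefault("capillary_density_target", 0.30)
        return cls(plexus=Plexus.DCP, seed=seed, **kw)

    @classmethod
    def cc(cls, seed: int = 0, **kw) -> "PhantomSpec":
        kw.setdefault("void_fraction_target", 0.25)
        return cls(plexus=Plexus.CC, seed=seed, **kw)


@dataclass
class GroundTruth:
    """A phantom's clean image and the masks/metrics it was drawn from."""

    clean_intensity: np.ndarray
    plexus: Plexus
    scale: float = DEFAULT_SCALE_MM_PER_PX
    vessel_mask: np.ndarray | None = None
    centerline_mask: np.ndarray | None = None
    void_mask: np.ndarray | None = None
    true_pd: float | None = None
    true_vld: float | None = None
    true_vdi: float | None = None
    true_fd: float | None = None

    def __post_init__(self) -> None:
        self.plexus = Plexus(self.plexus)
        if self.centerline_mask is not None and self.vessel_mask is not None:
            if np.any(self.centerline_mask & ~self.vessel_mask):
                raise ValueError("centerline_mask must be a subset of vessel_mask")


@dataclass(frozen=True)
class NoiseModel:
    """Acquisition-noise model applied frame-by-frame before averaging.

    ``speckle_multiplicative`` emulates the dominant OCT speckle component:
    each frame is ``clean * (1 + eps)`` with ``eps ~ N(0, sigma^2)`` (sigma is
    a *relative* amplitude), plus a small additive Gaussian floor
    (``additive_sigma``, intensity units) so that dark background pixels are
    noisy too.  ``gaussian`` is a pure additive model (sigma in intensity
    units) kept for analytic tests.
    """

    noise_kind: str = "speckle_multiplicative"
    sigma: float = 0.35
    n_volumes: int = 1
    seed: int = 0
    additive_sigma: float = 8.0

    def __post_init__(self) -> None:
        if self.noise_kind not in ("gaussian", "speckle_multiplicative"):
            raise ValueError(f"unknown noise_kind {self.noise_kind!r}")
        if self.sigma < 0 or self.additive_sigma < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if self.n_volumes < 1:
            raise ValueError("n_volumes must be >= 1")

    @classmethod
    def speckle(cls, sigma: float = 0.35, n_volumes: int = 1, seed: int = 0,
                additive_sigma: float = 8.0) -> "NoiseModel":
        return cls("speckle_multiplicative", sigma, n_volumes, seed, additive_sigma)

    @classmethod
    def gaussian(cls, sigma: float, n_volumes: int = 1, seed: int = 0) -> "NoiseModel":
        return cls("gaussian", sigma, n_volumes, seed, additive_sigma=0.0)


# ---------------------------------------------------------------------------
# Tube rendering


def _stamp_tube(edge: np.ndarray, intensity: np.ndarray, pts: np.ndarray,
                caliber: float) -> None:
    """Max-combine one tube into the edge and intensity fields in place.

    At distance d from the centerline polyline two profiles are rendered:

    * ``edge``: ``clip(caliber/2 + 0.5 - d, 0, 1)`` — 1 in the core, 0.5
      exactly at the nominal tube edge.  Re-thresholding at 0.5 recovers the
      boolean mask ``d <= caliber/2`` exactly.
    * ``intensity``: a rounded (circular cross-section) profile
      ``sqrt(1 - (d / (caliber/2 + 0.5))^2)`` emulating the smooth vessel
      profiles of real angiograms.
    """
    n = edge.shape[0]
    r = caliber / 2.0
    y0 = max(int(np.floor(pts[:, 0].min() - r - 1)), 0)
    y1 = min(int(np.ceil(pts[:, 0].max() + r + 1)), n - 1)
    x0 = max(int(np.floor(pts[:, 1].min() - r - 1)), 0)
    x1 = min(int(np.ceil(pts[:, 1].max() + r + 1)), n - 1)
    if y1 < y0 or x1 < x0:
        return
    yy, xx = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    grid = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    tree = cKDTree(pts)
    d, _ = tree.query(grid, k=1, distance_upper_bound=r + 0.5)
    e = np.clip(r + 0.5 - d, 0.0, 1.0).reshape(yy.shape)
    with np.errstate(invalid="ignore"):
        p = np.sqrt(np.clip(1.0 - (d / (r + 0.5)) ** 2, 0.0, 1.0)).reshape(yy.shape)
    np.maximum(edge[y0 : y1 + 1, x0 : x1 + 1], e,
               out=edge[y0 : y1 + 1, x0 : x1 + 1])
    np.maximum(intensity[y0 : y1 + 1, x0 : x1 + 1], p,
               out=intensity[y0 : y1 + 1, x0 : x1 + 1])


def render_tube_field(image_size: int,
                      tubes: list[tuple[np.ndarray, float]]
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Render a list of ``(polyline_points, caliber_px)`` tubes.

    Returns ``(edge_field, intensity_field)``, both in [0, 1]; the vessel
    mask is ``edge_field >= 0.5``.  Polyline points are (row, col)
    coordinates sampled densely (<= ~0.75 px apart) along the centerline.
    """
    edge = np.zeros((image_size, image_size), dtype=float)
    intensity = np.zeros((image_size, image_size), dtype=float)
    for pts, caliber in tubes:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        _stamp_tube(edge, intensity, pts, float(caliber))
    return edge, intensity


def _wrap_angle(a: np.ndarray | float) -> np.ndarray | float:
    return (a + np.pi) % (2 * np.pi) - np.pi


def _meander_path(rng: np.random.Generator, n: int, *,
                  epicenter: tuple[float, float] | None = None,
                  step: float = 0.75,
                  curvature_sd: float = 0.18,
                  steer: float = 0.12,
                  n_steps_range: tuple[int, int] = (150, 420)) -> np.ndarray:
    """A smooth random-walk centerline, optionally steered toward a point."""
    pos = rng.uniform(2.0, n - 3.0, size=2)
    heading = rng.uniform(0, 2 * np.pi)
    n_steps = int(rng.integers(*n_steps_range))
    pts = [pos.copy()]
    for _ in range(n_steps):
        heading += rng.normal(0.0, curvature_sd)
        if epicenter is not None:
            to_c = np.arctan2(epicenter[0] - pos[0], epicenter[1] - pos[1])
            heading += steer * _wrap_angle(to_c - heading)
            if np.hypot(*(pos - epicenter)) < 8.0:
                break
        nxt = pos + step * np.array([np.sin(heading), np.cos(heading)])
        # reflect off the frame edges
        for k in range(2):
            if nxt[k] < 1.0 or nxt[k] > n - 2.0:
                nxt[k] = np.clip(nxt[k], 1.0, n - 2.0)
                heading = -heading if k == 0 else np.pi - heading
        pos = nxt
        pts.append(pos.copy())
    return np.array(pts)


def _edge_crossing_path(rng: np.random.Generator, n: int, *,
                        step: float = 0.75,
                        curvature_sd: float = 0.05) -> np.ndarray:
    """A long, gently curved path entering at one edge and crossing the frame."""
    side = int(rng.integers(4))
    t = rng.uniform(0.1, 0.9) * (n - 1)
    if side == 0:  # top, heading down
        pos, heading = np.array([1.0, t]), np.pi / 2
    elif side == 1:  # bottom, heading up
        pos, heading = np.array([n - 2.0, t]), -np.pi / 2
    elif side == 2:  # left, heading right
        pos, heading = np.array([t, 1.0]), 0.0
    else:  # right, heading left
        pos, heading = np.array([t, n - 2.0]), np.pi
    heading += rng.uniform(-0.4, 0.4)
    pts = [pos.copy()]
    for _ in range(int(3 * n / step)):
        heading += rng.normal(0.0, curvature_sd)
        pos = pos + step * np.array([np.sin(heading), np.cos(heading)])
        if not (0 <= pos[0] <= n - 1 and 0 <= pos[1] <= n - 1):
            break
        pts.append(pos.copy())
    return np.array(pts)


def _ground_truth_from_field(edge: np.ndarray, intensity: np.ndarray,
                             plexus: Plexus, scale: float) -> GroundTruth:
    mask = edge >= 0.5
    centerline = skeletonize(mask)
    clean = _BG_LEVEL + (_VESSEL_LEVEL - _BG_LEVEL) * intensity
    n_center = int(centerline.sum())
    return GroundTruth(
        clean_intensity=np.clip(clean, 0.0, 255.0),
        plexus=plexus,
        scale=scale,
        vessel_mask=mask,
        centerline_mask=centerline,
        true_pd=100.0 * mask.mean(),
        true_vld=100.0 * centerline.mean(),
        true_vdi=(float(mask.sum()) / n_center) if n_center else None,
    )


def tube_phantom_from_paths(image_size: int,
                            tubes: list[tuple[np.ndarray, float]],
                            plexus: Plexus = Plexus.SCP,
                            scale: float = DEFAULT_SCALE_MM_PER_PX) -> GroundTruth:
    """Build a ground-truth phantom from explicitly given tube centerlines."""
    edge, intensity = render_tube_field(image_size, tubes)
    return _ground_truth_from_field(edge, intensity, Plexus(plexus), scale)


def generate_plexus_phantom(spec: PhantomSpec) -> GroundTruth:
    """Generate an SCP or DCP phantom meeting the spec's density target.

    Tubes are added one at a time until the vessel-mask fraction reaches
    ``capillary_density_target``; the achieved fraction is guaranteed within
    +-20% relative of the target, otherwise an error names both numbers.
    """
    plexus = Plexus(spec.plexus)
    if plexus not in (Plexus.SCP, Plexus.DCP):
        raise ValueError("generate_plexus_phantom handles SCP/DCP only")
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    edge = np.zeros((n, n), dtype=float)
    intensity = np.zeros((n, n), dtype=float)

    if plexus is Plexus.SCP:
        for _ in range(spec.n_large_vessels):
            pts = _edge_crossing_path(rng, n)
            caliber = rng.uniform(*spec.large_caliber_range)
            _stamp_tube(edge, intensity, pts, caliber)

    epicenter = ((n - 1) / 2.0, (n - 1) / 2.0) if plexus is Plexus.DCP else None
    target = spec.capillary_density_target
    max_tubes = 6000
    frac = (edge >= 0.5).mean()
    n_tubes = 0
    while frac < target and n_tubes < max_tubes:
        pts = _meander_path(rng, n, epicenter=epicenter)
        caliber = rng.uniform(*spec.vessel_caliber_range)
        _stamp_tube(edge, intensity, pts, caliber)
        frac = (edge >= 0.5).mean()
        n_tubes += 1
    if not (0.8 * target <= frac <= 1.2 * target):
        raise RuntimeError(
            f"vessel density target unreachable: achieved {frac:.4f} vs "
            f"requested {target:.4f} after {n_tubes} tubes"
        )
    return _ground_truth_from_field(edge, intensity, plexus, spec.scale)


def generate_cc_phantom(spec: PhantomSpec) -> GroundTruth:
    """Generate a choriocapillaris phantom: granular texture + void patches."""
    if Plexus(spec.plexus) is not Plexus.CC:
        raise ValueError("generate_cc_phantom requires plexus=CC")
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    # band-limited granular background texture
    tex = gaussian_filter(rng.standard_normal((n, n)), sigma=1.6)
    tex = (tex - tex.mean()) / tex.std()
    background = _CC_MEAN + _CC_TEXTURE_SD * tex

    target = spec.void_fraction_target
    raw = np.zeros((n, n), dtype=bool)
    yy, xx = np.mgrid[0:n, 0:n]
    n_blobs = 0
    max_blobs = 4000
    while raw.mean() < target and n_blobs < max_blobs:
        cy, cx = rng.uniform(0, n - 1, size=2)
        a = rng.uniform(3.0, 14.0)
        b = a * rng.uniform(0.4, 1.0)
        theta = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(theta) - dx * np.sin(theta)
        v = dy * np.sin(theta) + dx * np.cos(theta)
        raw |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
        n_blobs += 1
    if target == 0.0:
        void = raw  # all false: zero blobs requested
    else:
        # smooth and re-threshold so merged patches get irregular outlines
        void = gaussian_filter(raw.astype(float), sigma=1.0) > 0.5
        if not (0.8 * target <= void.mean() <= 1.2 * target):
            raise RuntimeError(
                f"void fraction target unreachable: achieved {void.mean():.4f} "
                f"vs requested {target:.4f} after {n_blobs} blobs"
            )
    void_soft = gaussian_filter(void.astype(float), sigma=0.8)
    clean = background * (1.0 - _CC_VOID_ATTENUATION * void_soft)
    return GroundTruth(
        clean_intensity=np.clip(clean, 0.0, 255.0),
        plexus=Plexus.CC,
        scale=spec.scale,
        void_mask=void,
        true_fd=100.0 * void.mean(),
    )


# ---------------------------------------------------------------------------
# Acquisition simulation


def simulate_acquisition(gt: GroundTruth, noise: NoiseModel,
                         eye_id: str = "") -> EnFaceImage:
    """Image a phantom as the mean of ``n_volumes`` independent noisy frames.

    With sigma = 0 the output equals the clean intensity exactly.  The
    acquisition mode is recorded as V1 for a single volume and V4 otherwise.
    """
    rng = np.random.default_rng(noise.seed)
    clean = gt.clean_intensity
    acc = np.zeros_like(clean)
    for _ in range(noise.n_volumes):
        if noise.noise_kind == "gaussian":
            frame = clean + (rng.normal(0.0, noise.sigma, clean.shape)
                             if noise.sigma > 0 else 0.0)
        else:
            frame = clean.copy()
            if noise.sigma > 0:
                frame = frame * (1.0 + rng.normal(0.0, noise.sigma, clean.shape))
            if noise.additive_sigma > 0:
                frame = frame + rng.normal(0.0, noise.additive_sigma, clean.shape)
        acc += frame
    img = np.clip(acc / noise.n_volumes, 0.0, 255.0)
    mode = AcquisitionMode.V1 if noise.n_volumes == 1 else AcquisitionMode.V4
    return EnFaceImage(pixels=img, plexus=gt.plexus, acquisition_mode=mode,
                       scale=gt.scale, eye_id=eye_id)


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass
class CohortEye:
    """One synthetic eye: per-plexus ground truth and its V1/V4 images."""

    eye_id: str
    truth: dict[Plexus, GroundTruth]
    images: dict[tuple[Plexus, AcquisitionMode], EnFaceImage]


def _jittered_spec(spec: PhantomSpec, rng: np.random.Generator,
                   seed: int, jitter: float) -> PhantomSpec:
    f_dens = 1.0 + rng.uniform(-jitter, jitter)
    f_cal = 1.0 + rng.uniform(-jitter, jitter)
    lo, hi = spec.vessel_caliber_range
    llo, lhi = spec.large_caliber_range
    return dataclasses.replace(
        spec,
        seed=seed,
        capillary_density_target=min(max(spec.capillary_density_target * f_dens,
                                         1e-3), 0.95),
        void_fraction_target=min(spec.void_fraction_target * f_dens, 0.95),
        vessel_caliber_range=(lo * f_cal, hi * f_cal),
        large_caliber_range=(llo * f_cal, lhi * f_cal),
    )


def generate_cohort(n_eyes: int,
                    specs: dict[Plexus, PhantomSpec] | None = None,
                    noise_v1: NoiseModel | None = None,
                    noise_v4: NoiseModel | None = None,
                    seed: int = 0,
                    jitter: float = 0.10) -> list[CohortEye]:
    """Generate ``n_eyes`` independent phantoms imaged under V1 and V4.

    Each eye receives its own seeded phantom per plexus, with density and
    caliber targets jittered by +-``jitter`` relative so that the cohort has
    between-eye variance, and is imaged under both noise models with
    eye-specific noise seeds.
    """
    if n_eyes < 2:
        raise ValueError("a cohort needs n_eyes >= 2")
    if specs is None:
        specs = {
            Plexus.SCP: PhantomSpec.scp(),
            Plexus.DCP: PhantomSpec.dcp(),
            Plexus.CC: PhantomSpec.cc(),
        }
    if noise_v1 is None:
        noise_v1 = NoiseModel.speckle(n_volumes=1)
    if noise_v4 is None:
        noise_v4 = NoiseModel.speckle(sigma=noise_v1.sigma, n_volumes=4,
                                      additive_sigma=noise_v1.additive_sigma)
    eyes: list[CohortEye] = []
    for e in range(n_eyes):
        eye_id = f"eye{e + 1:02d}"
        truth: dict[Plexus, GroundTruth] = {}
        images: dict[tuple[Plexus, AcquisitionMode], EnFaceImage] = {}
        for p_idx, (plexus, spec) in enumerate(sorted(specs.items(),
                                                      key=lambda kv: kv[0].value)):
            ss = np.random.SeedSequence([seed, e, p_idx])
            states = ss.generate_state(4)
            jit_rng = np.random.default_rng(states[0])
            spec_e = _jittered_spec(spec, jit_rng, int(states[1] % 2**31), jitter)
            if Plexus(plexus) is Plexus.CC:
                gt = generate_cc_phantom(spec_e)
            else:
                gt = generate_plexus_phantom(spec_e)
            truth[Plexus(plexus)] = gt
            for m_idx, base in enumerate((noise_v1, noise_v4)):
                nm = dataclasses.replace(base, seed=int(states[2 + m_idx] % 2**31))
                img = simulate_acquisition(gt, nm, eye_id=eye_id)
                images[(Plexus(plexus), img.acquisition_mode)] = img
        eyes.append(CohortEye(eye_id=eye_id, truth=truth, images=images))
    return eyes
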