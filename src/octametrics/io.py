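"""File I/O: 8-bit grayscale TIFF/PNG images, masks, and truth sidecars.

File naming follows ``<eyeID>_<plexus>_<mode>.tif`` (e.g.
``eye03_SCP_V4.tif``); ground truth is a JSON sidecar per eye holding the
scalar truth values.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .image import AcquisitionMode, EnFaceImage, Plexus
from .synthetic import GroundTruth

__all__ = [
    "write_image",
    "read_image",
    "write_mask",
    "write_truth_sidecar",
    "image_filename",
    "parse_image_filename",
]


def image_filename(eye_id: str, plexus: Plexus | str,
                   mode: AcquisitionMode | str, ext: str = "tif") -> str:
    return f"{eye_id}_{Plexus(plexus).value}_{AcquisitionMode(mode).value}.{ext}"


def parse_image_filename(path: str | Path) -> tuple[str, Plexus, AcquisitionMode]:
    """Recover (eye_id, plexus, mode) from the naming convention."""
    stem = Path(path).stem
    parts = stem.rsplit("_", 2)
    if len(parts) != 3:
        raise ValueError(f"unrecognized image filename {Path(path).name!r}")
    eye_id, plexus, mode = parts
    return eye_id, Plexus(plexus), AcquisitionMode(mode)


def _to_uint8(pixels: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(np.asarray(pixels, float)), 0, 255).astype(np.uint8)


def write_image(img: EnFaceImage, path: str | Path) -> None:
    """Write as 8-bit grayscale TIFF or PNG (by extension)."""
    path = Path(path)
    data = _to_uint8(img.pixels)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        Image.fromarray(data, mode="L").save(path)


def read_image(path: str | Path,
               plexus: Plexus | None = None,
               acquisition_mode: AcquisitionMode | None = None,
               eye_id: str | None = None) -> EnFaceImage:
    """Read an 8-bit grayscale image; metadata from the filename if omitted."""
    path = Path(path)
    if plexus is None or acquisition_mode is None or eye_id is None:
        f_eye, f_plexus, f_mode = parse_image_filename(path)
        eye_id = eye_id if eye_id is not None else f_eye
        plexus = plexus if plexus is not None else f_plexus
        acquisition_mode = (acquisition_mode if acquisition_mode is not None
                            else f_mode)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = np.asarray(Image.open(path).convert("L"))
    return EnFaceImage(pixels=np.asarray(data, float), plexus=plexus,
                       acquisition_mode=acquisition_mode, eye_id=eye_id)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean grid as an 8-bit {0, 255} TIFF."""
    data = (np.asarray(mask, bool).astype(np.uint8)) * 255
    tifffile.imwrite(Path(path), data)


def write_truth_sidecar(eye_id: str, truths: dict[Plexus, GroundTruth],
                        path: str | Path) -> None:
    """JSON sidecar with the scalar ground-truth values of one eye."""
    payload: dict = {"eye_id": eye_id}
    for plexus, gt in truths.items():
        payload[Plexus(plexus).value] = {
            "true_pd": gt.true_pd,
            "true_vld": gt.true_vld,
            "true_vdi": gt.true_vdi,
            "true_fd": gt.true_fd,
        }
    Path(path).write_text(json.dumps(payload, indent=2))
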