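"""Image preprocessing: grayscale conversion, resizing, min-max normalization.

Input smear images arrive in heterogeneous sizes and color modes; every
downstream stage (GAN augmentation, superpixel graph construction) assumes a
fixed-size single-channel raster with values in [0, 1]. The canonical side
length is 226 pixels.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize as _sk_resize

DEFAULT_SIDE = 226

#: ITU-R BT.601 luminance weights for R, G, B.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

CLASS_LABELS = ("ALL", "AML")


@dataclass
class ImageSample:
    """One labeled image: pixel raster, class label and provenance id."""

    pixels: np.ndarray
    label: str | None = None
    source_id: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse a 3-channel raster to single-channel luminance.

    Uses BT.601 weights 0.299 R + 0.587 G + 0.114 B. Single-channel input
    (2-D, or trailing axis of length 1) is passed through unchanged.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] == 1:
        return arr[:, :, 0]
    if arr.ndim == 3 and arr.shape[2] == 3:
        return arr @ LUMA_WEIGHTS
    raise ValueError(
        f"expected 1 or 3 channels, got array of shape {arr.shape}"
    )


def resize_image(image: np.ndarray, side: int) -> np.ndarray:
    """Resize a 2-D raster to ``side`` x ``side`` by bilinear interpolation.

    Anti-aliasing is applied when downscaling. Value range is preserved up to
    interpolation tolerance.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("expected a non-empty 2-D raster")
    if side < 2:
        raise ValueError(f"side must be >= 2, got {side}")
    if arr.shape == (side, side):
        return arr.copy()
    downscale = side < min(arr.shape)
    return _sk_resize(
        arr,
        (side, side),
        order=1,
        mode="reflect",
        anti_aliasing=downscale,
        preserve_range=True,
    )


def minmax_normalize(image: np.ndarray) -> np.ndarray:
    """Affinely rescale a raster to [0, 1] by its own min and max.

    A constant raster maps to all zeros (min maps to 0).
    """
    arr = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("raster contains NaN or Inf")
    lo = arr.min()
    hi = arr.max()
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def preprocess_image(image: np.ndarray, side: int = DEFAULT_SIDE) -> np.ndarray:
    """Full preprocessing chain: grayscale -> resize -> min-max normalize."""
    return minmax_normalize(resize_image(to_grayscale(image), side))


def load_image(path: str | Path) -> np.ndarray:
    """Decode a PNG/TIFF/JPEG file to a float array (grayscale or RGB).

    8- and 16-bit integer inputs are accepted; values are returned on their
    native scale (normalization happens later, per image).
    """
    with Image.open(path) as im:
        if im.mode in ("RGBA", "P", "CMYK"):
            im = im.convert("RGB")
        arr = np.asarray(im, dtype=float)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return arr


def load_manifest(manifest_path: str | Path) -> list[tuple[Path, str]]:
    """Read a ``path,label`` CSV manifest; relative paths resolve against the
    manifest's own directory. Labels must be ALL or AML."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    entries: list[tuple[Path, str]] = []
    with open(manifest_path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"path", "label"} <= set(
            reader.fieldnames
        ):
            raise ValueError("manifest must have a 'path,label' header")
        for row in reader:
            label = row["label"].strip()
            if label not in CLASS_LABELS:
                raise ValueError(f"unknown label {label!r} in manifest")
            p = Path(row["path"])
            if not p.is_absolute():
                p = base / p
            entries.append((p, label))
    return entries


def load_dataset(
    manifest_path: str | Path, side: int = DEFAULT_SIDE
) -> list[ImageSample]:
    """Load and preprocess every image listed in a manifest."""
    samples = []
    for path, label in load_manifest(manifest_path):
        raw = load_image(path)
        samples.append(
            ImageSample(
                pixels=preprocess_image(raw, side=side),
                label=label,
                source_id=str(path),
            )
        )
    return samples
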