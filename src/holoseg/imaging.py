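"""Raster image I/O and the standard preprocessing protocol.

Every image entering the pipeline is held as a :class:`RasterImage`: a float
array in [0, 1] tagged with its color space. The preprocessing protocol applied
to blood-smear micrographs is: resize to 224x224, min-max normalise to [0, 1],
convert RGB to HSV, select one channel (V by default), and invert so the dark
leukocyte becomes the bright dominant object.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from skimage import color as _skcolor
from skimage import transform as _sktransform

from .errors import DataError, FormatError, ParameterError, StateError

STANDARD_SIDE = 224

#: Closed label vocabulary of the four leukemia classes.
CLASS_LABELS = ("benign", "malignant-early", "malignant-pre", "malignant-pro")
UNCLASSIFIED = "unclassified"


@dataclass
class RasterImage:
    """Float raster in [0, 1] with a color-space tag.

    GRAY images are stored as 2-D ``(H, W)`` arrays; RGB/HSV as ``(H, W, 3)``.
    """

    pixels: np.ndarray
    color_space: str  # "RGB" | "HSV" | "GRAY"
    source_path: Optional[str] = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.color_space not in ("RGB", "HSV", "GRAY"):
            raise ParameterError(f"unknown color space {self.color_space!r}")
        if self.color_space == "GRAY":
            if self.pixels.ndim == 3 and self.pixels.shape[2] == 1:
                self.pixels = self.pixels[:, :, 0]
            if self.pixels.ndim != 2:
                raise ParameterError("GRAY image must be a single plane")
        else:
            if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
                raise ParameterError(f"{self.color_space} image must have 3 channels")
        h, w = self.pixels.shape[:2]
        if h < 8 or w < 8:
            raise ParameterError(f"image too small: {h}x{w} (need at least 8x8)")
        if not np.all(np.isfinite(self.pixels)):
            raise ParameterError("image contains non-finite values")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ParameterError("image values must lie in [0, 1]")
        self.pixels = np.clip(self.pixels, 0.0, 1.0)

    @property
    def shape(self):
        return self.pixels.shape[:2]


@dataclass
class BinaryMask:
    """H x W array of {0, 1}; positive pixels mean "cell"."""

    pixels: np.ndarray
    positive_meaning: str = "cell"

    def __post_init__(self):
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ParameterError("mask must be 2-D")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ParameterError("mask values must be 0 or 1")
        self.pixels = arr.astype(np.uint8)

    @property
    def shape(self):
        return self.pixels.shape

    def area(self) -> int:
        return int(self.pixels.sum())


@dataclass
class DatasetManifest:
    """Table of (image_path, optional mask_path, optional class label) records."""

    records: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["image_path", "mask_path", "label"]))

    def __post_init__(self):
        required = {"image_path", "mask_path", "label"}
        missing = required - set(self.records.columns)
        if missing:
            raise ParameterError(f"manifest missing columns: {sorted(missing)}")
        labels = self.records["label"].dropna()
        bad = set(labels) - set(CLASS_LABELS) - {""}
        if bad:
            raise ParameterError(f"unknown class labels in manifest: {sorted(bad)}")

    def __len__(self):
        return len(self.records)

    @classmethod
    def read_csv(cls, path) -> "DatasetManifest":
        if not os.path.exists(path):
            raise DataError(f"manifest not found: {path}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        df = df.replace({"": None})
        return cls(records=df)

    def write_csv(self, path) -> None:
        df = self.records.fillna("")
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_image(path) -> RasterImage:
    """Read a PNG/JPEG/TIFF/BMP image, scaling 8/16-bit values into [0, 1].

    3-channel input is tagged RGB, single-channel GRAY; a 4th (alpha) channel
    is dropped. Other channel counts are rejected.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise DataError(f"cannot read image: no such file {path!r}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # unreadable / truncated
        raise DataError(f"cannot read image {path!r}: {exc}") from exc
    if arr.dtype == np.uint8:
        pix = arr.astype(np.float64) / 255.0
    elif arr.dtype == np.uint16:
        pix = arr.astype(np.float64) / 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        pix = arr.astype(np.float64)
    else:
        raise FormatError(f"unsupported pixel dtype {arr.dtype} in {path!r}")
    if pix.ndim == 2:
        return RasterImage(pix, "GRAY", source_path=path)
    if pix.ndim == 3 and pix.shape[2] == 4:
        pix = pix[:, :, :3]
    if pix.ndim == 3 and pix.shape[2] == 3:
        return RasterImage(pix, "RGB", source_path=path)
    raise FormatError(
        f"unsupported channel count {pix.shape[2] if pix.ndim == 3 else pix.ndim} in {path!r}")


def write_image(img: RasterImage, path) -> None:
    """Write as 8-bit PNG/BMP/JPEG, or 32-bit float TIFF for .tif/.tiff paths."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        tifffile.imwrite(path, img.pixels.astype(np.float32))
        return
    arr = np.clip(np.round(img.pixels * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(path, arr)


def read_mask(path) -> BinaryMask:
    """Read a single-channel {0, 255} PNG mask, mapping to {0, 1}."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise DataError(f"cannot read mask: no such file {path!r}")
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return BinaryMask((arr > 127).astype(np.uint8))


def write_mask(mask: BinaryMask, path) -> None:
    iio.imwrite(os.fspath(path), (mask.pixels * 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# Preprocessing protocol
# ---------------------------------------------------------------------------

def resize_to_standard(img: RasterImage, side: int = STANDARD_SIDE) -> RasterImage:
    """Bilinear resize to ``side`` x ``side`` (anti-aliased on downscale)."""
    if side < 8:
        raise ParameterError(f"target side {side} too small (minimum 8)")
    if img.shape == (side, side):
        return RasterImage(img.pixels.copy(), img.color_space, img.source_path)
    downscale = side < max(img.shape)
    out = _sktransform.resize(
        img.pixels, (side, side), order=1, mode="edge",
        anti_aliasing=downscale, preserve_range=True)
    return RasterImage(np.clip(out, 0.0, 1.0), img.color_space, img.source_path)


def normalize_intensity(img: RasterImage) -> RasterImage:
    """Per-image min-max rescale onto exactly [0, 1]; constant images map to 0."""
    lo = img.pixels.min()
    hi = img.pixels.max()
    if hi - lo < 1e-12:
        out = np.zeros_like(img.pixels)
    else:
        out = (img.pixels - lo) / (hi - lo)
    return RasterImage(out, img.color_space, img.source_path)


def rgb_to_hsv(img: RasterImage) -> RasterImage:
    """Standard RGB -> HSV conversion, all channels in [0, 1]."""
    if img.color_space != "RGB":
        raise StateError(f"rgb_to_hsv needs RGB input, got {img.color_space}")
    hsv = _skcolor.rgb2hsv(img.pixels)
    return RasterImage(np.clip(hsv, 0.0, 1.0), "HSV", img.source_path)


def hsv_to_rgb(img: RasterImage) -> RasterImage:
    if img.color_space != "HSV":
        raise StateError(f"hsv_to_rgb needs HSV input, got {img.color_space}")
    rgb = _skcolor.hsv2rgb(img.pixels)
    return RasterImage(np.clip(rgb, 0.0, 1.0), "RGB", img.source_path)


def select_channel(img: RasterImage, channel: str) -> RasterImage:
    """Extract the H, S or V plane of an HSV image as a GRAY image."""
    if img.color_space != "HSV":
        raise StateError(f"select_channel needs HSV input, got {img.color_space}")
    idx = {"H": 0, "S": 1, "V": 2}.get(channel.upper())
    if idx is None:
        raise ParameterError(f"channel must be H, S or V, got {channel!r}")
    return RasterImage(img.pixels[:, :, idx].copy(), "GRAY", img.source_path)


def invert(img: RasterImage) -> RasterImage:
    """Pixelwise 1 - value; used so dark leukocytes become bright objects."""
    if img.color_space != "GRAY":
        raise StateError(f"invert needs GRAY input, got {img.color_space}")
    return RasterImage(1.0 - img.pixels, "GRAY", img.source_path)


def preprocess(img: RasterImage, side: int = STANDARD_SIDE, channel: str = "V",
               do_invert: bool = True) -> RasterImage:
    """Full protocol: resize, normalise, RGB->HSV, channel select, invert."""
    out = resize_to_standard(img, side)
    out = normalize_intensity(out)
    if out.color_space == "RGB":
        out = rgb_to_hsv(out)
        out = select_channel(out, channel)
    if do_invert:
        out = invert(out)
    return out
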