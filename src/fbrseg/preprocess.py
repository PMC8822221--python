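"""Image containers, file I/O and the intensity preprocessing chain.

Multiphoton slices arrive as integer TIFF pages (one page per channel);
internally every image is a float array in ``[0, 1]`` with a physical pixel
size attached.  The fibroblast/collagen preprocessing chain is min-max
normalization, gamma correction (``gamma = 0.5``) and histogram stretching
against a 50-pixel count threshold, followed by a bicubic resize from the
native 1064 px to the 512 px network input.  Label masks are resized with
nearest-neighbour interpolation only, so class codes stay crisp.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile
from skimage.transform import resize as _sk_resize

#: native acquisition geometry: 360 x 360 um imaged at 1064 x 1064 px
NATIVE_SIZE = 1064
NATIVE_PIXEL_SIZE_UM = 360.0 / 1064.0
NETWORK_INPUT_SIZE = 512

CHANNELS = ("GFP", "RFP", "SHG", "THG")


@dataclass
class IntensityImage:
    """One 2D grayscale channel slice with physical pixel size in um/px."""

    pixels: np.ndarray
    pixel_size: float = NATIVE_PIXEL_SIZE_UM
    channel: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("IntensityImage requires a non-empty 2D array")
        if self.channel is not None and self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}, expected one of {CHANNELS}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class MulticlassMask:
    """Integer class labels; 0=background, 1=scaffold-associated, 2=interstitial
    for the immune task, {0, 1} for binary tasks."""

    labels: np.ndarray
    n_classes: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = np.asarray(self.labels)
            if not np.allclose(lab, np.round(lab)):
                raise ValueError("mask labels must be integers")
            self.labels = lab.astype(np.int64)
        if self.labels.ndim != 2:
            raise ValueError("mask must be 2D")
        if self.labels.min() < 0:
            raise ValueError("negative class labels are not allowed")
        if self.n_classes is None:
            self.n_classes = int(self.labels.max()) + 1
        elif self.labels.max() >= self.n_classes:
            raise ValueError("label value exceeds n_classes")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def one_hot(self) -> np.ndarray:
        """(n_classes, H, W) one-hot view; sums to 1 at every pixel."""
        return np.stack([(self.labels == c).astype(np.float64) for c in range(self.n_classes)])


# ---------------------------------------------------------------------------
# intensity preprocessing


def normalize_minmax(img: IntensityImage) -> IntensityImage:
    """Linearly remap intensities to span [0, 1].

    A constant image has no dynamic range and maps to all zeros.
    """
    p = img.pixels
    lo, hi = float(p.min()), float(p.max())
    if hi == lo:
        return replace(img, pixels=np.zeros_like(p))
    return replace(img, pixels=(p - lo) / (hi - lo))


def gamma_correct(img: IntensityImage, gamma: float = 0.5) -> IntensityImage:
    """Power-law remap ``v -> v**gamma`` on a [0, 1] image.

    gamma < 1 expands dim structures; 0 and 1 are fixed points.
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    return replace(img, pixels=np.clip(img.pixels, 0.0, 1.0) ** gamma)


def histogram_stretch(
    img: IntensityImage, count_threshold: int = 50, n_bins: int = 256
) -> IntensityImage:
    """Stretch the densely populated intensity range to [0, 1].

    The lowest and highest of ``n_bins`` uniform levels whose pixel count
    exceeds ``count_threshold`` are remapped to 0 and 1; values landing
    outside [0, 1] are saturated.  If a single dense level exists the result
    is all zeros; if none exists the image is returned unchanged.
    """
    p = np.clip(img.pixels, 0.0, 1.0)
    counts, edges = np.histogram(p, bins=n_bins, range=(0.0, 1.0))
    dense = np.nonzero(counts > count_threshold)[0]
    if dense.size == 0:
        return replace(img, pixels=p)
    centers = (edges[:-1] + edges[1:]) / 2.0
    lo, hi = centers[dense[0]], centers[dense[-1]]
    if hi == lo:
        return replace(img, pixels=np.zeros_like(p))
    return replace(img, pixels=np.clip((p - lo) / (hi - lo), 0.0, 1.0))


def preprocess_chain(
    img: IntensityImage,
    gamma: float = 0.5,
    stretch_count_threshold: int = 50,
) -> IntensityImage:
    """Normalize -> gamma-correct -> histogram-stretch (fibroblast/collagen chain)."""
    out = normalize_minmax(img)
    out = gamma_correct(out, gamma=gamma)
    return histogram_stretch(out, count_threshold=stretch_count_threshold)


# ---------------------------------------------------------------------------
# resizing


def resize_bicubic(img: IntensityImage, target: int = NETWORK_INPUT_SIZE) -> IntensityImage:
    """Bicubic resize to ``target x target``; pixel size rescaled accordingly."""
    if target < 2:
        raise ValueError("target size must be >= 2")
    out = _sk_resize(
        img.pixels, (target, target), order=3, mode="edge",
        anti_aliasing=img.width > target, preserve_range=True,
    )
    scale = img.width / target
    return replace(img, pixels=out, pixel_size=img.pixel_size * scale)


def resize_labels(mask: MulticlassMask, target: int) -> MulticlassMask:
    """Nearest-neighbour label resize; never invents class codes."""
    if target < 1:
        raise ValueError("target size must be >= 1")
    out = _sk_resize(
        mask.labels, (target, target), order=0, mode="edge",
        anti_aliasing=False, preserve_range=True,
    ).astype(mask.labels.dtype)
    return MulticlassMask(out, n_classes=mask.n_classes)


def upsample_mask_nearest(mask: MulticlassMask, target: int = NATIVE_SIZE) -> MulticlassMask:
    """Restore a predicted mask to acquisition resolution (nearest neighbour)."""
    return resize_labels(mask, target)


# ---------------------------------------------------------------------------
# file I/O


def _rescale_integer(page: np.ndarray) -> np.ndarray:
    if np.issubdtype(page.dtype, np.integer):
        return page.astype(np.float64) / np.iinfo(page.dtype).max
    return page.astype(np.float64)


def read_image(
    path: str | Path,
    page: int = 0,
    channel: str | None = None,
    pixel_size: float | None = None,
) -> IntensityImage:
    """Read one page of a single- or multi-page TIFF as an IntensityImage.

    8/16-bit integer data are rescaled by the dtype maximum; float data are
    taken as-is.
    """
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.pages[page].asarray()
    if arr.ndim == 3:  # channel-last RGB-style page: take first plane
        arr = arr[..., 0]
    pix = _rescale_integer(arr)
    if pixel_size is None:
        pixel_size = NATIVE_PIXEL_SIZE_UM * (NATIVE_SIZE / arr.shape[1])
    return IntensityImage(pix, pixel_size=pixel_size, channel=channel)


def write_image(path: str | Path, img: IntensityImage) -> None:
    """Write preprocessed pixels as 32-bit float TIFF."""
    tifffile.imwrite(str(path), img.pixels.astype(np.float32))


def read_mask(path: str | Path, n_classes: int | None = None) -> MulticlassMask:
    """Read an integer-coded single-channel PNG/TIFF mask."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        arr = iio.imread(str(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return MulticlassMask(arr.astype(np.int64), n_classes=n_classes)


def write_mask(path: str | Path, mask: MulticlassMask) -> None:
    path = Path(path)
    data = mask.labels.astype(np.uint16)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(str(path), data)
    else:
        import imageio.v3 as iio

        iio.imwrite(str(path), data)
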