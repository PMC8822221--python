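"""Scaffold-relative collagen orientation via a bank of directional kernels.

The classic 8-direction compass-mask edge detector is generalized to an
arbitrary angular resolution: one antisymmetric 33x33 edge kernel per degree,
360 in total.  For a kernel at angle ``theta`` every coefficient starts as
the perpendicular pixel distance to the line through the kernel center at
that angle; distances in [0, 1] are kept, distances in [1, 2] ramp linearly
back down to 0, larger ones are zeroed.  Coefficients on the clockwise side
of the line are negated, support is clipped to a 15-px radius, and positive
and negative coefficients are normalized to sum to +1 and -1, so every
kernel sums to 0 and responses are comparable across angles.

Because ``K(theta + 180) = -K(theta)`` exactly, the signed maximum response
over all 360 kernels equals the maximum absolute response over the 180
distinct orientations; the response engine therefore convolves with half the
bank.  Orientation maps are post-processed by a variance filter over the
top-36 response magnitudes, exclusion of pixels under the dilated scaffold
mask, and an 8-connectivity cluster-size filter, then summarized as a
180-bin histogram smoothed by a circular 7-bin moving average whose argmax
is the preferential orientation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import fft as sfft
from scipy import ndimage
from skimage.morphology import skeletonize

NOT_ORIENTED = -1

SCAFFOLD_MAGNITUDE_THRESHOLD = 0.5
COLLAGEN_MAGNITUDE_THRESHOLD = 0.06
VARIANCE_THRESHOLD = 0.35e-3
TOP_K_VARIANCE = 36
MIN_CLUSTER_AREA = 15
BORDER_WIDTH = 4
HISTOGRAM_WINDOW = 7


# ---------------------------------------------------------------------------
# kernel bank


@dataclass
class OrientationKernelBank:
    """360 antisymmetric edge kernels at 1-degree angular resolution."""

    kernels: np.ndarray          # (n_angles, size, size)
    size: int
    radius: int
    n_angles: int
    _fft_cache: dict = field(default_factory=dict, repr=False)

    @property
    def angle_step(self) -> float:
        return 360.0 / self.n_angles

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), kernels=self.kernels)
        path.with_suffix(".json").write_text(
            json.dumps({"size": self.size, "radius": self.radius, "n_angles": self.n_angles})
        )

    @classmethod
    def load(cls, path: str | Path) -> "OrientationKernelBank":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        kernels = np.load(path.with_suffix(".npz"))["kernels"]
        return cls(kernels=kernels, **meta)


def build_kernel_bank(
    size: int = 33, radius: int = 15, n_angles: int = 360
) -> OrientationKernelBank:
    """Construct the directional edge-kernel bank.

    ``size`` must be odd (center pixel at index ``size // 2``) and ``radius``
    must fit inside the kernel.  Angle 0 points along the image rows
    (horizontal), increasing counterclockwise.
    """
    if size % 2 == 0:
        raise ValueError("kernel size must be odd")
    if radius > (size - 1) // 2:
        raise ValueError("radius must fit within the kernel")
    c = size // 2
    rows, cols = np.mgrid[0:size, 0:size]
    dr = (rows - c).astype(np.float64)
    dc = (cols - c).astype(np.float64)
    outside = dr**2 + dc**2 > radius**2

    kernels = np.zeros((n_angles, size, size))
    for i in range(n_angles):
        theta = np.deg2rad(i * 360.0 / n_angles)
        # line direction (row, col) = (-sin t, cos t); signed distance via cross product
        cross = -np.sin(theta) * dc - np.cos(theta) * dr
        d = np.abs(cross)
        coeff = np.where(d <= 1.0, d, np.where(d <= 2.0, 2.0 - d, 0.0))
        coeff = coeff * np.sign(cross)          # clockwise half-plane negated
        coeff[outside] = 0.0
        pos = coeff[coeff > 0].sum()
        neg = -coeff[coeff < 0].sum()
        coeff = np.where(coeff > 0, coeff / pos, coeff)
        coeff = np.where(coeff < 0, coeff / neg, coeff)
        kernels[i] = coeff
    return OrientationKernelBank(kernels=kernels, size=size, radius=radius, n_angles=n_angles)


def orientation_responses(img: np.ndarray, bank: OrientationKernelBank) -> np.ndarray:
    """Correlation responses of the half-bank: (n_angles/2, H, W) float32.

    Zero-padded linear correlation computed by FFT; by bank antisymmetry the
    absolute values of these responses carry the full 360-kernel information.
    """
    img = np.asarray(img, dtype=np.float64)
    h, w = img.shape
    half = bank.n_angles // 2
    k = bank.size
    fh = sfft.next_fast_len(h + k - 1)
    fw = sfft.next_fast_len(w + k - 1)
    img_f = sfft.rfft2(img, s=(fh, fw))

    key = (fh, fw)
    if key not in bank._fft_cache:
        nbytes = half * fh * (fw // 2 + 1) * 16
        ker_f = sfft.rfft2(bank.kernels[:half], s=(fh, fw), axes=(1, 2))
        if nbytes < 256 * 2**20:  # cache only when modest
            bank._fft_cache[key] = ker_f
    else:
        ker_f = bank._fft_cache[key]

    # correlation = convolution with the flipped kernel = -K, so negate
    full = sfft.irfft2(img_f[None] * ker_f, s=(fh, fw), axes=(1, 2))
    off = k // 2
    return (-full[:, off : off + h, off : off + w]).astype(np.float32)


# ---------------------------------------------------------------------------
# orientation maps


@dataclass
class OrientationMap:
    """Per-pixel orientation in integer degrees [0, 180) or NOT_ORIENTED (-1)."""

    angle: np.ndarray
    magnitude: np.ndarray
    response_stack: np.ndarray | None = None   # (180, H, W) |responses|

    @property
    def oriented(self) -> np.ndarray:
        return self.angle != NOT_ORIENTED

    def copy(self) -> "OrientationMap":
        return OrientationMap(self.angle.copy(), self.magnitude.copy(), self.response_stack)


def orientation_map(
    img: np.ndarray,
    bank: OrientationKernelBank,
    magnitude_threshold: float,
    border: int = BORDER_WIDTH,
    keep_stack: bool = True,
) -> OrientationMap:
    """Assign each pixel the angle of its maximum-response kernel.

    Pixels whose maximum response does not exceed ``magnitude_threshold`` and
    pixels on the width-``border`` frame are NOT_ORIENTED.  Response ties go
    to the smallest angle.
    """
    mags = np.abs(orientation_responses(img, bank))
    idx = mags.argmax(axis=0)
    mag = np.take_along_axis(mags, idx[None], axis=0)[0]
    angle = np.round(idx * bank.angle_step).astype(np.int16) % 180
    angle = np.where(mag > magnitude_threshold, angle, NOT_ORIENTED).astype(np.int16)
    if border > 0:
        angle[:border, :] = NOT_ORIENTED
        angle[-border:, :] = NOT_ORIENTED
        angle[:, :border] = NOT_ORIENTED
        angle[:, -border:] = NOT_ORIENTED
    return OrientationMap(angle, mag, response_stack=mags if keep_stack else None)


def variance_filter(
    omap: OrientationMap,
    top_k: int = TOP_K_VARIANCE,
    var_threshold: float = VARIANCE_THRESHOLD,
) -> OrientationMap:
    """Drop weakly oriented pixels: variance of the top-``top_k`` response
    magnitudes below ``var_threshold`` means many kernels responded alike."""
    if omap.response_stack is None:
        raise ValueError("orientation map was computed without its response stack")
    mags = omap.response_stack
    top = np.partition(mags, mags.shape[0] - top_k, axis=0)[-top_k:]
    var = top.var(axis=0)  # population variance over the top-k responses
    out = omap.copy()
    out.angle = np.where(var < var_threshold, NOT_ORIENTED, out.angle).astype(np.int16)
    return out


def mask_exclusion(
    omap: OrientationMap, dilated_scaffold: np.ndarray, keep_outside: bool = True
) -> OrientationMap:
    """Remove collagen orientations confounded by the scaffold.

    With ``keep_outside`` (default) pixels covered by the dilated scaffold
    mask are discarded; the switch inverts the rule for the literal
    outside-discarding reading.
    """
    scaffold = np.asarray(dilated_scaffold).astype(bool)
    if scaffold.shape != omap.angle.shape:
        raise ValueError("scaffold mask shape mismatch")
    drop = scaffold if keep_outside else ~scaffold
    out = omap.copy()
    out.angle = np.where(drop, NOT_ORIENTED, out.angle).astype(np.int16)
    return out


def filter_orientation_clusters(
    omap: OrientationMap, min_area: int = MIN_CLUSTER_AREA
) -> OrientationMap:
    """Discard 8-connected clusters of oriented pixels smaller than ``min_area``."""
    comp, n = ndimage.label(omap.oriented, structure=np.ones((3, 3), dtype=int))
    out = omap.copy()
    if n:
        areas = np.bincount(comp.ravel())
        small = areas[comp] < min_area
        out.angle = np.where(small & (comp > 0), NOT_ORIENTED, out.angle).astype(np.int16)
    return out


# ---------------------------------------------------------------------------
# histograms


@dataclass
class OrientationHistogram:
    counts: np.ndarray        # 180 one-degree bins
    smoothed: np.ndarray
    preferential: int | None  # argmax of smoothed counts; None if no oriented pixel

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "angle_deg": np.arange(180),
                "count": self.counts.astype(int),
                "smoothed_count": self.smoothed,
            }
        )


def circular_moving_average(values: np.ndarray, window: int = HISTOGRAM_WINDOW) -> np.ndarray:
    """Length-``window`` box filter with wrap-around (angles are periodic)."""
    half = window // 2
    padded = np.concatenate([values[-half:], values, values[:half]])
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def orientation_histogram(
    omap: OrientationMap, window: int = HISTOGRAM_WINDOW
) -> OrientationHistogram:
    """180-bin count histogram with a circularly smoothed trend.

    The preferential orientation is the angle holding the most pixels (raw
    counts; ties go to the smallest angle).  The smoothed trend is for
    presentation: a box average turns a sharp peak into a flat plateau whose
    argmax would be ill-conditioned.
    """
    angles = omap.angle[omap.oriented]
    counts = np.bincount(angles.astype(np.int64), minlength=180).astype(np.float64)
    smoothed = circular_moving_average(counts, window)
    preferential = int(np.argmax(counts)) if angles.size else None
    return OrientationHistogram(counts=counts, smoothed=smoothed, preferential=preferential)


def relative_orientation(
    hist: OrientationHistogram, scaffold_preferential: int | None
) -> OrientationHistogram:
    """Re-express a collagen histogram relative to the scaffold's preferential
    angle: every bin is shifted by ``-scaffold_preferential`` modulo 180."""
    if scaffold_preferential is None:
        raise ValueError("scaffold has no oriented pixels: no reference orientation")
    shift = int(scaffold_preferential) % 180
    counts = np.roll(hist.counts, -shift)
    smoothed = circular_moving_average(counts)
    preferential = int(np.argmax(counts)) if counts.sum() else None
    return OrientationHistogram(counts=counts, smoothed=smoothed, preferential=preferential)


def relative_orientation_map(omap: OrientationMap, scaffold_preferential: int | None) -> OrientationMap:
    if scaffold_preferential is None:
        raise ValueError("scaffold has no oriented pixels: no reference orientation")
    out = omap.copy()
    rel = (out.angle - int(scaffold_preferential)) % 180
    out.angle = np.where(omap.oriented, rel, NOT_ORIENTED).astype(np.int16)
    return out


# ---------------------------------------------------------------------------
# scaffold post-processing


def elliptical_footprint(height: int, width: int) -> np.ndarray:
    """Filled discrete ellipse inscribed in the bounding box (pixel centers
    tested against the ellipse equation); 2x2 and 3x3 degenerate to squares."""
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    r, c = np.mgrid[0:height, 0:width]
    return ((r - cy) / (height / 2.0)) ** 2 + ((c - cx) / (width / 2.0)) ** 2 <= 1.0


def scaffold_mask_postprocess(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Clean a predicted scaffold mask and extract its directional skeleton.

    Returns ``(skeleton_mask, dilated_mask)``: one binary opening with a
    20x20 elliptical element removes spurious objects; 20 dilations with a
    3x3 element smooth and fatten the fibers (the mask handed to collagen
    exclusion); the skeleton is Lee-thinned from that mask and re-dilated 3
    times with a 2x2 element for directional robustness.
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        return np.zeros_like(m), np.zeros_like(m)
    opened = ndimage.binary_opening(m, structure=elliptical_footprint(20, 20))
    if not opened.any():
        return np.zeros_like(m), np.zeros_like(m)
    dilated = ndimage.binary_dilation(opened, structure=elliptical_footprint(3, 3), iterations=20)
    skel = skeletonize(dilated, method="lee")
    skel = ndimage.binary_dilation(skel, structure=elliptical_footprint(2, 2), iterations=3)
    return skel, dilated


# ---------------------------------------------------------------------------
# end-to-end helpers


def scaffold_preferential_orientation(
    skeleton: np.ndarray, bank: OrientationKernelBank
) -> tuple[OrientationMap, OrientationHistogram]:
    """Orientation of the scaffold skeleton (0.5 response threshold)."""
    omap = orientation_map(
        skeleton.astype(np.float64), bank, SCAFFOLD_MAGNITUDE_THRESHOLD, keep_stack=False
    )
    return omap, orientation_histogram(omap)


def collagen_orientation(
    collagen: np.ndarray,
    bank: OrientationKernelBank,
    dilated_scaffold: np.ndarray | None = None,
    magnitude_threshold: float = COLLAGEN_MAGNITUDE_THRESHOLD,
    var_threshold: float = VARIANCE_THRESHOLD,
    min_cluster_area: int = MIN_CLUSTER_AREA,
    keep_outside: bool = True,
) -> tuple[OrientationMap, OrientationHistogram]:
    """Full collagen pipeline: map -> variance filter -> scaffold exclusion ->
    cluster filter -> histogram.  Each stage only removes oriented pixels."""
    omap = orientation_map(np.asarray(collagen, dtype=np.float64), bank, magnitude_threshold)
    omap = variance_filter(omap, var_threshold=var_threshold)
    if dilated_scaffold is not None:
        omap = mask_exclusion(omap, dilated_scaffold, keep_outside=keep_outside)
    omap = filter_orientation_clusters(omap, min_area=min_cluster_area)
    omap.response_stack = None
    return omap, orientation_histogram(omap)


def plot_histogram(hist: OrientationHistogram, path: str | Path, title: str = "") -> None:
    """Bar plot of raw counts with the smoothed trend overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.2))
    ax.bar(np.arange(180), hist.counts, width=1.0, color="#9ecae1", label="counts")
    ax.plot(np.arange(180), hist.smoothed, color="#08519c", lw=1.5, label="smoothed (7-bin)")
    if hist.preferential is not None:
        ax.axvline(hist.preferential, color="#cb181d", ls="--", lw=1,
                   label=f"preferential {hist.preferential}°")
    ax.set_xlabel("orientation (degrees)")
    ax.set_ylabel("pixel count")
    if title:
        ax.set_title(title)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
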