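"""Ground-truthed synthetic fixtures emulating the study's four channels.

No public dataset exists for this imaging domain, so every pipeline stage is
exercised on generated scenes whose ground truth is the rendering input
itself: a grid of bright scaffold fibers (THG-like), a bright cell layer
hugging the fibers plus scattered dim interstitial cells (GFP-like),
elongated irregular fibroblast blobs, some touching (RFP-like), and stripe
or segment textures with known orientations (SHG-like).  The field of view
matches the study (360 um across the image), so physical quantities such as
the 35-um filament width and the 20-40 um scaffold-associated band translate
to meaningful pixel counts at any fixture size.  Every generator is a pure
function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

FIELD_OF_VIEW_UM = 360.0
FILAMENT_WIDTH_UM = 35.0
ASSOCIATED_BAND_UM = (0.0, 30.0)   # cell layer extends up to 20-40 um from a fiber


def fixture_pixel_size(size: int) -> float:
    """um/px for a fixture spanning the study's 360-um field of view."""
    return FIELD_OF_VIEW_UM / size


@dataclass
class FixtureSpec:
    scene: str                       # scaffold_grid | immune_cells | fibroblasts | oriented_fibers
    size: int = 256
    seed: int = 0
    params: dict = field(default_factory=dict)


def make_fixture(spec: FixtureSpec):
    makers = {
        "scaffold_grid": make_scaffold_grid,
        "immune_cells": _immune_from_spec,
        "fibroblasts": make_fibroblasts,
        "oriented_fibers": make_oriented_fibers,
    }
    if spec.scene not in makers:
        raise ValueError(f"unknown scene {spec.scene!r}")
    return makers[spec.scene](size=spec.size, seed=spec.seed, **spec.params)


# ---------------------------------------------------------------------------
# scaffold grid (THG-like)


def make_scaffold_grid(
    size: int = 256,
    seed: int = 0,
    n_horizontal: int = 2,
    n_vertical: int = 2,
    width_px: int | None = None,
    noise: float = 0.01,
    blur_sigma: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal bright bars on a dark background; mask is the exact geometry."""
    rng = np.random.default_rng(seed)
    if width_px is None:
        width_px = max(3, int(round(FILAMENT_WIDTH_UM / fixture_pixel_size(size))))
    n_max = max(n_horizontal, n_vertical)
    if n_max and width_px * (n_max + 1) >= size:
        raise ValueError("bars exceed the image: reduce count or width")
    mask = np.zeros((size, size), dtype=bool)
    for i in range(n_horizontal):
        c = int(round((i + 1) * size / (n_horizontal + 1)))
        mask[max(0, c - width_px // 2) : c + (width_px + 1) // 2, :] = True
    for i in range(n_vertical):
        c = int(round((i + 1) * size / (n_vertical + 1)))
        mask[:, max(0, c - width_px // 2) : c + (width_px + 1) // 2] = True
    img = ndimage.gaussian_filter(mask.astype(np.float64), blur_sigma)
    if noise > 0:
        img = img + rng.normal(0.0, noise, img.shape)
    return np.clip(img, 0.0, 1.0), mask


# ---------------------------------------------------------------------------
# immune cells (GFP-like): scaffold-associated layer + interstitial blobs


def _place_discs(
    rng: np.random.Generator,
    allowed: np.ndarray,
    n: int,
    radius_range: tuple[int, int],
    min_gap: int,
) -> tuple[np.ndarray, int]:
    """Stamp up to ``n`` non-overlapping discs inside the allowed region."""
    size = allowed.shape[0]
    out = np.zeros_like(allowed, dtype=bool)
    free = allowed.copy()
    placed = 0
    for _ in range(n * 60):
        if placed == n:
            break
        r0, c0 = rng.integers(0, size, 2)
        rad = int(rng.integers(radius_range[0], radius_range[1] + 1))
        if not free[r0, c0]:
            continue
        rr, cc = np.ogrid[0:size, 0:size]
        disc = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
        zone = (rr - r0) ** 2 + (cc - c0) ** 2 <= (rad + min_gap) ** 2
        if not free[disc].all():
            continue
        out |= disc
        free &= ~zone
        placed += 1
    return out, placed


def make_immune_cells(
    scaffold_mask: np.ndarray,
    seed: int = 0,
    n_interstitial: int = 8,
    layer_fill: float = 0.75,
    noise: float = 0.02,
) -> tuple[np.ndarray, np.ndarray]:
    """GFP-like image and 3-class mask from a scaffold geometry.

    A bright cell layer occupies most of the band within ~30 um of a fiber
    (class 1, scaffold-associated); dimmer scattered blobs elsewhere are
    class 2 (interstitial); the rest, scaffold included, is background.
    """
    scaffold = np.asarray(scaffold_mask).astype(bool)
    size = scaffold.shape[0]
    rng = np.random.default_rng(seed)
    px = fixture_pixel_size(size)
    band_px = ASSOCIATED_BAND_UM[1] / px
    dist = ndimage.distance_transform_edt(~scaffold)
    band = (dist > 0) & (dist <= band_px)
    # carve a blobby but dense layer out of the band with smoothed noise
    tex = ndimage.gaussian_filter(rng.standard_normal(scaffold.shape), 4.0)
    thr = np.quantile(tex[band], 1.0 - layer_fill) if band.any() else np.inf
    layer = band & (tex >= thr)

    # interstitial cells ~10-18 um across, clear of the scaffold band
    r_lo = max(1, int(round(5.0 / px)))
    r_hi = max(r_lo, int(round(9.0 / px)))
    far = dist > band_px + 2
    interstitial, _ = _place_discs(rng, far, n_interstitial, (r_lo, r_hi), min_gap=3)

    labels = np.zeros(scaffold.shape, dtype=np.int64)
    labels[layer] = 1
    labels[interstitial] = 2

    img = np.full(scaffold.shape, 0.03)
    img[layer] = 0.9
    img[interstitial] = 0.4
    img = ndimage.gaussian_filter(img, 0.8)
    if noise > 0:
        img = img + rng.normal(0.0, noise, img.shape)
    return np.clip(img, 0.0, 1.0), labels


def _immune_from_spec(size: int = 256, seed: int = 0, **params):
    _, scaffold = make_scaffold_grid(size=size, seed=seed)
    return make_immune_cells(scaffold, seed=seed, **params)


# ---------------------------------------------------------------------------
# fibroblasts (RFP-like): elongated random-walk blobs, optionally touching


def _walk_blob(
    rng: np.random.Generator,
    size: int,
    start: tuple[int, int],
    n_steps: int,
    radius: int,
    heading: float,
    wobble: float = 0.35,
) -> np.ndarray:
    """Elongated irregular blob: a disc dragged along a persistent random walk."""
    rr, cc = np.ogrid[0:size, 0:size]
    mask = np.zeros((size, size), dtype=bool)
    r, c = float(start[0]), float(start[1])
    for _ in range(n_steps):
        mask |= (rr - r) ** 2 + (cc - c) ** 2 <= radius**2
        heading += rng.normal(0.0, wobble)
        r = float(np.clip(r + 1.6 * np.sin(heading), radius, size - 1 - radius))
        c = float(np.clip(c + 1.6 * np.cos(heading), radius, size - 1 - radius))
    return mask


def make_fibroblasts(
    size: int = 256,
    seed: int = 0,
    n_cells: int = 6,
    n_touching_pairs: int = 0,
    n_small: int = 0,
    radius: int = 4,
    n_steps: int = 35,
    noise: float = 0.02,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """RFP-like image, binary mask and instance labels.

    ``n_cells`` isolated elongated blobs are planted on a jittered grid;
    ``n_touching_pairs`` of them are grown as adjacent pairs to exercise the
    boundary-weighted loss; ``n_small`` sub-200-px discs are added as noise
    that downstream area filtering must remove (they are still real signal
    in the binary mask, instance id 0 in the label image marks background).
    """
    rng = np.random.default_rng(seed)
    if n_touching_pairs * 2 > n_cells:
        raise ValueError("more touching cells requested than cells")
    instances = np.zeros((size, size), dtype=np.int64)
    binary = np.zeros((size, size), dtype=bool)

    # jittered coarse grid keeps isolated cells apart deterministically
    grid = max(2, int(np.ceil(np.sqrt(n_cells))))
    cell_px = size // grid
    slots = [(i, j) for i in range(grid) for j in range(grid)]
    rng.shuffle(slots)

    next_id = 1
    placed = 0
    touching_left = n_touching_pairs
    for (i, j) in slots:
        if placed >= n_cells:
            break
        margin = radius + 3
        blob = None
        for _ in range(12):  # isolated cells must keep a 2-px clearance
            r0 = int(np.clip(i * cell_px + rng.integers(margin, max(margin + 1, cell_px - margin)),
                             margin, size - 1 - margin))
            c0 = int(np.clip(j * cell_px + rng.integers(margin, max(margin + 1, cell_px - margin)),
                             margin, size - 1 - margin))
            heading = rng.uniform(0, 2 * np.pi)
            cand = _walk_blob(rng, size, (r0, c0), n_steps, radius, heading)
            if cand.sum() >= 50 and not (
                ndimage.binary_dilation(cand, iterations=2) & binary
            ).any():
                blob = cand
                break
        if blob is None:
            continue
        instances[blob] = next_id
        binary |= blob
        next_id += 1
        placed += 1
        if touching_left > 0 and placed < n_cells:
            # grow a second cell starting just off the first one's envelope
            edge = ndimage.binary_dilation(blob, iterations=2) & ~ndimage.binary_dilation(blob)
            coords = np.argwhere(edge)
            if coords.size:
                r1, c1 = coords[rng.integers(len(coords))]
                blob2 = _walk_blob(rng, size, (int(r1), int(c1)), n_steps, radius,
                                   heading + np.pi / 2)
                blob2 &= instances == 0
                if blob2.sum() >= 50:
                    instances[blob2] = next_id
                    binary |= blob2
                    next_id += 1
                    placed += 1
                    touching_left -= 1

    free = ~ndimage.binary_dilation(binary, iterations=4)
    small, _ = _place_discs(rng, free, n_small, (3, 5), min_gap=4)
    binary |= small

    img = np.full((size, size), 0.05)
    for cid in range(1, next_id):
        img[instances == cid] = rng.uniform(0.55, 0.95)
    img[small] = 0.6
    img = ndimage.gaussian_filter(img, 0.8)
    if noise > 0:
        img = img + rng.normal(0.0, noise, img.shape)
    return np.clip(img, 0.0, 1.0), binary, instances


# ---------------------------------------------------------------------------
# oriented fibers (SHG-like)


def _stripe_pattern(
    size: int, angle_deg: float, spacing: float, width: float, supersample: int = 3
) -> np.ndarray:
    """Anti-aliased parallel stripes: 0 degrees runs along image rows.

    Rendered on a ``supersample``-times finer grid and box-averaged down, so
    edge pixels carry the sub-pixel fiber position the way real
    (band-limited) microscopy intensities do.
    """
    theta = np.deg2rad(angle_deg)
    n = size * supersample
    rr, cc = np.mgrid[0:n, 0:n].astype(np.float64) / supersample
    dr, dc = rr - size / 2.0, cc - size / 2.0
    s = -np.sin(theta) * dc - np.cos(theta) * dr   # signed distance across stripes
    pat = (np.mod(s, spacing) < width).astype(np.float64)
    return pat.reshape(size, supersample, size, supersample).mean(axis=(1, 3))


def make_oriented_fibers(
    size: int = 256,
    seed: int = 0,
    mode: str = "parallel",
    angle: float = 30.0,
    angles: tuple[float, float] = (0.0, 90.0),
    spacing: float = 8.0,
    width: float = 2.0,
    n_segments: int = 150,
    segment_length: int = 40,
    noise: float = 0.0,
):
    """SHG-like fiber texture with known ground-truth orientation.

    ``parallel`` renders stripes at ``angle`` and returns (image, angle);
    ``crossed`` overlays two stripe families and returns (image, angles);
    ``chaotic`` scatters short segments at uniform random angles and returns
    (image, None).
    """
    rng = np.random.default_rng(seed)
    if not 0.0 <= angle < 180.0:
        raise ValueError("angle must lie in [0, 180)")
    if mode == "parallel":
        img = _stripe_pattern(size, angle, spacing, width)
        truth = angle
    elif mode == "crossed":
        img = np.maximum(
            _stripe_pattern(size, angles[0] % 180.0, spacing, width),
            _stripe_pattern(size, angles[1] % 180.0, spacing, width),
        )
        truth = tuple(a % 180.0 for a in angles)
    elif mode == "chaotic":
        img = np.zeros((size, size))
        from skimage.draw import line

        for _ in range(n_segments):
            a = rng.uniform(0.0, np.pi)
            r0 = rng.integers(0, size)
            c0 = rng.integers(0, size)
            r1 = int(np.clip(r0 - segment_length * np.sin(a), 0, size - 1))
            c1 = int(np.clip(c0 + segment_length * np.cos(a), 0, size - 1))
            rr, cc = line(r0, c0, r1, c1)
            img[rr, cc] = 1.0
        img = ndimage.binary_dilation(img > 0, iterations=1).astype(np.float64)
        truth = None
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if noise > 0:
        img = np.clip(img + rng.normal(0.0, noise, img.shape), 0.0, 1.0)
    return img, truth
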