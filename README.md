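# fbrseg

Automated quantification of the foreign-body response (FBR) in intravital
multiphoton microscopy.  When a biomaterial — here a 3D-printed
polycaprolactone (PCL) grid scaffold — is implanted under the skin, immune
cells infiltrate it, activated fibroblasts accumulate, and collagen is
deposited into an oriented fibrotic capsule.  `fbrseg` turns the four
imaging channels of that process (GFP immune cells, RFP fibroblasts,
SHG collagen + scaffold, THG scaffold) into numbers:

1. **Immune-cell segmentation** — a U-Net variant performs three-class
   semantic segmentation (scaffold-associated cells, interstitial cells,
   background) and reports per-class areas.
2. **Fibroblast instance segmentation** — the same network, trained with a
   boundary-weighted loss that emphasizes the background ridges between
   adjacent cells, yields per-cell masks, counts, areas, centroids and
   pairwise distances.
3. **Collagen orientation** — a bank of 360 directional edge kernels (the
   compass-mask operator generalized to 1° spacing) assigns per-pixel
   orientations to collagen fibers and reports them relative to the
   scaffold's preferential orientation.

It is written for microscopy core facilities and biomaterials labs that
need reproducible, hands-off quantification of implant-site images, and
for methodologists who want a compact, fully inspectable reference
implementation of these three building blocks.

## The models in brief

**Class-balanced Dice loss.**  For classes C with one-hot targets y_C and
predicted probabilities ŷ_C,

    L = 1 − Σ_C α_C · 2 Σ_x y_C ŷ_C / (Σ_x y_C + Σ_x ŷ_C),

with α_C ∝ 1/(pixel frequency of C), Σα_C = 1, averaged over the
mini-batch, plus an L2 penalty (λ/2)‖ω‖², λ = 0.01.

**Boundary-weighted BCE.**  Background pixels at distances d₁ ≤ d₂ from
the two nearest 8-connected cells get weight w_B = a·exp(−(d₁+d₂)²/2σ²)
(a = 100, σ = 5 px; zero on cells), shifted by the class importance
i_B = mean(w_B + 1) over training background; the loss is the
weight-normalized mean of per-pixel binary cross-entropy.  A weighted
likelihood metric M = Σ w·(yŷ + (1−y)(1−ŷ)) / Σ w ∈ [0, 1] tracks border
quality.

**Compass kernel bank.**  Each 33 × 33 kernel carries a triangular
coefficient ridge along a line at angle θ (distance profile d → d on
[0, 1], 2 − d on [1, 2], 0 beyond), negated on the clockwise side, clipped
to a 15-px radius, positives/negatives normalized to ±1.  Per pixel, the
maximum response over the bank gives the orientation (mod 180°); maps are
pruned by a top-36 response-variance filter, scaffold-mask exclusion and a
15-px cluster filter, then summarized as a 180-bin histogram whose mode is
the preferential orientation.

The network engine (convolutions, batch norm, transposed convolutions,
Adam, the sigmoid learning-rate decay) is implemented directly on NumPy
with explicit backward passes; no deep-learning framework is required.
See `docs/methods.md` for assumptions, defaults and numerical conventions.

## Worked example

Everything below runs on synthetic fixtures with known ground truth
(`fbrseg synth`), so it works without any data download.

Collagen at 40° over a horizontal scaffold grid:

```sh
fbrseg synth --scene oriented_fibers --out-dir fx --size 256 --param angle=40.0
fbrseg synth --scene scaffold_grid   --out-dir fx --size 256
fbrseg orient --shg fx/oriented_fibers_0000_img.tif \
              --thg fx/scaffold_grid_0000_mask.tif --out orient_out --relative
```

prints

```
{"preferential_deg": 40, "scaffold_preferential_deg": 0, "oriented_pixel_count": 13181, "relative": true}
```

— the scaffold's preferential orientation is 0° (horizontal bars dominate
its skeleton histogram), and the collagen peak sits 40° away from it,
exactly the planted angle.  `orient_out/` also holds the 180-row
`histogram.csv`, a rendered `histogram.png` and the orientation map as a
16-bit TIFF (angle + 1, 0 = not oriented).

Fibroblast quantification from a ground-truth mask:

```sh
fbrseg synth --scene fibroblasts --out-dir fx --size 256 --param n_cells=5
fbrseg quantify --mask-path fx/fibroblasts_0000_mask.tif --out-dir quant \
                --task fibroblast --min-area 200
```

prints

```
areas: {'background': 125271.1669921875, 'fibroblast': 4328.8330078125}; instances: 5
```

and writes `instances.csv` / `distances.csv`, e.g.

```
id,area_px,area_um2,centroid_row,centroid_col
1,425,840.4541015625,17.021176470588234,215.86352941176472
2,477,943.2861328125,107.80712788259959,188.70859538784066
...
id_a,id_b,distance_um
1,2,133.2564118731949
```

All five planted cells are recovered (areas in µm² use the fixture's
1.41 µm/px); cells 1 and 2 have centroids 133 µm apart.

Training the scaled-down U-Net on fixtures:

```sh
fbrseg synth --scene fibroblasts --out-dir data --size 128 --count 10
fbrseg train --task fibroblast --data-dir data --out-dir run --seed 0
fbrseg predict --model-path run/model --in-path data/fibroblasts_0003_img.tif \
               --out-path pred.tif
```

The run directory records the resolved configuration, the seed and the
per-epoch loss/IoU history, so a rerun with the same config reproduces the
same outputs.

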