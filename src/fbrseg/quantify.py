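"""Biological read-outs from predicted masks.

Per-class areas quantify cellular species content; fibroblast instances are
8-connected foreground components at the restored acquisition resolution,
with components below 200 px discarded as noise (the 200-px component
itself survives).  Centroids are unweighted pixel-coordinate means and
inter-fibroblast distances are pairwise centroid separations in um.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import measure

from .preprocess import MulticlassMask

MIN_INSTANCE_AREA = 200

CLASS_NAMES = {0: "background", 1: "scaffold_associated", 2: "interstitial"}


@dataclass
class CellInstance:
    id: int
    pixel_set: np.ndarray      # (n, 2) array of (row, col)
    area_px: int
    area_um2: float
    centroid: tuple[float, float]


@dataclass
class QuantificationReport:
    class_areas_px: dict[str, int]
    class_areas_um2: dict[str, float]
    pixel_size: float
    instances: list[CellInstance] | None = None
    distances_um: list[tuple[int, int, float]] | None = None


def class_areas(mask: MulticlassMask, pixel_size: float) -> QuantificationReport:
    """Pixel and um^2 area of every class; classes partition the image."""
    counts = np.bincount(mask.labels.ravel(), minlength=mask.n_classes)
    px = {CLASS_NAMES.get(c, f"class_{c}"): int(counts[c]) for c in range(mask.n_classes)}
    um2 = {k: v * pixel_size**2 for k, v in px.items()}
    return QuantificationReport(class_areas_px=px, class_areas_um2=um2, pixel_size=pixel_size)


def extract_instances(
    mask: np.ndarray | MulticlassMask,
    pixel_size: float = 1.0,
    min_area: int = MIN_INSTANCE_AREA,
) -> list[CellInstance]:
    """8-connected instances of a binary mask, area-filtered, raster-ordered ids.

    Components whose area is strictly lower than ``min_area`` are discarded.
    Ids follow the raster order of each component's top-left pixel, so
    repeated runs on the same mask produce identical reports.
    """
    lab = mask.labels if isinstance(mask, MulticlassMask) else np.asarray(mask)
    comp = measure.label(lab > 0, connectivity=2)
    regions = [r for r in measure.regionprops(comp) if r.area >= min_area]
    # raster order of the first (topmost, then leftmost) pixel of each region
    regions.sort(key=lambda r: (r.coords[:, 0].min(),
                                r.coords[r.coords[:, 0] == r.coords[:, 0].min(), 1].min()))
    out = []
    for i, r in enumerate(regions, start=1):
        out.append(
            CellInstance(
                id=i,
                pixel_set=r.coords,
                area_px=int(r.area),
                area_um2=float(r.area) * pixel_size**2,
                centroid=tuple(map(float, r.coords.mean(axis=0))),
            )
        )
    return out


def centroid_distances(
    cells: list[CellInstance], pixel_size: float = 1.0
) -> list[tuple[int, int, float]]:
    """All n(n-1)/2 pairwise centroid distances, in um."""
    out = []
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            ci, cj = np.array(cells[i].centroid), np.array(cells[j].centroid)
            out.append((cells[i].id, cells[j].id, float(np.linalg.norm(ci - cj) * pixel_size)))
    return out


def quantify_fibroblasts(
    mask: np.ndarray | MulticlassMask,
    pixel_size: float,
    min_area: int = MIN_INSTANCE_AREA,
) -> QuantificationReport:
    """Full fibroblast report: binary class areas, instances, distances."""
    lab = mask.labels if isinstance(mask, MulticlassMask) else np.asarray(mask)
    fg = int((lab > 0).sum())
    px = {"background": lab.size - fg, "fibroblast": fg}
    report = QuantificationReport(
        class_areas_px=px,
        class_areas_um2={k: v * pixel_size**2 for k, v in px.items()},
        pixel_size=pixel_size,
    )
    report.instances = extract_instances(lab, pixel_size=pixel_size, min_area=min_area)
    report.distances_um = centroid_distances(report.instances, pixel_size=pixel_size)
    return report


# ---------------------------------------------------------------------------
# CSV reports


def write_reports(report: QuantificationReport, out_dir: str | Path) -> None:
    """class_areas.csv, instances.csv and distances.csv under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "class": list(report.class_areas_px),
            "px": list(report.class_areas_px.values()),
            "um2": [report.class_areas_um2[k] for k in report.class_areas_px],
        }
    ).to_csv(out_dir / "class_areas.csv", index=False)
    if report.instances is not None:
        pd.DataFrame(
            [
                {
                    "id": c.id,
                    "area_px": c.area_px,
                    "area_um2": c.area_um2,
                    "centroid_row": c.centroid[0],
                    "centroid_col": c.centroid[1],
                }
                for c in report.instances
            ]
        ).to_csv(out_dir / "instances.csv", index=False)
    if report.distances_um is not None:
        pd.DataFrame(report.distances_um, columns=["id_a", "id_b", "distance_um"]).to_csv(
            out_dir / "distances.csv", index=False
        )
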