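"""Map classified cell behaviors back onto tissue coordinates.

Each behavior category gets a 2-D count grid over the field of view
(cells binned by their position at a reference frame), mirroring
per-category frequency heat maps across the imaged regions (impact site,
lateral site, below-impact site, and control sites).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .classify import BehaviorCategory, ClassificationResult
from .tracking import CellTracks

UNASSIGNED = "unassigned"


@dataclass
class Region:
    """A rectangular imaging region at an offset within the mosaic.

    Region ids follow the acquisition convention: 1 impact site, 2 lateral
    to it, 3 below it, 4-5 on the unimpacted control.
    """

    region_id: int
    x0: float
    y0: float
    width: float
    height: float

    def contains(self, x: float, y: float) -> bool:
        # closed bounds: boundary pixels match (ties resolved by region order)
        return (self.x0 <= x <= self.x0 + self.width
                and self.y0 <= y <= self.y0 + self.height)


@dataclass
class SpatialMap:
    """Per-category 2-D count grids with shared binning."""

    grids: dict[BehaviorCategory, np.ndarray]
    bin_size: float
    field_shape: tuple[int, int]
    reference_frame: int
    regions: list[Region] = field(default_factory=list)

    def total_counts(self) -> int:
        return int(sum(g.sum() for g in self.grids.values()))

    def grid(self, category: BehaviorCategory | str) -> np.ndarray:
        return self.grids[BehaviorCategory(str(category))]

    def write_csv(self, directory: str | Path) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for cat, g in self.grids.items():
            p = directory / f"map_{cat.value}.csv"
            pd.DataFrame(g).to_csv(p, index=False, header=False)
            paths.append(p)
        return paths


def assign_region(
    position: tuple[float, float], regions: list[Region]
) -> int | str:
    """Deterministic containment test; boundary points go to the
    lowest-indexed region; positions outside all regions are
    ``"unassigned"``."""
    x, y = position
    for region in sorted(regions, key=lambda r: r.region_id):
        if region.contains(x, y):
            return region.region_id
    return UNASSIGNED


def category_map(
    labels: ClassificationResult | Mapping[int, BehaviorCategory | str],
    tracks: CellTracks,
    bin_size: float = 64.0,
    field_shape: tuple[int, int] = (512, 512),
    reference_frame: int = 0,
    regions: list[Region] | None = None,
) -> SpatialMap:
    """Bin labeled cells into per-category count grids.

    Every labeled cell must have a position (of any provenance) at the
    reference frame.  Bins are half-open ``[lo, hi)`` squares of
    ``bin_size`` px; each category grid sums to the number of cells
    carrying that label.
    """
    if isinstance(labels, ClassificationResult):
        labels = labels.as_mapping()
    labels = {int(c): BehaviorCategory(str(v)) for c, v in labels.items()}
    at = tracks.positions_at(reference_frame).set_index("cell_id")
    missing = sorted(set(labels) - set(at.index))
    if missing:
        raise ValueError(
            f"labeled cells without a position at frame {reference_frame}: "
            f"{missing[:10]}"
        )
    ny = int(np.ceil(field_shape[0] / bin_size))
    nx = int(np.ceil(field_shape[1] / bin_size))
    grids = {cat: np.zeros((ny, nx), dtype=int) for cat in BehaviorCategory}
    for cid, cat in sorted(labels.items()):
        x = float(at.loc[cid, "x"])
        y = float(at.loc[cid, "y"])
        ix = min(int(x // bin_size), nx - 1)
        iy = min(int(y // bin_size), ny - 1)
        grids[cat][iy, ix] += 1
    return SpatialMap(
        grids=grids,
        bin_size=bin_size,
        field_shape=field_shape,
        reference_frame=reference_frame,
        regions=regions or [],
    )


def plot_map(
    spatial_map: SpatialMap, path: str | Path, categories=None
) -> Path:
    """Write per-category heat maps as a PNG panel (colorbars independent)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cats = [BehaviorCategory(str(c)) for c in categories] if categories \
        else list(BehaviorCategory)
    ncol = 4
    nrow = int(np.ceil(len(cats) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 3 * nrow))
    for ax, cat in zip(np.ravel(axes), cats):
        im = ax.imshow(spatial_map.grids[cat], origin="upper", cmap="magma")
        ax.set_title(cat.value)
        fig.colorbar(im, ax=ax, shrink=0.8)
    for ax in np.ravel(axes)[len(cats):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return Path(path)
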