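"""Tumor-T-cell cluster (rosette) detection in two-channel co-culture images.

A cluster is operationalized as a connected component of the union of the
two thresholded channels that (a) contains foreground from both populations
within a small adjacency distance and (b) exceeds a minimum area, by
default the footprint of three cell profiles.  The dual-population rule is
symmetric in the channels, so swapping green (tumor, CFSE) and red (T cell)
leaves every count and area unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

DEFAULT_ADJACENCY_UM = 2.0
DEFAULT_CELL_DIAMETER_UM = 10.0


@dataclass(frozen=True)
class TwoChannelImage:
    """Green (tumor) and red (T cell) intensity grids with a pixel size."""

    green: np.ndarray
    red: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        g, r = np.asarray(self.green), np.asarray(self.red)
        if g.shape != r.shape or g.ndim != 2:
            raise ValueError("green and red channels must be equal-shaped 2-D grids")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "green", g)
        object.__setattr__(self, "red", r)


@dataclass(frozen=True)
class ClusterParams:
    adjacency_distance: float = DEFAULT_ADJACENCY_UM
    cell_diameter: float = DEFAULT_CELL_DIAMETER_UM
    min_area: float | None = None  # µm²; default = 3 cell profiles

    def resolved_min_area(self) -> float:
        if self.min_area is not None:
            return self.min_area
        return 3.0 * np.pi * (self.cell_diameter / 2.0) ** 2


@dataclass
class ClusterSet:
    labels: np.ndarray
    areas: list[float]  # µm²
    count: int
    condition: str = ""
    pixel_size: float = 1.0


def _foreground(channel: np.ndarray) -> np.ndarray:
    vals = np.asarray(channel, dtype=float)
    if vals.max() == vals.min():
        return np.zeros(vals.shape, dtype=bool)
    return vals > threshold_otsu(vals)


def detect_clusters(
    image: TwoChannelImage,
    params: ClusterParams = ClusterParams(),
    condition: str = "",
) -> ClusterSet:
    """Detect dual-population clusters.

    Each channel is thresholded (Otsu; a constant channel gives empty
    foreground).  Connected components of the union foreground are kept as
    clusters when they contain green pixels and red pixels that approach
    each other within ``adjacency_distance`` and their pixel-counted area
    exceeds the minimum.  Areas are exact pixel counts times pixel area.
    """
    px = image.pixel_size
    green_fg = _foreground(image.green)
    red_fg = _foreground(image.red)
    union = green_fg | red_fg
    labels, n = ndimage.label(union)
    out = np.zeros_like(labels, dtype=np.int32)
    areas: list[float] = []
    min_area = params.resolved_min_area()
    next_label = 1
    for sl, lab in zip(ndimage.find_objects(labels), range(1, n + 1)):
        comp = labels[sl] == lab
        g = comp & green_fg[sl]
        r = comp & red_fg[sl]
        if not (g.any() and r.any()):
            continue
        # both populations must come within the adjacency distance
        dist_to_green = ndimage.distance_transform_edt(~g, sampling=(px, px))
        if float(dist_to_green[r].min()) > params.adjacency_distance:
            continue
        area = float(comp.sum()) * px * px
        if area < min_area:
            continue
        out[sl][comp] = next_label
        areas.append(area)
        next_label += 1
    return ClusterSet(
        labels=out, areas=areas, count=len(areas), condition=condition, pixel_size=px
    )


def cluster_size_summary(clusters_by_condition: dict[str, Sequence[ClusterSet]]) -> pd.DataFrame:
    """Per-condition mean cluster area with sem and counts.

    The sem is computed over individual cluster areas pooled across the
    condition's images; with fewer than two clusters it is reported NaN.
    """
    rows = []
    for cond, sets in clusters_by_condition.items():
        areas = np.array([a for cs in sets for a in cs.areas], dtype=float)
        n = areas.size
        rows.append(
            {
                "condition": cond,
                "n_images": len(sets),
                "n_clusters": int(n),
                "mean_area_um2": float(areas.mean()) if n else float("nan"),
                "sem_area_um2": float(areas.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
                "median_area_um2": float(np.median(areas)) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def clusters_to_frame(cs: ClusterSet) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "condition": cs.condition,
            "cluster_label": np.arange(1, cs.count + 1),
            "area_um2": cs.areas,
        }
    )
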