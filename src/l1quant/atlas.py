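"""Subregion label maps, the region hierarchy, and area roll-ups.

The imaging arm consumes an atlas-registered label image in which every pixel
carries the integer id of one anatomical subregion.  This module holds the
subregion -> parent-region hierarchy, converts pixel counts to areas (mm^2 in
2D, mm^3 in 3D), and attributes detected objects to subregions by the pixel
under their centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RegionHierarchy", "compute_geometry", "assign_subregion"]


@dataclass
class RegionHierarchy:
    """Maps each subregion id to its parent region and holds pixel sizes.

    ``pixel_size`` is the in-plane pixel edge in micrometres; ``z_step`` the
    spacing between planes for 3D stacks (ignored in 2D).
    """

    parents: dict  # subregion_id -> parent region name
    names: dict = field(default_factory=dict)  # subregion_id -> display name
    pixel_size: float = 1.0
    z_step: float = 1.0

    def __post_init__(self):
        if self.pixel_size <= 0 or self.z_step <= 0:
            raise ValueError("pixel sizes must be positive")
        self.parents = {int(k): str(v) for k, v in self.parents.items()}

    @property
    def subregion_ids(self):
        return sorted(self.parents)

    @classmethod
    def from_table(cls, table: pd.DataFrame, pixel_size: float = 1.0, z_step: float = 1.0):
        """Build from a two-column table (subregion_id, parent[, name])."""
        names = (
            dict(zip(table["subregion_id"], table["name"]))
            if "name" in table.columns
            else {}
        )
        return cls(
            parents=dict(zip(table["subregion_id"], table["parent"])),
            names=names,
            pixel_size=pixel_size,
            z_step=z_step,
        )


def compute_geometry(region_map: np.ndarray, hierarchy: RegionHierarchy) -> pd.DataFrame:
    """Per-subregion pixel counts and areas, with parent-region roll-ups.

    Returns a frame with columns ``subregion_id`` (NaN on parent rows),
    ``parent``, ``level`` ('subregion' | 'region'), ``pixel_count`` and
    ``area_mm2`` (a volume in mm^3 for 3D maps, kept under the same column
    name so downstream density code is dimension-agnostic).
    """
    region_map = np.asarray(region_map)
    if region_map.ndim not in (2, 3):
        raise ValueError("region map must be 2D or 3D")
    ids, counts = np.unique(region_map, return_counts=True)
    present = {int(i): int(c) for i, c in zip(ids, counts) if i != 0}
    orphans = sorted(set(present) - set(hierarchy.parents))
    if orphans:
        raise ValueError(f"subregion ids missing from hierarchy: {orphans}")

    px = hierarchy.pixel_size
    if region_map.ndim == 2:
        unit = px * px / 1e6  # um^2 -> mm^2
    else:
        unit = px * px * hierarchy.z_step / 1e9  # um^3 -> mm^3

    rows = []
    for sid in sorted(present):
        rows.append(
            {
                "subregion_id": sid,
                "parent": hierarchy.parents[sid],
                "level": "subregion",
                "pixel_count": present[sid],
                "area_mm2": present[sid] * unit,
            }
        )
    sub = pd.DataFrame(rows)
    parents = (
        sub.groupby("parent", as_index=False)[["pixel_count", "area_mm2"]]
        .sum()
        .assign(subregion_id=np.nan, level="region")
    )
    return pd.concat([sub, parents], ignore_index=True)[
        ["subregion_id", "parent", "level", "pixel_count", "area_mm2"]
    ]


def assign_subregion(centroids, region_map: np.ndarray) -> np.ndarray:
    """Subregion id of the pixel under each centroid (nearest pixel, no
    interpolation; a centroid on a boundary pixel gets that pixel's id).

    ``centroids`` is (n, ndim) in array (row, col[, plane-first]) order.
    """
    region_map = np.asarray(region_map)
    pts = np.atleast_2d(np.asarray(centroids, dtype=float))
    if pts.shape[1] != region_map.ndim:
        raise ValueError(
            f"centroid dimensionality {pts.shape[1]} != map dimensionality {region_map.ndim}"
        )
    idx = np.rint(pts).astype(int)
    for axis, size in enumerate(region_map.shape):
        bad = (idx[:, axis] < 0) | (idx[:, axis] >= size)
        if np.any(bad):
            raise ValueError(f"centroid(s) {np.flatnonzero(bad).tolist()} out of bounds")
    return region_map[tuple(idx.T)]
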