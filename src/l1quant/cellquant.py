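"""Region-wise quantification of marker-positive cells.

The central imaging computation: estimate per-subregion background from
pixels outside every detected object, measure detected nuclei and cell
bodies, associate each cell with a nucleus (2D centroid rule or 3D
half-volume rule), classify cells as neuronal (NeuN+/-) and target-marker
positive (e.g. ORF1p+/-) against background-derived intensity thresholds,
and aggregate counts, densities (cells per mm^2), class proportions and
background-subtracted intensities per subregion, per parent region and
brain-wide.

Classification always uses raw mean intensities against the threshold
``background_mean + k_sigma * background_sd`` of the cell's own subregion;
background-subtracted ("normalized") intensities are recorded alongside and
deliberately not clamped at zero so intensity distributions keep their
shape for downstream distribution comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.measure import regionprops_table

from .atlas import RegionHierarchy, assign_subregion

__all__ = [
    "estimate_background",
    "measure_objects",
    "associate_nucleus_cell",
    "classify_cells",
    "summarize_regions",
    "quantify",
    "CLASS_LABELS",
]

#: the four cell classes, in reporting order
CLASS_LABELS = (
    "target_pos_neun_pos",
    "target_pos_neun_neg",
    "target_neg_neun_pos",
    "target_neg_neun_neg",
)


def estimate_background(
    image: np.ndarray,
    nuclei_labels: np.ndarray,
    cell_labels: np.ndarray,
    region_map: np.ndarray,
) -> pd.DataFrame:
    """Per-subregion background statistics for one channel.

    Background is the set of pixels not belonging to any detected nucleus or
    cell; per subregion the mean and SD of the channel intensity over those
    free pixels are reported.  A subregion fully covered by objects has no
    free pixels and is flagged; consuming a flagged entry downstream is an
    error.
    """
    image = np.asarray(image, dtype=float)
    for name, lab in (("nuclei", nuclei_labels), ("cells", cell_labels), ("regions", region_map)):
        if np.asarray(lab).shape != image.shape:
            raise ValueError(f"{name} label map shape differs from image shape")
    free = (np.asarray(nuclei_labels) == 0) & (np.asarray(cell_labels) == 0)
    rows = []
    for sid in np.unique(region_map):
        if sid == 0:
            continue
        sel = (region_map == sid) & free
        n = int(sel.sum())
        if n == 0:
            rows.append(
                {"subregion_id": int(sid), "mean": np.nan, "sd": np.nan,
                 "n_pixels": 0, "flagged": True}
            )
        else:
            vals = image[sel]
            rows.append(
                {"subregion_id": int(sid), "mean": float(vals.mean()),
                 "sd": float(vals.std()), "n_pixels": n, "flagged": False}
            )
    return pd.DataFrame(rows).set_index("subregion_id")


def measure_objects(
    labels: np.ndarray, channels: dict, region_map: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-object size, centroid, per-channel mean intensity and subregion.

    ``channels`` maps channel name -> intensity image.  Centroids are in
    array (row, col[, plane]) order; the subregion is that of the pixel
    under the centroid.  When a region map is supplied, intensity means are
    taken over the object's pixels *within its own subregion* — objects
    straddling a subregion boundary would otherwise mix in the neighbouring
    subregion's background, which has a different offset.  (An object with
    no pixels in its centroid's subregion falls back to its full mask.)
    """
    labels = np.asarray(labels)
    if labels.max() == 0:
        cols = ["label", "size"] + [f"mean_{c}" for c in channels]
        return pd.DataFrame(columns=cols)
    props = regionprops_table(labels, properties=("label", "area", "centroid"))
    table = pd.DataFrame(props).rename(columns={"area": "size"})
    centroid_cols = [c for c in table.columns if c.startswith("centroid-")]

    if region_map is None:
        for name, img in channels.items():
            res = regionprops_table(
                labels, intensity_image=np.asarray(img, dtype=float),
                properties=("label", "intensity_mean"),
            )
            table[f"mean_{name}"] = res["intensity_mean"]
        return table

    table["subregion_id"] = assign_subregion(
        table[centroid_cols].to_numpy(), region_map
    )
    # per-(label, subregion) sums via a combined integer key
    n_sid = int(region_map.max()) + 1
    flat_labels = labels.ravel()
    key = flat_labels.astype(np.int64) * n_sid + region_map.ravel()
    minlength = (int(labels.max()) + 1) * n_sid
    own_key = (
        table["label"].to_numpy(np.int64) * n_sid
        + table["subregion_id"].to_numpy(np.int64)
    )
    counts_by_key = np.bincount(key, minlength=minlength)
    own_counts = counts_by_key[own_key]
    fallback = own_counts == 0
    for name, img in channels.items():
        sums_by_key = np.bincount(
            key, weights=np.asarray(img, dtype=float).ravel(), minlength=minlength
        )
        means = np.full(len(table), np.nan)
        ok = ~fallback
        means[ok] = sums_by_key[own_key[ok]] / own_counts[ok]
        if fallback.any():
            res = regionprops_table(
                labels, intensity_image=np.asarray(img, dtype=float),
                properties=("label", "intensity_mean"),
            )
            full = dict(zip(res["label"], res["intensity_mean"]))
            for i in np.flatnonzero(fallback):
                means[i] = full[int(table["label"].iloc[i])]
        table[f"mean_{name}"] = means
    return table


def _overlap_counts(a_labels: np.ndarray, b_labels: np.ndarray) -> dict:
    """Pixel overlap of every co-occurring (a, b) label pair."""
    both = (a_labels > 0) & (b_labels > 0)
    if not both.any():
        return {}
    pairs = np.stack([a_labels[both], b_labels[both]])
    uniq, counts = np.unique(pairs, axis=1, return_counts=True)
    return {(int(a), int(b)): int(c) for a, b, c in zip(uniq[0], uniq[1], counts)}


def associate_nucleus_cell(
    nuclei: pd.DataFrame,
    nuclei_labels: np.ndarray,
    cells: pd.DataFrame,
    cell_labels: np.ndarray,
    mode: str = "centroid2d",
) -> tuple[pd.DataFrame, list]:
    """Assign at most one nucleus to each cell; list cells left without one.

    ``centroid2d``: a nucleus belongs to the cell whose mask contains its
    centroid pixel (the slide-scanner rule).  ``halfvolume3d``: a nucleus
    belongs to a cell when at least half of its voxels — inclusive — lie
    inside that cell's mask (the confocal z-stack rule).  If several nuclei
    qualify for one cell, the nucleus with the largest mask overlap wins,
    ties to the lowest nucleus id.  Cells without an assigned nucleus are
    discarded from the pairing and reported.
    """
    if mode not in ("centroid2d", "halfvolume3d"):
        raise ValueError("mode must be 'centroid2d' or 'halfvolume3d'")
    nuclei_labels = np.asarray(nuclei_labels)
    cell_labels = np.asarray(cell_labels)
    overlaps = _overlap_counts(nuclei_labels, cell_labels)

    # candidate (cell, nucleus, overlap) triples per the mode's rule
    candidates: list = []
    if mode == "centroid2d":
        centroid_cols = sorted(c for c in nuclei.columns if c.startswith("centroid-"))
        cents = nuclei[centroid_cols].to_numpy(dtype=float)
        for nuc_id, cent in zip(nuclei["label"].astype(int), cents):
            pos = tuple(int(round(v)) for v in cent)
            cell_id = int(cell_labels[pos])
            if cell_id > 0:
                ov = overlaps.get((int(nuc_id), cell_id), 0)
                candidates.append((cell_id, int(nuc_id), ov))
    else:
        sizes = dict(zip(nuclei["label"].astype(int), nuclei["size"].astype(int)))
        for (nuc_id, cell_id), ov in overlaps.items():
            if ov / sizes[nuc_id] >= 0.5:  # inclusive half-volume rule
                candidates.append((cell_id, nuc_id, ov))

    # keep the best nucleus per cell: largest overlap, then lowest nucleus id
    candidates.sort(key=lambda t: (t[0], -t[2], t[1]))
    pairs, seen_cells, seen_nuclei = [], set(), set()
    for cell_id, nuc_id, ov in candidates:
        if cell_id in seen_cells or nuc_id in seen_nuclei:
            continue
        seen_cells.add(cell_id)
        seen_nuclei.add(nuc_id)
        pairs.append({"cell_id": cell_id, "nucleus_id": nuc_id, "overlap_px": ov})

    discarded = sorted(set(cells["label"].astype(int)) - seen_cells)
    return pd.DataFrame(pairs, columns=["cell_id", "nucleus_id", "overlap_px"]), discarded


def classify_cells(
    pairs: pd.DataFrame,
    cells: pd.DataFrame,
    backgrounds: dict,
    k_sigma: float = 2.0,
    neun_channel: str = "neun",
    target_channel: str = "target",
) -> pd.DataFrame:
    """Classify associated cells as NeuN+/- and target+/-.

    ``backgrounds`` maps channel name -> the frame from
    :func:`estimate_background`.  A cell is positive for a marker when its
    raw mean intensity in that channel is at least
    ``background_mean + k_sigma * background_sd`` of its own subregion.
    Background-subtracted intensities (raw - background mean, possibly
    negative) are recorded per channel; classification never uses them.
    """
    cells_idx = cells.set_index("label")
    rows = []
    for pair in pairs.itertuples(index=False):
        cell = cells_idx.loc[pair.cell_id]
        sid = int(cell["subregion_id"])
        rec = {"cell_id": int(pair.cell_id), "nucleus_id": int(pair.nucleus_id),
               "subregion_id": sid}
        for channel, positive_col in (
            (neun_channel, "neun_pos"),
            (target_channel, "target_pos"),
        ):
            bg = backgrounds[channel]
            if sid not in bg.index:
                raise KeyError(f"no background entry for subregion {sid}")
            entry = bg.loc[sid]
            if bool(entry["flagged"]):
                raise ValueError(
                    f"background for subregion {sid} channel {channel!r} is "
                    "flagged (no object-free pixels)"
                )
            raw = float(cell[f"mean_{channel}"])
            rec[f"raw_{channel}"] = raw
            rec[f"norm_{channel}"] = raw - float(entry["mean"])
            rec[positive_col] = raw >= entry["mean"] + k_sigma * entry["sd"]
        rows.append(rec)
    return pd.DataFrame(rows)


def _class_of(row) -> str:
    t = "target_pos" if row["target_pos"] else "target_neg"
    n = "neun_pos" if row["neun_pos"] else "neun_neg"
    return f"{t}_{n}"


def summarize_regions(
    cell_table: pd.DataFrame,
    geometry: pd.DataFrame,
    hierarchy: RegionHierarchy,
    target_channel: str = "target",
) -> pd.DataFrame:
    """Counts, densities, proportions and intensities per region level.

    One row per subregion, per parent region and one brain-wide row.  Parent
    and brain-wide rows are formed by summing counts and areas and pooling
    the per-cell intensity lists — densities are recomputed from the pooled
    counts, never averaged across children.  Intensity statistics (mean, SD)
    cover the background-subtracted target intensity of target-positive
    cells only.
    """
    sub_geo = geometry[geometry["level"] == "subregion"].set_index("subregion_id")
    if (sub_geo["area_mm2"] <= 0).any():
        raise ValueError("region with zero area")
    missing = set(cell_table["subregion_id"]) - set(sub_geo.index)
    if missing:
        raise ValueError(f"geometry missing for subregions {sorted(missing)}")

    work = cell_table.copy()
    work["cls"] = work.apply(_class_of, axis=1)
    norm_col = f"norm_{target_channel}"

    def one_row(cells: pd.DataFrame, area: float, name, level, parent) -> dict:
        counts = {c: int((cells["cls"] == c).sum()) for c in CLASS_LABELS}
        total = sum(counts.values())
        pos = cells.loc[cells["target_pos"], norm_col]
        row = {
            "name": name,
            "level": level,
            "parent": parent,
            "area_mm2": area,
            "n_cells": total,
        }
        for c in CLASS_LABELS:
            row[f"count_{c}"] = counts[c]
            row[f"density_{c}"] = counts[c] / area
            row[f"prop_{c}"] = counts[c] / total if total else np.nan
        row["density_target_pos"] = (
            counts["target_pos_neun_pos"] + counts["target_pos_neun_neg"]
        ) / area
        row["mean_norm_target"] = float(pos.mean()) if len(pos) else np.nan
        row["sd_norm_target"] = float(pos.std(ddof=1)) if len(pos) > 1 else np.nan
        row["n_target_pos"] = int(len(pos))
        return row

    rows = []
    for sid in sub_geo.index:
        rows.append(
            one_row(
                work[work["subregion_id"] == sid],
                float(sub_geo.loc[sid, "area_mm2"]),
                sid,
                "subregion",
                hierarchy.parents.get(int(sid)),
            )
        )
    parent_of = hierarchy.parents
    work["parent"] = work["subregion_id"].map(lambda s: parent_of.get(int(s)))
    for parent in sorted(set(parent_of[int(s)] for s in sub_geo.index)):
        sids = [s for s in sub_geo.index if parent_of[int(s)] == parent]
        rows.append(
            one_row(
                work[work["parent"] == parent],
                float(sub_geo.loc[sids, "area_mm2"].sum()),
                parent,
                "region",
                "brain",
            )
        )
    rows.append(one_row(work, float(sub_geo["area_mm2"].sum()), "brain", "brain", None))
    return pd.DataFrame(rows)


def quantify(
    channels: dict,
    nuclei_labels: np.ndarray,
    cell_labels: np.ndarray,
    region_map: np.ndarray,
    hierarchy: RegionHierarchy,
    mode: str = "centroid2d",
    k_sigma: float = 2.0,
    neun_channel: str = "neun",
    target_channel: str = "target",
) -> dict:
    """Run the full quantification over given label maps.

    Composes background estimation, object measurement, nucleus-cell
    association, classification and region summarisation.  The label maps
    may come from :mod:`~l1quant.detection` or be injected ground truth
    (segmentation bypass).  Returns a dict with the cell table, region
    summary, backgrounds, pairs and discarded cells.
    """
    from .atlas import compute_geometry

    geometry = compute_geometry(region_map, hierarchy)
    nuclei = measure_objects(nuclei_labels, channels, region_map)
    cells = measure_objects(cell_labels, channels, region_map)
    backgrounds = {
        ch: estimate_background(channels[ch], nuclei_labels, cell_labels, region_map)
        for ch in (neun_channel, target_channel)
    }
    pairs, discarded = associate_nucleus_cell(
        nuclei, nuclei_labels, cells, cell_labels, mode=mode
    )
    cell_table = classify_cells(
        pairs, cells, backgrounds, k_sigma=k_sigma,
        neun_channel=neun_channel, target_channel=target_channel,
    )
    summary = summarize_regions(cell_table, geometry, hierarchy, target_channel)
    return {
        "cell_table": cell_table,
        "summary": summary,
        "backgrounds": backgrounds,
        "pairs": pairs,
        "discarded_cells": discarded,
        "geometry": geometry,
    }
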