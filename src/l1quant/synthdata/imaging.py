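"""Synthetic multichannel brain images with ground truth.

The imaging model mirrors what the quantification pipeline assumes about
real slide-scanner and confocal acquisitions:

* the field of view is partitioned into atlas subregions, each with its own
  scalar background level per channel (i.i.d. Gaussian pixel noise around a
  per-subregion offset, clipped at zero);
* cells are disks (2D) or spheres (3D) with a concentric nucleus; the
  neuronal marker is rendered as a cytoplasmic annulus (NeuN-like), the
  target marker fills the whole cell body of target-positive cells;
* cell counts per subregion are Poisson in density x area; class membership
  (neuron, target-positive) is Bernoulli with programmed fractions; true
  signal amplitudes are log-normal, added on top of the background;
* an ``age_effect`` factor multiplies the target-channel amplitude of
  target-positive cells, emulating an aged cohort.

Ground truth carries every placed cell with its class flags, true
amplitudes, and rasterized nucleus/cell label maps, so segmentation can be
bypassed and parameter recovery checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CHANNELS = ("nuclear", "neun", "target")

__all__ = [
    "CHANNELS",
    "RegionSpec",
    "CellPopulationSpec",
    "ImageBundle",
    "GroundTruth",
    "generate_region_map",
    "generate_brain_image",
]


def _per_channel(value) -> dict:
    if isinstance(value, dict):
        return {c: float(value.get(c, 0.0)) for c in CHANNELS}
    return {c: float(value) for c in CHANNELS}


@dataclass
class RegionSpec:
    """One atlas subregion: its share of the image and its background."""

    subregion_id: int
    parent_region: str
    area_fraction: float
    background_mean: dict | float = 100.0  # per channel, intensity units
    background_sd: dict | float = 10.0
    name: str | None = None

    def __post_init__(self):
        if self.subregion_id <= 0:
            raise ValueError("subregion ids must be positive")
        if self.area_fraction <= 0:
            raise ValueError(
                f"zero/negative area fraction for subregion {self.subregion_id}"
            )
        self.background_mean = _per_channel(self.background_mean)
        self.background_sd = _per_channel(self.background_sd)
        if any(v < 0 for v in self.background_sd.values()):
            raise ValueError("background_sd must be >= 0")


@dataclass
class CellPopulationSpec:
    """Programmed cell population of one subregion.

    ``density`` is in cells per mm^2 (of in-plane area), radii in
    micrometres, ``intensity_lognormal`` maps channel -> (mu, sigma) of the
    log signal amplitude, and ``age_effect`` multiplies the target-channel
    amplitude of target-positive cells.
    """

    density: float = 300.0
    neuron_fraction: float = 0.4
    target_pos_fraction_in_neurons: float = 0.5
    target_pos_fraction_in_nonneurons: float = 0.02
    intensity_lognormal: dict = field(
        default_factory=lambda: {
            "nuclear": (6.0, 0.3),
            "neun": (6.0, 0.3),
            "target": (6.0, 0.5),
        }
    )
    nucleus_radius: float = 4.0
    cell_radius: float = 8.0
    age_effect: float = 1.0

    def __post_init__(self):
        for p in (
            self.neuron_fraction,
            self.target_pos_fraction_in_neurons,
            self.target_pos_fraction_in_nonneurons,
        ):
            if not 0 <= p <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.nucleus_radius <= 0 or self.cell_radius <= 0:
            raise ValueError("radii must be positive")
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if self.age_effect <= 0:
            raise ValueError("age_effect must be positive")


@dataclass
class ImageBundle:
    """Multichannel intensity images plus acquisition metadata."""

    channels: dict  # channel name -> ndarray
    pixel_size: float  # um per pixel edge
    mode: str  # '2D' | '3D'


@dataclass
class GroundTruth:
    """Everything the generator knows about the placed cells."""

    cells: pd.DataFrame  # one row per cell
    nuclei_labels: np.ndarray
    cell_labels: np.ndarray


def generate_region_map(
    specs: list, shape: tuple, pixel_size: float = 1.0, seed: int = 0
) -> tuple[np.ndarray, pd.DataFrame]:
    """Partition an image into subregions with the requested area fractions.

    Subregions are contiguous raster-order blocks whose pixel counts follow
    the largest-remainder apportionment of the requested fractions (exact to
    one pixel); the block order is shuffled by the seed.  Returns the label
    image and a hierarchy table (subregion_id, parent, name).
    """
    if not specs:
        raise ValueError("no region specs given")
    ids = [s.subregion_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subregion ids")
    fractions = np.array([s.area_fraction for s in specs], dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("area fractions must sum to 1")
    if len(shape) not in (2, 3):
        raise ValueError("shape must be 2D or 3D")

    n_pixels = int(np.prod(shape))
    quotas = fractions * n_pixels
    counts = np.floor(quotas).astype(int)
    remainder = n_pixels - counts.sum()
    order_by_frac = np.argsort(-(quotas - counts))
    counts[order_by_frac[:remainder]] += 1
    if (counts == 0).any():
        bad = [ids[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"zero-area realization for subregions {bad}")

    rng = np.random.default_rng(seed)
    block_order = rng.permutation(len(specs))
    flat = np.empty(n_pixels, dtype=np.int32)
    pos = 0
    for i in block_order:
        flat[pos : pos + counts[i]] = ids[i]
        pos += counts[i]
    label_image = flat.reshape(shape)

    hierarchy = pd.DataFrame(
        {
            "subregion_id": ids,
            "parent": [s.parent_region for s in specs],
            "name": [s.name or f"subregion-{s.subregion_id}" for s in specs],
        }
    )
    return label_image, hierarchy


def _ball_mask(radius_px: float, ndim: int) -> np.ndarray:
    r = int(np.ceil(radius_px))
    grids = np.ogrid[tuple(slice(-r, r + 1) for _ in range(ndim))]
    dist2 = sum(g.astype(float) ** 2 for g in grids)
    return dist2 <= radius_px**2


def _paste(target: np.ndarray, mask: np.ndarray, center: tuple, value: float) -> None:
    r = mask.shape[0] // 2
    slices_t, slices_m = [], []
    for c, size in zip(center, target.shape):
        lo, hi = c - r, c + r + 1
        slices_t.append(slice(max(lo, 0), min(hi, size)))
        slices_m.append(slice(max(lo, 0) - lo, mask.shape[0] - (hi - min(hi, size))))
    region = target[tuple(slices_t)]
    region[mask[tuple(slices_m)]] += value


def _paste_label(target: np.ndarray, mask: np.ndarray, center: tuple, label: int) -> None:
    r = mask.shape[0] // 2
    slices_t, slices_m = [], []
    for c, size in zip(center, target.shape):
        lo, hi = c - r, c + r + 1
        slices_t.append(slice(max(lo, 0), min(hi, size)))
        slices_m.append(slice(max(lo, 0) - lo, mask.shape[0] - (hi - min(hi, size))))
    region = target[tuple(slices_t)]
    region[mask[tuple(slices_m)]] = label


def generate_brain_image(
    region_map: np.ndarray,
    populations: dict,
    region_specs: dict,
    pixel_size: float = 1.0,
    mode: str = "2D",
    seed: int = 0,
    max_retries: int = 100,
) -> tuple[ImageBundle, GroundTruth]:
    """Render a synthetic acquisition over a subregion label map.

    ``populations`` and ``region_specs`` map subregion id to
    :class:`CellPopulationSpec` and :class:`RegionSpec`.  Cell placement,
    class flags and amplitudes are drawn from one RNG stream and the
    background noise from an independent child stream, so two runs that
    differ only in ``age_effect`` place identical cells with target
    amplitudes scaled by exactly the ratio of the factors.
    """
    region_map = np.asarray(region_map)
    if mode not in ("2D", "3D"):
        raise ValueError("mode must be '2D' or '3D'")
    if (mode == "2D") != (region_map.ndim == 2):
        raise ValueError("mode and region map dimensionality disagree")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    sids = [int(s) for s in np.unique(region_map) if s != 0]
    missing = [s for s in sids if s not in populations]
    if missing:
        raise ValueError(f"no population spec for subregions {missing}")

    ss = np.random.SeedSequence(seed)
    rng_cells, rng_bg = (np.random.default_rng(c) for c in ss.spawn(2))
    ndim = region_map.ndim

    # in-plane area per subregion (xy footprint for 3D stacks)
    n_planes = region_map.shape[0] if ndim == 3 else 1
    px_area_mm2 = pixel_size**2 / 1e6

    cells_rows = []
    nuclei_labels = np.zeros(region_map.shape, dtype=np.int32)
    cell_labels = np.zeros(region_map.shape, dtype=np.int32)
    images = {c: np.zeros(region_map.shape, dtype=float) for c in CHANNELS}
    next_id = 1

    placed_centers = np.empty((0, ndim), dtype=float)
    placed_radii = np.empty(0, dtype=float)

    for sid in sids:
        pop = populations[sid]
        radius_px = pop.cell_radius / pixel_size
        nucleus_px = pop.nucleus_radius / pixel_size
        if radius_px < 1 or nucleus_px < 1:
            raise ValueError("cell/nucleus radius smaller than one pixel")
        cell_mask = _ball_mask(radius_px, ndim)
        nucleus_mask = _ball_mask(nucleus_px, ndim)

        coords = np.argwhere(region_map == sid)
        area_mm2 = (len(coords) / n_planes) * px_area_mm2
        n_cells = rng_cells.poisson(pop.density * area_mm2)

        for _ in range(n_cells):
            center = None
            for _attempt in range(max_retries):
                cand = coords[rng_cells.integers(len(coords))]
                if len(placed_centers):
                    d2 = ((placed_centers - cand) ** 2).sum(axis=1)
                    if (d2 < (placed_radii + radius_px) ** 2).any():
                        continue
                if any(cand < np.ceil(radius_px)) or any(
                    cand > np.array(region_map.shape) - np.ceil(radius_px) - 1
                ):
                    continue
                center = cand
                break
            if center is None:
                raise RuntimeError(
                    f"cannot place requested density in subregion {sid} "
                    f"without overlap after {max_retries} retries"
                )
            placed_centers = np.vstack([placed_centers, cand[None, :].astype(float)])
            placed_radii = np.append(placed_radii, radius_px)

            is_neuron = rng_cells.random() < pop.neuron_fraction
            p_target = (
                pop.target_pos_fraction_in_neurons
                if is_neuron
                else pop.target_pos_fraction_in_nonneurons
            )
            is_target = rng_cells.random() < p_target
            amps = {
                c: float(rng_cells.lognormal(*pop.intensity_lognormal[c]))
                for c in CHANNELS
            }
            amps["target"] *= pop.age_effect

            center_t = tuple(int(v) for v in center)
            _paste(images["nuclear"], nucleus_mask, center_t, amps["nuclear"])
            if is_neuron:
                # cytoplasmic annulus: whole body minus the nucleus
                _paste(images["neun"], cell_mask, center_t, amps["neun"])
                _paste(images["neun"], nucleus_mask, center_t, -amps["neun"])
            if is_target:
                _paste(images["target"], cell_mask, center_t, amps["target"])
            _paste_label(nuclei_labels, nucleus_mask, center_t, next_id)
            _paste_label(cell_labels, cell_mask, center_t, next_id)

            cells_rows.append(
                {
                    "cell_id": next_id,
                    **{f"centroid-{i}": float(center[i]) for i in range(ndim)},
                    "subregion_id": sid,
                    "is_neuron": is_neuron,
                    "is_target_pos": is_target,
                    "true_nuclear": amps["nuclear"],
                    "true_neun": amps["neun"] if is_neuron else 0.0,
                    "true_target": amps["target"] if is_target else 0.0,
                }
            )
            next_id += 1

    # per-subregion background, independent noise stream
    for channel in CHANNELS:
        bg = np.zeros(region_map.shape, dtype=float)
        for sid in sids:
            spec = region_specs[sid]
            sel = region_map == sid
            noise = rng_bg.normal(
                spec.background_mean[channel], spec.background_sd[channel],
                size=int(sel.sum()),
            )
            bg[sel] = np.clip(noise, 0, None)
        images[channel] += bg

    columns = (
        ["cell_id"]
        + [f"centroid-{i}" for i in range(ndim)]
        + ["subregion_id", "is_neuron", "is_target_pos",
           "true_nuclear", "true_neun", "true_target"]
    )
    cells = pd.DataFrame(cells_rows, columns=columns)
    bundle = ImageBundle(channels=images, pixel_size=pixel_size, mode=mode)
    truth = GroundTruth(cells=cells, nuclei_labels=nuclei_labels, cell_labels=cell_labels)
    return bundle, truth
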