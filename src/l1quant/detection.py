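"""Instance segmentation of nuclei and cell bodies, and object filtering.

The production pipelines in this field run pretrained deep-learning
segmenters (StarDist for nuclei, Cellpose for cell bodies).  Those models are
external artifacts, not part of this package; here they appear behind two
interchangeable entry points:

* a **builtin classical segmenter** (Otsu threshold + distance-transform
  watershed + connected components) sufficient for the synthetic images the
  test-bed generates, and
* a **file-based adapter contract** for any external tool that reads an
  intensity TIFF and writes an instance-label TIFF.

Detection is optionally run on a downscaled image and the label map rescaled
back to the original resolution, matching the common practice for large
acquisitions.  Objects are then filtered by size (area in 2D, voxels in 3D)
and by mean intensity against a background-derived threshold.
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import watershed
from skimage.transform import rescale

__all__ = [
    "SegmenterConfig",
    "segment_objects",
    "rescale_label_map",
    "filter_objects",
]


@dataclass
class SegmenterConfig:
    """Configuration of a segmentation run.

    ``method`` is ``"builtin"`` or ``"external"``.  ``downscale_factor``
    downsamples the image before detection (labels are rescaled back).
    ``min_distance`` separates watershed seeds (pixels, at the detection
    scale); ``smoothing_sigma`` is the Gaussian pre-filter.  ``command``
    holds the external adapter template with ``{input}``/``{output}``
    placeholders; any extra model hyperparameters ride along untouched in
    ``passthrough``.
    """

    method: str = "builtin"
    downscale_factor: int = 1
    min_distance: int = 5
    smoothing_sigma: float = 1.0
    command: str | None = None
    passthrough: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.downscale_factor < 1 or int(self.downscale_factor) != self.downscale_factor:
            raise ValueError("downscale_factor must be an integer >= 1")
        if self.method not in ("builtin", "external"):
            raise ValueError("method must be 'builtin' or 'external'")
        if self.method == "external" and not self.command:
            raise ValueError("external method requires a command template")


def _builtin_segment(image: np.ndarray, config: SegmenterConfig) -> np.ndarray:
    smoothed = gaussian(image.astype(float), sigma=config.smoothing_sigma)
    if np.ptp(smoothed) == 0:  # constant image: nothing to detect
        return np.zeros(image.shape, dtype=np.int32)
    thr = threshold_otsu(smoothed)
    mask = smoothed > thr
    if not mask.any():
        return np.zeros(image.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance, min_distance=config.min_distance, labels=cc_label(mask)
    )
    if len(peaks) == 0:
        return cc_label(mask).astype(np.int32)
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, markers, mask=mask)
    return _relabel(labels)  # renumber to consecutive positive ids


def _relabel(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids != 0]
    lut = np.zeros(labels.max() + 1 if labels.size else 1, dtype=np.int32)
    lut[ids] = np.arange(1, len(ids) + 1)
    return lut[labels]


def _external_segment(image: np.ndarray, config: SegmenterConfig) -> np.ndarray:
    import tifffile

    with tempfile.TemporaryDirectory() as tmp:
        inp = Path(tmp) / "input.tif"
        out = Path(tmp) / "labels.tif"
        tifffile.imwrite(inp, image)
        cmd = config.command.format(input=inp, output=out, **config.passthrough)
        subprocess.run(shlex.split(cmd), check=True)
        if not out.exists():
            raise RuntimeError("external segmenter wrote no label TIFF")
        labels = tifffile.imread(out)
    if labels.shape != image.shape:
        raise ValueError(
            f"adapter returned shape {labels.shape}, expected {image.shape}"
        )
    return labels.astype(np.int32)


def segment_objects(image: np.ndarray, config: SegmenterConfig | None = None) -> np.ndarray:
    """Segment one channel into an instance label map (0 = background)."""
    config = config or SegmenterConfig()
    image = np.asarray(image)
    if image.ndim not in (2, 3):
        raise ValueError("expected a single-channel 2D or 3D image")
    f = int(config.downscale_factor)
    work = image
    if f > 1:
        work = rescale(
            image.astype(float), 1.0 / f, anti_aliasing=True, preserve_range=True
        )
    if config.method == "builtin":
        labels = _builtin_segment(work, config)
    else:
        labels = _external_segment(work, config)
    if f > 1:
        labels = rescale_label_map(labels, f)
        labels = _match_shape(labels, image.shape)
    return labels


def _match_shape(labels: np.ndarray, shape: tuple) -> np.ndarray:
    """Crop/edge-pad a rescaled label map to the original shape."""
    out = labels
    for axis, target in enumerate(shape):
        size = out.shape[axis]
        if size > target:
            out = np.take(out, range(target), axis=axis)
        elif size < target:
            pad = [(0, 0)] * out.ndim
            pad[axis] = (0, target - size)
            out = np.pad(out, pad, mode="edge")
    return out


def rescale_label_map(labels: np.ndarray, factor: int) -> np.ndarray:
    """Nearest-neighbour upscaling of an instance label map.

    Label identities are preserved and no new labels appear; each pixel
    becomes a ``factor``-sized block, so per-label pixel counts scale by
    ``factor ** ndim`` exactly.
    """
    if factor != int(factor) or factor < 1:
        raise ValueError("rescale factor must be an integer >= 1")
    factor = int(factor)
    out = np.asarray(labels)
    for axis in range(out.ndim):
        out = np.repeat(out, factor, axis=axis)
    return out


def filter_objects(
    labels: np.ndarray,
    measurements: pd.DataFrame,
    size_range: tuple,
    min_mean_intensity: float = 0.0,
    intensity_column: str = "mean_intensity",
) -> tuple[np.ndarray, pd.DataFrame]:
    """Remove objects outside a size window or below an intensity threshold.

    ``measurements`` must carry one row per label with columns ``label``,
    ``size`` and the intensity column (typically the object's mean intensity
    in its own channel).  Removed labels are set to background and the
    removal log states the violated criterion per object.  The operation is
    idempotent: filtering an already-filtered map changes nothing.
    """
    size_min, size_max = size_range
    if size_min > size_max:
        raise ValueError("size_min > size_max")
    labels = np.asarray(labels)
    present = set(np.unique(labels)) - {0}
    covered = set(measurements["label"].astype(int))
    missing = sorted(present - covered)
    if missing:
        raise ValueError(f"measurements missing for labels {missing}")

    log_rows = []
    drop = []
    for row in measurements.itertuples(index=False):
        if row.label not in present:
            continue
        reasons = []
        if not size_min <= row.size <= size_max:
            reasons.append("size")
        if getattr(row, intensity_column) < min_mean_intensity:
            reasons.append("intensity")
        if reasons:
            drop.append(row.label)
            log_rows.append({"label": int(row.label), "reason": "+".join(reasons)})

    out = labels.copy()
    if drop:
        out[np.isin(out, drop)] = 0
    return out, pd.DataFrame(log_rows, columns=["label", "reason"])
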