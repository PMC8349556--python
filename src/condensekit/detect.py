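"""Threshold segmentation and per-object measurement.

The particle-analysis step: apply an intensity threshold to a channel,
label connected components (8-connectivity in 2D, 26 in 3D), discard
objects below a size floor, and measure each object's intensity-weighted
centroid, pixel area, and raw intensity sum. Measurements are always taken
on the original, unthresholded intensities within each component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = ["DetectedObject", "segment_channel", "auto_threshold", "objects_to_table"]


@dataclass(frozen=True)
class DetectedObject:
    """A single segmented particle in one frame of one channel.

    ``centroid`` is the intensity-weighted center of mass in (row, col)
    pixel coordinates (origin top-left, 0-based). ``on_border`` flags
    objects touching the image edge; they are kept, not dropped.
    """

    frame: int
    channel: str
    label: int
    centroid: tuple[float, ...]
    area: int
    intensity_sum: float
    on_border: bool = False


def segment_channel(
    image,
    threshold: float,
    min_size: int = 1,
    *,
    frame: int = 0,
    channel: str = "",
) -> list[DetectedObject]:
    """Segment one frame of one channel into measured objects.

    Objects are the 8-connected components (26-connected for 3D input) of
    ``{pixel >= threshold}`` with at least ``min_size`` pixels. Labels are
    re-densified to 1..N after the size filter. An image with nothing
    above threshold yields an empty list.
    """
    img = np.asarray(image, dtype=float)
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    mask = img >= threshold
    structure = ndimage.generate_binary_structure(img.ndim, img.ndim)
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return []

    counts = np.bincount(labels.ravel())[1:]  # per-label pixel counts
    keep = np.flatnonzero(counts >= min_size) + 1

    objects: list[DetectedObject] = []
    border = _border_labels(labels)
    for new_label, lab in enumerate(keep, start=1):
        com = ndimage.center_of_mass(img, labels, lab)
        isum = float(ndimage.sum_labels(img, labels, lab))
        objects.append(
            DetectedObject(
                frame=frame,
                channel=channel,
                label=new_label,
                centroid=tuple(float(c) for c in com),
                area=int(counts[lab - 1]),
                intensity_sum=isum,
                on_border=lab in border,
            )
        )
    return objects


def _border_labels(labels: np.ndarray) -> set[int]:
    edge = set()
    for axis in range(labels.ndim):
        edge.update(np.unique(np.take(labels, 0, axis=axis)))
        edge.update(np.unique(np.take(labels, -1, axis=axis)))
    edge.discard(0)
    return edge


def auto_threshold(image, method: str = "otsu", k: float = 3.0) -> float:
    """Reproducible default threshold for a channel.

    ``method='otsu'`` uses Otsu's criterion on a 256-bin histogram and
    fails on a constant image (use ``mean_plus_k_sd`` there, which returns
    exactly ``mean + k·sd``).
    """
    img = np.asarray(image, dtype=float)
    if method == "otsu":
        if img.max() == img.min():
            raise ValueError(
                "otsu is undefined on a constant image; use method='mean_plus_k_sd'"
            )
        return float(threshold_otsu(img, nbins=256))
    if method == "mean_plus_k_sd":
        return float(img.mean() + k * img.std())
    raise ValueError(f"unknown method {method!r}")


def objects_to_table(objects: list[DetectedObject]) -> pd.DataFrame:
    """Flatten detected objects into the standard objects table."""
    rows = []
    for o in objects:
        row = o.centroid[-2] if len(o.centroid) >= 2 else o.centroid[0]
        col = o.centroid[-1]
        rows.append(
            {
                "frame": o.frame,
                "channel": o.channel,
                "label": o.label,
                "row": row,
                "col": col,
                "area_px": o.area,
                "intensity_sum": o.intensity_sum,
                "on_border": o.on_border,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "frame", "channel", "label", "row", "col",
            "area_px", "intensity_sum", "on_border",
        ],
    )
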