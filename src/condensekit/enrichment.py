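"""Fold-enrichment in condensates and microtubule-density scoring.

Two immunofluorescence readouts:

* ``fold_enrichment`` — how concentrated a stained protein is inside a
  condensate relative to the cytoplasm, measured from a few small square
  ROIs sampled at random inside each compartment (mean of ROI means per
  cell), with an exclusion zone around centrosomes embedded in the
  condensate so centrosomal signal does not inflate the condensate mean.
* ``tubulin_density_ratio`` — regrowing-microtubule density (intensity
  sum per area) inside a condensate region over the density in the 1-μm
  annulus just outside it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .stats import mean_ci95

__all__ = ["EnrichmentResult", "fold_enrichment", "group_fold_enrichment",
           "tubulin_density_ratio"]


@dataclass(frozen=True)
class EnrichmentResult:
    cell_id: int
    condensate_mean: float
    cytoplasm_mean: float

    @property
    def fold_enrichment(self) -> float:
        return self.condensate_mean / self.cytoplasm_mean


def _sample_rois(
    mask: np.ndarray,
    side_px: int,
    n_rois: int,
    rng: np.random.Generator,
    forbidden: np.ndarray | None,
    name: str,
) -> list[tuple[int, int]]:
    """Uniformly sample top-left corners of square ROIs fully inside mask."""
    if min(mask.shape) < side_px:
        raise ValueError(f"{name} mask too small for a {side_px}px square ROI")
    windows = np.lib.stride_tricks.sliding_window_view(mask, (side_px, side_px))
    valid = windows.all(axis=(2, 3))
    if forbidden is not None:
        overlap = np.lib.stride_tricks.sliding_window_view(
            forbidden, (side_px, side_px)
        ).any(axis=(2, 3))
        valid &= ~overlap
    corners = np.argwhere(valid)
    if corners.shape[0] == 0:
        raise ValueError(f"{name} mask too small for a {side_px}px square ROI")
    idx = rng.integers(0, corners.shape[0], size=n_rois)
    return [tuple(c) for c in corners[idx]]


def fold_enrichment(
    image,
    condensate_mask,
    cytoplasm_mask,
    centrosome_positions=(),
    roi_area: float = 2.25,
    n_rois: int = 3,
    calibration: float = 0.1,
    exclusion_radius: float = 0.5,
    seed: int = 0,
    cell_id: int = 0,
) -> EnrichmentResult:
    """Fold enrichment of a stained protein in the condensate of one cell.

    ``n_rois`` square ROIs of ``roi_area`` μm² (side √area, default
    2.25 μm² → 1.5 μm side) are placed uniformly at random fully inside
    each of the condensate and cytoplasm masks; the per-compartment value
    is the mean of the ROI means. Condensate ROIs additionally avoid a
    disk of ``exclusion_radius`` μm around each centrosome position
    (pixels, row/col) so embedded centrosomal signal is excluded.
    """
    img = np.asarray(image, dtype=float)
    cond = np.asarray(condensate_mask, dtype=bool)
    cyto = np.asarray(cytoplasm_mask, dtype=bool)
    if (cond & cyto).any():
        raise ValueError("condensate and cytoplasm masks must be disjoint")
    if n_rois < 3:
        raise ValueError("need at least 3 ROIs per compartment")
    side_px = max(1, int(round(np.sqrt(roi_area) / calibration)))
    rng = np.random.default_rng(seed)

    forbidden = None
    if len(centrosome_positions) and exclusion_radius > 0:
        forbidden = np.zeros_like(cond)
        rr, cc = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
        r_px = exclusion_radius / calibration
        for (py, px) in centrosome_positions:
            forbidden |= (rr - py) ** 2 + (cc - px) ** 2 <= r_px**2

    means = {}
    for name, mask, forb in (
        ("condensate", cond, forbidden),
        ("cytoplasm", cyto, None),
    ):
        corners = _sample_rois(mask, side_px, n_rois, rng, forb, name)
        roi_means = [
            float(img[y : y + side_px, x : x + side_px].mean())
            for (y, x) in corners
        ]
        means[name] = float(np.mean(roi_means))
    return EnrichmentResult(
        cell_id=cell_id,
        condensate_mean=means["condensate"],
        cytoplasm_mean=means["cytoplasm"],
    )


def group_fold_enrichment(results: list[EnrichmentResult]) -> dict:
    """Group-level fold enrichment across cells.

    The group fold is the mean condensate intensity across cells over the
    mean cytoplasm intensity across cells; per-cell folds and their 95%
    CI, and a t-test of the per-cell folds against unity, are included.
    """
    if not results:
        raise ValueError("no cells supplied")
    cond = np.array([r.condensate_mean for r in results])
    cyto = np.array([r.cytoplasm_mean for r in results])
    folds = cond / cyto
    out = {
        "fold_enrichment": float(cond.mean() / cyto.mean()),
        "per_cell_folds": folds.tolist(),
        "n_cells": len(results),
    }
    if len(results) >= 2:
        m, lo, hi = mean_ci95(folds)
        out["per_cell_fold_mean"] = m
        out["per_cell_fold_ci95"] = [lo, hi]
        if folds.std(ddof=1) > 0:
            from scipy import stats as sps

            out["t_vs_unity_p"] = float(sps.ttest_1samp(folds, 1.0).pvalue)
    return out


def tubulin_density_ratio(image, region_mask, calibration: float = 0.1) -> float:
    """Normalized microtubule density: condensate over its 1-μm annulus.

    Density is intensity sum per pixel area inside the condensate region
    and inside the annulus obtained by dilating the region by 1 μm and
    subtracting it. The region must leave room for the full annulus
    inside the image.
    """
    img = np.asarray(image, dtype=float)
    region = np.asarray(region_mask, dtype=bool)
    if not region.any():
        raise ValueError("region mask is empty")
    r_px = int(round(1.0 / calibration))
    yy, xx = np.mgrid[-r_px : r_px + 1, -r_px : r_px + 1]
    selem = yy**2 + xx**2 <= r_px**2
    dilated = ndimage.binary_dilation(region, structure=selem)
    # the annulus must fit: dilation may silently clip at the border
    edge = (
        dilated[0, :].any() or dilated[-1, :].any()
        or dilated[:, 0].any() or dilated[:, -1].any()
    )
    if edge:
        raise ValueError("region too close to the image border for a 1 um annulus")
    annulus = dilated & ~region
    if not annulus.any():
        raise ValueError("annulus is empty")
    dens_in = img[region].sum() / region.sum()
    dens_out = img[annulus].sum() / annulus.sum()
    return float(dens_in / dens_out)
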