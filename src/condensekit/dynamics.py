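"""Per-cell condensate kinetics, staging, granule counts and dissolution.

Turns tracked cells into the quantities plotted in condensate time-lapse
studies: condensate number, total size and distance to the centrosome per
cell over time, aligned at each cell's phase-separation onset; granule
counts with centrosome-coincident objects excluded; a rule-based
cell-cycle stager; and per-cell percentage-remaining dissolution curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import StatResult, mean_ci95, one_way_anova
from .track import CellTrack

__all__ = [
    "condensate_timeseries",
    "align_at_onset",
    "distance_at_onset",
    "count_granules",
    "classify_stage",
    "StageFeatures",
    "dissolution_percent_remaining",
    "STAGES",
]

STAGES = (
    "G1/early S",
    "S/early G2",
    "late G2",
    "prophase",
    "prometaphase",
    "metaphase",
    "anaphase",
    "unclassified",
)


def condensate_timeseries(
    cell_track: CellTrack,
    calibration: float,
    frame_interval_s: float,
) -> pd.DataFrame:
    """Per-frame condensate metrics for one cell.

    Returns a frame-indexed table with columns time_s, count,
    total_area_um2, mean_distance_um and the per-condensate distance list.
    Size is the summed pixel area scaled by calibration²; each
    condensate's distance is the Euclidean centroid distance (μm) to the
    nearest centrosome assigned to the same cell in that frame; the
    per-cell distance is the unweighted mean over condensates. Frames with
    no condensates carry count 0, size 0 and NaN distance; frames with no
    centrosome carry NaN distance and are flagged.
    """
    rows = []
    for f in cell_track.frames:
        conds = cell_track.condensates.get(f, [])
        cents = cell_track.centrosomes.get(f, [])
        total_area = sum(o.area for o in conds) * calibration**2
        dists: list[float] = []
        no_centrosome = bool(conds) and not cents
        if conds and cents:
            cpos = np.array([o.centroid[-2:] for o in cents], dtype=float) * calibration
            for o in conds:
                p = np.asarray(o.centroid[-2:], dtype=float) * calibration
                dists.append(float(np.min(np.linalg.norm(cpos - p, axis=1))))
        rows.append(
            {
                "frame": f,
                "time_s": f * frame_interval_s,
                "count": len(conds),
                "total_area_um2": total_area,
                "max_condensate_area_um2": (
                    max(o.area for o in conds) * calibration**2 if conds else 0.0
                ),
                "mean_distance_um": float(np.mean(dists)) if dists else np.nan,
                "distances_um": dists,
                "no_centrosome": no_centrosome,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["cell_id"] = cell_track.cell_id
    return df


def align_at_onset(series: pd.DataFrame, min_area: float = 0.0) -> pd.DataFrame | None:
    """Re-zero a cell's time axis at its phase-separation onset.

    Onset is the first frame holding at least one condensate whose area is
    ``≥ min_area`` (μm²); the returned copy gains a ``time_aligned_s``
    column that is 0 there. A cell that never qualifies returns ``None``
    (callers count these in QC).
    """
    if series.empty:
        return None
    qualifies = (series["count"] >= 1) & (
        series["max_condensate_area_um2"] >= min_area
    )
    if not qualifies.any():
        return None
    onset_idx = int(np.argmax(qualifies.to_numpy()))
    onset_time = float(series["time_s"].iloc[onset_idx])
    out = series.copy()
    out["time_aligned_s"] = out["time_s"] - onset_time
    out.attrs.update(series.attrs)
    out.attrs["onset_frame"] = int(series["frame"].iloc[onset_idx])
    return out


def distance_at_onset(groups: dict[str, list[pd.DataFrame]]) -> tuple[pd.DataFrame, StatResult]:
    """Per-condensate distance at onset, compared across groups by ANOVA.

    ``groups`` maps condition name → list of onset-aligned per-cell
    series. For each cell the condensate-to-centrosome distances at its
    onset frame (time_aligned_s == 0) are pooled per group. Groups with
    fewer than 2 usable condensates are dropped with a warning; at least
    two groups must remain.
    Returns the pooled per-condensate table (with per-group median and
    quartiles in ``attrs['summary']``) and the one-way ANOVA result.
    """
    import warnings

    if len(groups) < 2:
        raise ValueError("distance_at_onset requires >= 2 groups")
    rows = []
    pooled: dict[str, list[float]] = {}
    for name, series_list in groups.items():
        vals: list[float] = []
        for s in series_list:
            if s is None or "time_aligned_s" not in s:
                continue
            at0 = s[s["time_aligned_s"] == 0]
            for d in at0["distances_um"]:
                vals.extend(d)
        if len(vals) < 2:
            warnings.warn(f"group {name!r} has <2 onset condensates; excluded")
            continue
        pooled[name] = vals
        rows.extend({"group": name, "distance_um": v} for v in vals)
    if len(pooled) < 2:
        raise ValueError("fewer than 2 groups with usable onset condensates")
    table = pd.DataFrame(rows)
    summary = {
        name: {
            "median": float(np.median(v)),
            "q1": float(np.percentile(v, 25)),
            "q3": float(np.percentile(v, 75)),
            "n": len(v),
        }
        for name, v in pooled.items()
    }
    table.attrs["summary"] = summary
    anova = one_way_anova(*pooled.values())
    return table, anova


def count_granules(
    cell_track: CellTrack,
    frame: int,
    calibration: float,
    centrosome_exclusion_radius: float = 0.5,
) -> int:
    """Count condensate-channel granules in a cell, excluding centrosomes.

    Objects whose centroid falls within ``centrosome_exclusion_radius``
    (μm) of an assigned centrosome are centrosomal material, not granules.
    """
    conds = cell_track.condensates.get(frame, [])
    cents = cell_track.centrosomes.get(frame, [])
    if not conds:
        return 0
    if not cents:
        return len(conds)
    cpos = np.array([o.centroid[-2:] for o in cents], dtype=float) * calibration
    n = 0
    for o in conds:
        p = np.asarray(o.centroid[-2:], dtype=float) * calibration
        if np.min(np.linalg.norm(cpos - p, axis=1)) > centrosome_exclusion_radius:
            n += 1
    return n


@dataclass(frozen=True)
class StageFeatures:
    """Annotation features the cell-cycle stager consumes.

    The morphology flags (DNA condensation, nuclear-envelope integrity,
    metaphase-plate alignment, segregation, PCM expansion) are inputs from
    ground truth or manual annotation — staging is a rule engine over
    them, not an image classifier.
    """

    n_centrosomes: int
    centrosome_separation_um: float
    centrin_dots_per_centrosome: tuple[int, ...]
    dna_condensed: bool
    ne_intact: bool
    dna_at_equator: bool = False
    chromosomes_segregating: bool = False
    pcm_expanded: bool = False


def classify_stage(features: StageFeatures) -> tuple[str, str]:
    """Deterministic cell-cycle staging from centrosome/DNA features.

    The rule cascade:

    * condensed DNA with segregating chromosomes → anaphase; aligned at
      the equator → metaphase; envelope intact → prophase; envelope
      broken down → prometaphase.
    * uncondensed DNA: one centrosome bearing two centrin dots →
      G1/early S; two centrosomes < 1 μm apart, each with a dot pair →
      S/early G2; two centrosomes > 1 μm apart with expanded PCM →
      late G2.

    Combinations outside the cascade return ``("unclassified", reason)``;
    the function is total over its feature domain. Returns
    ``(label, reason)`` where reason is empty for a clean call.
    """
    f = features
    for name in ("n_centrosomes", "centrosome_separation_um",
                 "centrin_dots_per_centrosome", "dna_condensed", "ne_intact"):
        if getattr(f, name, None) is None:
            raise ValueError(f"missing staging feature: {name}")

    if f.dna_condensed:
        if f.chromosomes_segregating:
            return "anaphase", ""
        if f.dna_at_equator:
            return "metaphase", ""
        if f.ne_intact:
            return "prophase", ""
        return "prometaphase", ""

    # interphase branch
    if f.chromosomes_segregating or f.dna_at_equator:
        return "unclassified", "mitotic DNA flags with uncondensed DNA"
    if f.n_centrosomes == 1:
        if f.centrin_dots_per_centrosome and f.centrin_dots_per_centrosome[0] == 2:
            return "G1/early S", ""
        return "unclassified", "single centrosome without a centrin-dot pair"
    if f.n_centrosomes == 2:
        pairs = all(d == 2 for d in f.centrin_dots_per_centrosome)
        if not pairs:
            return "unclassified", "centrosome without a centrin-dot pair"
        if f.centrosome_separation_um < 1.0:
            return "S/early G2", ""
        if f.pcm_expanded:
            return "late G2", ""
        return "unclassified", "separated centrosomes without PCM expansion"
    return "unclassified", f"{f.n_centrosomes} centrosomes with uncondensed DNA"


def dissolution_percent_remaining(
    counts: pd.DataFrame,
    t0: float = 0.0,
    interval: str = "ci95",
) -> pd.DataFrame:
    """Per-cell %-granules-remaining curves and their group summary.

    ``counts`` is long format (condition, cell, time_min, count). Each
    cell is normalized to its own count at the treatment time ``t0`` (so
    every curve starts at 100%); cells with zero granules at ``t0`` are
    excluded and logged. The summary per (condition, time) is the
    across-cell mean with either a 95% t-interval (``interval='ci95'``)
    or the standard error (``'sem'``).
    """
    import logging

    if interval not in ("ci95", "sem"):
        raise ValueError("interval must be 'ci95' or 'sem'")
    log = logging.getLogger(__name__)
    out = []
    for (cond, cell), g in counts.groupby(["condition", "cell"]):
        g = g.sort_values("time_min")
        base = g.loc[g["time_min"] == t0, "count"]
        if base.empty or base.iloc[0] <= 0:
            log.info("cell %s (%s) has no granules at t0; excluded", cell, cond)
            continue
        n0 = float(base.iloc[0])
        for _, r in g.iterrows():
            out.append(
                {"condition": cond, "cell": cell, "time_min": r["time_min"],
                 "percent_remaining": 100.0 * r["count"] / n0}
            )
    percell = pd.DataFrame(out)
    if percell.empty:
        raise ValueError("no cells with granules at the treatment time")

    summ = []
    for (cond, tm), g in percell.groupby(["condition", "time_min"]):
        vals = g["percent_remaining"].to_numpy()
        m = float(vals.mean())
        if vals.size >= 2:
            if interval == "ci95":
                m, lo, hi = mean_ci95(vals)
            else:
                sem = float(vals.std(ddof=1)) / math.sqrt(vals.size)
                lo, hi = m - sem, m + sem
        else:
            lo = hi = m
        summ.append(
            {"condition": cond, "time_min": tm, "mean_percent": m,
             "lower": lo, "upper": hi, "n_cells": int(vals.size)}
        )
    summary = pd.DataFrame(summ)
    summary.attrs["per_cell"] = percell
    return summary
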