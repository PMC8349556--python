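"""Dense/light phase decomposition and critical-concentration estimation.

A cell expressing a condensation-prone protein is decomposed with two
thresholds on its (voxel or pixel) intensities: the dense phase is
everything above the higher threshold (the condensates), the "whole"
compartment everything above the lower one (dense plus dilute cytoplasm).
Light-phase volume and intensity follow by subtraction, and relative
concentrations are intensity sum per volume. The critical concentration
Csat is read out as the light-phase concentration at the moment phase
separation just occurs — the frame where a cell's separated flag first
flips true — averaged across cells with a 95% t-interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import mean_ci95

__all__ = [
    "PhaseMeasurement",
    "CsatEstimate",
    "decompose_phases",
    "classify_separated",
    "estimate_csat",
    "phase_diagram",
]


@dataclass(frozen=True)
class PhaseMeasurement:
    """Dense/whole/light decomposition of one cell at one timepoint.

    Volumes are μm³ in voxel mode or μm² in the 2-D area fallback
    (``mode`` records which); concentrations are a.u. per unit volume.
    """

    cell_id: int
    time_s: float
    dense_volume: float
    dense_intensity: float
    whole_volume: float
    whole_intensity: float
    separated: bool = False
    mode: str = "3d"

    @property
    def light_volume(self) -> float:
        return self.whole_volume - self.dense_volume

    @property
    def light_intensity(self) -> float:
        return self.whole_intensity - self.dense_intensity

    @property
    def light_concentration(self) -> float:
        lv = self.light_volume
        return self.light_intensity / lv if lv > 0 else float("nan")

    @property
    def dense_concentration(self) -> float:
        dv = self.dense_volume
        return self.dense_intensity / dv if dv > 0 else float("nan")

    @property
    def whole_concentration(self) -> float:
        return self.whole_intensity / self.whole_volume


def decompose_phases(
    region,
    dense_threshold: float,
    whole_threshold: float,
    voxel_volume: float = 1.0,
    *,
    cell_id: int = 0,
    time_s: float = 0.0,
) -> PhaseMeasurement:
    """Decompose a cell's intensity region into dense and light phases.

    ``region`` is the array of the cell's voxels (2-D works too; then
    ``voxel_volume`` is the pixel area and results are per-area). The
    dense compartment is ``{v ≥ dense_threshold}``, the whole compartment
    ``{v ≥ whole_threshold}``, intensities are raw sums within each, and
    light-phase quantities are their differences. ``dense_threshold`` must
    exceed ``whole_threshold``, and the whole compartment must be
    non-empty.
    """
    if dense_threshold <= whole_threshold:
        raise ValueError("dense_threshold must exceed whole_threshold")
    v = np.asarray(region, dtype=float)
    whole_mask = v >= whole_threshold
    if not whole_mask.any():
        raise ValueError("whole compartment is empty at this threshold")
    dense_mask = v >= dense_threshold
    return PhaseMeasurement(
        cell_id=cell_id,
        time_s=time_s,
        dense_volume=float(dense_mask.sum()) * voxel_volume,
        dense_intensity=float(v[dense_mask].sum()),
        whole_volume=float(whole_mask.sum()) * voxel_volume,
        whole_intensity=float(v[whole_mask].sum()),
        mode="3d" if v.ndim == 3 else "2d-area",
    )


def classify_separated(
    measurement: PhaseMeasurement, min_dense_volume: float
) -> PhaseMeasurement:
    """Flag a measurement as phase-separated.

    Separated ⇔ dense volume ≥ ``min_dense_volume`` (inclusive). Returns
    a copy carrying the flag.
    """
    from dataclasses import replace

    return replace(
        measurement, separated=measurement.dense_volume >= min_dense_volume
    )


@dataclass(frozen=True)
class CsatEstimate:
    """Across-cell critical-concentration estimate.

    ``value`` is the mean of the per-cell light concentrations at onset;
    ``ci`` the 95% t-interval; ``onset_concentrations`` the per-cell
    values entering the mean.
    """

    value: float
    ci: tuple[float, float]
    n_cells: int
    onset_concentrations: tuple[float, ...]

    def to_dict(self) -> dict:
        return {
            "csat": self.value,
            "ci95": list(self.ci),
            "n_cells": self.n_cells,
            "onset_concentrations": list(self.onset_concentrations),
        }

    def summary(self) -> str:
        lo, hi = self.ci
        return (
            f"Csat = {self.value:.4g} a.u./vol "
            f"(95% CI {lo:.4g}–{hi:.4g}, n = {self.n_cells} cells)"
        )


def _to_frame(measurements) -> pd.DataFrame:
    if isinstance(measurements, pd.DataFrame):
        df = measurements.copy()
        if "light_conc" not in df:
            raise ValueError("DataFrame input needs a 'light_conc' column")
        return df
    rows = [
        {
            "cell_id": m.cell_id,
            "time_s": m.time_s,
            "light_conc": m.light_concentration,
            "separated": m.separated,
        }
        for m in measurements
    ]
    return pd.DataFrame(rows)


def estimate_csat(measurements, min_cells: int = 3) -> CsatEstimate:
    """Estimate Csat from per-cell time courses of phase measurements.

    Accepts an iterable of :class:`PhaseMeasurement` or a DataFrame with
    columns cell_id, time_s, light_conc, separated. For each cell whose
    separated flag transitions false→true, the light concentration at
    that onset frame is taken; the estimate is the across-cell mean with
    a 95% t-interval. Requires at least ``min_cells`` cells with an
    observed onset.
    """
    df = _to_frame(measurements)
    onset_vals: list[float] = []
    for _, g in df.sort_values("time_s").groupby("cell_id"):
        sep = g["separated"].to_numpy(dtype=bool)
        if not sep.any() or sep[0]:
            continue  # never separated, or already separated at first frame
        onset_vals.append(float(g["light_conc"].iloc[int(np.argmax(sep))]))
    if len(onset_vals) < min_cells:
        raise ValueError(
            f"no phase-separating cells (need >= {min_cells} observed onsets, "
            f"got {len(onset_vals)})"
        )
    m, lo, hi = mean_ci95(onset_vals)
    return CsatEstimate(
        value=m, ci=(lo, hi), n_cells=len(onset_vals),
        onset_concentrations=tuple(onset_vals),
    )


def phase_diagram(constructs: dict) -> pd.DataFrame:
    """Per-construct concentration/state table with Csat where it exists.

    ``constructs`` maps construct name → measurements (any form
    :func:`estimate_csat` accepts). Each cell contributes its maximal
    whole-cell concentration and whether it ever separated; constructs in
    which no cell ever separates are reported as "no LLPS detected up to
    max concentration". The per-construct Csat (or None) is stored in
    ``attrs['csat']``.
    """
    rows = []
    csats: dict[str, dict | None] = {}
    for name, meas in constructs.items():
        df = _to_frame(meas)
        if df.empty:
            csats[name] = None
            continue
        conc_col = "whole_conc" if "whole_conc" in df else "light_conc"
        for cid, g in df.groupby("cell_id"):
            rows.append(
                {
                    "construct": name,
                    "cell_id": cid,
                    "max_concentration": float(g[conc_col].max()),
                    "separated": bool(g["separated"].any()),
                }
            )
        try:
            csats[name] = estimate_csat(df).to_dict()
        except ValueError:
            csats[name] = None
    table = pd.DataFrame(
        rows, columns=["construct", "cell_id", "max_concentration", "separated"]
    )
    table.attrs["csat"] = csats
    table.attrs["verdict"] = {
        name: ("LLPS" if c is not None else "no LLPS detected up to max concentration")
        for name, c in csats.items()
    }
    return table
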