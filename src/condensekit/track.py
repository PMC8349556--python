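"""Nucleus-anchored cell tracking and object-to-cell assignment.

Nuclei are the least mobile structure in the field, so cell identity is
carried by the nucleus: nuclei in consecutive frames are matched so that
total centroid displacement is minimal (optimal bipartite assignment),
with matches beyond a displacement gate cut. Condensates and centrosomes
are then paired, frame by frame, to the nearest tracked nucleus within an
assignment radius. A machine-readable QC report replaces manual
verification of the pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .detect import DetectedObject

__all__ = ["CellTrack", "TrackingQC", "link_nuclei", "assign_to_cells", "tracks_to_table"]


@dataclass
class CellTrack:
    """One cell across frames, anchored to its nucleus.

    ``nuclei`` maps frame → nucleus object (frames the track spans);
    ``condensates`` and ``centrosomes`` map frame → objects assigned to
    this cell in that frame.
    """

    cell_id: int
    nuclei: dict[int, DetectedObject] = field(default_factory=dict)
    condensates: dict[int, list[DetectedObject]] = field(default_factory=dict)
    centrosomes: dict[int, list[DetectedObject]] = field(default_factory=dict)

    @property
    def frames(self) -> list[int]:
        return sorted(self.nuclei)

    @property
    def length(self) -> int:
        return len(self.nuclei)


@dataclass
class TrackingQC:
    """Counts and listings that stand in for manual pairing verification."""

    gate_cuts: int = 0
    new_tracks_after_first_frame: int = 0
    unassigned: list[dict] = field(default_factory=list)
    frames_without_nuclei: list[int] = field(default_factory=list)
    multi_centrosome_cells: list[int] = field(default_factory=list)
    short_tracks: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "gate_cuts": self.gate_cuts,
            "new_tracks_after_first_frame": self.new_tracks_after_first_frame,
            "n_unassigned_objects": len(self.unassigned),
            "unassigned": self.unassigned,
            "frames_without_nuclei": self.frames_without_nuclei,
            "multi_centrosome_cells": self.multi_centrosome_cells,
            "short_tracks": self.short_tracks,
        }


def _centroid_um(obj: DetectedObject, calibration: float) -> np.ndarray:
    return np.asarray(obj.centroid[-2:], dtype=float) * calibration


def link_nuclei(
    nuclei_by_frame: dict[int, list[DetectedObject]],
    max_displacement: float,
    calibration: float = 1.0,
    qc: TrackingQC | None = None,
) -> list[CellTrack]:
    """Link nucleus detections across consecutive frames into cell tracks.

    Parameters
    ----------
    nuclei_by_frame : dict
        Frame index → nucleus-channel detections for that frame.
    max_displacement : float
        Gate in μm: a matched pair moving farther than this is cut, ending
        the old track and starting a new one. No gap closing — a track
        interrupted by a missed detection restarts.
    calibration : float
        μm per pixel, applied to centroids before distances are computed.

    The per-transition assignment minimizes the total displacement over
    all matched pairs (Hungarian algorithm), which is the global reading
    of "the same nucleus moved the least between consecutive frames".
    """
    if max_displacement <= 0:
        raise ValueError("max_displacement must be > 0")
    qc = qc if qc is not None else TrackingQC()
    frames = sorted(nuclei_by_frame)
    tracks: list[CellTrack] = []
    active: dict[int, CellTrack] = {}  # index within previous frame -> track

    prev_objs: list[DetectedObject] = []
    first = True
    for f in frames:
        objs = list(nuclei_by_frame.get(f, []))
        new_active: dict[int, CellTrack] = {}
        matched_cur: set[int] = set()
        if prev_objs and objs:
            prev_pos = np.array([_centroid_um(o, calibration) for o in prev_objs])
            cur_pos = np.array([_centroid_um(o, calibration) for o in objs])
            cost = np.linalg.norm(prev_pos[:, None, :] - cur_pos[None, :, :], axis=2)
            ri, ci = linear_sum_assignment(cost)
            for i, j in zip(ri, ci):
                if cost[i, j] > max_displacement:
                    qc.gate_cuts += 1
                    continue
                tr = active.get(i)
                if tr is None:
                    continue
                tr.nuclei[f] = objs[j]
                new_active[j] = tr
                matched_cur.add(j)
        for j, o in enumerate(objs):
            if j in matched_cur:
                continue
            tr = CellTrack(cell_id=len(tracks))
            tr.nuclei[f] = o
            tracks.append(tr)
            new_active[j] = tr
            if not first:
                qc.new_tracks_after_first_frame += 1
        active = new_active
        prev_objs = objs
        first = False

    qc.short_tracks.extend(t.cell_id for t in tracks if t.length < 3)
    return tracks


def assign_to_cells(
    tracks: list[CellTrack],
    condensates_by_frame: dict[int, list[DetectedObject]],
    centrosomes_by_frame: dict[int, list[DetectedObject]],
    assignment_radius: float,
    calibration: float = 1.0,
    qc: TrackingQC | None = None,
) -> tuple[list[CellTrack], TrackingQC]:
    """Pair condensate and centrosome objects with the nearest nucleus.

    Each object goes to the cell whose nucleus centroid is closest in that
    frame, provided the distance is within ``assignment_radius`` (μm);
    exact ties break toward the lower cell_id. Objects with no nucleus in
    range are recorded unassigned in the QC report, as are frames that
    have objects but no nuclei at all.
    """
    if assignment_radius <= 0:
        raise ValueError("assignment_radius must be > 0")
    qc = qc if qc is not None else TrackingQC()

    all_frames = set(condensates_by_frame) | set(centrosomes_by_frame)
    for f in sorted(all_frames):
        present = [t for t in tracks if f in t.nuclei]
        # deterministic tie-break: sort by cell_id, argmin takes the first
        present.sort(key=lambda t: t.cell_id)
        if present:
            nuc_pos = np.array(
                [_centroid_um(t.nuclei[f], calibration) for t in present]
            )
        for kind, by_frame in (("condensate", condensates_by_frame),
                               ("centrosome", centrosomes_by_frame)):
            for obj in by_frame.get(f, []):
                if not present:
                    qc.unassigned.append(
                        {"frame": f, "type": kind, "label": obj.label,
                         "reason": "no nuclei in frame"}
                    )
                    if f not in qc.frames_without_nuclei:
                        qc.frames_without_nuclei.append(f)
                    continue
                p = _centroid_um(obj, calibration)
                d = np.linalg.norm(nuc_pos - p, axis=1)
                i = int(np.argmin(d))
                if d[i] > assignment_radius:
                    qc.unassigned.append(
                        {"frame": f, "type": kind, "label": obj.label,
                         "reason": "beyond assignment radius"}
                    )
                    continue
                tr = present[i]
                store = tr.condensates if kind == "condensate" else tr.centrosomes
                store.setdefault(f, []).append(obj)

    for t in tracks:
        if any(len(v) > 1 for v in t.centrosomes.values()):
            qc.multi_centrosome_cells.append(t.cell_id)
    return tracks, qc


def tracks_to_table(tracks: list[CellTrack]) -> pd.DataFrame:
    """Long-format tracks table: one row per assigned object per frame."""
    rows = []
    for t in tracks:
        for f in t.frames:
            n = t.nuclei[f]
            rows.append(_row(f, t.cell_id, "nucleus", n))
            for o in t.centrosomes.get(f, []):
                rows.append(_row(f, t.cell_id, "centrosome", o))
            for o in t.condensates.get(f, []):
                rows.append(_row(f, t.cell_id, "condensate", o))
    return pd.DataFrame(
        rows,
        columns=["frame", "cell_id", "object_type", "label", "row", "col",
                 "area_px", "intensity_sum"],
    )


def _row(f: int, cid: int, kind: str, o: DetectedObject) -> dict:
    return {
        "frame": f,
        "cell_id": cid,
        "object_type": kind,
        "label": o.label,
        "row": o.centroid[-2],
        "col": o.centroid[-1],
        "area_px": o.area,
        "intensity_sum": o.intensity_sum,
    }
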