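"""Ground-truth simulation of condensate biology for pipeline validation.

The generator encodes the phenomenology the downstream estimators assume:

* Each cell is an annular cytoplasm between a nucleus ellipse and a cell
  boundary ellipse, with one or two centrosomes riding along with the
  slowly drifting nucleus.
* An inducible expression ramp raises the total protein concentration
  ``C_tot(t)`` linearly. While ``C_tot ≤ Csat`` the protein stays diffuse;
  above ``Csat`` the system obeys the lever rule: the light (dilute) phase
  is pinned at ``Csat`` and the excess ``(C_tot − Csat) × cytoplasm area``
  partitions into condensates whose internal concentration is
  ``dense_ratio × Csat``.
* Condensates take a directed step of ``transport_speed · Δt`` toward the
  nearest centrosome (the dynein/microtubule transport analog; zero under
  motor inhibition or depolymerization) plus an isotropic Brownian step of
  sd ``√(2·D·Δt)`` per axis, and fuse when they touch, conserving summed
  intensity and area.
* New condensates nucleate only while supersaturated, at positions drawn
  with a tunable radial bias toward the centrosome.

All randomness flows from one ``numpy.random.Generator`` seeded from the
scene config, so identical configs give bit-identical scenes.

The module also houses the FRAP-trace and granule-dissolution generators
and the %(w/v) ↔ mM reagent conversion.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "SceneConfig",
    "Condensate",
    "FrameTruth",
    "CellTruth",
    "GroundTruthScene",
    "ImageStack",
    "FrapTruth",
    "AlcoholSpec",
    "simulate_scene",
    "transport_step",
    "truth_detections",
    "render_stack",
    "simulate_frap_trace",
    "simulate_dissolution",
    "simulate_phase_experiment",
    "alcohol_panel",
    "percent_to_molar",
    "molar_to_percent",
]


# ---------------------------------------------------------------------------
# configuration and truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a simulated time-lapse field.

    Units: lengths in μm, times in seconds for ``frame_interval_s`` and in
    minutes for the motility rates (matching how such rates are reported),
    intensities/concentrations in arbitrary units with 2-D concentrations
    as a.u./μm².
    """

    n_cells: int = 4
    field_size: tuple[int, int] = (256, 256)  # (rows, cols) px
    calibration: float = 0.1  # μm / pixel
    frame_interval_s: float = 240.0
    n_frames: int = 30
    csat_true: float = 1.0  # a.u. / μm²
    initial_concentration: float = 0.4  # a.u. / μm² at frame 0
    production_rate: float = 0.05  # a.u. / μm² per frame
    dense_ratio: float = 50.0  # dense-phase / light-phase concentration
    transport_speed: float = 0.5  # μm / min toward nearest centrosome
    diffusion_coeff: float = 0.02  # μm² / min
    nucleation_radial_bias: float = 0.0  # 0 = uniform in cytoplasm
    nucleation_rate: float = 0.7  # mean new condensates per supersaturated frame
    fusion_on: bool = True
    nucleus_drift_sd: float = 0.15  # μm per frame, per axis
    n_centrosomes: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if min(self.field_size) <= 0:
            raise ValueError("field_size must be positive")
        if self.csat_true <= 0:
            raise ValueError("csat_true must be > 0")
        if self.dense_ratio <= 1:
            raise ValueError("dense_ratio must be > 1")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.calibration <= 0:
            raise ValueError("calibration must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass
class Condensate:
    """One condensate at one frame; center in μm (y, x), area μm²."""

    id: int
    center: tuple[float, float]
    area: float
    intensity: float
    birth_frame: int


@dataclass
class FrameTruth:
    c_tot: float
    light_concentration: float
    condensates: list[Condensate] = field(default_factory=list)


@dataclass
class CellTruth:
    """Per-cell geometry, annotation flags, and per-frame truth.

    ``nucleus_centers[f]`` is the (y, x) nucleus center in μm at frame f;
    centrosomes keep a fixed offset from the nucleus. ``centrin_dots`` per
    centrosome and the DNA/envelope flags feed the cell-cycle stager.
    """

    cell_id: int
    nucleus_axes: tuple[float, float]  # semi-axes, μm
    cell_axes: tuple[float, float]
    nucleus_centers: np.ndarray  # (n_frames, 2) μm
    centrosome_offsets: np.ndarray  # (k, 2) μm relative to nucleus center
    centrin_dots: tuple[int, ...]
    dna_condensed: bool = False
    ne_intact: bool = True
    frames: list[FrameTruth] = field(default_factory=list)

    def centrosome_positions(self, frame: int) -> np.ndarray:
        return self.nucleus_centers[frame][None, :] + self.centrosome_offsets

    @property
    def cytoplasm_area(self) -> float:
        """Annulus area between cell and nucleus ellipses, μm²."""
        a = math.pi * self.cell_axes[0] * self.cell_axes[1]
        b = math.pi * self.nucleus_axes[0] * self.nucleus_axes[1]
        return a - b


@dataclass
class GroundTruthScene:
    config: SceneConfig
    cells: list[CellTruth]
    events: list[dict] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.config.n_frames

    def to_json(self, path) -> None:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if hasattr(o, "__dict__"):
                return o.__dict__
            raise TypeError(type(o))

        payload = {
            "config": asdict(self.config),
            "events": self.events,
            "cells": [
                {
                    "cell_id": c.cell_id,
                    "nucleus_axes": c.nucleus_axes,
                    "cell_axes": c.cell_axes,
                    "nucleus_centers": c.nucleus_centers.tolist(),
                    "centrosome_offsets": c.centrosome_offsets.tolist(),
                    "centrin_dots": c.centrin_dots,
                    "dna_condensed": c.dna_condensed,
                    "ne_intact": c.ne_intact,
                    "frames": [
                        {
                            "c_tot": f.c_tot,
                            "light_concentration": f.light_concentration,
                            "condensates": [asdict(k) for k in f.condensates],
                        }
                        for f in c.frames
                    ],
                }
                for c in self.cells
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, default=_default)


@dataclass
class ImageStack:
    """Calibrated multi-channel image time series.

    ``data`` is indexed (frame, channel, row, col); coordinates are
    0-based with origin top-left and (row, col) order. 3-D voxel stacks
    use (channel, z, row, col) with ``z_step_um`` set.
    """

    data: np.ndarray
    channels: tuple[str, ...]
    calibration: float  # μm / pixel
    timestamps: np.ndarray | None = None
    z_step_um: float | None = None

    def __post_init__(self):
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------


def _cell_layout(config: SceneConfig, rng: np.random.Generator):
    """Place cells on a jittered grid so boundary ellipses stay in-field."""
    h_um = config.field_size[0] * config.calibration
    w_um = config.field_size[1] * config.calibration
    side = math.ceil(math.sqrt(config.n_cells))
    pitch_y, pitch_x = h_um / side, w_um / side
    cell_ax = (0.40 * min(pitch_y, pitch_x), 0.34 * min(pitch_y, pitch_x))
    nuc_ax = (0.45 * cell_ax[0], 0.45 * cell_ax[1])
    centers = []
    for i in range(config.n_cells):
        r, c = divmod(i, side)
        cy = (r + 0.5) * pitch_y + rng.uniform(-0.05, 0.05) * pitch_y
        cx = (c + 0.5) * pitch_x + rng.uniform(-0.05, 0.05) * pitch_x
        centers.append((cy, cx))
    return centers, cell_ax, nuc_ax


def transport_step(
    positions: np.ndarray,
    centrosomes: np.ndarray,
    transport_speed: float,
    diffusion_coeff: float,
    dt_s: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance condensate centers by one frame of directed + Brownian motion.

    Each position moves ``transport_speed · Δt`` (μm, Δt in minutes)
    straight toward its nearest centrosome — never overshooting it — then
    takes an isotropic Gaussian step with per-axis sd ``√(2·D·Δt)``.
    """
    if positions.size == 0:
        return positions
    dt_min = dt_s / 60.0
    pos = positions.astype(float).copy()
    if centrosomes.size and transport_speed > 0:
        d = pos[:, None, :] - centrosomes[None, :, :]
        dist = np.linalg.norm(d, axis=2)
        nearest = np.argmin(dist, axis=1)
        target = centrosomes[nearest]
        vec = target - pos
        norm = np.linalg.norm(vec, axis=1)
        step = np.minimum(transport_speed * dt_min, norm)
        nz = norm > 0
        pos[nz] += (vec[nz].T / norm[nz] * step[nz]).T
    if diffusion_coeff > 0:
        sd = math.sqrt(2.0 * diffusion_coeff * dt_min)
        pos += rng.normal(0.0, sd, size=pos.shape)
    return pos


def _inside_ellipse(p, center, axes) -> bool:
    return ((p[0] - center[0]) / axes[0]) ** 2 + ((p[1] - center[1]) / axes[1]) ** 2 <= 1.0


def _confine(pos, nucleus_center, nucleus_axes, cell_axes):
    """Project a point into the cytoplasmic annulus (between the ellipses)."""
    rel = pos - nucleus_center
    # outside cell boundary -> pull radially onto it
    q = (rel[0] / cell_axes[0]) ** 2 + (rel[1] / cell_axes[1]) ** 2
    if q > 1.0:
        rel = rel / math.sqrt(q) * 0.98
    # inside nucleus -> push radially just outside it
    q = (rel[0] / nucleus_axes[0]) ** 2 + (rel[1] / nucleus_axes[1]) ** 2
    if q < 1.0:
        if q == 0.0:
            rel = np.array([nucleus_axes[0] * 1.05, 0.0])
        else:
            rel = rel / math.sqrt(q) * 1.02
    return nucleus_center + rel


def _draw_nucleation_site(cell: CellTruth, frame: int, bias: float,
                          rng: np.random.Generator) -> tuple[float, float]:
    """Rejection-sample a cytoplasm position, optionally biased centrosome-ward.

    Acceptance weight exp(−bias · d/d_max) where d is the distance to the
    nearest centrosome; bias 0 gives a uniform draw over the annulus.
    """
    nc = cell.nucleus_centers[frame]
    cent = cell.centrosome_positions(frame)
    d_max = 2.0 * max(cell.cell_axes)
    for _ in range(2000):
        p = nc + rng.uniform(-1.0, 1.0, size=2) * np.array(cell.cell_axes)
        if not _inside_ellipse(p, nc, cell.cell_axes):
            continue
        if _inside_ellipse(p, nc, cell.nucleus_axes):
            continue
        if bias > 0 and cent.size:
            d = float(np.min(np.linalg.norm(cent - p, axis=1)))
            if rng.uniform() > math.exp(-bias * d / d_max):
                continue
        return (float(p[0]), float(p[1]))
    # pathological bias: fall back to a point near the centrosome
    p = _confine(cent[0].copy(), nc, cell.nucleus_axes, cell.cell_axes)
    return (float(p[0]), float(p[1]))


def simulate_scene(config: SceneConfig) -> GroundTruthScene:
    """Generate a full ground-truth scene from a :class:`SceneConfig`.

    The lever rule is enforced exactly at every frame: while
    ``C_tot ≤ Csat`` there are no condensates and the light concentration
    equals ``C_tot``; above it the light phase sits at ``Csat`` and the
    summed condensate intensity equals ``(C_tot − Csat) × cytoplasm area``.
    Condensate area is tied to intensity through the dense-phase
    concentration ``dense_ratio × Csat``, so fusion's intensity
    conservation implies area additivity.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    centers, cell_ax, nuc_ax = _cell_layout(config, rng)

    cells: list[CellTruth] = []
    events: list[dict] = []
    dense_conc = config.dense_ratio * config.csat_true
    dt = config.frame_interval_s

    for cid, c0 in enumerate(centers):
        drift = rng.normal(0.0, config.nucleus_drift_sd, size=(config.n_frames, 2))
        drift[0] = 0.0
        nucleus_centers = np.asarray(c0)[None, :] + np.cumsum(drift, axis=0)
        k = config.n_centrosomes
        offsets = np.empty((k, 2))
        base_angle = rng.uniform(0, 2 * math.pi)
        r0 = nuc_ax[0] * 1.25
        for j in range(k):
            ang = base_angle + j * (0.25 + rng.uniform(0, 0.15))
            offsets[j] = (r0 * math.sin(ang), r0 * math.cos(ang))
        cell = CellTruth(
            cell_id=cid,
            nucleus_axes=nuc_ax,
            cell_axes=cell_ax,
            nucleus_centers=nucleus_centers,
            centrosome_offsets=offsets,
            centrin_dots=tuple(2 for _ in range(k)),
        )
        area_cyto = cell.cytoplasm_area
        next_id = 0
        prev: list[Condensate] = []
        for f in range(config.n_frames):
            c_tot = config.initial_concentration + config.production_rate * f
            nc = nucleus_centers[f]
            cent = cell.centrosome_positions(f)

            # move what already exists
            if prev:
                pos = np.array([k_.center for k_ in prev])
                pos = transport_step(
                    pos, cent, config.transport_speed,
                    config.diffusion_coeff, dt, rng,
                )
                cur = []
                for k_, p in zip(prev, pos):
                    p = _confine(p, nc, cell.nucleus_axes, cell.cell_axes)
                    cur.append(
                        Condensate(k_.id, (float(p[0]), float(p[1])),
                                   k_.area, k_.intensity, k_.birth_frame)
                    )
            else:
                cur = []

            # fusion: merge touching pairs until stable
            if config.fusion_on and len(cur) > 1:
                cur = _fuse(cur, f, cid, events)

            excess = (c_tot - config.csat_true) * area_cyto
            if excess <= 0:
                cur = []
                light = c_tot
            else:
                light = config.csat_true
                i_cur = sum(k_.intensity for k_ in cur)
                delta = excess - i_cur
                if delta > 0:
                    n_new = int(rng.poisson(config.nucleation_rate))
                    if not cur and n_new == 0:
                        n_new = 1
                    newcomers = []
                    for _ in range(n_new):
                        site = _draw_nucleation_site(
                            cell, f, config.nucleation_radial_bias, rng
                        )
                        newcomers.append(
                            Condensate(next_id, site, 0.0, 0.0, birth_frame=f)
                        )
                        events.append(
                            {"frame": f, "cell": cid, "type": "nucleation",
                             "id": next_id}
                        )
                        next_id += 1
                    if newcomers:
                        seed_share = delta * (0.5 if cur else 1.0) / len(newcomers)
                        for k_ in newcomers:
                            k_.intensity = seed_share
                        delta -= seed_share * len(newcomers)
                        cur.extend(newcomers)
                    if delta > 0 and cur:
                        w = np.array([k_.intensity for k_ in cur])
                        w = w / w.sum() if w.sum() > 0 else np.full(len(cur), 1 / len(cur))
                        for k_, wi in zip(cur, w):
                            k_.intensity += delta * wi
                # pin the total exactly to the lever-rule excess
                i_cur = sum(k_.intensity for k_ in cur)
                if cur and i_cur > 0 and i_cur != excess:
                    scale = excess / i_cur
                    for k_ in cur:
                        k_.intensity *= scale
                for k_ in cur:
                    k_.area = k_.intensity / dense_conc

            cell.frames.append(
                FrameTruth(
                    c_tot=c_tot,
                    light_concentration=light,
                    condensates=[
                        Condensate(k_.id, k_.center, k_.area, k_.intensity,
                                   k_.birth_frame)
                        for k_ in cur
                    ],
                )
            )
            prev = cur
        cells.append(cell)
    return GroundTruthScene(config=config, cells=cells, events=events)


def _fuse(cur: list[Condensate], frame: int, cid: int, events: list[dict]):
    """Merge any pair closer than the sum of equivalent radii; repeats to fixpoint."""
    changed = True
    while changed and len(cur) > 1:
        changed = False
        for i in range(len(cur)):
            for j in range(i + 1, len(cur)):
                a, b = cur[i], cur[j]
                ra = math.sqrt(a.area / math.pi)
                rb = math.sqrt(b.area / math.pi)
                d = math.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                if d < ra + rb:
                    itot = a.intensity + b.intensity
                    if itot > 0:
                        cy = (a.center[0] * a.intensity + b.center[0] * b.intensity) / itot
                        cx = (a.center[1] * a.intensity + b.center[1] * b.intensity) / itot
                    else:
                        cy = (a.center[0] + b.center[0]) / 2
                        cx = (a.center[1] + b.center[1]) / 2
                    keep_id = min(a.id, b.id)
                    birth = min(a.birth_frame, b.birth_frame)
                    merged = Condensate(keep_id, (cy, cx), a.area + b.area,
                                        itot, birth)
                    events.append(
                        {"frame": frame, "cell": cid, "type": "fusion",
                         "ids": [a.id, b.id], "kept": keep_id}
                    )
                    cur = [c for k_, c in enumerate(cur) if k_ not in (i, j)]
                    cur.append(merged)
                    changed = True
                    break
            if changed:
                break
    return cur


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

CHANNELS = ("condensate", "nucleus", "centrosome")


def _deposit_bilinear(img: np.ndarray, y: float, x: float, amount: float) -> None:
    """Spread a point mass over the 4 neighboring pixels (sum-preserving)."""
    y0, x0 = int(np.floor(y)), int(np.floor(x))
    fy, fx = y - y0, x - x0
    for dy, wy in ((0, 1 - fy), (1, fy)):
        for dx, wx in ((0, 1 - fx), (1, fx)):
            yy, xx = y0 + dy, x0 + dx
            if 0 <= yy < img.shape[0] and 0 <= xx < img.shape[1]:
                img[yy, xx] += amount * wy * wx


def _paint_disk(img: np.ndarray, y: float, x: float, radius_px: float,
                total: float) -> None:
    if radius_px < 0.7:
        _deposit_bilinear(img, y, x, total)
        return
    y0 = max(0, int(math.floor(y - radius_px)))
    y1 = min(img.shape[0], int(math.ceil(y + radius_px)) + 1)
    x0 = max(0, int(math.floor(x - radius_px)))
    x1 = min(img.shape[1], int(math.ceil(x + radius_px)) + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (yy - y) ** 2 + (xx - x) ** 2 <= radius_px**2
    n = int(mask.sum())
    if n == 0:
        _deposit_bilinear(img, y, x, total)
        return
    img[y0:y1, x0:x1][mask] += total / n


def _paint_ellipse(img, cy, cx, ay, ax_, total):
    y0 = max(0, int(math.floor(cy - ay)))
    y1 = min(img.shape[0], int(math.ceil(cy + ay)) + 1)
    x0 = max(0, int(math.floor(cx - ax_)))
    x1 = min(img.shape[1], int(math.ceil(cx + ax_)) + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax_) ** 2 <= 1.0
    n = int(mask.sum())
    if n:
        img[y0:y1, x0:x1][mask] += total / n


def render_stack(
    scene: GroundTruthScene,
    psf_sigma: float = 0.15,
    background: float = 10.0,
    poisson_noise: bool = False,
    *,
    intensity_scale: float = 1000.0,
    nucleus_intensity: float = 50_000.0,
    centrosome_intensity: float = 2_000.0,
    seed: int | None = None,
) -> ImageStack:
    """Render a scene into a (frame, channel, row, col) image stack.

    Objects are painted sum-preservingly (condensates as uniform disks of
    their true area, nuclei as filled ellipses, centrosomes as sub-pixel
    point deposits), convolved with a Gaussian PSF of ``psf_sigma`` μm,
    offset by a constant background, and optionally Poisson-sampled.
    ``intensity_scale`` is the camera gain mapping the truth's
    concentration-scale condensate intensities to photon-scale counts; a
    noiseless render conserves each condensate's scaled intensity sum
    (boundary clipping excepted). Objects outside the field are clipped
    with a logged warning.
    """
    import logging

    if psf_sigma < 0:
        raise ValueError("psf_sigma must be >= 0")
    log = logging.getLogger(__name__)
    cfg = scene.config
    h, w = cfg.field_size
    cal = cfg.calibration
    nf = cfg.n_frames
    data = np.zeros((nf, len(CHANNELS), h, w), dtype=float)
    sigma_px = psf_sigma / cal

    for cell in scene.cells:
        for f in range(nf):
            ny, nx = cell.nucleus_centers[f] / cal
            if not (0 <= ny < h and 0 <= nx < w):
                log.warning("cell %d nucleus outside field at frame %d; clipped",
                            cell.cell_id, f)
            _paint_ellipse(
                data[f, 1], ny, nx,
                cell.nucleus_axes[0] / cal, cell.nucleus_axes[1] / cal,
                nucleus_intensity,
            )
            for p in cell.centrosome_positions(f):
                _deposit_bilinear(data[f, 2], p[0] / cal, p[1] / cal,
                                  centrosome_intensity)
            for k in cell.frames[f].condensates:
                r_px = math.sqrt(k.area / math.pi) / cal
                _paint_disk(data[f, 0], k.center[0] / cal, k.center[1] / cal,
                            r_px, k.intensity * intensity_scale)

    if sigma_px > 0:
        for f in range(nf):
            for c in range(len(CHANNELS)):
                data[f, c] = gaussian_filter(data[f, c], sigma_px, mode="constant")
    data += background
    if poisson_noise:
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        data = rng.poisson(np.clip(data, 0, None)).astype(float)
    timestamps = np.arange(nf) * cfg.frame_interval_s
    return ImageStack(data=data, channels=CHANNELS, calibration=cal,
                      timestamps=timestamps)


def truth_detections(scene: GroundTruthScene) -> dict[str, dict[int, list]]:
    """Convert ground truth into per-frame detection objects.

    Produces the same ``{channel: {frame: [DetectedObject]}}`` structure
    the detect stage emits, but straight from truth (pixel centroids from
    the true μm positions, areas and intensity sums from the true
    values). Lets tracking and kinetics be exercised at scale without
    rendering images; labels are per-frame and carry no identity.
    """
    from .detect import DetectedObject

    cfg = scene.config
    cal = cfg.calibration
    out: dict[str, dict[int, list]] = {
        "nucleus": {}, "centrosome": {}, "condensate": {}
    }
    for f in range(cfg.n_frames):
        nuc, cen, con = [], [], []
        for cell in scene.cells:
            ny, nx = cell.nucleus_centers[f] / cal
            nuc.append(
                DetectedObject(f, "nucleus", len(nuc) + 1, (float(ny), float(nx)),
                               area=1, intensity_sum=1.0)
            )
            for p in cell.centrosome_positions(f):
                cen.append(
                    DetectedObject(f, "centrosome", len(cen) + 1,
                                   (float(p[0] / cal), float(p[1] / cal)),
                                   area=1, intensity_sum=1.0)
                )
            for k in cell.frames[f].condensates:
                con.append(
                    DetectedObject(
                        f, "condensate", len(con) + 1,
                        (float(k.center[0] / cal), float(k.center[1] / cal)),
                        area=max(1, int(round(k.area / cal**2))),
                        intensity_sum=k.intensity,
                    )
                )
        out["nucleus"][f] = nuc
        out["centrosome"][f] = cen
        out["condensate"][f] = con
    return out


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrapTruth:
    """True parameters of a simulated bleach-recovery experiment."""

    f_post: float
    f_inf: float
    k: float  # 1/s
    f_pre: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if not (self.f_post <= self.f_inf <= self.f_pre):
            raise ValueError("require f_post <= f_inf <= f_pre")
        if self.k < 0 or self.noise_sd < 0:
            raise ValueError("k and noise_sd must be >= 0")


def simulate_frap_trace(truth: FrapTruth, times, seed: int = 0):
    """Simulate a FRAP trace on the given time grid.

    ``times`` are seconds relative to the bleach: negative samples are
    pre-bleach at ``f_pre``; samples at t ≥ 0 follow the exponential
    recovery. Gaussian noise of sd ``noise_sd`` is added throughout.
    Returns a :class:`condensekit.frap.FrapTrace`.
    """
    from .frap import FrapTrace

    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be sorted strictly increasing")
    if t[0] >= 0:
        raise ValueError("times must include pre-bleach (negative) samples")
    rng = np.random.default_rng(seed)
    post = t >= 0
    y = np.full(t.shape, truth.f_pre, dtype=float)
    y[post] = truth.f_post + (truth.f_inf - truth.f_post) * (
        1.0 - np.exp(-truth.k * t[post])
    )
    if truth.noise_sd > 0:
        y += rng.normal(0.0, truth.noise_sd, size=y.shape)
    bleach_index = int(np.argmax(post))
    return FrapTrace(times=t, intensities=y, bleach_index=bleach_index)


# ---------------------------------------------------------------------------
# dissolution by aliphatic alcohols
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlcoholSpec:
    """An aliphatic alcohol with its granule-dissolving potency.

    ``dissolution_rate`` is the per-granule exponential hazard (1/min);
    within a panel it must increase with ``hydrophobicity_rank``,
    reflecting that more hydrophobic alcohols dissolve liquid-like
    assemblies faster.
    """

    name: str
    molar_mass: float  # g/mol
    hydrophobicity_rank: int
    dissolution_rate: float  # 1/min

    def __post_init__(self):
        if self.dissolution_rate < 0:
            raise ValueError("dissolution_rate must be >= 0")
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be > 0")


def alcohol_panel() -> list[AlcoholSpec]:
    """A default panel of aliphatic alcohols ordered by hydrophobicity.

    Rates are illustrative simulator settings chosen so dissolution
    half-times span roughly 2–35 min, bracketing granule dissolution
    "within minutes" for the most hydrophobic members.
    """
    panel = [
        AlcoholSpec("1,2-propanediol", 76.09, 1, 0.02),
        AlcoholSpec("1,4-butanediol", 90.12, 2, 0.06),
        AlcoholSpec("2,5-hexanediol", 118.17, 3, 0.12),
        AlcoholSpec("1,6-hexanediol", 118.17, 4, 0.25),
        AlcoholSpec("1,7-heptanediol", 132.20, 5, 0.40),
    ]
    _check_panel(panel)
    return panel


def _check_panel(panel: list[AlcoholSpec]) -> None:
    ordered = sorted(panel, key=lambda a: a.hydrophobicity_rank)
    rates = [a.dissolution_rate for a in ordered]
    if any(b <= a for a, b in zip(rates, rates[1:])):
        raise ValueError(
            "dissolution_rate must strictly increase with hydrophobicity_rank"
        )


def simulate_dissolution(
    n_granules_per_cell,
    alcohol: AlcoholSpec,
    times,
    seed: int = 0,
    include_control: bool = True,
) -> pd.DataFrame:
    """Simulate per-cell granule survival after acute alcohol addition.

    Each granule independently dissolves with exponential hazard
    ``alcohol.dissolution_rate`` (1/min); centrosome-incorporated material
    is refractory and is not part of the granule counts. Returns a long
    table (condition, cell, time_min, count); the untreated control keeps
    all granules.
    """
    counts0 = np.asarray(n_granules_per_cell, dtype=int)
    if np.any(counts0 < 0):
        raise ValueError("granule counts must be >= 0")
    t = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for cell, n0 in enumerate(counts0):
        if alcohol.dissolution_rate > 0:
            lifetimes = rng.exponential(1.0 / alcohol.dissolution_rate, size=n0)
        else:
            lifetimes = np.full(n0, np.inf)
        for tm in t:
            rows.append(
                {"condition": alcohol.name, "cell": cell, "time_min": float(tm),
                 "count": int(np.sum(lifetimes > tm))}
            )
        if include_control:
            for tm in t:
                rows.append(
                    {"condition": "untreated", "cell": cell,
                     "time_min": float(tm), "count": int(n0)}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# phase-experiment shortcut (truth-level concentration ramps)
# ---------------------------------------------------------------------------


def simulate_phase_experiment(
    n_cells: int = 30,
    csat_true: float = 1.0,
    noise_frac: float = 0.10,
    n_frames: int = 40,
    production_rate: float = 0.05,
    initial_concentration: float = 0.3,
    dense_ratio: float = 50.0,
    cytoplasm_volume: float = 500.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the per-cell concentration-ramp measurements of a Csat assay.

    Each cell ramps its total concentration linearly (cell-to-cell
    variation in start and rate), phase separates on crossing
    ``csat_true`` per the lever rule, and every measured concentration and
    volume carries independent multiplicative Gaussian noise of relative
    sd ``noise_frac`` — the measurement-noise model for dense/whole surface
    rendering. Columns match the phase-table convention:
    cell_id, time_s, whole_conc, light_conc, dense_conc, dense_volume,
    whole_volume, separated.
    """
    rng = np.random.default_rng(seed)
    rows = []
    dense_conc_true = dense_ratio * csat_true
    for cid in range(n_cells):
        c0 = initial_concentration * rng.uniform(0.6, 1.4)
        rate = production_rate * rng.uniform(0.7, 1.3)
        vol = cytoplasm_volume * rng.uniform(0.8, 1.2)
        for f in range(n_frames):
            c_tot = c0 + rate * f
            if c_tot <= csat_true:
                light, dense_vol = c_tot, 0.0
            else:
                light = csat_true
                dense_vol = (c_tot - csat_true) * vol / (dense_conc_true - csat_true)

            def meas(x):
                return max(x * (1.0 + noise_frac * rng.standard_normal()), 0.0) \
                    if x > 0 else 0.0

            rows.append(
                {
                    "cell_id": cid,
                    "time_s": f * 240.0,
                    "whole_conc": meas(c_tot),
                    "light_conc": meas(light),
                    "dense_conc": meas(dense_conc_true) if dense_vol > 0 else 0.0,
                    "dense_volume": meas(dense_vol),
                    "whole_volume": meas(vol + dense_vol),
                    "separated": dense_vol > 0,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reagent arithmetic
# ---------------------------------------------------------------------------


def percent_to_molar(percent_wv: float, molar_mass: float) -> float:
    """Convert %(w/v) (g per 100 mL) to mM: ``percent × 10 × 1000 / M``."""
    if molar_mass <= 0:
        raise ValueError("molar_mass must be > 0")
    if percent_wv < 0:
        raise ValueError("percent must be >= 0")
    return percent_wv * 10.0 * 1000.0 / molar_mass


def molar_to_percent(millimolar: float, molar_mass: float) -> float:
    """Inverse of :func:`percent_to_molar`."""
    if molar_mass <= 0:
        raise ValueError("molar_mass must be > 0")
    if millimolar < 0:
        raise ValueError("concentration must be >= 0")
    return millimolar * molar_mass / 10.0 / 1000.0
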