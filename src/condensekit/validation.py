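"""Self-validation experiments run against the synthetic ground truth.

Each function simulates a study at its stated conditions, runs the
corresponding estimator through the public pipeline, and reports how well
the truth was recovered. They are the package's reproducible substitute
for benchmarking on raw microscopy data, and they power both the test
suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from . import dynamics, phase, simulate, stats, track

__all__ = [
    "csat_recovery",
    "tracking_identity",
    "transport_slope_experiment",
    "null_calibration",
    "frap_recovery_bias",
    "enrichment_recovery",
]


def csat_recovery(
    n_replicates: int = 100,
    n_cells: int = 30,
    csat_true: float = 1.0,
    noise_frac: float = 0.10,
    seed: int = 0,
) -> dict:
    """Replicate Csat estimation on noisy simulated concentration ramps.

    Each replicate simulates ``n_cells`` cells ramping through the phase
    boundary with ``noise_frac`` relative measurement noise, estimates
    Csat from the light concentration at each cell's onset, and records
    the relative error and whether the 95% CI covers the truth.
    """
    rel_errors, covered, estimates = [], 0, []
    for i in range(n_replicates):
        df = simulate.simulate_phase_experiment(
            n_cells=n_cells, csat_true=csat_true, noise_frac=noise_frac,
            seed=seed * 100_003 + i,
        )
        est = phase.estimate_csat(df)
        estimates.append(est.value)
        rel_errors.append(abs(est.value - csat_true) / csat_true)
        lo, hi = est.ci
        covered += lo <= csat_true <= hi
    return {
        "csat_true": csat_true,
        "n_replicates": n_replicates,
        "mean_estimate": float(np.mean(estimates)),
        "max_relative_error": float(np.max(rel_errors)),
        "mean_relative_error": float(np.mean(rel_errors)),
        "ci_coverage": covered / n_replicates,
    }


def _track_scene(scene, gate: float = 3.0, radius: float = 15.0):
    dets = simulate.truth_detections(scene)
    tracks = track.link_nuclei(dets["nucleus"], gate, scene.config.calibration)
    tracks, qc = track.assign_to_cells(
        tracks, dets["condensate"], dets["centrosome"], radius,
        scene.config.calibration,
    )
    return tracks, qc


def tracking_identity(n_scenes: int = 20, seed: int = 0) -> dict:
    """Count identity switches of the tracker against ground truth.

    Scenes obey the displacement gate (nucleus drift well below both the
    gate and half the inter-nucleus spacing), so linking must reproduce
    each cell's identity in every frame and every condensate must land on
    its true cell.
    """
    identity_errors = 0
    assignment_errors = 0
    n_tracks_wrong = 0
    for s in range(n_scenes):
        cfg = simulate.SceneConfig(n_cells=4, n_frames=15,
                                   nucleus_drift_sd=0.1, seed=seed + 1000 + s)
        scene = simulate.simulate_scene(cfg)
        tracks, _ = _track_scene(scene)
        if len(tracks) != cfg.n_cells:
            n_tracks_wrong += 1
        cal = cfg.calibration
        # truth condensate location -> owning cell, per frame
        owners = {
            f: {
                (round(k.center[0], 9), round(k.center[1], 9)): cell.cell_id
                for cell in scene.cells
                for k in cell.frames[f].condensates
            }
            for f in range(cfg.n_frames)
        }
        for t in tracks:
            f0 = t.frames[0]
            start = np.array(t.nuclei[f0].centroid) * cal
            truth_cell = min(
                scene.cells,
                key=lambda c: np.linalg.norm(c.nucleus_centers[f0] - start),
            )
            for f in t.frames:
                got = np.array(t.nuclei[f].centroid) * cal
                if np.linalg.norm(got - truth_cell.nucleus_centers[f]) > 1e-6:
                    identity_errors += 1
                for obj in t.condensates.get(f, []):
                    pos = (
                        round(obj.centroid[0] * cal, 9),
                        round(obj.centroid[1] * cal, 9),
                    )
                    if owners[f].get(pos) != truth_cell.cell_id:
                        assignment_errors += 1
    return {
        "n_scenes": n_scenes,
        "identity_switches": identity_errors,
        "assignment_errors": assignment_errors,
        "scenes_with_wrong_track_count": n_tracks_wrong,
    }


def transport_slope_experiment(
    n_cells: int = 50,
    n_frames: int = 20,
    transport_speed: float = 0.5,
    seed: int = 0,
) -> dict:
    """Directed-transport vs motor-inhibited distance kinetics.

    Simulates matched conditions differing only in ``transport_speed``
    (μm/min toward the centrosome; 0 models dynein inhibition or
    microtubule depolymerization), tracks cells from truth detections,
    aligns each cell at its phase-separation onset, and compares the
    distance-vs-time slopes with the extra-sum-of-squares F-test. Also
    fits a per-cell OLS slope in the transport-off arm and reports the
    95% CI of its mean (expected to straddle zero).
    """
    def run_condition(speed: float, cond_seed: int):
        cfg = simulate.SceneConfig(
            n_cells=n_cells, field_size=(800, 800), n_frames=n_frames,
            transport_speed=speed, nucleation_rate=0.25, seed=cond_seed,
        )
        scene = simulate.simulate_scene(cfg)
        tracks, _ = _track_scene(scene, radius=8.0)
        xs, ys, per_cell_slopes = [], [], []
        for t in tracks:
            s = dynamics.condensate_timeseries(
                t, cfg.calibration, cfg.frame_interval_s
            )
            a = dynamics.align_at_onset(s)
            if a is None:
                continue
            sel = a[(a["time_aligned_s"] >= 0) & a["mean_distance_um"].notna()]
            if len(sel) < 3:
                continue
            x = sel["time_aligned_s"].to_numpy() / 60.0  # minutes
            y = sel["mean_distance_um"].to_numpy()
            xs.extend(x)
            ys.extend(y)
            if np.unique(x).size >= 2:
                per_cell_slopes.append(float(np.polyfit(x, y, 1)[0]))
        return np.asarray(xs), np.asarray(ys), per_cell_slopes

    x_on, y_on, _ = run_condition(transport_speed, seed + 21)
    x_off, y_off, slopes_off = run_condition(0.0, seed + 22)
    comp = stats.slope_equality_ftest(
        {"transport_on": (x_on, y_on), "transport_off": (x_off, y_off)}
    )
    m, lo, hi = stats.mean_ci95(slopes_off)
    return {
        "slope_on_um_per_min": comp.slopes["transport_on"],
        "slope_off_um_per_min": comp.slopes["transport_off"],
        "f_statistic": comp.f_statistic,
        "p_value": comp.p_value,
        "off_mean_cell_slope": m,
        "off_cell_slope_ci": (lo, hi),
        "n_cells_off": len(slopes_off),
    }


def null_calibration(n_reps: int = 1000, seed: int = 0) -> dict:
    """Type-I error rates of the three tests under their null hypotheses."""
    rng = np.random.default_rng(seed + 7)
    rej_t = rej_f = rej_slope = 0
    x = np.linspace(0.0, 5.0, 10)
    for _ in range(n_reps):
        a, b, c = (rng.standard_normal(10) for _ in range(3))
        if stats.t_test_unpaired(a, b).p_value < 0.05:
            rej_t += 1
        if stats.one_way_anova(a, b, c).p_value < 0.05:
            rej_f += 1
        g = {
            "a": (x, 1.0 + 0.5 * x + rng.standard_normal(10)),
            "b": (x, 1.0 + 0.5 * x + rng.standard_normal(10)),
        }
        if stats.slope_equality_ftest(g).p_value < 0.05:
            rej_slope += 1
    return {
        "n_reps": n_reps,
        "t_test_rejection_rate": rej_t / n_reps,
        "anova_rejection_rate": rej_f / n_reps,
        "slope_f_rejection_rate": rej_slope / n_reps,
    }


def frap_recovery_bias(
    n_traces: int = 100,
    f_post: float = 0.2,
    f_inf: float = 0.8,
    k: float = 0.1,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> dict:
    """Bias and CI coverage of the FRAP fit on noisy simulated traces."""
    from .frap import fit_recovery

    truth_pct = 100.0 * (f_inf - f_post) / (1.0 - f_post)
    truth = simulate.FrapTruth(f_post=f_post, f_inf=f_inf, k=k, noise_sd=noise_sd)
    times = np.concatenate([[-10.0, -5.0], np.arange(0.0, 120.0, 2.0)])
    recs, covered = [], 0
    for i in range(n_traces):
        fit = fit_recovery(simulate.simulate_frap_trace(truth, times,
                                                        seed=seed * 9973 + i))
        recs.append(fit.percent_recovery)
        lo, hi = fit.percent_recovery_ci
        covered += lo <= truth_pct <= hi
    return {
        "truth_percent_recovery": truth_pct,
        "mean_fitted_percent_recovery": float(np.mean(recs)),
        "bias_points": float(np.mean(recs) - truth_pct),
        "ci_coverage": covered / n_traces,
    }


def enrichment_recovery(
    n_cells: int = 20, true_ratio: float = 3.0, seed: int = 0
) -> dict:
    """Recover a known condensate/cytoplasm intensity ratio under shot noise."""
    from .enrichment import fold_enrichment, group_fold_enrichment

    rng = np.random.default_rng(seed + 3)
    shape = (100, 100)
    cond = np.zeros(shape, dtype=bool)
    cond[20:60, 20:60] = True
    cyto = np.zeros(shape, dtype=bool)
    cyto[70:95, 5:95] = True
    results = []
    for cell in range(n_cells):
        img = np.full(shape, 10.0)
        img[cond] = 10.0 * true_ratio
        noisy = rng.poisson(img).astype(float)
        results.append(
            fold_enrichment(noisy, cond, cyto, seed=seed * 31 + cell,
                            cell_id=cell)
        )
    group = group_fold_enrichment(results)
    est = group["fold_enrichment"]
    return {
        "true_ratio": true_ratio,
        "estimated_fold": est,
        "relative_error": abs(est - true_ratio) / true_ratio,
        "n_cells": n_cells,
    }
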