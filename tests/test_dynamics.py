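"""Condensate kinetics, onset alignment, staging, granule counts,
dissolution curves."""

import itertools

import numpy as np
import pandas as pd
import pytest

from condensekit import simulate
from condensekit.detect import DetectedObject
from condensekit.dynamics import (
    StageFeatures,
    align_at_onset,
    classify_stage,
    condensate_timeseries,
    count_granules,
    dissolution_percent_remaining,
    distance_at_onset,
    STAGES,
)
from condensekit.track import CellTrack


def make_track(cond_by_frame, cent_by_frame):
    t = CellTrack(cell_id=0)
    frames = set(cond_by_frame) | set(cent_by_frame)
    for f in frames:
        t.nuclei[f] = DetectedObject(f, "nucleus", 1, (0.0, 0.0), 10, 1.0)
        t.condensates[f] = [
            DetectedObject(f, "condensate", i + 1, rc, area, 10.0)
            for i, (rc, area) in enumerate(cond_by_frame.get(f, []))
        ]
        t.centrosomes[f] = [
            DetectedObject(f, "centrosome", i + 1, rc, 1, 1.0)
            for i, rc in enumerate(cent_by_frame.get(f, []))
        ]
    return t


class TestTimeseries:
    def test_area_scaling_and_count(self):
        t = make_track({0: [((1.0, 1.0), 4), ((5.0, 5.0), 6)]}, {0: [(0.0, 0.0)]})
        s = condensate_timeseries(t, calibration=0.1, frame_interval_s=240.0)
        r = s.iloc[0]
        assert r["count"] == 2
        assert r["total_area_um2"] == pytest.approx(0.10)

    def test_three_four_five_distance(self):
        t = make_track({0: [((3.0, 4.0), 4)]}, {0: [(0.0, 0.0)]})
        s = condensate_timeseries(t, 0.1, 240.0)
        assert s.iloc[0]["mean_distance_um"] == pytest.approx(0.5)

    def test_nearest_of_two_centrosomes(self):
        t = make_track({0: [((0.0, 10.0), 4)]}, {0: [(0.0, 0.0), (0.0, 12.0)]})
        s = condensate_timeseries(t, 1.0, 240.0)
        assert s.iloc[0]["mean_distance_um"] == pytest.approx(2.0)

    def test_empty_frame_zero_count_nan_distance(self):
        t = make_track({0: []}, {0: [(0.0, 0.0)]})
        s = condensate_timeseries(t, 0.1, 240.0)
        r = s.iloc[0]
        assert r["count"] == 0 and r["total_area_um2"] == 0.0
        assert np.isnan(r["mean_distance_um"])

    def test_missing_centrosome_flagged(self):
        t = make_track({0: [((1.0, 1.0), 4)]}, {0: []})
        s = condensate_timeseries(t, 0.1, 240.0)
        assert bool(s.iloc[0]["no_centrosome"])
        assert np.isnan(s.iloc[0]["mean_distance_um"])


class TestOnsetAlignment:
    def series(self, counts, areas=None):
        areas = areas or [1.0] * len(counts)
        return pd.DataFrame(
            {
                "frame": range(len(counts)),
                "time_s": [240.0 * f for f in range(len(counts))],
                "count": counts,
                "total_area_um2": areas,
                "max_condensate_area_um2": areas,
                "mean_distance_um": [np.nan] * len(counts),
                "distances_um": [[] for _ in counts],
                "no_centrosome": [False] * len(counts),
            }
        )

    def test_onset_at_first_nonzero_count(self):
        a = align_at_onset(self.series([0, 0, 1, 2]))
        assert a.attrs["onset_frame"] == 2
        assert list(a["time_aligned_s"]) == [-480.0, -240.0, 0.0, 240.0]

    def test_all_zero_series_excluded(self):
        assert align_at_onset(self.series([0, 0, 0])) is None

    def test_min_area_defers_onset(self):
        s = self.series([0, 1, 1], areas=[0.0, 0.05, 0.5])
        a = align_at_onset(s, min_area=0.1)
        assert a.attrs["onset_frame"] == 2


class TestDistanceAtOnset:
    def aligned(self, dists):
        df = pd.DataFrame(
            {
                "frame": [0, 1],
                "time_aligned_s": [0.0, 240.0],
                "distances_um": [list(dists), []],
            }
        )
        return df

    def test_anova_across_groups(self, rng):
        groups = {
            "near": [self.aligned(rng.uniform(1, 2, 5)) for _ in range(6)],
            "far": [self.aligned(rng.uniform(8, 9, 5)) for _ in range(6)],
        }
        table, anova = distance_at_onset(groups)
        assert anova.p_value < 1e-6
        summary = table.attrs["summary"]
        assert summary["near"]["median"] < summary["far"]["median"]

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            distance_at_onset({"only": [self.aligned([1, 2])]})

    def test_sparse_group_excluded_with_warning(self, rng):
        groups = {
            "ok1": [self.aligned(rng.uniform(1, 2, 5)) for _ in range(4)],
            "ok2": [self.aligned(rng.uniform(2, 3, 5)) for _ in range(4)],
            "thin": [self.aligned([1.0])],
        }
        with pytest.warns(UserWarning, match="thin"):
            table, _ = distance_at_onset(groups)
        assert set(table["group"]) == {"ok1", "ok2"}


class TestGranuleCount:
    def track_with(self, cond_pos, cent_pos):
        return make_track({0: [(p, 4) for p in cond_pos]}, {0: cent_pos})

    def test_centrosome_coincident_objects_excluded(self):
        # 5 objects, 2 coincide with the two centrosomes → 3 granules
        t = self.track_with(
            [(10, 10), (20, 20), (30, 30), (50, 50), (70, 70)],
            [(10.5, 10.5), (50.2, 50.2)],
        )
        assert count_granules(t, 0, calibration=0.1,
                              centrosome_exclusion_radius=0.5) == 3

    def test_no_objects_zero(self):
        t = self.track_with([], [(10, 10)])
        assert count_granules(t, 0, 0.1) == 0

    def test_truth_roundtrip_on_simulated_cell(self):
        cfg = simulate.SceneConfig(n_cells=1, n_frames=20, seed=4,
                                   nucleation_rate=0.5, transport_speed=0.0)
        scene = simulate.simulate_scene(cfg)
        dets = simulate.truth_detections(scene)
        from condensekit.track import assign_to_cells, link_nuclei

        tracks = link_nuclei(dets["nucleus"], 3.0, cfg.calibration)
        tracks, _ = assign_to_cells(tracks, dets["condensate"],
                                    dets["centrosome"], 20.0, cfg.calibration)
        f = cfg.n_frames - 1
        truth_granules = sum(
            1
            for k in scene.cells[0].frames[f].condensates
            if min(
                np.linalg.norm(
                    np.array(k.center) - scene.cells[0].centrosome_positions(f),
                    axis=1,
                )
            )
            > 0.5
        )
        got = count_granules(tracks[0], f, cfg.calibration,
                             centrosome_exclusion_radius=0.5)
        assert got == truth_granules


def test_transport_makes_per_cell_distance_slopes_predominantly_negative():
    """With directed transport on, most cells' distance-vs-time OLS slopes
    are negative; continued nucleation and cells whose condensates are born
    next to the centrosome keep the fraction below 1."""
    from condensekit.validation import _track_scene

    neg = tot = 0
    for seed in (29, 30, 31, 32):
        cfg = simulate.SceneConfig(
            n_cells=50, field_size=(800, 800), n_frames=20,
            transport_speed=0.5, nucleation_rate=0.25, seed=seed,
        )
        scene = simulate.simulate_scene(cfg)
        tracks, _ = _track_scene(scene, radius=8.0)
        for t in tracks:
            s = condensate_timeseries(t, cfg.calibration, cfg.frame_interval_s)
            a = align_at_onset(s)
            if a is None:
                continue
            sel = a[(a["time_aligned_s"] >= 0) & a["mean_distance_um"].notna()]
            if len(sel) < 3:
                continue
            x = sel["time_aligned_s"].to_numpy() / 60.0
            y = sel["mean_distance_um"].to_numpy()
            tot += 1
            neg += np.polyfit(x, y, 1)[0] < 0
    assert tot >= 150
    assert neg / tot > 0.75


class TestStaging:
    def feats(self, **kw):
        base = dict(
            n_centrosomes=1,
            centrosome_separation_um=0.0,
            centrin_dots_per_centrosome=(2,),
            dna_condensed=False,
            ne_intact=True,
        )
        base.update(kw)
        return StageFeatures(**base)

    def test_reference_definitions(self):
        assert classify_stage(self.feats())[0] == "G1/early S"
        assert classify_stage(
            self.feats(n_centrosomes=2, centrosome_separation_um=0.8,
                       centrin_dots_per_centrosome=(2, 2))
        )[0] == "S/early G2"
        assert classify_stage(
            self.feats(n_centrosomes=2, centrosome_separation_um=1.5,
                       centrin_dots_per_centrosome=(2, 2), pcm_expanded=True)
        )[0] == "late G2"
        assert classify_stage(self.feats(dna_condensed=True))[0] == "prophase"
        assert classify_stage(
            self.feats(dna_condensed=True, ne_intact=False)
        )[0] == "prometaphase"
        assert classify_stage(
            self.feats(dna_condensed=True, ne_intact=False, dna_at_equator=True)
        )[0] == "metaphase"
        assert classify_stage(
            self.feats(dna_condensed=True, ne_intact=False,
                       chromosomes_segregating=True)
        )[0] == "anaphase"

    def test_total_over_discrete_feature_grid(self):
        """Every feature combination maps to a stage (or 'unclassified')."""
        labels = set()
        for (nc, sep, dots, dna, ne, eq, seg, pcm) in itertools.product(
            (1, 2, 3),
            (0.5, 1.5),
            ((1,), (2,), (2, 2), (2, 1)),
            (False, True),
            (False, True),
            (False, True),
            (False, True),
            (False, True),
        ):
            label, reason = classify_stage(
                StageFeatures(nc, sep, dots, dna, ne, eq, seg, pcm)
            )
            assert label in STAGES
            if label == "unclassified":
                assert reason
            labels.add(label)
        assert labels >= set(STAGES) - {"metaphase"}  # equator needs NE down

    def test_ambiguous_combination_reported(self):
        label, reason = classify_stage(
            self.feats(n_centrosomes=2, centrosome_separation_um=2.0,
                       centrin_dots_per_centrosome=(2, 2), pcm_expanded=False)
        )
        assert label == "unclassified" and "PCM" in reason


class TestDissolutionCurves:
    def counts(self, rows):
        return pd.DataFrame(rows, columns=["condition", "cell", "time_min", "count"])

    def test_per_cell_normalization(self):
        df = self.counts([("hex", 0, 0.0, 10), ("hex", 0, 5.0, 5), ("hex", 0, 10.0, 0)])
        out = dissolution_percent_remaining(df)
        per = out.attrs["per_cell"]
        assert list(per["percent_remaining"]) == [100.0, 50.0, 0.0]

    def test_untreated_stays_at_100(self):
        df = self.counts([("ctrl", c, t, 7) for c in range(3) for t in (0.0, 5.0)])
        out = dissolution_percent_remaining(df)
        assert (out["mean_percent"] == 100.0).all()

    def test_zero_baseline_cell_excluded(self):
        df = self.counts(
            [("hex", 0, 0.0, 0), ("hex", 0, 5.0, 0),
             ("hex", 1, 0.0, 4), ("hex", 1, 5.0, 2)]
        )
        out = dissolution_percent_remaining(df)
        assert set(out.attrs["per_cell"]["cell"]) == {1}

    def test_hydrophobicity_ordering_of_remaining_fraction(self):
        t = [0.0, 10.0]
        means = []
        for alc in simulate.alcohol_panel():
            counts = simulate.simulate_dissolution([40] * 10, alc, t, seed=6,
                                                   include_control=False)
            curve = dissolution_percent_remaining(counts)
            means.append(
                float(curve.loc[curve.time_min == 10.0, "mean_percent"].iloc[0])
            )
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_sem_interval_narrower_than_ci(self):
        df = self.counts(
            [("hex", c, t, n) for c, ns in enumerate([(10, 6), (8, 3), (12, 7)])
             for t, n in zip((0.0, 5.0), ns)]
        )
        ci = dissolution_percent_remaining(df, interval="ci95")
        sem = dissolution_percent_remaining(df, interval="sem")
        at5 = lambda d: d[d.time_min == 5.0].iloc[0]
        assert (at5(sem)["upper"] - at5(sem)["lower"]) < (
            at5(ci)["upper"] - at5(ci)["lower"]
        )
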