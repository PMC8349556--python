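# condensekit

Quantitative analysis of biomolecular condensates in fluorescence
microscopy, built for studies of pericentriolar-material scaffold proteins
(pericentrin and its fragments) that phase separate in cells, but applicable
to any micron-scale membraneless assembly imaged as a bright object in a
dedicated channel.

The package covers the full measurement chain such studies need:

* **Detection** — intensity-threshold segmentation with particle-analysis
  measurements (intensity-weighted centroid, pixel area, raw intensity sum).
* **Nucleus-anchored tracking** — cell identity is carried by the nucleus,
  matched across consecutive frames by minimal total centroid displacement
  (optimal bipartite assignment with a displacement gate); condensates and
  centrosomes are then paired to the nearest nucleus per frame, with a
  machine-readable QC report in place of manual pairing checks.
* **Condensate kinetics** — per-cell condensate number, total area and
  distance to the nearest centrosome over time, aligned at each cell's
  phase-separation onset (time 0); granule counting with
  centrosome-coincident objects excluded; a rule-based cell-cycle stager;
  per-cell % -granules-remaining dissolution curves.
* **Phase decomposition and C<sub>sat</sub>** — dual-threshold dense/whole
  decomposition of a cell's voxels, concentrations as intensity sum per
  volume, and the critical concentration estimated as the light-phase
  concentration when phase separation just occurs, averaged across cells
  with a 95% CI.
* **FRAP** — pre-bleach normalization and single-exponential recovery
  fitting, F(t) = f₀ + (f∞ − f₀)(1 − e^(−kt)), reporting percentage
  recovery 100·(f∞ − f₀)/(1 − f₀) and t½ = ln2/k with delta-method CIs.
* **Enrichment** — fold enrichment of a stained protein in condensate vs
  cytoplasm from randomly placed square ROIs (with a centrosome exclusion
  zone), and microtubule-regrowth density normalized to a 1-μm annulus.
* **Statistics** — mean ± 95% t-interval, unpaired two-tailed Student's
  t-test (pooled; Welch behind a flag), one-way ANOVA, and the
  extra-sum-of-squares F-test comparing regression slopes between groups.
* **Simulation** — a seeded ground-truth generator (concentration ramps
  with lever-rule phase separation, directed-plus-Brownian condensate
  motion with fusion, FRAP traces, first-order granule dissolution) and a
  sum-preserving renderer (Gaussian PSF, Poisson noise), so every estimator
  can be validated against known truth.

## Worked example

Simulate a two-cell time-lapse in which protein production pushes cells
through the phase boundary and condensates are carried toward the
centrosome, then run the pipeline and the two model fits:

```python
import numpy as np
from condensekit import io as ckio
from condensekit import phase, simulate
from condensekit.frap import fit_recovery

cfg = simulate.SceneConfig(n_cells=2, n_frames=25, seed=7)
rc = ckio.RunConfig(
    scene=cfg,
    thresholds={"condensate": 30.0, "nucleus": 20.0, "centrosome": 30.0},
    min_size={"nucleus": 50},
)
bundle = ckio.run_pipeline(rc)
aligned = bundle["aligned"][0]
print(aligned[aligned["time_aligned_s"].between(0, 1200)]
      [["frame", "count", "total_area_um2", "mean_distance_um",
        "time_aligned_s"]].to_string(index=False))

df = simulate.simulate_phase_experiment(n_cells=30, csat_true=1.0,
                                        noise_frac=0.10, seed=7)
print(phase.estimate_csat(df).summary())

truth = simulate.FrapTruth(f_post=0.2, f_inf=0.8, k=0.1, noise_sd=0.02)
times = np.concatenate([[-10.0, -5.0], np.arange(0.0, 120.0, 2.0)])
print(fit_recovery(simulate.simulate_frap_trace(truth, times, seed=7)).summary())
```

Output:

```
 frame  count  total_area_um2  mean_distance_um  time_aligned_s
    13      1            0.38          2.741486             0.0
    14      2            0.73          2.730279           240.0
    15      3            1.05          1.768243           480.0
    16      2            1.24          0.989112           720.0
    17      1            0.85          0.154172           960.0
    18      1            0.88          0.487171          1200.0
Csat = 1.007 a.u./vol (95% CI 0.9674–1.046, n = 30 cells)
FRAP recovery fit (single exponential)
  percent recovery: 74.7% [73.4, 76.0]
  t1/2: 7.01 s [6.60, 7.42]
  k: 0.09887 /s   f_post: 0.195   f_inf: 0.796
  residual sd: 0.01759   n(post) = 60
```

Reading the numbers: the first cell crosses its phase boundary at frame 13
(time re-zeroed there); condensate area grows as the total concentration
ramps while the mean distance to the centrosome falls from 2.7 μm toward
contact — the signature of directed transport. The critical-concentration
estimate recovers the simulated C<sub>sat</sub> = 1.0 a.u. within its CI
from 30 noisy cells, and the FRAP fit recovers the simulated 75% mobile
fraction and t½ = ln2/0.1 ≈ 6.9 s from a noisy trace.

A thin CLI mirrors the library (`condensekit simulate | detect | track |
kinetics | phase | frap | enrich | stats | convert`); e.g.
`condensekit convert --percent 3.5 --molar-mass 118.17` prints the molar
equivalent of a 3.5% (w/v) 1,6-hexanediol treatment (296 mM).

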