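# Methods

This note records the models, conventions and numerical choices behind
condensekit, and what the synthetic validation does and does not
establish about real data.

## The measurement problem

Scaffold proteins of the pericentriolar material (pericentrin and its
N-terminal fragments) can de-mix in cells into micron-scale liquid-like
condensates once their concentration exceeds a critical value, and those
condensates are transported along microtubules toward the centrosome.
Quantifying this from live imaging requires a chain of steps — object
detection, per-cell bookkeeping over time, onset-aligned kinetics,
dilute-phase concentration measurement, bleach-recovery fitting, and a
small set of hypothesis tests — each of which is implemented here as an
independently testable unit.

## Synthetic ground truth

Because estimator correctness cannot be audited on real images without
per-object truth, the `simulate` module generates scenes with complete
truth at every frame.

**Geometry.** Cells sit on a jittered grid; each is an annular cytoplasm
between a nucleus ellipse and a cell-boundary ellipse, with one or two
centrosomes at fixed offsets from the nucleus. The nucleus performs a slow
Gaussian random walk (default sd 0.15 μm/frame per axis) so tracking is
exercised; centrosomes ride along rigidly.

**Phase behaviour.** Total concentration ramps linearly,
C_tot(t) = C₀ + r·t (defaults C₀ = 0.4, r = 0.05 a.u./μm² per 4-min
frame, crossing the default Csat = 1.0 mid-movie — an inducible-expression
analog). The lever rule is enforced exactly at every frame: below Csat the
light phase equals C_tot and no condensates exist; above it the light
phase is pinned at Csat and the summed condensate intensity equals
(C_tot − Csat) × cytoplasm area. Condensate area is tied to intensity via
the dense-phase concentration (dense_ratio × Csat, default ratio 50), so
fusion's intensity conservation implies area additivity. This is a
bookkeeping model, not coarsening physics: no Ostwald ripening, no
surface tension, no photobleaching.

**Motion.** Per frame each condensate steps transport_speed·Δt straight
toward its nearest centrosome (never overshooting) plus an isotropic
Gaussian step of per-axis sd √(2·D·Δt). Defaults: 0.5 μm/min transport
(0 models dynein inhibition or microtubule depolymerization),
D = 0.02 μm²/min, 240-s frames — speeds that let a condensate born a few
μm out reach the centrosome within a handful of frames, matching the
qualitative phenomenology the analyses assume. Pairs closer than the sum
of their equivalent radii merge when fusion is on; new condensates
nucleate only while supersaturated, Poisson-many per frame (default mean
0.7), at cytoplasm positions drawn with acceptance weight
exp(−bias·d/d_max) toward the centrosome (bias 0 = uniform).

**Rendering.** Objects are painted sum-preservingly (condensates as
uniform disks of their true area, with sub-pixel bilinear deposition for
disks under a pixel; nuclei as filled ellipses; centrosomes as point
deposits), convolved with a Gaussian PSF (default σ 0.15 μm at
0.1 μm/px), offset by a constant background (default 10 a.u.) and
optionally Poisson-sampled. An `intensity_scale` gain (default 1000) maps
concentration-scale condensate intensities to photon-scale counts. A
noiseless render conserves each object's (scaled) intensity sum exactly
except at field boundaries; with the PSF it is conserved to well under 1%
away from borders.

All randomness in a scene flows from one seeded generator; identical
config + seed gives bit-identical scenes.

## Detection and tracking conventions

* Components are 8-connected (26 in 3-D); measurements use the raw,
  unthresholded intensities within each component; objects touching the
  border are kept but flagged. These defaults are stated because common
  particle-analysis practice varies.
* Centroids are intensity-weighted centers of mass, (row, col), 0-based,
  origin top-left.
* Nucleus linking minimizes total displacement per transition (Hungarian
  algorithm) — the global reading of "the same nucleus moves least
  between consecutive frames" — with a hard gate (default 3 μm) and no
  gap closing: a track interrupted by a missed detection restarts, and
  the QC report counts gate cuts, restarts, short tracks, unassigned
  objects and multi-centrosome cells. Ties in object-to-cell pairing
  break toward the lower cell id, making assignment deterministic.

## Kinetics

Per cell and frame: condensate count, total area (pixel areas ×
calibration²), each condensate's Euclidean distance to the nearest
assigned centrosome, and their unweighted mean (the per-cell summary;
per-condensate values are kept for onset-distance comparisons). Onset is
the first frame with a condensate of area ≥ min_area (default 0; set it
to ~2× the detection size floor in μm² to stop single-pixel noise
triggering onset); times are re-zeroed there and never-separating cells
are excluded and counted. Granule counts exclude objects whose centroid
lies within an exclusion radius (default 0.5 μm) of a centrosome, since
centrosomal scaffold material is not a free granule. The cell-cycle
stager is a total, deterministic rule cascade over annotated features
(centrosome number/separation at the 1-μm criterion, centrin-dot pairs,
DNA condensation, nuclear-envelope integrity, metaphase-plate alignment,
segregation, PCM expansion); morphology flags are inputs, not inferred
from images. Dissolution curves normalize each cell to its own granule
count at treatment time (100% at t₀) before averaging — the per-cell
reading of "% granules remaining"; pooling counts across cells first
would weight big cells more and is deliberately not done.

## Phase decomposition and Csat

Dense = voxels ≥ the higher threshold; whole = voxels ≥ the lower;
light-phase volume and intensity by subtraction (identities exact in
voxel counts); concentrations are intensity sum per volume, in relative
units. A cell is "separated" when its dense volume reaches a floor
(inclusive). Csat is read at onset — the light concentration at the
false→true transition of the separated flag — rather than averaging all
post-onset frames; the onset reading matches "when phase separation just
occurs" and is robust to later condensate aging, at the cost of using one
frame per cell. The across-cell mean with a 95% t-interval is reported.
Thresholds may be supplied per cell or derived by `auto_threshold`; both
are recorded in outputs. 3-D voxel mode is canonical; the 2-D area
fallback is labeled `2d-area` in the measurement.

## FRAP

Single-exponential recovery with the floor fixed at the first post-bleach
sample, plateau and rate free (bounded f∞ ≥ f₀, k > 0). Percentage
recovery is defined against the bleached depth, 100·(f∞ − f₀)/(1 − f₀) —
the standard mobile-fraction reading, stated explicitly because
conventions differ. CIs come from the fit covariance by the delta method;
the fixed floor's measurement noise (estimated by the residual sd) is
propagated as an independent variance component, without which the
recovery CI is anticonservative. Values above 100% are reported but
flagged `growing-structure` (an assembly gaining material during recovery
can overshoot); a flat trace is reported as 0% with t½ = ∞ and a
`no-recovery` flag rather than an unidentifiable rate. No reference-region
photobleaching correction is applied. The single-exponential choice is the
simplest model consistent with generic "non-linear regression" fitting;
residual sd is reported so a double-exponential extension can be judged.

## Enrichment

Square ROIs (side √area; 2.25 μm² → 1.5 μm side, the 0.159 μm² variant
for sub-micron assemblies) are placed uniformly at random fully inside
each compartment mask, seeded for reproducibility; the per-cell value is
the mean of ROI means, and the group fold is mean condensate intensity
over mean cytoplasm intensity across cells. Condensate ROIs avoid a
configurable exclusion disk around centrosomes so embedded centrosomal
signal does not inflate the estimate. The microtubule-density ratio uses
morphological dilation by a calibrated 1-μm disk to build the cytoplasm
annulus; a region too close to the border for its full annulus is an
error rather than a silently clipped measurement.

## Statistics

Student's t is pooled-variance by default (Welch behind a flag) to match
the naming convention of the analyses it supports; zero-variance
degenerate inputs return t = 0, p = 1 with a flag instead of NaN. The
slope comparison is the ANCOVA extra-sum-of-squares construction: full
model with per-group slopes and intercepts vs reduced model with a common
slope, F = [(SSE_r − SSE_f)/(k−1)] / [SSE_f/(N−2k)], with points pooled
within groups (per-cell fits are also computed in the validation
experiments for the zero-slope check). No multiple-testing correction is
applied, and cell-level repeated measures are not modeled — a known
limitation of pooling points.

## Validation experiments and their scope

`condensekit.validation` fixes the study conditions used by the test
suite and `scripts/acceptance.py`:

* Csat recovery: 100 replicates of 30 cells at 10% multiplicative
  measurement noise.
* Tracking identity: 20 scenes of 4 cells × 15 frames with drift sd
  0.1 μm/frame (well under the 3-μm gate and half the cell spacing).
* Transport slopes: 50 cells per condition, 20 frames, 0.5 μm/min vs 0,
  nucleation rate 0.25 so early condensates dominate the distance signal.
* Null calibration: 1000 replicates per test at n = 10 per group.
* FRAP bias: 100 noisy traces (sd 0.02) at 2-s sampling over 2 min.
* Enrichment: 20 shot-noise cells at a true ratio of 3.0.

These sizes keep the full validation under a minute on one CPU while
leaving Monte-Carlo margins comfortably inside the asserted bounds.

Passing these experiments shows the estimators are correct on data obeying
the generator's assumptions: ellipsoidal cells, linear ramps, exact lever
rule, Gaussian PSF, Poisson noise, no photobleaching, no cell division or
death, no segmentation errors beyond what thresholding produces. They do
not establish robustness to real-microscopy pathologies — uneven
illumination, z-drift, touching nuclei, mitotic shape change — which is
why thresholds, gates and exclusion radii remain exposed configuration
rather than tuned constants.

## Known limitations

* No watershed splitting of touching nuclei and no lineage handling
  through mitosis; a dividing cell becomes two new tracks.
* The simulator's granule size distribution is a free parameter, not
  calibrated to measured size spectra.
* Concentrations are relative (a.u. per volume); no absolute calibration
  is attempted.
* Binodal/spinodal fitting and temperature dependence are out of scope;
  the phase module estimates a single boundary concentration.
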