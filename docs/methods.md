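# Methods

This note documents the models, conventions, parameter choices and known
limitations of `trackmigrate`. It states no empirical result that the test
suite does not itself compute.

## Track model and conventions

A track is an ordered sequence of 2D positions (µm) at strictly increasing
0-based frame indices; time in minutes is `frame × frame_interval`
(default 20 min, the sampling used for slow neuronal migration over
recordings of up to ~84 h). Frame gaps are permitted: all rate-like
descriptors divide by the actual time difference between consecutive
retained points, and MSD pairs spanning a gap are simply absent (no
interpolation). Coordinates are 2D only — z is discarded at import because
the tracks analyzed here originate from maximum-intensity projections.

The Imaris "Position" export dialect is auto-detected by scanning for the
column-header row (`Position X`, `TrackID`), tolerating title/preamble
lines and column-name suffixes such as `Position X [µm]`. The `Time`
column (1-based frame number) is shifted so the earliest frame in the file
becomes frame 0.

## The 48 descriptors

Feature classes and the conventions that are not self-evident:

- **Speed statistics** use instantaneous speeds `|Δr| / Δt` per retained
  step; all standard deviations in the package are population (1/n) form.
- **Directional changes** are unsigned angles in [0°, 180°] between
  consecutive displacement vectors; zero-length displacements are skipped.
  Threshold counts report the fraction of angles strictly greater than
  20°, 45° and 90°. The 20° threshold is the canonical screening readout;
  the others complete the class and are configurable.
- **Average velocity** is the time-weighted mean of step velocities, which
  equals net displacement over duration; its angle is measured
  counter-clockwise from +x in [0°, 360°), and a zero net displacement
  reports (0, 0) by convention.
- **Gyration tensor** T = (1/N) Σ (rᵢ − r̄)(rᵢ − r̄)ᵀ, unweighted over all
  points. With eigenvalues λ₁ ≥ λ₂: radius = √(λ₁+λ₂), axis lengths are
  the full-ellipse convention 2√λ (the alternative √λ convention differs
  by a factor of 2; the non-moving filter threshold is configurable to
  absorb this), asphericity = (λ₁−λ₂)/(λ₁+λ₂), orientation in [0°, 180°).
- **Confinement ratio** = net displacement / path length ∈ [0, 1].
- **Degenerate cases** (fewer than two non-zero steps, zero path length,
  no dwell states, no tracklet with ≥ 3 points, no interior RDP nodes)
  yield 0 rather than a missing value, so the clustering input is always
  complete. The cost is that 0 is overloaded; for screening purposes this
  is acceptable because such tracks are rare after filtering.

## Dwell/move partitioning

Points are embedded as (x, y, frame · t_scale) and clustered with DBSCAN
(Euclidean metric). Defaults: t_scale = 1.1 µm-equivalent per frame,
ε = 3.3 µm, min_pts = 4. The time axis is scaled per *frame*, not per
minute: at 20 min/frame a per-minute scaling of 1.1 would put consecutive
points 22 µm apart on the time axis alone, making ε = 3.3 unreachable and
the partition vacuous.

min_pts = 4 means a pause must persist ≥ 4 frames (80 min) to register as
a dwell state; it is configurable. Post-processing enforces the semantics
"a dwell state is a pause *episode*, not a location": a DBSCAN cluster
whose member points are not temporally contiguous (the cell left and came
back) is split into contiguous episodes. Isolated single moving points
flanked by dwell states are absorbed into the neighboring state with the
nearer centroid; moving tracklets are the remaining maximal runs of ≥ 2
consecutive moving points.

Partition descriptors use point counts for the relative dwell/moving
durations (dwell frames / total frames) and frame spans × frame_interval
for mean durations. Tracklets with fewer than 3 points contribute no
directional-change value.

## RDP segmentation

Classic recursive Ramer–Douglas–Peucker on the (x, y) polyline, time
ignored; endpoints always kept; the split criterion is perpendicular
distance to the infinite line through the chord endpoints (distance to the
first endpoint when the chord is degenerate). Two scales are computed,
ε = 0.5 µm (fine, noise-level) and ε = 3 µm (coarse, major directional
changes only). Node count is non-increasing in ε, and every dropped point
lies within ε of its reconstruction segment — both properties are verified
by brute force in the test suite.

## MSD and VAC

MSD is time-averaged per track with overlapping windows, lags from one
frame interval up to min(max_lag, duration − Δt); default max_lag = 24 h.
Cluster curves are unweighted means across tracks at each lag, dropping
lags with fewer than 3 contributing tracks — so long tracks do not
dominate the population curve. The log-log slope utility fits ordinary
least squares on log(MSD) vs log(τ) (≈ 2 ballistic, ≈ 1 diffusive).

VAC uses step velocities between consecutive frames and is normalized
**per track** by that track's mean squared speed, guaranteeing VAC(0) = 1
(decay-from-1 presentation). Ensemble normalization was the alternative;
per-track normalization was chosen so that slow and fast tracks contribute
comparable persistence information to a cluster mean.

## Mode clustering

Fitted on the control group only: z-score (zero-variance descriptors are
dropped with a warning — e.g. `duration` in a cohort of equal-length
tracks), PCA with the smallest component count reaching ≥ 95% cumulative
explained variance, K-means (Lloyd, squared Euclidean, tol 1e-6, default
k = 10 with 20 random restarts keeping the lowest inertia). All tracks are
then normalized with the *control* parameters, projected, and assigned to
the nearest center (ties → lowest cluster id). This anchoring makes
treatment compositions directly comparable to the control distribution. A
`cluster_all_groups` switch fits on every track instead, as a sanity-check
variant; on a no-effect cohort both variants agree within sampling error
(verified in the acceptance suite).

Clusters are relabeled by descending mean `speed_mean` of their control
members, and `default_mode_map(k)` splits the reordered ids into three
contiguous blocks — Directed / Exploratory / Confined; at k = 10 this is
0–3 / 4–6 / 7–9. The block boundaries are a convention, not an inference:
the biological grouping of clusters into modes is inherently a manual
judgment, so the map is an editable configuration, serialized with the
model. Mode composition shifts are reported as proportions and fold
changes without hypothesis tests, since they are computed on the full data
with no replicate structure.

The descriptor dendrogram groups descriptors (not tracks) by Ward linkage
on the transposed z-scored matrix, cut into exactly L = 9 flat groups.

k is a parameter: the elbow scan reports best-of-restarts inertia per k
and deliberately performs no automatic selection.

## Screening statistics

Per descriptor: Kruskal–Wallis (tie-corrected H, chi-square p) across all
groups, then two-sided Mann–Whitney U of each treatment vs control. The
exact U null distribution is used when both samples have ≤ 20 observations
and no ties (the exact distribution is invalid under ties); otherwise the
normal approximation with tie and continuity correction. Bonferroni
correction multiplies by the number of treatment comparisons per
descriptor (per-panel family); a global family is a configuration choice.
Stars: 0.05 / 0.01 / 0.001.

Effects are log2(treatment median / control median) — the median is the
default central value because speed and pause-duration distributions are
right-skewed; the mean is available by configuration. Entries are masked
(not fabricated) when a center is non-positive or the descriptor is
angular (`velocity_avg_angle`, `gyration_orientation`), and flagged
non-significant when the corrected p ≥ α.

## Synthetic data

The generator's defaults describe a slow saltatory migrator sampled at
20 min/frame: run speed 0.5 µm/min, random-walk step scale 2 µm/frame,
positional jitter 0.3 µm (segmentation noise), geometric run/dwell
lengths with means 8 and 6 frames, confinement tether 5 µm, 150 frames
(50 h). Where no value was externally prescribed these were chosen once as
field-realistic magnitudes for neuronal migration in tissue and are not
revisited. Models:

- *ballistic*: constant velocity plus isotropic Gaussian jitter;
- *random_walk*: iid Gaussian steps (per-axis sd `step_sd`);
- *persistent_walk*: AR(1) step process with weight `persistence`,
  innovation variance scaled so the stationary step sd equals `step_sd`;
- *saltatory*: alternating ballistic runs and jitter-about-a-point dwells
  with geometric segment lengths (memoryless switching — the simplest
  two-state description of movement separated by pausing). The starting
  state is drawn from the stationary distribution so the expected dwell
  fraction is `dwell_mean / (run_mean + dwell_mean)` at any track length.
  `segment_min_frames` imposes a floor on segment length (shifted
  geometric, mean preserved) for experiments that require detectable
  pauses (≥ min_pts frames);
- *confined*: AR(1) positions with stationary sd `tether_sd` (mean
  reversion toward the origin);
- *stationary*: pure positional jitter.

One global seed spawns per-track child seeds via `SeedSequence`, so
cohorts are reproducible independent of generation order.

What the generator does **not** emulate: morphology (leading process,
branching), track fragmentation and identity switches from tracking
errors, spatially varying guidance cues, cell–cell interactions, and
drift. A green synthetic test therefore establishes correctness of the
computation and sensible behavior on the stated motion models — not
robustness to every artifact of real tracking data.

## Numerical choices

- Angles from `arccos` of clipped cosines (guards rounding outside
  [−1, 1]); eigen-decompositions via symmetric solvers with negative
  eigenvalues clipped at 0.
- Feature-table round-trips are exact to 1e-9 relative tolerance (CSV with
  full precision; units in a sidecar comment line).
- K-means determinism: fixed `random_state` seeds the restarts; the same
  seed yields bit-identical centers.
- Filters are idempotent and the non-moving filter is monotone in its
  thresholds; retention requires passing **both** thresholds by default
  (the conservative reading), with an `either` switch.

## Known limitations

- 2D tracks only; no 3D support, no image I/O, no tracking.
- Descriptor names reconstruct the attested feature classes; name-for-name
  parity with any external descriptor catalogue is not guaranteed.
- The MSD/VAC module assumes gapless tracks for VAC (step velocities are
  undefined across gaps); MSD tolerates gaps by pair omission.
- Mode boundaries (`default_mode_map`) are a labeling convention; k and
  the map should be reviewed against an elbow scan and cluster summaries
  for any new dataset.
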