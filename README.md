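# trackmigrate

Quantitative analysis of saltatory cell-migration tracks from time-lapse
imaging. Migrating neurons — cortical interneurons in particular — do not
glide smoothly: they alternate nucleokinesis jumps with pauses. A treatment
screen therefore needs more than a mean speed per cell; it needs descriptors
that separate *how fast* a cell moves from *how often it pauses* and *how
straight it travels*, and a way to classify whole tracks into migration modes.

`trackmigrate` takes 2D centroid tracks (µm, fixed frame interval, default
20 min) and provides:

- **48 per-track descriptors** grouped in feature classes: path length and
  duration, net displacement, pairwise-diameter statistics, instantaneous
  speed statistics, directional-change statistics and threshold counts
  (20°/45°/90°), time-weighted average velocity, gyration-tensor shape
  descriptors, confinement ratio, mean straight-line speed, dwell/move
  partition statistics, and Ramer–Douglas–Peucker (RDP) segment statistics
  at ε = 0.5 and 3 µm.
- **Dwell/move partitioning** by DBSCAN on the spatiotemporal embedding
  (x, y, frame · t_scale) with defaults t_scale = 1.1, ε = 3.3 µm,
  min_pts = 4: dense clumps are pause episodes ("dwell states"), the rest
  are moving tracklets.
- **Artifact filters**: minimum track length (12 frames = 240 min) and a
  non-moving filter (track diameter < 15 µm or gyration-tensor major axis
  < 5 µm).
- **Population dynamics**: time-averaged mean-squared displacement,
  MSD(τ) = ⟨|r(t+τ) − r(t)|²⟩_t, and the normalized velocity
  autocorrelation VAC(τ) = ⟨v(t)·v(t+τ)⟩ / ⟨|v|²⟩, aggregated per cluster.
- **Control-anchored mode clustering**: z-score → PCA (components chosen to
  reach ≥ 95% explained variance) → K-means (k = 10, 20 restarts), all
  fitted on the control group only; every track is then assigned to the
  nearest center, clusters are reordered by mean speed and grouped into
  three migration modes — **Directed**, **Exploratory**, **Confined** —
  whose per-treatment composition and fold change vs control are reported.
- **Screening statistics**: per descriptor, Kruskal–Wallis across groups,
  then two-sided Mann–Whitney U of each treatment vs control with
  Bonferroni correction; effects as log2 ratios of group medians over the
  control median, masked where non-significant.
- **A synthetic track simulator** (ballistic, random walk, persistent walk,
  saltatory run/dwell, confined, stationary) with per-track ground truth,
  so every stage is testable without real data.

## Worked example

```python
from trackmigrate.simulate import MotionConfig, CohortConfig, gen_cohort
from trackmigrate.pipeline import PipelineConfig, run_pipeline

cohort = CohortConfig(
    groups={
        "control": [
            (MotionConfig(model="ballistic", speed=0.3, n_frames=100), 60),
            (MotionConfig(model="saltatory", speed=0.4, n_frames=100), 60),
            (MotionConfig(model="confined", tether_sd=4.0, step_sd=1.5, n_frames=100), 60),
        ],
        "blocker": [
            (MotionConfig(model="confined", tether_sd=4.0, step_sd=1.5, n_frames=100), 90),
        ],
    },
    seed=42,
)
tracks, truth = gen_cohort(cohort)
result = run_pipeline(tracks, PipelineConfig(k=3, seed=42))
print(result.composition.proportions.round(3))
print(result.composition.fold_change.round(2))
```

prints

```
mode     Directed  Exploratory  Confined
group
control     0.357        0.357     0.286
blocker     0.000        0.000     1.000

mode     Directed  Exploratory  Confined
group
control       1.0          1.0       1.0
blocker       0.0          0.0       3.5
```

The control cohort mixes three planted motion modes in roughly equal
proportions (a few confined tracks fall below the non-moving thresholds and
are filtered, hence 0.286). The "blocker" treatment, simulated as purely
confined motion, lands entirely in the Confined mode — a 3.5-fold
enrichment over control. The accompanying statistics table flags the
descriptors driving the shift, e.g.

```
            feature   group  effect_log2  p_bonferroni
       dc_prop_gt45 blocker       1.0566           0.0
dwell_diameter_mean blocker       2.2285           0.0
   rdp05_node_count blocker       1.1155           0.0
```

(confined cells turn more per unit path and their paths simplify into many
short RDP segments).

## Command line

Every stage is also a subcommand of `trackmigrate`:

```sh
trackmigrate simulate --out tracks.csv --truth-out truth.csv --seed 5
trackmigrate features --tracks tracks.csv --out features.csv
trackmigrate filter   --tracks tracks.csv --features features.csv --out moving.csv
trackmigrate partition --tracks tracks.csv --labels-out states.csv
trackmigrate msd --tracks tracks.csv --out msd.csv
trackmigrate cluster fit --features features.csv -k 10 --out model.json
trackmigrate cluster assign --features features.csv --model model.json --out assign.csv
trackmigrate stats --features features.csv --out stats.csv
trackmigrate pipeline --tracks tracks.csv --out outdir/
```

Input tracks can be a generic long-format CSV (`track_id, frame, x_um,
y_um`) or an Imaris "Position" statistics export (`--dialect imaris`).

## Acceptance script

`scripts/acceptance.py` generates a three-group synthetic screen (control
plus a sedating and an activating treatment), runs the complete pipeline —
filters, 48-descriptor feature table, control-anchored clustering, mode
composition, group statistics, MSD/VAC curves — and writes a JSON report:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All randomness (simulation and K-means restarts) derives from `--seed`.
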