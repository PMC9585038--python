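# Methods

This note documents the analysis conventions, parameter choices and
known limitations of `dglat`. Units are given for every parameter;
defaults live in the code next to the functions they govern.

## Experimental model

Sessions emulate head-fixed two-photon imaging of dentate granule cells
on a 4 m virtual linear track, imaged at **15.5 Hz**. Two visually
distinct contexts (familiar = 0, novel = 1) alternate as interleaved
traversals ("runs"); after each run the animal teleports back to the
start. The track is discretized into **80 bins × 5 cm**. Each context
has a reward zone (5 bins around its reward center) used only by the
behavioral lick-ratio control.

## Synthetic data (`dglat.simulate`)

The simulator is the package's data source and ground-truth oracle; its
defaults define the study conditions used throughout the tests.

**Behavior** — per-run speed follows an Ornstein–Uhlenbeck process
around 20 cm/s (σ = 6 cm/s, τ = 2 s), floored at 0; rest bouts (mean
2 s, ~10% of time, position stationary) are inserted between runs;
licking is Poisson at 4 Hz inside the current context's reward zone and
0.5 Hz elsewhere.

**Cells** — a cell is *active* with probability `frac_active`; an
active cell is a *place cell* with probability `frac_place_of_active`.
Place cells have one Gaussian field (center uniform on the track, width
~6–10 bins FWHM) and emit in-field Poisson events at
`infield_event_rate_hz` with per-run center jitter `run_jitter_bins`;
out-of-field and non-place rates are 0.02 and 0.08 Hz. With probability
`frac_global_remap` a place cell's novel-context field is redrawn
independently of its familiar field (global remapping); otherwise it is
preserved (generalization). Across days, fields drift with probability
`day_drift_prob` per day while cell identity persists. Events are
convolved with a GCaMP6s-like double-exponential kernel (rise 0.18 s,
decay 0.55 s), scaled, and added to a baseline with Gaussian photon
noise; a small fraction of cells receive slow multiplicative baseline
drift.

**Hemisphere presets** — `left_like` (frac_active 0.25,
frac_place_of_active 0.55, in-field 0.70 Hz, jitter 0.8 bins,
frac_global_remap 0.65) and `right_like` (0.15, 0.40, 0.55 Hz, 1.8
bins, 0.30). These encode the qualitative contrast the pipeline must
recover: the denser, sharper, more strongly remapping population has
higher spatial information, higher reliability, lower cross-context map
correlation and a larger low-correlation fraction.

The event rates, kernel constants, jitter values and cohort sizes are
package choices selected to put every analysis in a sensitive but
non-trivial regime on a single CPU; they are not measurements.

## Preprocessing (`dglat.preprocess`)

- **ΔF/F**: F₀ is a rolling 8th percentile in a 20 s window (numba
  sliding-sorted-buffer); ΔF/F = (F − F₀)/F₀.
- **Noise σ**: standard deviation of ΔF/F after one-sided clipping at
  2.3 σ (iterated), so transients do not inflate the estimate.
- **Significant transients**: a grid search over onset thresholds
  σ ∈ {2.0, 2.5, 3.0, 3.5, 4.0} × minimum durations {2, …, 12} frames
  (offset at 0.5 σ) counts positive-going and negative-going events per
  cell; the **false-positive proxy** is the negative/positive event
  ratio, and a (σ, duration) pair is admissible when it is **< 5%**.
  The *least stringent* admissible pair is accepted; cells with no
  admissible pair are **flagged** and excluded downstream. The masked
  trace keeps ΔF/F inside significant transients and is 0 elsewhere.
- **Active cells**: > 1 transient per minute of running time, and not
  flagged. Running frames require speed ≥ 2 cm/s and a finite position.

`TransientExtractor` is a scikit-learn transformer: `fit(X)` with X of
shape (n_frames, n_cells) populates `fpr_`, `flagged_`,
`transient_count_` and per-cell `traces_`; `transform` returns the
masked ΔF/F.

## Spatial tuning (`dglat.spatial`)

- **Maps**: per-bin mean masked ΔF/F over running frames of one
  context, with occupancy p_i; smoothing is a 3-point boxcar whose edge
  bins average the 2 available neighbors (NaN bins are excluded from
  each window).
- **Spatial information**: Skaggs SI = Σᵢ pᵢ λᵢ log₂(λᵢ/λ̄) bits·s⁻¹,
  with 0·log 0 = 0.
- **Shuffle test**: the null displaces activity relative to position by
  a circular shift of ≥ 10 s drawn uniformly **on the full session
  timeline**, re-masking to running frames afterwards. Shifting the
  compressed running-frames sequence instead is anticonservative
  (type-I ≈ 13–16% instead of 5%): transient clumps that straddle the
  run-boundary seams of the compressed sequence get split, flattening
  shuffled maps and deflating the null. SI ≤ 0 is assigned p = 1. A
  `style="permute"` fallback permutes included frames.
- **Place fields**: on the smoothed map, candidate spans are contiguous
  bins above baseline + 25% of (peak − baseline), with baseline = mean
  of the 20 lowest bins. A span is accepted as a field when (1) width
  ≥ 3 bins, (2) in-field mean ≥ 7× out-field mean (out-field excludes
  all candidate spans), (3) presence ≥ 0.2 (fraction of in-field
  running frames carrying significant transients). Multiple fields per
  cell are allowed.
- **Bootstrap**: the masked trace and transient mask are cut into
  50-frame segments, segment-shuffled, and the full detector re-run;
  P = fraction of shuffles yielding any field, accepted when P < 0.05.
  At sparse expression this gate is *conservative*: borderline
  shuffled maps occasionally satisfy all criteria, so genuinely tuned
  but weakly expressed cells can receive P ≈ 0.05–0.12. Densely
  sampled fields (transients on most traversals) get P ≈ 0.

## Context and stability metrics (`dglat.metrics`)

- **Reliability**: mean pairwise Pearson r of per-run maps (degenerate
  runs excluded pairwise). **Session consistency**: r between the mean
  maps of the first and last 5-run blocks.
- **Remapping classes** from the cross-context map correlation r of
  smoothed maps: r ≤ 0.1 low (global remapping), r ≥ 0.6 high
  (generalization), else medium.
- **Chance-corrected remapping fraction**: the naive low-r fraction
  *understates* the true globally-remapping fraction because an
  independently relocated field lands near its old position by chance
  in ~20–25% of cells. `remap_fraction_estimate` calibrates this
  leakage from the data by pairing each cell's familiar map with novel
  maps of other cells (realizing the independent null) and reports
  f̂ = P(low | observed) / P(low | null), clipped to 1. Valid in the
  regime where stable well-expressed maps essentially never fall below
  the threshold (cells with detected fields in both contexts); recovery
  error is ≲ 0.06 at 600 cells (acceptance test 6).
- **Cross-day matrices**: median over day-d place cells of
  corr(map_d, map_e), per context.
- **Behavioral controls**: occupancy-normalized in-zone/out-zone lick
  rate ratio; mean running speed over running frames.

## Decoding (`dglat.decoding`)

Population-vector decoding with run-wise cross-validation: runs of each
context are split by parity into template and test halves. Templates
are per-cell mean masked ΔF/F in each of the 160 (context × bin)
states; test activity is averaged in 100 ms bins and assigned to the
state whose template has the highest Pearson correlation (ties and
degenerate bins count as errors). Reported errors: context error
(fraction of misclassified bins; chance 0.5) and median absolute
position error in cm. `error_vs_ensemble_size` subsamples cells;
`cumulative_context_accuracy` accumulates evidence by majority vote
over k consecutive bins, which for i.i.d. per-bin error p follows the
binomial closed form P(Binom(k, p) < k/2) (acceptance test 5), and
reports the time to reach 90% accuracy. Decoding quality depends
strongly on expression density: sparse presets at 0.7 Hz in-field rates
sit near chance, while dense populations reach context error < 0.1 and
spatial error ~15 cm (README example).

## Pipeline and I/O (`dglat.io`, `dglat.pipeline`, `dglat.cli`)

Sessions round-trip exactly through an HDF5 schema (fluorescence,
behavior streams, track geometry, optional ground truth);
`validate_session` checks shapes, finiteness, stream alignment and
value ranges. `run_pipeline` executes simulate → preprocess → spatial +
context analysis → decode → report for each profile/day, caching each
stage on disk and keyed by a config hash. Determinism is exact: all
randomness derives from the config seed, CSVs are written with
`%.17g` floats and read back with round-trip parsing, so repeated runs
produce byte-identical artifacts (acceptance test 7). The `dglat` CLI
exposes each stage plus `report`.

## Limitations

- The simulator idealizes behavior (no position-dependent speed
  modulation beyond rest bouts, no systematic lick anticipation) and
  optics (Gaussian noise, limited drift, no neuropil contamination or
  motion artifacts); absolute metric values will differ on real data.
- The negative/positive event ratio is a proxy for the transient
  false-positive rate; it assumes noise symmetry around baseline.
- The field bootstrap is conservative at sparse expression (see above),
  trading sensitivity for a strict bound on spurious fields.
- The smoothing edge convention (average of available neighbors) makes
  edge bins slightly less smoothed than interior bins.
- The remapping-fraction correction assumes stable maps never classify
  as low-r; with very noisy maps it becomes an upper-bound estimate.
- Problem sizes in tests (cells, days, shuffle counts) are scaled to a
  single-CPU budget; production analyses should raise shuffle and
  bootstrap counts to ≥ 1000.
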