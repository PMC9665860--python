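# Methods

## Data model and input dialect

One tab-delimited UTF-8 file per antibody slide, header row with columns
`Order, Main.Row, Main.Col, Sub.Row, Sub.Col, Series.Id, Spot.Type,
Dilution, Net.Value, Raw.Value, Background.Value`. Grid coordinates are
1-based; `Dilution` holds the declared relative concentration of the step
(1, 0.5, 0.25, …), so step 1 is undiluted; intensities are in scanner
fluorescence units, and `Net = Raw − Background` whenever all three are
present. Spot types are `Sample`, `PosCtrl`, `NegCtrl`, `Buffer`, `Blank`
and `NoiseRep` (technical-replicate series). The antibody name is the file
basename. This dialect follows the SuperCurve-lineage layout; it is fixed
here so outputs are byte-reproducible.

Row-level anomalies (negative intensities, unparseable numerics) are
retained and warned about; slide-level problems (missing columns, duplicate
coordinates, undecodable bytes) fail only that slide. Negative net
intensities stay in the fit — censoring them would bias the baseline.

### Design inference

The slide design is inferred from the first file, in lexicographic order,
that parses cleanly: grid dimensions are the observed coordinate maxima,
the step count D is the maximum dilution step among Sample spots, and the
dilution factor f is the common ratio of consecutive declared
concentrations (all consecutive ratios must agree to a relative 1e-6,
otherwise the ladder is rejected as inconsistent). Slides with a single
dilution step are rejected: the joint-curve method needs serial dilutions
and does not apply to one-dot arrays. Every subsequent slide is validated
position-by-position against the design — coordinates, spot types, series
placement and ladder — and any discrepancy fails that slide. Whether
per-slide ladders should ever be allowed to differ is deliberately answered
"no" here: a batch shares one design.

## Joint response-curve fit

Model: `y_ij = α + β/(1 + exp(−γ(x_i + d_j))) + ε`, midpoint pinned at
x = 0 (see README). The three-parameter logistic is the lineage's standard
choice; spline or loess response shapes are out of scope. Least squares is
unweighted.

Fitting alternates two sub-problems until the RSS stops improving:

1. curve step — nonlinear least squares over (α, β, γ) with all x fixed
   (trust-region reflective, analytic Jacobian);
2. position step — each x_i minimized on [−15, 15] by golden-section
   search, vectorised over all series (bracket shrunk below 1e-10).

Iteration stops when the RSS improvement falls below `rss_tolerance`
(default 1e-8, relative) or after `max_iterations` (default 100). Because
a noise-free slide drives the RSS to zero and a purely relative criterion
then never triggers, an absolute floor of `n_spots · (1e-8 · intensity
scale)²` also counts as converged.

Alternating descent is robust but linearly convergent and can stall on its
zigzag path short of the optimum, so by default the alternating solution
seeds one joint Gauss-Newton solve over (α, β, γ, x_1…x_n) with an
analytic Jacobian (`joint_refinement` option). The polish is kept only if
it does not increase the RSS. The test suite checks the final RSS against
an independent simultaneous optimizer (Levenberg-Marquardt with numeric
derivatives) to 1e-6 relative.

Initialization is deterministic and scale-aware: α₀ and α₀+β₀ at the 5th
and 95th intensity percentiles, γ₀ = 1, and x_i⁰ from the inverse logistic
of each series' clamped mean intensity.

β is bounded above by `beta_max_factor` (default 4) times the 5th–95th
percentile intensity spread. An upper asymptote far beyond the observed
intensities is not identifiable, and with an uncapped β a single strong
multiplicative outlier series can stretch the curve until every regular
series sits on its scale-free exponential bottom, hiding the outlier from
the residual diagnostics that the exclusion workflow depends on.

Series participating in the fit: `Sample`, `PosCtrl` and `NoiseRep` (the
replicates are real dilution series of one sample and inform the curve);
`NegCtrl`, `Buffer` and `Blank` series carry no dose-response and are
positioned post hoc only. The set is configurable. At least `min_series`
(default 8) fitting series are required — the four curve/identifiability
degrees of freedom need support. A slide whose intensity range is below
`min_intensity_range` fails with "no signal".

### Concentration estimates, errors and flags

Each series gets a relative log2 concentration x̂, a standard error from
the curvature of its residual profile (RSS_i(x) ≈ const + h/2·(x−x̂)², so
Var(x̂) ≈ 2σ̂²/h with σ̂² the residual variance over the slide's remaining
degrees of freedom), per-step residuals, and flags. A series whose spots
all lie above `α + 0.99β` is `Saturated`; all below `α + 0.01β` is
`BelowDetection` — in both cases the position is clamped to the x bounds
and the SE is undefined, because the inverse logistic blows up at the
asymptotes. `PoorFit` marks non-convergence or a max residual above half
the dynamic range. The clamp fractions are configurable.

### Exclusion workflow

Series named in `excluded_series` are excluded from curve construction on
every slide of the batch, then normalized post hoc against the frozen
curve (`in_fit = False`). Estimates of the remaining series match a run
where the excluded series is absent from the input entirely (verified to
1e-6). `fit_diagnostics` ranks series by max |residual|/β and lists those
above a threshold (default 0.1) as exclusion candidates for the next run;
choosing which to exclude is the operator's judgment.

## Spatial adjustment (optional, off by default)

Controls are the technical-replicate spots at one common dilution step —
by default the most concentrated step present, whose intensities have the
highest log-scale signal-to-noise. (Pooling the diluted steps lets i.i.d.
intensity noise leak into the surface: at 1% of β noise, the diluted
steps' log2 deviations are several times larger, and the smoothed surface
then violated the flat-slide guard below.) Each control's deviation is
`log2(observed) − log2(10%-trimmed mean of its group)`; deviations are
smoothed over the flattened physical grid (main×sub row/column index —
scanner X/Y positions are ignored as dialect-dependent) by local linear
regression with tricube weights at span 0.75, evaluated at every grid
node. The smoothed log surface is exponentiated, clamped to [0.25, 4] and
median-centered to 1, so correction redistributes intensity without
changing the slide's level; a uniform global bias is by construction not
"spatial" and is removed by nothing. Every spot's net intensity is divided
by the surface at its position (multiplicative on intensity — equivalently
additive on the log scale; the multiplicative convention is recorded in
the slide provenance). Fewer than `min_controls` (default 10) usable
controls yields an identity surface with a warning; controls covering less
than a quarter of the grid area attach an extrapolation warning.

Guard: on slides with i.i.d. noise and no spatial signal, the median
|log2 m| stays below 0.1 at the default span (checked on seeded slides).
Spatial adjustment runs before curve fitting when enabled.

## Noise metric

The noise metric is the sample standard deviation (n−1 denominator) of the
technical replicates' estimated log2 concentrations; the replicate mean is
reported alongside. The metric is computed on concentrations, not raw
intensities, so it is in the same units as the sample output and
comparable across slides and antibodies — the replicates express the
protein of interest and ride the same curve as the samples. Replicates
flagged `Saturated`/`BelowDetection` are dropped with a warning (their
position is meaningless); with fewer than two usable replicates the SD is
reported as NA. A batch-level descriptive check reports the Pearson
correlation between noise and replicate mean expression across slides —
no thresholding, since judging a slide "too noisy" against prior data is a
human decision. Near the curve's asymptotes the intensity-to-concentration
mapping steepens, so replicates printed at extreme levels show more
concentration spread than mid-range ones; printing the replicate lysate at
a mid-range level keeps the metric comparable.

## Loading normalization

Per-sample loading differences appear as additive row offsets on the log2
matrix. Three registered methods (the registry is extensible and
deliberately smaller than the full lineage catalog):

- `none` — bit-identical pass-through, for users who correct downstream;
- `median_centering` — subtract each sample's cross-antibody median,
  restore the grand median; idempotent, NA-aware;
- `median_polish_loading` — Tukey two-way median polish; only the fitted
  row (sample) effects are removed, antibody effects remain. Removal is
  iterated to a fixed point (outer tolerance 1e-10): a single polish pass
  leaves O(noise) residual row effects through median/interaction
  coupling, and the fixed-point iteration makes the operation idempotent
  to 1e-9 as well as fully removing row structure.

Both raw and normalized matrices are always written. The matrix holds
Sample series only; control series live in the per-slide tables. Loading
correction presumes per-sample loading variation dominates the per-sample
median of biological variation — with very few antibodies, medians across
antibodies are dominated by real biology and centering can hurt, which the
examples demonstrate at 6+ antibodies.

## Batch pipeline

Fixed stage order: read → validate → [spatial] → curve_fit → noise →
assemble matrix → [loading] → write. Spatial (off by default) and loading
(on, `median_centering`) are optional; curve fitting and the noise metric
are core (noise can be disabled in config but defaults on). Per-slide
stages run across `workers` processes (joblib); slides are independent and
results are returned in input order, so all numeric outputs are
bit-identical for any worker count. Per-antibody (= per-slide) is the
parallelism grain — stages within a slide are sequential.

Any per-slide failure is caught, recorded as `(slide, stage, message)` and
the batch continues; the run is fatal only when no file at all yields a
valid design. `errors.txt` and `warnings.txt` carry one timestamped line
per event (timestamp, slide, stage, message) and exist even when empty.
The timestamps are the one non-reproducible output field; every numeric
table is byte-identical across re-runs and worker counts. If the
configured loading method is inapplicable (e.g. one antibody), the matrix
passes through unnormalized with a warning rather than failing the batch.

Optional per-slide figures (`--plots`) are off by default; they are
diagnostics, not outputs.

## Synthetic slides

The generator emulates a production-style slide: default 4×12 main grid of
4×4 sub-grids (768 spots), 96 sample series with true x uniform on [−4, 4],
dilution factor 2 over 4 steps, curve α = 200, β = 40000, γ = 0.8 (a
typical 16-bit-scanner dynamic range), 24 technical-replicate series
sharing one true level (default 0, optionally jittered per series to
emulate deposition variability), remaining slots filled with baseline-only
buffer series. Replicates are spread on an even stride across the grid.
Noise is additive Gaussian on intensity (matching the unweighted
least-squares assumption; an intensity-proportional option exists), the
optional spatial field is a linear gradient or radial blob of configurable
fold range, outliers are per-series multiplicative factors, and batches
can plant shared per-sample loading offsets. Every slide ships with truth
tables (per-series x, curve, field, per-spot noiseless intensity), and the
same seed reproduces files byte-for-byte.

Not emulated: antibody cross-reactivity, spot morphology/segmentation
artifacts, carry-over between steps, intensity quantization, or correlated
(striped) noise. Passing recovery tests therefore shows the estimators are
correct under the stated model, not that real slides satisfy the model;
the spatial and noise machinery exists precisely because real slides
deviate.

## Problem sizes and numerical choices

The test suite and the acceptance script use full-size slides (96 samples,
768 spots) for recovery properties and a compact 24-sample slide for
orchestration checks, with 5–20 seeded replicates per property — enough
for the chi-square and correlation margins involved. Ties in medians
follow numpy's midpoint convention; golden-section brackets resolve
position ties deterministically; series order never affects results beyond
floating-point summation order (estimates agree to better than 1e-6, and
byte-identity holds for fixed input order). Scaled relative error for
concentrations is measured as |x̂ − x|/max(1, |x|), since x is a log scale
crossing zero.

## Known limitations

- One response-curve shape (3-parameter logistic); no 5PL, spline or loess
  variants, no Bayesian uncertainty.
- Standard errors are curvature-based and ignore uncertainty in the shared
  curve (anti-conservative by roughly the ratio of one series' spots to
  the slide's).
- The loading-method registry is intentionally minimal; total-protein
  stain normalization needs an input channel this dialect does not carry.
- Scanner images are never read; quantitation starts from the spot table.
- The spatial smoother assumes a smooth field; sharp sub-grid block
  artifacts are better handled by excluding the affected series.
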