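# Methods

This note records the model assumptions, parameter choices and numerical
decisions behind `photophen`, at the level of detail a maintainer or a
careful user needs. The README describes the pipeline end to end; here
we concentrate on *why* each piece looks the way it does and what the
synthetic experiments do and do not demonstrate.

## The retrieval model

Photosynthetic phenology is defined on the smoothed daily GPP curve
GPP_S, not on raw observations: the transition dates are the days at
which GPP_S passes fixed fractions (10/25/50 %) of the seasonal
amplitude measured from the dormancy baselines. The approach combines a
smoothing stage (spline interpolation + iterative Savitzky-Golay with
outlier replacement), an exact change-point segmentation (PELT,
Gaussian change-in-mean cost), and a cycle/threshold geometry stage. It
makes three structural assumptions:

- a growing season is a rise from a dormancy baseline to a peak and a
  return to a (possibly different) baseline, all resolvable at the
  14-day segment scale;
- observation noise is short-lived relative to the season, so a
  31-day smoothing window separates signal from noise without erasing
  the flanks;
- baselines are meaningful: GPP in dormancy fluctuates around a level
  rather than trending.

Years violating these (e.g. evergreen-tropical-like seasons with no
dormancy) yield no cycle and are reported missing, by design.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `sg_window_days` / `sg_polyorder` | 31 / 3 | days / – | Savitzky-Golay bandwidth. Window scans (41–61 d, orders 2/4) degrade flank fidelity faster than they suppress noise; 31/3 keeps the noise-free crossing error ≤ 0.6 d. |
| `grubbs_alpha` | 0.05 | – | gate of the outlier-replacement loop (two-sided). |
| `max_iter` | 20 | – | hard cap of the replacement loop. |
| `penalty` | 0.5 | (g C m⁻² d⁻¹)² | PELT per-changepoint penalty, applied to raw SSE in native units. |
| `min_segment_days` | 14 | days | minimum PELT segment. |
| `thresholds` | 0.10/0.25/0.50 | – | amplitude fractions for SOS/EOS. |
| `relative_peak_floor` | 0.25 | – | cycles with peak below this fraction of the year's maximum peak are unreliable and dropped. |
| `min_relative_amplitude` | 0.25 | – | alternations of the segment-mean series shallower than this fraction of its range are noise wiggles, merged before cycle assembly. |
| `gpp_floor` / `latitude_min` | 2.0 / 30.0 | g C m⁻² d⁻¹ / °N | vegetation mask for gridded runs. |
| `bootstrap_n` | 100 | – | Monte-Carlo replicates; 5th/95th percentiles form the envelope. |

With penalty 0.5 in native GPP² units the segmentation is fine (most
segments sit at the 14-day minimum); the method's robustness therefore
comes from the segment *means*, the alternation pruning and the peak
floor, not from a sparse segmentation.

## Numerical decisions

**Spline and edges.** Not-a-knot end conditions; days outside the
observed range are clamped to the nearest observation rather than
extrapolated (cubic extrapolation of winter composites is wild). An
8-day composite is stamped on the first day of its window (DOY 1, 9, …,
361); more than three consecutive missing composites, or fewer than
four usable points, make the pixel-year missing.

**Smoothing loop accounting.** One "iteration" = one smooth + one
Grubbs screen. A clean series therefore terminates at 1 iteration with
no replacements. The Grubbs test is the continue/stop gate; the 1-SD
rule on the ratio vector selects which days are replaced. Days with
smooth values below 10⁻⁶ are excluded from the ratios (winter zeros).
Because the rule works on *ratios*, an in-season spike is damped, not
erased — its relative deviation shrinks quickly below the dormancy
ratio noise.

**PELT exactness under a minimum segment length.** The classic pruning
argument assumes the dominating candidate is immediately admissible,
which fails within `min_segment_days` of the current end. Pruning is
therefore *delayed*: a dominated candidate is only removed once the
dominating one is itself admissible. Property tests compare the
segmentation against an exhaustive optimal-partitioning dynamic program
on hundreds of short series; costs and breakpoints agree exactly. Ties
resolve toward fewer changepoints, then earlier ones.

**Cycle geometry under noise.** Three refinements keep the threshold
geometry stable at realistic noise (all are no-ops on clean curves):

1. *Alternation pruning.* Plateau segments of a smoothed noisy season
   differ by a few tenths of a unit, which would split one season into
   several cycles whose peaks all survive a peak-*value* floor.
   Adjacent extremum pairs with amplitude below
   `min_relative_amplitude` × (range of segment means) are merged away;
   bottoms and peaks are the minimum and maximum *of each cycle*.
2. *Adjacent bottoms.* On the outer flanks the cycle's bottom is the
   dormancy dip nearest the season (among dips within the significance
   floor of the year minimum), not the deepest dip of the year — a
   February minimum says nothing about the May baseline.
3. *Plateau-mean baselines.* A minimum-mean segment understates the
   baseline precisely because it was selected as the minimum. Baseline
   values are length-weighted means over the contiguous dormancy
   plateau, where a neighbouring segment joins the plateau while its
   mean stays within 0.15 × (segment-mean range) of the running mean.
   0.15 is the largest band that can never absorb a true flank segment
   (flank segments step by ≥ ~0.2 of the range per minimum segment);
   at 0.20 the clean-curve crossing bias jumps from 0.6 to 1.7 days.

**Peak-anchored crossings.** SOS is the *last* upward crossing of the
threshold level before the peak; EOS the *first* downward crossing
after it. Scanning outward from the peak makes the dates immune to
dormancy noise bumps, which at the 10 % level would otherwise be
mistaken for the transition weeks early or late (first-crossing
scanning from the bottom raised the 10 % RMSE from ~3 to ~19 days in
our experiments). A bump *inside* the season sits far above every
level, so it cannot truncate the season either. Crossings are linearly
interpolated between days; `LOS = EOS − SOS` holds exactly by
construction, as does threshold monotonicity.

**Bootstrap.** The published procedure prescribes 100 uniform
resamplings per pixel-year without fixing the resampled quantity; we
resample composite-level residuals about the smooth (with replacement)
and re-run the full pipeline, because this perturbs the input without a
parametric noise model. Raw residuals understate the noise: the fitted
smooth at the observations is a linear map S of them, so residuals are
deflated by sqrt(diag((I−S)(I−S)ᵀ)) ≈ 0.56 on average for the
8-day/31-day defaults. Residuals are rescaled by this exact
per-observation factor before resampling; without the correction the
envelopes are systematically narrow (72 % instead of ~92 % coverage of
a 5–95 envelope in our simulations). Replicate seasons are matched to
the point estimate by nearest peak day (±60 d); replicates whose
pipeline fails are dropped, and fewer than 50 successes make the
envelope missing. Percentiles use the linear-interpolation convention.
A `case` scheme (resampling composites themselves) is available as a
sensitivity check.

**Grid runs.** Pixels are processed independently with per-pixel seed
`base_seed XOR linear index`, so output is reproducible and independent
of evaluation order. Failures land in a QA layer (0 ok, 1 masked, 2
insufficient data, 3 no cycle) and never abort the run. Output NetCDF
is classic format via xarray's scipy backend, coordinates are 0.05°
cell centres stored ascending, fill value NaN; files follow
`<year>_<METRIC>.nc` (second growing season in `..._season2.nc`) with
variables `<METRIC>_<thr>`, `<METRIC>_<thr>_low`, `<METRIC>_<thr>_up`.

## The synthetic generator

`photophen.synthetic` emulates a GPP pixel as a baseline plus
double-logistic pulses, GPP(t) = B + Σ A·[σ(k₁(t−s₁)) − σ(k₂(t−s₂))],
sampled at the 8-day cadence with additive Gaussian noise and optional
spike outliers. Defaults: a boreal-forest-like single season (B = 0.5,
A = 8 g C m⁻² day⁻¹, inflections DOY 130/260, k = 0.15 day⁻¹, noise
SD 0.5) and a double-cropping variant with pulses centred near DOY 120
and 260. Truth transition dates come from Brent root-finding on the
noise-free continuous curve, so they are exact and cadence-independent.
Grid scenarios cover uniform single seasons, mixed single/double
checkerboards, low-GPP masked patches (record maximum pinned below the
vegetation floor so the drop set is known by construction), and a
season that shifts by a fixed number of days per year for trend tests.

What passing these tests shows: the algorithm recovers known transition
dates to ~1.5–3 days RMSE at the prescribed noise, counts seasons
correctly, and quantifies its own uncertainty with near-nominal
coverage — *under iid Gaussian composite noise on smooth logistic
seasons*. What it does not show: performance under real-data pathologies
the generator omits — temporally correlated (weather-driven) noise,
snow/cloud contamination with seasonal structure, mixed pixels,
baseline drift, or product-specific retrieval artifacts. The validation
module exists precisely to compare against independent (e.g. flux
tower) phenology when such data are available.

## Problem sizes

The test-suite and acceptance-script ensembles use 100-seed ensembles
per condition, 200 truth seeds for envelope coverage, 100 bootstrap
replicates per series, 10×10×2-year cubes for I/O checks and ≤ 60-point
series for the exhaustive changepoint oracle — sizes chosen so the
statistics are stable (RMSE estimates to ~±0.2 d, coverage to ~±3
points) while a full run stays in the minutes range on one CPU.

## Known limitations

- Years are processed independently; cycles truncated at the calendar
  boundary use the year-edge segment as their bottom, which biases
  dates for seasons straddling New Year (high-latitude Southern
  Hemisphere). An optional ±60-day padding hook exists in the design
  but is off by default.
- The 10 % threshold is intrinsically the noisiest: its level sits
  ~1.6 noise SD above dormancy, and its recovery RMSE (~2.5–3.3 days
  across seed ensembles at noise SD 0.5) is about twice that of the
  25 %/50 % thresholds. Shelf-like noise features merging into a flank
  can still displace a 10 % date by one to two weeks in a few percent
  of years.
- The leverage correction of the bootstrap treats the smoothing chain
  as linear, ignoring the outlier-replacement nonlinearity; coverage is
  nominal in simulation but the correction is first-order.
- The Grubbs gate is applied once per iteration to the full ratio
  vector; its α is a screening level, not a per-day error rate.
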