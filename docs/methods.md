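# Methods

## Scope and model

`htstox` computes hazard scores for a library of test agents from
plate-based HTS data.  The unit of observation is the well: one measured
value with full experimental coordinates (plate, well position, endpoint,
exposure time, biological replicate, cell line, serum condition, material,
dose, role).  Five endpoints are supported out of the box — CTG (ATP
luminescence), DAPI (cell count), Caspase-3, γH2AX and 8OHG imaging
intensities — but nothing in the pipeline is specific to five; endpoints
are data-driven.

The score is deliberately model-free on the dose–response side: no
Hill/4PL fitting and no benchmark-dose modelling.  Three summary metrics
are taken per (material × endpoint × time × cell line × serum) series and
combined in a ToxPi-style weighted index.  This trades statistical
efficiency for robustness and transparency: every slice of the final pie
traces back to one endpoint/time condition.

## Normalization chain

Order of operations per endpoint (defaults; each step is an independent
function and the recipe is reconfigurable):

1. **DAPI technical duplicates** are averaged (the imaging station reads
   DAPI twice per well).
2. **Zero-DAPI rule**: an averaged DAPI of exactly 0 means either real
   cell death or a failed image focus.  The biological replicates at the
   same (material, dose, time, cell line, serum) decide: central value
   (default median, configurable to mean) ≤ 50 counts → real death, DAPI
   stays 0 and the associated imaging endpoints of the same well are set
   to 0; > 50 → focus failure, everything becomes NaN.  The threshold of
   50 counts and the median statistic are defaults, both configurable.
   The rule never touches a nonzero DAPI value.
3. **0-h baseline** (endpoints with 0-h plates, i.e. CTG): the median of
   the replicate 0-h values per well position is subtracted.  This
   removes seeding signal and material-induced assay interference
   (luminescence quenching/enhancement).  A ratio mode (divide by the 0-h
   median) is available as an option, subtraction is the default.  The
   0-h plates are dropped afterwards: being pre-exposure measurements
   they carry no dose–response information, and their baseline-corrected
   control values are identically ~0, which would make percent-of-control
   degenerate.  Baseline precedes percent-of-control (the order is
   configurable in the low-level API).
4. **Percent of control**, per plate: vehicle-control wells are first
   cleaned by the Tukey fence `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]` (linear-
   interpolation quantiles, numpy default / R type 7 — the quantile rule
   must be pinned for reproducibility); the filtered control median
   defines 100%.  Viability-type endpoints (CTG, DAPI) are expressed as
   % inhibition, damage/apoptosis endpoints as % effect, so "larger =
   more toxic" holds uniformly and the first-significant-effect
   threshold (control median + k·SD) is meaningful on every endpoint.
5. **Caspase correction**: caspase signal shrinks as cells die, so the
   normalized caspase value is divided by
   `1 − mean(CTG loss, DAPI loss)/100`.  When the mean loss reaches 100%
   the correction is undefined and the value becomes NaN with a warning.
6. **Replicate aggregation**: median over biological replicates (mean
   optional), NaNs excluded, all-NaN keys stay NaN.

All applied operations and their parameters are appended to the
dataset's provenance log and serialized with it.

## Dose–response metrics

For each series (doses ascending, per-replicate normalized effects):

* **First significant dose** (k = 2 and k = 3): the lowest tested dose
  whose replicate mean exceeds the pooled control median + k·SD *and*
  whose replicates differ from the pooled control values by a two-tailed
  Welch t-test at α = 0.05.  The hypothesis test is deliberately
  swappable; Welch was chosen over Student since plate controls and
  treated replicates have no reason to share variance.  Degenerate
  zero-variance tests (p = NaN) count as not significant.  Controls are
  pooled per (endpoint, time, cell line, serum) across replicate plates.
* **AUC**: effects below control median + 2·SD are set to 0 — zeroed,
  not dropped, so the dose grid (and hence the attainable area) stays
  comparable across materials — then the trapezoid rule is applied over
  log10(dose).  Dose-0 rows are excluded from the x-axis (controls define
  the threshold, not the curve) and nothing is extrapolated beyond the
  highest tested dose.  With the thresholded effects non-negative, AUC ≥ 0.
* **Max effect**: median over replicates of each replicate's maximum
  effect across doses — the only metric that still ranks materials whose
  responses never clear the 2 SD cutoff.

By construction the 3 SD qualifying set is a subset of the 2 SD one, so
`first_sig_3sd ≥ first_sig_2sd` whenever both exist.

## Tox5 scoring

Per metric column over the material library: transform, then min-max
scale to [0, 1].  Defaults: first-significant doses get `−log10(x) + 6`
(small dose = high toxicity = high value; the +6 offset assumes doses in
µg/ml and any negative output is clipped to 0), AUC and max effect get
`√x` (negative inputs clipped to 0); the Yeo-Johnson transform with
ML-estimated λ is available per column.  Scaling dialect: `(x − min) /
(max − min)` over the library; a constant column scales to all 0; a
missing metric (no significant effect observed) scales to 0, i.e. least
toxic — so low-toxicity materials still receive a score, possibly driven
by max effect alone, with declining resolution as toxicity decreases.

Auto-slicing groups the four metrics of each endpoint × time (×cell line
× serum) into one slice; within a slice first-sig-3SD carries 50% and
the other three metrics (1 − 0.5)/3 ≈ 16.67% each, emphasizing the dose
sensitivity of the response.  Slice weights default to equal; the total
is the slice-weight-weighted mean, hence also in [0, 1] and monotone in
every scaled metric.  Ranking is competition style (ties share the
smaller rank), rank 1 = most toxic.

**Bootstrap CIs.**  The resampling unit is the material row.  Each
resample redraws the library with replacement, recomputes the min-max
bounds per column, rescales *all original* materials under those bounds
(clipped to [0, 1]) and rescores them; 2.5/97.5 percentiles over
resamples bound each slice score, total and rank.  Resampling raw
replicate wells instead is a defensible alternative; library resampling
was chosen because the dominant uncertainty in a min-max-scaled index is
the composition of the library itself, and it is cheap and exactly
reproducible under a seed.  The percentile intervals are widened, when
necessary, to contain the point estimate, so `ci_low ≤ point ≤ ci_high`
is an exact contract rather than a statistical accident.

## Clustering and cluster support

Materials are clustered on their slice-score vectors (agglomerative;
Euclidean/cityblock/cosine/hamming/minkowski × ward/single/complete/
average, Ward restricted to Euclidean).  Defaults are Euclidean + Ward.
k is user-set or chosen by the elbow rule (maximize the second
difference W(k−1) − 2W(k) + W(k+1) of the within-cluster sum of squares)
or mean silhouette; flat/degenerate data fall back to k = 2.  Quality
indices (silhouette, Davies-Bouldin, Calinski-Harabasz) come from
scikit-learn; an index undefined for a partition is reported NaN.

Cluster support follows the multiscale bootstrap: for relative scales
r ∈ {0.5, …, 1.4} (step 0.1, n_boot = 1000 by default — the cited
method's conventional settings), `round(r·p)` feature columns are drawn
with replacement, the materials reclustered, and each original node's
member set counted when it reappears.  `z_r = Φ⁻¹(1 − BP_r)` is fitted
against `v·√r + c/√r` by WLS with inverse delta-method variance weights
(`var(z_r) ≈ BP(1−BP)/(n_boot·φ(z)²)`); then `AU = 1 − Φ(v − c)` and
`BP = 1 − Φ(v + c)`.  Only scales with interior BP (0 < BP_r < 1) enter
the fit — a probit at the boundary carries no shape information; nodes
at the boundary everywhere are unanimous and get AU = BP = 1 (or 0).
BP_r is clipped to `[1/(n_boot+1), n_boot/(n_boot+1)]` before the
probit.  AU > 0.95 is the conventional significance threshold.

## Synthetic campaigns

The generator's defaults encode the reference screening design: 5
endpoints, CTG at 0/6/24/72 h, imaging at 6/24/72 h, 4 biological
replicates, 12 doses 2-fold from 256 µg/ml, ±serum, BEAS-2B, 16×24
plates with 0.1 cm² wells and 50 µl assay volume; each material occupies
one plate row, vehicle controls sit in two fixed columns, the rest is
blank.  This yields the design arithmetic 12,288 CTG / 18,432 DAPI
(technical duplicates) / 9,216 per remaining imaging endpoint / 58,368
data points per campaign.

Truth is a Hill curve per material on the percent-effect scale
(`effect = top · f(t) · dʰ/(EC50ʰ + dʰ)` with a saturating time factor),
mapped to signals as follows: controls grow as `g(t) = 2^(t/24)`
(doubling per day — without growth, baseline-subtracted controls would
be identically zero and percent-of-control undefined); CTG =
`L·(1 + interference + (g−1)·(1−effect/100))`, DAPI = `L·g·(1−effect/100)`,
caspase = `L·g·(1+effect/100)·(1−viability loss/100)` (so the Eq.-style
cell-loss correction exactly inverts it), per-cell intensities =
`L·(1+effect/100)`.  Noise is homoscedastic Gaussian on the signal scale
(default sd 3% of the seeding-level signal, a typical plate-reader CV;
heteroscedastic noise deliberately off by default), plus a per-plate
multiplier (sd 2%).  Libraries always contain one inert and one clearly
potent material with a strict log-spaced EC50 gradient in between.

Injected artifacts: control wells multiplied by 5 (must be caught by the
IQR fence), focus failures (DAPI = 0 in one replicate with healthy
replicates elsewhere → must become NaN), and a dead-well block (DAPI = 0
in all replicates at the top dose of the most potent material → must
stay 0).

What the generator does *not* emulate — and hence what green tests do
not show about real data: spatial plate effects (edge evaporation,
gradients), optical interference spectra of particles, dose-dependent
variance, non-monotone (hormetic) dose responses, material
sedimentation/dissolution kinetics, and inter-screen batch drift beyond
a scalar plate multiplier.

## Numerical choices and degenerate inputs

* Quantiles: linear interpolation (type 7) everywhere.
* Control SD: sample SD (ddof = 1); a single control value gives SD 0.
* Percent-of-control with a zero control median raises (rather than
  emitting infinities).
* AUC with < 2 finite positive-dose points is 0 with a warning;
  first-significant-dose with < 2 replicates at every dose is NaN with a
  warning.
* Min-max scaling of a constant column is 0 by decision (the ToxPi
  alternative of 0.5 would reward uninformative columns).
* Well addressing accepts `A01` and `A1`; internal coordinates are
  0-based (row, col) on a 16×24 grid.
* All stochastic components (generator, bootstrap, multiscale bootstrap)
  take explicit integer seeds and are bit-reproducible.

## Problem sizes

The test suite and the acceptance script run full synthetic campaigns of
6–8 materials (56 plates, ~59 k wells each), bootstrap sizes of 40–500
and multiscale bootstrap of 200–1000 resamples per scale — sizes chosen
so a complete run takes well under a minute per campaign on one core
while still exercising every pipeline stage at the reference design's
full plate count.

## Known limitations

* The NeXus layout (group names, dense-axis order material × dose × time
  × replicate × serum) is this package's documented dialect; it uses the
  standard NXentry/NXprocess/NXdata class tags but is not validated
  against an official application definition.
* Unit 4 dosing ("cell-delivered dose") expects an externally supplied
  per-material delivered fraction; no sedimentation/diffusion dosimetry
  model is included.
* The two published plate geometries disagree in one reference table
  (the µg/cm² column implies a 0.0795 cm² well area while the cm²/cm²
  column implies 0.1 cm²); both geometries are supported and the
  discrepancy is documented rather than resolved.
* Rank CIs come from the same percentile machinery as score CIs; for
  small libraries rank distributions are coarse and their intervals
  conservative.
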