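# Methods

This note documents the models, numerical conventions and design
choices behind `riverwqi`, and what the synthetic scenarios do and do
not establish about real monitoring data.

## Quality ratings and the weighted arithmetic index

The rating `qᵢ = 100·(Vᵢ − V₀)/(Sᵢ − V₀)` is anchored at two points:
the ideal value V₀ maps to 0 and the permissible limit Sᵢ to 100. The
same expression serves all three objective directions:

* **ceiling** (most pollutants): V₀ = 0 by default, so qᵢ is simply
  100·Vᵢ/Sᵢ;
* **floor** (dissolved oxygen): V₀ = 14.6 mg/L (saturation at 0 °C),
  Sᵢ = 6 mg/L; the denominator is negative, which flips the sense so
  oxygen *below* the floor rates above 100;
* **range** (pH): V₀ = 7.0 and the bound on the measurement's side of
  the ideal is used, so both 6.5 and 8.5 rate exactly 100.

Ratings below zero (a measurement on the safe side of the ideal, e.g.
supersaturated oxygen) are clamped to 0; ratings above 100 are *not*
clamped, because the "unsuitable (> 100)" class requires the index to
exceed 100. The WAWQI itself is the weight-normalized mean, so it is
invariant to uniform weight rescaling, monotone in every rating, and
bounded by the extreme ratings.

Class bins are contiguous and upper-inclusive at 25/50/75/100. The
conventional printed scheme ("0–25, 26–50, …") leaves the interval
(25, 26) undefined; the half-open convention closes the gap without
moving any printed example across a class boundary.

Which parameters enter the index is configuration. The default is every
parameter with a statutory limit in the shipped registry (COD, BOD, TN,
phenol, NH₃-N, DO, TP, TDS, pH, fluoride, sulfate, chloride); the
remaining monitored parameters carry clearly flagged non-statutory
placeholder guidelines and join only with `include_nonstatutory`.
Weights default to a 4/3/2/1 ranking by ecological and human-health
risk (organic/toxic load highest) and are likewise configuration, not
ground truth.

## The CCME-style index

Within a test pool (by default all records of one site-sector-season
group; a flag pools both seasons for multi-visit usage):

* F1 = 100 · (parameters with ≥ 1 failed test) / (parameters tested);
* F2 = 100 · (failed tests) / (tests);
* excursion of a failed test: `value/guideline − 1` (ceiling),
  `guideline/value − 1` (floor), nearest-bound analog for ranges;
  a zero measurement under a floor objective has an unbounded
  excursion and is capped (default 100) with a logged warning;
* `nse = Σ excursions / tests`, `F3 = nse / (0.01·nse + 0.01)`;
* `CWQI = 100 − √(F1² + F2² + F3²) / 1.732`, clamped to [0, 100].

The divisor is kept literally at 1.732 rather than √3, which makes the
worst case (all factors 100) land at −0.0029 before the clamp.

**Amplitude dilution.** Because nse divides by the *total* test count,
appending a failed test whose excursion is below the pool's mean
excursion lowers F3 and can raise the score slightly. This is a trait
of the CCME formulation, not an implementation artifact; the
monotonicity tests therefore enumerate added failures at least as
severe as the pool mean, where the score is provably non-increasing.

The WAWQI rates the *mean* of replicate values per parameter within a
group; the CWQI treats every replicate as one test. With three
replicates a single failing parameter thus fails three tests, leaving
F1/F2 proportions unchanged relative to single-visit pools.

## Spatial interpolation

IDW with default power n = 2 over all points (k-nearest optional).
Estimates are convex combinations of observations, exact at sample
locations (zero distance returns the observed value), converge to the
nearest-neighbor surface as n grows and to the neighborhood mean as
n → 0. Coincident duplicate coordinates are averaged before
interpolation, deterministically and order-independently.

Geographic coordinates are projected to planar metres with a local
equirectangular projection about the mean latitude (x = R·Δλ·cos φ̄,
y = R·Δφ, R = 6 371 000 m). For a ~1° corridor the scale error is far
below the sampling geometry's own uncertainty; spans over 5° of
latitude are refused with instructions to supply projected coordinates.

Grids default to 100 m cells over the sample bounding box padded by
1 km (the worked examples use coarser cells purely to keep output
small); an optional GeoJSON corridor polygon masks cells to NODATA.
Rasters are Esri ASCII grids with a fixed header order and NODATA
−9999.

Cross-validation is leave-one-out over *points*: replicates are
averaged per point first (the surface interpolates point means), then
each point is re-estimated from all remaining points, including
co-located lateral-sector points at the same site. RMSE ≥ MAE always
(power-mean inequality) and both are reported per parameter and season.

Correlations are Pearson product-moment on one row per
site-sector-season group (parameter means), with both index scores
appended as variables; p-values come from the exact t-transform and are
reported raw, without multiple-testing correction. Zero-variance
variables are flagged and their correlations left undefined.

## Synthetic scenarios

The generator emulates the structure the pipeline assumes, not any
specific dataset:

* **Layout**: sites on a straight 120 km corridor, lateral main/east/
  west points offset ±250 m; the impacted preset uses 8 sites and the
  sector pattern 3-3-1-3-3-1-1-3 → 18 points, 3 replicates each → 54
  samples per season.
* **Baselines** per parameter and season, chosen as typical background
  values for a large, fast, self-purifying river: all statutory
  parameters comfortably within limits; summer DO low (4.6 mg/L,
  reflecting deep-water dam releases and heat) vs winter high
  (8.2 mg/L); winter water at 17.5 °C vs 24.5 °C in summer.
* **Hotspots** as isotropic exponential plumes with decay lengths of
  400–500 m. The impacted preset has four: two winter-only sugar-mill
  discharges (the mills run January–May), a year-round paper mill
  (the only phenol source, 9 µg/L at the outfall against a 1 µg/L
  limit), and a ferroalloy plant whose cooling water perturbs
  temperature only. Amplitudes are calibrated once so the outfall-point
  values land mid-range of the motivating campaign's reported spans
  (winter COD 55.3 mg/L at the sugar+paper outfall, turbidity ≈ 8.5–11
  NTU at discharge points vs 0.55 NTU background).
* **Couplings**: BOD is drawn as ratio·COD with ratio ~ U(0.5, 0.7)
  (biodegradable effluent), and DO is depressed by 0.03 mg/L per mg/L
  of COD above background. Both are optional; disabling them recovers
  exact baselines when noise is off.
* **Noise**: multiplicative mean-one log-normal per parameter with CVs
  of 3–12% (typical analytical precision, tightest for COD/BOD and
  alkalinity/hardness, loosest for turbidity and TSS); pH and
  temperature use additive Gaussian noise (σ = 0.08 and 0.3 °C).
  Concentrations are clamped non-negative, pH to [0, 14].

Everything is deterministic given (scenario, seed); one seeded
generator drives a run in a fixed iteration order, and the seed is
recorded in the dataset provenance.

**What passing tests show — and don't.** The recovery tests establish
that the pipeline identifies the most-impacted sampling point and
separates background from discharge-adjacent water reliably *under the
generator's assumptions*: isotropic plumes, independent log-normal
noise, no advection, no flow seasonality beyond on/off hotspot
schedules, no biological response. Real rivers violate all of these to
some degree (plumes hug the bank and stretch downstream; errors can be
correlated across parameters), so field performance must be judged with
the LOOCV report on the real data, not inferred from the synthetic
pass rates. "Hotspot-adjacent" in the recovery tests means the sampling
point nearest a discharge active in that season; "background" means
points farther than 2.5 km from every hotspot (several decay lengths,
where plume contributions are negligible).

## Numerical and formatting conventions

* Exported tables are written with 4-decimal formatting for
  byte-stable regression comparisons; a full-precision sidecar
  (`indices_full.csv`) retains the unrounded values.
* Sample-table floats are exported with `repr` round-tripping, so
  write → read → write is byte-identical.
* Excursion caps, skipped parameters (< 2 points for LOOCV) and
  zero-variance variables are logged with a WARN-prefixed,
  machine-greppable message.
* Problem sizes in the test suite (grid sizes, seed counts of the
  recovery tests: 200 seeds for single-hotspot recovery, 100 for
  scenario calibration) are the package's chosen verification sizes;
  at these sizes the whole suite runs in seconds.

## Known limitations

* No kriging or variogram diagnostics; IDW only, by design.
* No unit conversion: a unit mismatch against the registry is an
  error, never a silent rescale.
* The CWQI amplitude-dilution behaviour described above.
* The local projection is unsuitable for reaches spanning more than a
  few degrees of latitude.
* GeoTIFF output exists only when `rasterio` is importable; the
  canonical raster format is the Esri ASCII grid.
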