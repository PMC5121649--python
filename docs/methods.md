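# Methods

This note documents the statistical procedures implemented in
`tempomics`, the defaults and why they were chosen, what the synthetic
data generator does and does not emulate, and the package's known
limitations.

## Data model and missingness

An `OmicsObject` is a two-level ordered mapping: sample label →
component identifier → (measurements, metadata).  Sample labels encode
the sampling times (e.g. study days); `create_time_series` parses them
with a deterministic rule (first maximal numeric run, overridable by a
regex or callable) and aligns every component on the sorted time grid.

Missingness has two sources — a value explicitly recorded as missing,
and a component simply not measured in a sample — and both are
canonicalized to `NaN` in extracted series so downstream code sees one
representation.  Inside the container the `MISSING` sentinel is a
distinct object, never conflated with zero: a below-detection
measurement is not a zero measurement.  Multi-channel measurements
(e.g. replicate intensities) are never aggregated implicitly; every
time-series operation takes an explicit channel index.

## Normalization

* **Quantile normalization** (per omics, across samples).  With
  complete, equally sized samples this is the textbook method (each
  rank is replaced by the across-sample mean of that rank).  With
  missing values, each sample's sorted observed values sit at plotting
  positions (k−0.5)/m; the reference is the across-sample mean of the
  per-sample linearly-interpolated empirical quantile functions (held
  constant outside the outermost positions), evaluated at each sample's
  own positions.  Ties within a sample receive the mean of the
  reference values they span, so equal inputs stay equal.
* **Box-Cox.**  (xᵏ−1)/k for k≠0, ln x at k=0 (the continuous limit).
  The exponent maximizes the standard profile log-likelihood over
  [−5, 5] (bounded scalar minimization, tolerance 1e-6).  Nonpositive
  inputs trigger an automatic shift of 1e-3 − min, recorded in the fit;
  constant input is rejected (degenerate likelihood).
* **Reference-point normalization.**  For series on a log-like scale,
  subtracting the value at a designated reference time (e.g. a healthy
  baseline visit) expresses each series as fold change relative to that
  state.  Components missing at the reference are removed and reported;
  the result is invariant under adding a constant to a whole series.
* Default pipeline order: tag low values → quantile normalize (per
  omics) → Box-Cox / log scaling → reference normalization →
  missing-fraction filter.  Each step is optional and the order is
  configurable; the missing-fraction filter (default cutoff 0.6 in the
  CLI pipeline) is the quality-control step that removes
  under-observed series before spectral analysis.

## Spectral analysis

The Lomb-Scargle periodogram is the least-squares spectral estimator
valid for uneven sampling; missing values are dropped, never imputed,
on this path.  Power is normalized by the sample variance (ddof 1), so
white-noise power is O(1) per frequency, and the estimator is invariant
under time translation and value scaling.  On complete even grids it
equals the classical periodogram at the Fourier frequencies (verified
to 1e-6 relative error in the tests, and cross-checked against an
independent library implementation).

The default frequency grid is k/T for k = 1 … ⌊f_max·T⌋, where T is the
observed span and f_max = 1/(2·mean adjacent spacing) (a pseudo-Nyquist
limit; 1/(2·min spacing) selectable).  Oversampling densifies the grid
without raising f_max.  Classification uses oversampling 1 so that all
series in a dataset share one discrete set of frequency classes.

Autocorrelations are computed two ways, matching two use cases:

1. **Inverse-spectrum**: the cosine transform of Lomb-Scargle power
   over the grid, normalized to 1 at lag 0.  Because the spectrum is
   one-sided and phaseless this is a Wiener–Khinchin surrogate, not an
   exact inverse.  Lags are uniform with spacing T/M and stop at T/2: a
   discrete spectrum at frequencies k/T makes the transform T-periodic,
   so larger lags carry no information.
2. **Interpolated**: observed points are interpolated (cubic by
   default, linear for very short series) onto a uniform grid of the
   same span, then the standard biased estimator r_j = c_j/c_0 is
   applied.  No extrapolation beyond observed endpoints.  On complete
   even grids interpolation is the identity and the estimator is the
   classical one.

## Classification

Every component receives exactly one label.  For the three cutoff-based
methods (periodogram, inverse-spectrum autocorrelation, interpolated
autocorrelation) the decision sequence is: dominant frequency/lag class
(maximum statistic above the null cutoff; ties break toward the lowest
bin), then SpikeMax (series maximum above cutoff), then SpikeMin, else
Unclassified.  Frequency classes and spike classes are therefore
mutually exclusive by construction.

**Bootstrap null.**  Surrogates resample the pooled observed values of
the dataset with replacement onto the real time grid, applying the
dataset's average missingness — this destroys temporal structure while
preserving the marginal value distribution and the sampling pattern.
Pooling across components reflects a dataset-level null; per-series
pooling would confound a series' own signal with its null.

**Joint calibration.**  Three null tests run in sequence, so plain
per-test 0.95 quantiles would leave ~14% of null series classified.
By default the shared per-statistic quantile level is raised on the
bootstrap sample (bisection, 60 iterations) until the fraction of
surrogates exceeding *any* of the three cutoffs equals 1 − quantile;
the overall rate of null series leaving Unclassified then matches the
nominal level (measured ≈5% at quantile 0.95).  `calibration="marginal"`
gives plain per-statistic quantiles instead.  Per-frequency marginal
quantiles are always reported as diagnostics.  The decision cutoff for
frequency classes is a quantile of the surrogate *maximum* statistic —
a per-frequency decision rule would multiply the false-positive rate by
the number of frequencies.

**Spike detectability.**  A singular event is detectable only if it
rises above the null maximum: for ~21 samples the ~98th percentile of
the null series maximum is ≈3.2 noise SD, so a spike must be several
SD beyond that.  Two consequences are built into the defaults: the
synthetic generator plants spikes at 8 noise SD (`spike_scale=8`), and
spikes must be *rare* — pulse values enter the bootstrap pool, so if
more than ~(1 − calibrated quantile) of components carry pulses the
null maxima saturate at the pulse scale and mask the spikes themselves.
The calibration experiments therefore plant spikes in ~1% of
components, the regime the method is designed for.

**Model-based methods.**  Series are interpolated to an even grid
(cubic) where needed, then all ARMA(p, q) candidates with p, q ≤ 2 are
fitted by maximum likelihood (statsmodels) and the kind — WhiteNoise,
AR, MA, ARMA — is selected by information criterion.  The default
criterion is BIC: with n ≈ 200 the AICc penalty (~2 per parameter) lets
an overparameterized ARMA candidate beat the true AR model by chance
~15–25% of the time, while BIC's ln(n) penalty keeps kind selection
consistent (AR(1), φ=0.8, n=200: selected as AR in 96/100 seeds, mean
|φ̂ − φ| ≈ 0.02).  AICc remains selectable.  Parameter-level classes
group fits of identical kind and orders whose parameter vectors are
within a max-norm tolerance, transitively closed by single linkage.

## Clustering

Agglomerative (average linkage by default; complete and Ward
available), deterministic given the input order.  The number of groups
is chosen by cutting the tree at each candidate k (default 2 …
min(8, n−1)) and maximizing the mean silhouette width computed with the
same metric as the tree; ties go to the smaller k, and a best
silhouette below 0.25 triggers a weak-structure warning.

Two-tier clustering: tier 1 uses euclidean distances between
(variance-normalized) periodogram vectors; tier 2 re-clusters each
tier-1 group on the original series with distance 1 − Pearson
correlation over pairwise-complete time points.  The spectral tier
groups series with the same rhythm regardless of sign or phase; the
real-space tier separates correlated from anti-correlated members.
Tier-1 groups with fewer than 3 members stay a single subgroup.  Pairs
with undefined correlation (zero variance on the common support) get
distance 0 if identical, else 1.  Matrix biclustering applies the same
linkage + silhouette machinery independently to rows and columns.

## Enrichment

Annotations are read from GAF 2.x (term → object-id sets; NOT-qualified
rows excluded; the universe is every object id seen) or from two-column
TSV mappings (identifier, category, optional description).  There is
**no propagation up the GO graph** — annotations are used exactly as
given in the file.  The hypergeometric upper tail is computed with the
survival function of the scipy hypergeometric distribution (stable in
log space); BH q-values implement the step-up formula directly and are
cross-checked against statsmodels.  The default background is the
annotation universe; the measured component set can and usually should
be supplied instead.  Query identifiers outside the background are
excluded from n and reported, never silently dropped.  Defaults:
FDR cutoff 0.05, minimum overlap 1, BH adjustment (Bonferroni
selectable).  Compound-vs-map queries use identical mechanics.

## Synthetic data generator

`synth_timegrid` emulates a longitudinal single-subject profile:
21 samples by default over days 186–400, unevenly spaced (uniform grid
jittered by up to 40% of the spacing, endpoints fixed, rounded to 4
decimals so labels round-trip).  `synth_omics` plants, per component:
a sinusoid at a grid-representable frequency (amplitude = snr ×
noise SD; defaults snr 3, noise SD 1, frequencies drawn from the lower
80% of the grid so the planted peak is resolvable), a rare singular
spike (±8 noise SD on a noisy flat baseline), or pure Gaussian noise;
missingness (default 20%) is uniform at random with at least 4 observed
points per series and the spike observation itself always retained.
Class counts follow the requested mix exactly (largest-remainder
allocation, then a seeded shuffle).  Defaults mirror the sample counts
and day range typical of pilot longitudinal multi-omics studies; noise
is Gaussian only.

What passing tests on this generator do **not** show: robustness to
heavy-tailed or count-distributed noise (e.g. raw RNA-seq counts),
batch effects, informatively missing data (censoring at a detection
limit correlates with signal), or drifting baselines.  The generator is
a calibration surface, not a biological simulator.

## Numerical and design choices

* Component ordering is lexicographic wherever outputs are serialized;
  linkage tie-breaks follow the condensed-distance order — together
  with seeded RNGs this makes whole-pipeline outputs byte-identical
  across runs.
* Lomb-Scargle needs ≥3 observed points and nonzero variance; series
  failing that skip the spectral test and fall through to the spike
  tests (or Unclassified).
* The marginal-calibration exceedance of the max-power cutoff on fresh
  null series is ≈5% by construction; with familywise calibration the
  union exceedance is ≈5% and each marginal test is correspondingly
  stricter.
* CLI exit codes: 0 success, 2 configuration error, 3 data error,
  4 stage failure.  Figures render last so a plotting failure never
  corrupts tabular outputs.
* Problem sizes in the test and acceptance experiments (hundreds of
  components, 21-point grids, 300–500 bootstrap replicates, 100-seed
  model-selection sweeps) were chosen to put Monte-Carlo error well
  inside the tested bands while keeping the suites quick to run.

## Limitations

* No analytic Lomb-Scargle significance levels; cutoffs are always
  bootstrap-based.
* Model-based classification assumes even sampling after cubic
  interpolation; heavy missingness will bias ARMA estimates.
* Quantile normalization across samples with very different missing
  fractions equalizes distributions only approximately (exactly, on
  complete data).
* No batch-effect correction and no cross-omics normalization beyond
  placing each omics on a common transformed scale.
* Enrichment treats annotation files as flat category memberships; GO
  ancestor propagation, if desired, must be applied upstream.
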