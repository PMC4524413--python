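# Methods

This note documents the models, numerical choices and limitations behind
`lcmspipe`, in the order data flows through the package.

## Core model and conventions

Three entities move between stages: a **Scan** (sorted m/z–intensity
pairs at a retention time), a **Feature** (one ion trace: time vector,
intensity vector, characteristic retention time *t*ᵣ, characteristic
m/z), and a **FeatureSet** (co-eluting features at the mean member *t*ᵣ).
All operations are pure — inputs are never mutated — which is what makes
per-stage snapshotting and resumable execution safe.

Conventions adopted where the literature is not prescriptive:

* *t*ᵣ is the **apex time** of the trace (ties break to the earliest
  scan). A weighted-mean definition would differ on asymmetric peaks;
  apex is robust for the sharp peaks this pipeline targets.
* Time is **seconds** everywhere; mzML minute values are converted on
  read. Scan indices are 0-based in file order.
* Every mass tolerance is **relative (ppm)**, never Da, so behaviour is
  uniform across the mass range.
* The feature-matrix cell value defaults to the **trapezoidal area** of
  the trace (apex height is available as an option). A single-point trace
  has zero area by this definition.

## Centroiding

Profile spectra are reduced to sticks with a continuous-wavelet-transform
picker using the Ricker (Mexican-hat) kernel, the de-facto standard for
mass-spectral peak picking. The response is computed at scales {2, 4, 8,
16} profile points (1/√s normalization); a candidate is kept when

1. it is a local maximum of the smallest-scale response,
2. a matching maximum exists at the next scale within one scale width
   (ridge persistence across ≥ 2 consecutive scales), and
3. its response exceeds `min_snr` (default 3) times the noise at **both**
   ridge scales, noise being 1.4826 × MAD of that scale's response.

Gating both scales matters: single-point noise spikes survive the
smallest scale but die under the wider kernel, which is what pushes
precision above 90 % at peak SNR 10 while keeping recall at ~100 %.
A relative response floor (10⁻⁹ of the scan maximum) suppresses
floating-point fuzz in empty regions of noise-free spectra, where the MAD
noise estimate is exactly zero. Centroid m/z is the intensity-weighted
mean of profile points within ±10 ppm of the ridge apex; centroid
intensity is the profile maximum in that window. Because both the
response and the MAD estimate are linear in intensity, rescaling a
spectrum never changes the picked m/z set. Scans without a
representation term are classified by a uniform-spacing heuristic
(median point spacing within 20 %) and the decision is logged.

## Filtering and baseline correction

The intensity threshold is a global cutoff (per-scan adaptive thresholds
were deliberately omitted for predictability); range filters are
inclusive on both ends. Baseline correction operates **per feature
trace** with asymmetric least squares: a second-difference-penalized
smoother (smoothness 10⁴) with weights `asymmetry` (0.01) above the
running baseline and `1 − asymmetry` below, iterated to weight
convergence (max 20 iterations, tolerance 10⁻⁶); negative residuals are
clamped to zero, and traces under 5 scans pass through. All filters are
idempotent, and the scan-width filter is monotone in `min_scans`.

## Trace extraction and deconvolution

Traces are built greedily over MS1 scans in time order. Each centroid
joins the open trace whose running intensity-weighted mean m/z is nearest
within `tol_ppm` (default 10); assignment is globally nearest-first per
scan, so each trace takes at most one centroid per scan and each centroid
joins at most one trace — and the result is independent of within-scan
pair order. A trace closes after more than `max_gap_scans` (default 1)
consecutive missed scans, and is kept only if its apex exceeds
`min_intensity`. MSⁿ scans are carried through and may be associated to
features by precursor m/z; they are never processed spectrally.

Deconvolution smooths the trace with a Savitzky–Golay filter (order 2,
window 9 scans), finds smoothed local maxima with SNR ≥ 3 (noise =
1.4826 × MAD of the smoothing residual), and splits at the minimum
between adjacent apexes when that valley falls to ≤ `valley_fraction`
(0.5) of the lower apex. Children keep the **raw** intensities — the
smoothed signal is used only for decisions — and the split point belongs
to the earlier child, so total intensity is conserved exactly.

## Grouping

"Belonging together" is decided chromatographically: two features connect
when |Δ*t*ᵣ| ≤ `rt_tol` (5 s) and the cosine of their elution profiles,
linearly resampled onto the union of their scan times over the span
overlap, is ≥ `min_similarity` (0.9). Connected components (single
linkage, so M+H — M+Na — M+1 chains stay together transitively) become
feature sets. An alternative reading of profile similarity — per-scan
mass-spectral vectors rather than elution profiles — was considered and
not implemented; elution profiles are the stronger evidence for
co-elution in MS1 data.

## Annotation

Isotopologues are found at spacings k·1.0033548/|z| Th (k ≤ 3, z ∈ {1,2},
charge inferred from the spacing) with the M+k apex at most 1.1 × the
anchor's; chains anchor at the lightest non-isotope member and are scored
by the elution-profile cosine. Adduct pairs are found by inverting each
rule, neutral(f, r) = (m/z·|z| − shift)/n: when two features' implied
neutral masses agree within tolerance, both gain annotations and the set
records the mean implied mass as its consensus neutral mass. The
transform inverts exactly (round-trip to < 10⁻⁹ relative). Fragments use
the same rule machinery with negative shifts supplied by the user.
Reference matching reports **all** candidates with mass and rt error
columns rather than a forced best hit, since identity verification is a
human step downstream; the main peak of a set is the M+H (positive) or
M−H (negative) member, falling back to the most intense non-isotope
member (ties to lowest m/z).

## Alignment and the feature matrix

Landmarks are unique mutual-nearest feature matches between target and
reference runs (within ppm and an rt window), ranked by intensity, top
50. If the landmark deltas show no drift trend (|Theil–Sen slope| <
0.005) the map is a constant offset — the median of all deltas — which
estimates a uniform shift far more precisely than binned knots; otherwise
a monotone piecewise-linear map through per-bin medians (10 equal-count
bins, cumulative-max enforced) is used, extrapolating with the edge shift.
Fewer than 5 landmarks falls back to the identity map with a warning.
The reference run is the one with the most features. Matrix building is
greedy centroid-style: features in descending apex intensity join the
nearest group within tolerance that lacks a feature from their sample.
Missing cells stay missing; no imputation, no gap-filling by targeted
re-integration.

## Pipeline executor

Workflows are DAGs of typed stages (cell kinds: sample, features, feature
sets). Validation reports every kind-mismatched edge, cycle, unfed or
doubly-fed in-port and parameter-schema violation as data; a validated
workflow cannot raise a kind mismatch at run time. Batch execution is
per-file independent (one corrupt file cannot abort the batch), routes
`per_mode` parameter variants by each sample's polarity (file polarity
first, then an explicit override; an error if mode-specific parameters
exist but the mode is unknown), and snapshots every stage output when
asked. Snapshots are a 4-byte magic plus JSON with an explicit kind tag
and schema version; floats use shortest round-trip representation, so
round-trips are bit-identical and equal runs produce hash-equal files.
Stages are pure, so per-sample concurrency is permitted by contract;
shipped code runs serially and deterministically (a global seed field
exists for future stochastic stages).

## Synthetic ground truth

The generator emulates reference-standard runs: each compound elutes as a
symmetric Gaussian (tailing available but off by default) and appears per
adduct rule at (n·M + shift)/|z|, with isotopologue peaks scaled by its
isotope ratios; chemical noise is exponential-tailed at uniform random
m/z with Poisson count per scan; a linear baseline and Gaussian per-peak
m/z jitter can be added; profile mode renders each stick as a Gaussian of
4 grid points (0.01 Th spacing) width. Isotope ratios default to a crude
carbon-count heuristic (M+1 ≈ 0.011 × round(M/14)) — synthetic, not
chemically exact. The truth manifest records every injected trace, which
is what recall/precision and identification rates are scored against.

What the generator does **not** emulate — peak tailing and fronting under
real gradients, detector saturation, correlated (structured) chemical
background, mass-calibration drift, real isotope fine structure, MS²
chemistry — bounds what passing tests show: they validate the algorithms'
contracts and accuracy under idealized, known-truth conditions, not
instrument-specific performance.

## Problem sizes in the shipped checks

The standards suite mirrors a 58-compound composition (30 positive-only,
16 negative-only, 12 in both modes → 70 runs of 640 scans each); feature
recovery uses one 50-compound noisy run; alignment uses 5 runs of 50
shared compounds with a +10 s shift on two and 1 s rt jitter;
deconvolution conservation uses 200 random two-peak traces; validation
soundness uses 100 randomly composed workflows. These sizes exercise
every code path while keeping the whole suite fast on a single CPU.

## Known limitations

* No vendor RAW, mzXML or mzData input, and no mzML writing beyond the
  synthetic generator's minimal files; no Excel side-inputs.
* Snapshot files are this package's own format, not interchangeable with
  any other tool's serialization.
* No model-based (e.g. exponentially-modified Gaussian) peak fitting; no
  online compound-database queries; no blank subtraction or lock-mass
  recalibration; no cross-sample correlation evidence during grouping.
* Identity matches are unranked candidates; scoring/ranking is left to
  the analyst.
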