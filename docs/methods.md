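# Methods

`scancentric` characterizes peaks from multi-scan, direct-injection
Fourier-transform mass spectrometry (FT-MS) profile spectra by treating the
individual scans — rather than an averaged aggregate spectrum — as the unit
of measurement. This note describes the model and procedure, the parameters
that matter, what the synthetic-data generator does and does not emulate,
and the numerical choices made where the design was genuinely open.

## The frequency axis

Orbitrap analyzers measure ion axial oscillation frequency, which scales as
1/√(m/z); vendor files expose only the m/z grid. Because the underlying
frequency grid is uniform, a proxy frequency can be recovered per adjacent
point pair as

    f_i = ((mz_i + mz_{i+1}) / 2) / (mz_{i+1} − mz_i),

i.e. midpoint over spacing. Successive proxy values are equally spaced, and
their modal difference equals the exponent-scaled grid step (0.5 for the
square-root law of the Orbitrap). The package estimates the mode from a
histogram with bin width median/100, with bins anchored at `min − width/2`
so a degenerate (constant) difference list yields that constant exactly.
Points whose local difference is within ±2 % of the mode (`freq_diff_tol`)
are the *useful* points for model fitting; with a mode of 0.5 this accepts
0.49–0.51.

Per scan, ordinary least squares fits

    f = a + x/mz + y/√mz + z/∛mz          (forward)
    mz = a′ + x′/f + y′/f² + z′/f³        (inverse)

on the useful points. The inverse fit is performed in the scaled variable
u = f₀/f (f₀ = median frequency) because the raw columns 1/f, 1/f², 1/f³
span ~18 orders of magnitude at Orbitrap frequencies and would collapse the
numerical rank. The physics needs only the √ term; the extra terms absorb
small geometry/space-charge imperfections. The design matrix is strongly
collinear (condition number ~6·10⁴ over m/z 150–1000), so the minor
coefficients are only identifiable when their contributions exceed the
noise floor; the √ coefficient `y` is always well determined and is the
quantity used for quality control.

Scan-level fits are screened two ways: scans whose `y` falls outside the
Tukey fences (quartiles ± 1.5·IQR across scans, computed only when ≥ 4
scans are available) are removed, and a run aborts if per-scan modal
differences disagree by more than 10 % (an inconsistent acquisition, e.g.
mixed map shapes or resolutions). A single *master* model — the scan whose
`y` is closest to the across-scan median, ties to the earliest scan — then
converts **all** points of every retained scan; per-scan models are not
used for conversion because crossing model curves can reorder points
between the m/z and frequency axes, which `check_order_preservation`
verifies never happens (strictly decreasing frequency against strictly
increasing m/z).

Round-trip accuracy (m/z → frequency → m/z below 10⁻⁶ Th) holds for
√-dominated model pairs, where the inverse family represents the true
inverse exactly; a hypothetical model with large non-√ terms has an inverse
outside the cubic-in-1/f family and would not round-trip to that precision.

## Intervals, density filtering and regions

Frequencies are mapped to integers by `round(f × 400)` (half away from
zero), preserving point spacing; all intervals are closed and "overlap"
means a shared integer position. Sliding windows 10 points wide with a
1-point stride count non-zero-intensity points pooled across scans.
Profile baselines are zero-floored by the instrument firmware, so non-zero
density — not intensity — separates signal from noise, which matters
because scan intensities are not yet normalized at this stage. The counts
are summarized per 1000-frequency-unit tile by their 99th percentile
(type-7 quantile of the windows whose start lies in the tile); the cutoff
is ⌈median(tile p99) × 1.5⌉, and only windows with counts **strictly**
greater than the cutoff survive. Survivors merge into initial regions.
For the statistic to be meaningful most tiles must be signal-free, which
holds for real direct-infusion spectra and for the generator's clustered
peak layout.

Within each initial region, per-scan candidate peaks are detected by bump
hunting: a local maximum with at least two strictly increasing points
before and two strictly decreasing after (plateaus break a run). Candidate
centers are binned into one-point-wide tiles; empty tiles split the region,
each maximal run of occupied tiles becoming one peak region. A scan that
contributes two or more accepted peaks to a single peak region is discarded
for that region (its local data are suspect); regions ending with no peaks
are dropped.

## Centroiding

Each candidate is centroided by a weighted quadratic fit of log intensity
against frequency position,

    ln(I + c) = a + x·p + y·p²,  y < 0,

with weights w_i = ln(I_i + c)/ln(I_max + c). A Gaussian peak is exactly
parabolic in log space, so the vertex −x/(2y) is the center, a − x²/(4y)
the log height, and the analytic integral of exp(fit) over the point
support the area. The additive constant c = 1 makes the log defined at
zero-floored points while being negligible against real intensities
(≥ ~10³); its perturbation of the fit scales as 1/I_min (≈10⁻⁵ in the
center at I_min = 10³), so exactness tests use c = 0 where the model is
exact. Position is fitted in frequency (equally spaced); the m/z center
comes from the inverse master model afterwards. Natural logs are used
throughout; base-10 appears only in reporting.

## Scan normalization

Scans are near-replicates whose overall intensity differs multiplicatively.
Normalization peaks must (a) be present in at least as many scans as the
95th percentile of per-peak scan counts and (b) have a log height of at
least 0.7 × the scan's maximum log peak height. The intensity ratio is
applied to **log** heights: over a realistic four-decade dynamic range a
raw-height ratio of 0.7 would leave only the one or two tallest peaks,
which cannot satisfy the ≥ 25-peaks-per-scan guard that the method
enforces; the log-scale ratio is also invariant to the logarithm base. A
run aborts if any scan retains fewer than `min_norm_peaks` (25) usable
peaks.

The reference scan minimizes the summed pairwise Euclidean distance between
log-height vectors over shared peaks (ties to the earliest scan), and each
scan's additive ln factor is the median log height difference to the
reference over shared usable peaks. Factors apply subtractively to log
heights and divisively to raw point intensities. The two-pass variant
(`doublenorm`) recomputes factors after removing peaks whose normalized log
height correlates with scan order (|Pearson r| > 0.5, evaluated only for
peaks seen in ≥ 3 scans); such peaks — a sample-gradient artifact — are
flagged in the final output either way. Supported modes: `nonorm`,
`singlenorm` (presence filter only), `singlenorm_int` (presence +
intensity), `doublenorm`. Because the median is robust, a minority of
trending peaks shifts the factors by an amount proportional to the
peak-height noise scale; the two-pass exclusion removes that bias, and the
intensity filter helps exactly when trending peaks are predominantly
low-intensity.

## Aggregation, offsets and flags

Per peak region, the normalized non-zero raw points of all contributing
scans are pooled and refitted with the same weighted parabola, giving the
final center and height; scan-level centroids give the mean/SD of the
center in frequency units (the frequency standard deviation, FSD) and of
the height in raw space (sample SD; an n = 1 peak gets SD 0 plus a
`low_replication` flag). The *offset* converts one median point spacing at
the peak center to m/z through the inverse model — a natural match
tolerance for downstream assignment. High-peak-density (HPD) artifacts
survive as singular peaks with inflated FSD; peaks with FSD above
median + 1.5·IQR of the spectrum-wide FSD distribution are **marked**
(never removed) in `filtersd` mode.

### Censoring correction (experimental)

Peaks absent from some scans are left-censored at the detection floor. The
optional correction (off by default) calibrates the SD shrinkage by
subsampling scan subsets (fractions 5–95 % in 5 % steps, 200 draws each) of
peaks present in all scans, fits a cubic of mean SD ratio against fraction,
divides each censored peak's log-SD by the predicted ratio, and
re-estimates the mean log height by maximum likelihood under a left-censored
normal with that SD, censoring at the peak's minimum observed normalized
log height. The corrected mean is reported in raw space as exp(μ̂);
corrected values are stored alongside raw ones, never replacing them — in
downstream comparisons the raw scan-centric intensities perform better, so
the correction is retained only with its internal mathematics under test.

## Quality metrics

RSD (across-scan SD / mean of raw-space heights, peaks in ≥ 3 scans) is the
primary per-peak precision measure; its distribution is summarized by mean,
SD, median, max, and up to two kernel-density modes (Gaussian kernel,
Silverman bandwidth; a second mode is reported only at ≥ 0.2 × the tallest
density, modes listed low to high). Isotopologue consistency uses
|ln(NAP₁/NAP₂) − ln(I₁/I₂)| over peak pairs, for caller-supplied natural
abundance probabilities. External centroid lists are matched within a
±2 ppm window, nearest |Δm/z| winning, ties to the lower m/z, one query
allowed to serve several references. HPD sites on centroid lists are
sliding 1000-frequency-unit windows (stride 100) whose counts exceed
median + 1.5·IQR of the non-zero window counts, merged when overlapping;
this mirrors the FSD fence rather than re-implementing the original HPD
criterion, and is documented as an approximation.

## Synthetic data

The generator renders what the pipeline assumes and what breaks it: a
uniform 0.5-spaced frequency grid mapped through a known √-law model
(f = 10⁷/√mz by default, i.e. 5·10⁵ at m/z 400); Gaussian-in-frequency
peaks (σ = 1.5 frequency units) in isotopologue-like clusters of 8 within
300 frequency units so most density tiles stay empty; base heights
log-uniform over 10⁴–10⁸; multiplicative per-scan factors
(ln-normal, sd 0.2, the magnitude seen in real normalization factors);
per-peak-per-scan lognormal noise (sd 0.25, reproducing realistic RSDs of
~0.25); center jitter of 0.05 frequency units per scan; additive Gaussian
noise (sd 200) floored together with everything below the detection
threshold (10³) to zero; sparse single-point noise spikes (10 per 1000
frequency units per scan, 10³–10^4.5); optional scan-trending peaks
(ln-slope −0.12/scan) and HPD-like peaks with 10× center jitter. The m/z
grid is shared across scans, as the FT bin raster is for a fixed
resolution. Ten scans are generated by default.

What it does **not** emulate: image-current/transient physics, FT leakage
and ringing, real isotope fine structure, correlated (heteroscedastic)
noise, space-charge-dependent calibration drift, or spray dropout bursts.
Passing tests therefore certify the pipeline's statistical machinery under
its stated error model, not instrument-specific behavior.

Test fixtures run the generator over a narrower m/z window (340–480 Th,
~86 000 frequency units, ~172 000 grid points per scan) with the default
noise conditions; statistical checks state their replicate counts and fixed
seeds in the tests themselves. Dropout comparisons drive censoring through
the shared scan factor (sd 0.4) with modest per-peak noise (sd 0.1): that
is the mechanism under which scan-centric heights (which are normalized)
beat zero-inclusive spectrum averaging — if dropout were driven by large
independent per-peak noise, conditioning on detection would bias the
scan-centric mean instead.

## Numerical choices and limitations

* Half-away-from-zero rounding for integer positions; closed intervals;
  merges require a shared position (pure adjacency does not merge).
* Strict inequality at the density cutoff; type-7 percentiles everywhere.
* Weighted SSR is reported for centroid fits; candidates with non-negative
  curvature or degenerate designs are rejected, pooled fits that lose
  concavity drop the peak with a log entry.
* The 4 s scan-gap filter is greedy against the last *kept* scan —
  deterministic and order-preserving.
* Reference-scan and master-model ties resolve to the earliest scan, making
  runs reproducible byte-for-byte.
* The mzML layer (reader and writer) covers profile MS1 spectra with
  32/64-bit float arrays, zlib or no compression, minute/second retention
  times; chromatograms and numpress encodings are out of scope.
* Cross-sample normalization, molecular-formula assignment and differential
  analysis are downstream concerns and deliberately absent.
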