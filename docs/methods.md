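# Methods

This note documents the models, defaults, and numerical choices behind
blotkit, and what the synthetic-data tests do and do not establish about
real blots.

## Densitometry

A band is an axis-aligned ROI (0-based, half-open extents) on an 8/16-bit
grayscale image. Quantification is: estimate the local background as the
**median of the frame of pixels surrounding the ROI** (default margin 3 px,
pixels inside other registered ROIs excluded), subtract it per pixel with
**clipping at zero**, sum over the ROI, and divide by the ROI width.

- The surround median was chosen because commercial blot software does not
  disclose its background algorithm; the median is local, deterministic,
  and robust to bright specks. It is a documented stand-in, not a claim
  about any vendor implementation.
- Per-pixel clipping keeps densities non-negative and bounds the influence
  of sub-background speckle; it makes density monotonically non-increasing
  in the background estimate.
- "Width" is the ROI's horizontal extent (the lane-width direction).
  Dividing by width makes the density invariant to lane width at constant
  per-pixel intensity: a band stretched to double width at the same
  intensity has double the integral and the same width-normalized density.
  (Holding the *total* signal fixed while doubling width necessarily halves
  the width-normalized value — the two formulations are sometimes conflated;
  the invariance that the width division actually provides, and that the
  tests assert, is the constant-intensity one.)
- Intensities are used as stored; no gamma or bit-depth rescaling.

## Normalization

Two ratio stages, then a reporting rescale:

1. **Blot-set average**: each band of protein *p* is divided by the mean of
   all *p* sample bands in its blot set. The average is per protein, never
   pooled across proteins, because antibody gains differ by orders of
   magnitude.
2. **Control-sample ratio**: the result is divided by the (stage-1) value
   of the pooled control-sample band for *p* on the same blot. The control
   sample models a pooled aliquot of every animal's sample, run in a
   dedicated lane on every blot.
3. **Fold-of-reference**: values are divided by the reference-group mean
   per protein, making that mean exactly 1 (to float precision; the test
   bound is 1e-12).

Because stages 1 and 2 are both ratios taken within the same blot set, the
order of application is immaterial and any factor multiplying a whole blot
cancels exactly; the provenance record fixes the order actually applied
(set-average first). Replicate bands for the same animal × protein are
averaged after stage 2. The loading control (GAPDH) is *not* used as a
per-lane divisor; it feeds only the QC below.

**Loading-control QC** compares each group to the reference on the control
protein with the same Monte-Carlo procedure used for the panel; the QC
passes when no comparison is significant. A QC failure is reported and
recorded in provenance but does not abort the run.

## Contrast indices

`index(A, B) = (A − B)/(A + B)` for non-negative inputs with A + B > 0;
undefined balance (A = B = 0) and negative inputs are errors. The index is
antisymmetric, scale-invariant, bounded in [−1, 1], and strictly increasing
in A. Indices are computed **per animal** (pairing both proteins within an
animal) so that group dispersion, and hence the Monte-Carlo comparison,
applies to indices exactly as to single proteins; computation on group
means is available (`per_animal=False`) for sensitivity checks.

## Monte-Carlo group comparison

For reference summary (m, s) and comparator size n:

- pool: `pool_size` draws from N(m, s²) (default 1,000,000 — the printed
  source for this procedure is typographically ambiguous between 10⁵ and
  10⁶; both are supported and the CIs agree within Monte-Carlo noise, which
  the acceptance suite asserts);
- sampling distribution: `reps` = 10,000 means of n draws taken with
  replacement from the pool;
- CI: empirical (α/2, 1 − α/2) percentiles of those means (the CI
  construction is a percentile interval by design decision — it matches
  "observed mean outside the simulated distribution" semantics);
- significance: observed comparator mean strictly outside the CI, two-sided;
  boundary values count as inside. An epsilon guard (1e-9 relative) keeps
  degenerate sd = 0 intervals from being breached by accumulated float
  round-off; it is invisible at any stochastic interval width;
- p-value: `2 × min(frac ≤ obs, frac ≥ obs)`, floored at 1/reps (zero
  exceedances cannot justify p = 0) and capped at 1. Stars follow the
  figure-legend convention, compared with ≤ so the floor still earns
  \*\*\*\*;
- the full ordered reference × comparator matrix is computed, self-pairs
  included, one CI column per reference in the wide rendering. Each
  comparison draws from an independent, order-independent RNG stream
  derived from (seed, measure, reference, comparator), so the matrix is
  deterministic regardless of evaluation order.
- no multiple-testing correction is applied (none is part of the emulated
  procedure); the provenance records the number of comparisons.

### Calibration, and a known defect of the procedure

With the reference (m, s) set to *true* population parameters the test is
well calibrated: the measured null rejection rate at α = 0.05 is ≈ 0.05
(acceptance suite: within [0.035, 0.065] over 2,000 replications), and the
CI half-width matches 1.96·s/√n within 5% across s ∈ {0.05, 0.1, 0.3},
n ∈ {6, 8}.

The procedure as specified, however, plugs in the reference group's
*sample* mean and SD as if they were known. At reference n = 6–8 this is
strongly anti-conservative: the comparison statistic m̂_c − m̂_r has
variance σ²(1/n_c + 1/n_r) while the CI width reflects only σ̂_r/√n_c, and
σ̂_r itself carries only ~5–7 degrees of freedom. Simulation at these group
sizes puts the per-comparison false-positive rate near 0.2 (scale-free in
σ). Consequences documented deliberately rather than patched:

- a true-null protein is flagged in some comparison far more often than α
  suggests; the study-scale acceptance test records this measured rate and
  the package does not silently correct the procedure, since reproducing it
  is the point;
- the loading-control QC under a true null passes at ≈ 0.5 for three
  comparisons, not (1 − α)³ ≈ 0.86. The QC remains a useful gross-error
  screen: a 1.5-fold loading shift is detected essentially always.

Detection power for the study's large effects is unaffected in practice:
the −29% VGLUT1 effect at n = 8 (SD ≈ 0.085) is flagged in 200/200 seeded
runs.

## Synthetic data

The generator is the forward model the analysis assumes:

    raw(a, p) = mu(g(a), p) · e(a, p) · B(blot(a)) · L(lane(a))

- `mu` — true group mean on the fold-of-normal scale. Defaults encode the
  emulated study's reported percent changes (e.g. VGLUT1: fluoxetine 0.71,
  MD 1.25; gephyrin: MD 0.55; full map in `blotkit.synthetic`). Groups
  without a reported change, the reference group, and the loading control
  are 1.0.
- `e` — between-animal effect, normal with mean 1 and SD chosen so the raw
  density has the target SD, truncated positive by resampling. SDs are
  reconstructed from reported SEMs as SD = SEM·√n (n = 6 or 8 per group);
  unreported cells use a conservative 0.10. Normality-on-the-linear-scale
  matches the assumption of the comparison procedure itself.
- `B`, `L` — blot-batch and per-lane loading factors, log-normal with
  median 1 (defaults: batch SD 0.10, loading SD 0.05). Multiplicative and
  positive, hence removable by the ratio normalization; median 1 keeps the
  zero-noise table exactly equal to design truth.
- Design: 28 animals (6 + 8 + 6 + 8) assigned round-robin to 2 blots (one
  blot set), one replicate per animal × protein by default (replication is
  configurable; the emulated study's reprobing count is unstated), control
  sample in the last lane of each blot with composition equal to the
  animal-weighted mean of group means.

What it does *not* model: chemiluminescence saturation and antibody
nonlinearity, membrane stripping losses, spatial blot artifacts, molecular
weight ladders, or correlated animal effects across proteins. Tests passing
on this generator establish that the *computational chain* is correct under
its stated assumptions, not that those assumptions hold on any particular
real blot.

**Gel rendering** draws each band as a 2-D Gaussian (σ = extent/8 per axis)
on a constant integer background in a 16-bit image, scaled so the pixel sum
over the band's ROI equals `density × width`. Quantization uses
residual-redistributing integer rounding (largest-remainder assignment of
the rounding deficit), keeping each ROI sum exact to ±0.5 counts — naive
rounding systematically loses the sub-half-count tails of faint bands
(~3% at the low end of a two-decade density range). Bands that would
saturate 16 bits are rejected.

## Problem sizes and numerical defaults in the test/acceptance suites

Chosen as the package's own verification design:

- densitometry oracle: 100 random ROIs against an independent per-pixel
  loop; exact equality for integer images with integer-valued backgrounds
  (float64 sums of integers are order-independent below 2⁵³), ≤ 1e-9
  relative for float images where summation order matters;
- round trip: 12 densities log-spaced over 50–5000 counts, 1% tolerance;
- batch-effect removal: 50 simulations (batch SD 0.15 and 0.3, lane jitter
  0.05, between-animal noise off so the measured bias isolates the
  normalization itself), bias < 2% of truth;
- calibration: 2,000 replications with a 100,000-point pool (the rejection
  rate is insensitive to pool size; reps stay at 10,000);
- study-scale power: 200 seeded studies with a 100,000-point pool.

## Design choices that were genuinely open

- **Direction of the comparison**: the emulated description is ambiguous
  about which group seeds the simulation; here the reference supplies
  (mean, SD) and the comparator supplies n and its observed mean, and the
  full ordered matrix is always computed so both directions are available.
- **Two-sidedness**: "greater or less than 95% of the simulated
  distribution" is implemented as a two-sided test at level α (outside the
  central interval), since both increases and decreases are reported as
  significant.
- **Set average over samples only**: the blot-set mean excludes the control
  lane; with the control ratio applied afterwards the choice is provably
  irrelevant (common factors cancel), and excluding it keeps stage 1 a pure
  sample statistic.
- **Control-sample composition**: modelled as the expected pooled value
  (animal-weighted mean of group means) rather than the realized pool of
  simulated animals; the simplification only affects the synthetic truth,
  not the pipeline, and vanishes under the fold-of-reference rescale.
- **Indices per animal** rather than on group means, so that index
  comparisons have a per-animal dispersion to feed the Monte-Carlo null.

## Limitations

- The statistical procedure's anti-conservativeness (above) is inherent and
  reproduced, not corrected; treat isolated single-star flags at n = 6–8
  with caution.
- Densitometry assumes rectangular, non-overlapping, user-supplied ROIs; no
  automatic band/lane detection.
- The normalization has no imputation or outlier handling; missing control
  bands are hard errors.
- Synthetic defaults reconstruct SDs from printed SEMs and fill unreported
  cells with a fixed 0.10; real between-animal dispersion structure may
  differ.
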