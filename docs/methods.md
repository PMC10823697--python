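# Methods

This note documents the models and procedures `laccscreen` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical decisions taken where the underlying protocol
leaves room.

## Overlay-screen densitometry

A plate photograph is a 2D intensity field in [0, 1]; processing tracks a
`stage` tag (`raw` → `inverted` → `background_subtracted`) so stages cannot
be skipped or repeated silently.

**Inversion.** Colorimetric product darkens the membrane, so signal is
`1 − intensity` of the normalized grayscale image.

**Background illumination function.** From one or more blank membrane
images (inverted): the minimum intensity of every `block_size × block_size`
section (default 5 px; trailing blocks at image edges may be truncated so
the whole image is covered), combined across blanks by elementwise minimum,
upsampled to pixel resolution by block replication, then median-filtered
with a square window of side `2·filter_radius + 1` (default radius 7 px).
The block minimum tracks the smooth illumination floor while rejecting
bright local features; the median filter removes artifacts that survive the
minimum (e.g. a dim speck covering a whole block). Neither the filter
window nor the block-to-pixel interpolation is pinned down by the protocol;
both are explicit configuration here, and block replication (nearest
neighbour) was chosen over smooth interpolation because the subsequent
median filter flattens the staircase anyway. Combining blanks by minimum
(rather than mean) keeps the field an underestimate, so subtraction never
removes genuine colony signal.

**Subtraction** clamps at zero: intensities are physical signal, and the
minimum-based field makes negative residuals rare and small.

**Site measurement.** A circle of configurable diameter (101 px for the
reference imaging geometry) is centered at each site of the 24 × 16 grid;
the site value is the mean over pixels whose centers lie within the radius
(Euclidean, inclusive boundary). Grid geometry comes from configuration —
automatic grid registration is out of scope. The measurement circle must
fit strictly inside the grid pitch.

**Growth flags.** Manual 1/0 flags mark sites with no or abnormal growth.
Flag-0 sites keep their measured intensity and receive scores, but are
excluded from every median and from hit calling; without this, empty sites
drag plate medians down. Missing flags default to 1 (normal), since manual
flagging is the exception workflow.

## Per-plate scoring

1. **Plate normalization** divides by the median of flag-1 site values, so
   the flag-1 median is exactly 1 afterwards. Inter-plate comparability
   comes solely from this per-plate step; no global rescaling is applied.
2. **Zone correction.** Zones are concentric rectangular rings indexed
   `1 + floor(min(row, col, n_rows−1−row, n_cols−1−col) / zone_width)`,
   ring 1 at the periphery; the default `zone_width` of 1 makes each ring
   its own zone (8 zones on a 16 × 24 array). A zone whose flag-1 median
   exceeds 1.0 (strictly) has every value in it — flag-0 sites included —
   divided by that median. The correction never increases a value, is
   idempotent, and leaves any corrected zone with a flag-1 median of
   exactly 1. Zones with no flag-1 sites are left unchanged with a warning.
   This targets the concentric pattern of elevated edge signal; row/column
   polish corrections used by colony-size tools are deliberately not
   implemented.
3. **Modified Z-score.** `z = (x − median) / MAD` with
   `MAD = 1.4826 · median(|x − median|)`, median and MAD over flag-1 sites
   of the plate; 1.4826 makes the MAD consistent with the standard
   deviation under normality. A zero MAD (no spread) is an error, not a
   silent division.
4. **Hit calling.** Positive when `z ≥ threshold` (default 2.5) in at least
   `min_replicates` (default 2) replicates; negative by the mirrored rule
   `z ≤ −threshold`. The mirrored negative rule is an interpretation — the
   threshold is conventionally quoted for the positive side only — and both
   threshold and replicate count are configurable. A strain qualifying on
   both sides is demoted to no call with a warning. Even-count medians are
   the mean of the two central order statistics throughout.

## Liquid kinetic assay

**Linear-range trimming.** Substrate depletion bends A420 traces downward
late; mixing lag can bend them early. Points are therefore removed only
from the ends of the series, keeping the retained range contiguous. The
default `trailing_first` strategy drops the last point whenever that
improves r, falling back to the first point otherwise; `best_improvement`
always drops whichever end helps more. A trace that already reaches
`r ≥ r_min` (default 0.999, Pearson) is returned untrimmed. Once trimming
has started, it continues past the threshold for as long as a removal still
strictly improves r (with a 1e-12 tolerance so floating-point ties do not
count): stopping at the first window that scrapes past 0.999 would retain
several early-saturation points and bias the slope by a few percent,
whereas the local-optimum rule terminates exactly at the linear segment on
noiseless data and removes at most a few extra points on noisy data. A
floor of `min_points` (default 5) retained points prevents degenerate
two-point "perfect" fits; failure reports the best r achieved. Whether the
protocol's correlation criterion means r or R² is ambiguous; Pearson r is
used and the threshold is configurable so R² semantics can be matched.

**Beer–Lambert conversion.**
`activity = slope / (ε · ℓ) · V_reaction · 10⁶` µmol/min, with defaults
ε = 36,000 M⁻¹cm⁻¹ (literature value for the oxidized ABTS radical at
420 nm), ℓ = 0.58 cm (200 µL in a flat-bottom 96-well), V = 200 µL. These
constants are not recoverable from the assay description itself, so only
relative quantities (fold changes) are comparable across laboratories;
all are explicit configuration. Activity is reported per reaction well by
default; `per_supernatant=True` rescales by V_reaction/V_supernatant (10×
with the default 20 µL supernatant input).

**Normalization and statistics.** Per-replicate activity is divided by
culture OD600; a strain's fold change is mean(strain)/mean(reference) on
the same plate grouping. Group comparisons use one-way ANOVA with
Dunnett's correction versus the reference or Tukey's for all pairs
(`scipy.stats.dunnett` / `tukey_hsd`); the Dunnett multivariate-t
integration is quasi-random, so it is seeded for repeatable p-values. The
test suite cross-checks both adjustments against independent Monte-Carlo
max-statistic nulls (10⁵ draws, agreement within 0.005). Stars follow the
adjusted-p cutpoints 0.05/0.01/0.005.

## Synthetic data: what it emulates, and what it does not

The generator renders, in the inverted signal space: uniform colony disks
(Gaussian edge blur, σ = 1 px) whose mean intensity is
`base_signal · effect · site_noise · (1 + edge_amplitude · zone_factor)`;
a smooth deterministic membrane illumination field; additive per-pixel
Gaussian noise; and lognormal per-site biological noise with configurable
CV, redrawn per replicate. The emitted image is the raw-stage complement
(dark colonies on a light membrane). `zone_factor` is 1 on the outermost
ring and decreases linearly ring-by-ring to 0 at the center, so the edge
artifact has exactly the concentric-rectangle geometry the zone correction
targets — the magnitude of the real artifact is not documented anywhere, so
`edge_amplitude` (default 0.25) is a free parameter. Kinetic traces are
linear then approach a plateau exponentially (default time constant
15 min) with a continuous first derivative at the break; only the linear
phase carries information, so the exact saturation form is a modeling
convenience. Activity studies draw OD600-normalized activities around
`effect × reference_mean` at a given CV, with independently drawn culture
densities so the normalization step has real work to do.

Deliberately not emulated: colony morphology and size variation, agarose
diffusion halos, camera optics and vignetting beyond the smooth field,
grid misalignment, and plate-to-plate layout errors. Passing recovery
tests therefore demonstrates the correctness of the computation, not
robustness to gross imaging pathologies — grid placement in particular is
assumed known.

Default simulated geometry is 960 × 640 px (pitch 40 px, colony radius
13 px, measurement circle 31 px): a scaled-down stand-in for the real
imaging geometry chosen so that a complete multi-plate screen renders in
seconds, with every geometric relation (colony inside circle inside pitch)
preserved. The recovery benchmark (`laccscreen.benchmark`) runs 4 plates ×
3 replicates with 6 planted 3× positives per plate, 4 empty flagged sites
per plate, and 10% site CV; planted positives are recovered with
sensitivity ≥ 0.9 and false positives stay near the nominal tail of the
z ≥ 2.5 in ≥ 2-of-3 rule (the lognormal noise model's right tail makes the
realized rate a small multiple of the Gaussian nominal ~1.2 × 10⁻⁴).

## Degenerate inputs and tie-breaks

- All-flag-0 plates, zero plate medians, zero MAD, constant traces,
  unreachable r thresholds, missing references and non-positive OD600 all
  raise errors naming the condition rather than propagating NaNs.
- Zone-correction trigger is strictly `> 1.0`; a zone median of exactly 1
  is left alone.
- Circle membership uses an inclusive boundary (`distance ≤ radius`).
- All randomness flows from explicit seeds; reruns are bit-identical.

## Known limitations

- Grid coordinates must be supplied; there is no auto-detection or
  deskewing.
- Camera RAW (.CR2) decoding is out of scope; images are read as 8/16-bit
  TIFF or PNG.
- The absolute activity scale depends on ε, path length and dilution basis;
  treat µmol/min values as instrument-relative unless those constants have
  been verified for the actual plate geometry.
- Negative-hit calling mirrors the positive threshold; screens with
  asymmetric noise may warrant a different negative cutoff.
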