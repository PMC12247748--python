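# Methods

## The measurement problem

An oocyte or early embryo is imaged as a confocal z-stack, sum-projected,
rotated so the anteroposterior (AP) axis is horizontal with the posterior
at the right, and outlined by hand; the outline becomes a binary mask. The
question is how strongly a channel (an HA-tagged protein, Vasa, *nanos*,
*pgc*) is enriched at the anterior, in a way comparable across specimens
that differ in size, shape, staining efficiency, and exposure.

## Per-pixel z-score and anterior integrated enrichment

For channel intensity I over the N mask pixels, each pixel is standardized
as z = (I − μ)/σ with μ and σ the whole-mask mean and standard deviation.
σ uses the population convention (÷N); sample vs population SD is a pure
scale choice that cancels in all comparisons, and the population form makes
the invariant Σz = 0 exact. Standardization makes the statistic invariant
under affine intensity changes I → aI + b (a > 0), i.e. under gain and
offset differences between sessions.

**Anterior integrated enrichment** is Σz over the anterior-most 15% of the
mask. Two readings of "anterior-most 15%" are implemented:

- `pixels` (default): the round(0.15·N) mask pixels of smallest x, ties at
  equal x broken by ascending y. Rounding is half-up, never banker's, so
  the selection size is deterministic.
- `length`: all mask pixels with x < x_min + 0.15·(x_max − x_min), i.e. a
  fraction of the AP extent; fraction 1 is special-cased to the whole mask
  (the strict inequality would otherwise drop the last column).

The two coincide exactly on masks with constant pixels-per-column and
differ slightly on tapered shapes. Because Σz = 0 over the mask,
enrichment over the anterior set equals minus the enrichment over its
complement, and whole-mask "enrichment" is identically 0 — both are used
as self-checks in the test suite.

## AP profiles

The 2-D z-field is reduced to one value per mask column (mean z over that
column's mask pixels). Column centres are mapped linearly from
[x_min, x_max] to [0, 1] (0 = anterior) and values are linearly
interpolated onto a standard 300-point grid, so specimens of different
pixel sizes can be averaged pointwise. Interior columns with no mask
pixels (possible for non-convex traced outlines) are bridged linearly from
their populated neighbours; single-column masks are rejected. The
per-column mean is the simplest reduction consistent with taking the
anterior/posterior boundaries from the mask; other reductions (e.g.
per-column sum) would confound profile shape with specimen thickness.
Group aggregation reports the pointwise mean and mean ± 1.96·SEM (sample
SD, n−1); one sample yields a zero-width band.

## Colocalization

Within the anterior region, "high-anchor" pixels are selected on the
*unfiltered* anchor channel, by either an intensity threshold
(mean + 2 SD over the region, strictly above — an all-equal region selects
nothing) or a rank threshold (top 17.5% of region pixels; ties broken by
value, then (y, x)). Both selection rules are in circulation for this
measurement; the intensity threshold is the default and the rank rule is a
configuration switch.

Both channels are then smoothed with a Gaussian filter (default σ = 1 px)
and the Pearson correlation is computed over the selected pixels, provided
at least 2 pixels were selected and neither vector is constant; otherwise
the result is flagged undefined and excluded from group summaries rather
than raised as an error.

Filtering is **mask-aware** (normalized convolution): the smoothed value
inside the mask is G(I·M)/G(M), where G is the Gaussian kernel and M the
mask indicator. A plain convolution of the zero-filled masked image darkens
every pixel near the outline, and since the anterior cap of an ellipse-like
specimen lies almost entirely near the outline, that shared geometric
gradient alone drives the correlation of *any* two channels toward 1
(measured at r ≈ 0.92 between independent-noise channels). Normalized
convolution removes the exterior's influence and reduces exactly to the
ordinary Gaussian filter on a full-frame mask. Whether the original
measurement filtered one or both channels is not specified by the protocol
this package standardizes; filtering both is the default here.

## Pole-cell statistics

Score tables hold one row per embryo: genotype, category
(`negative` | `attempt` | `anterior_pole_cells`), and anterior/posterior
pole-cell counts; the positive category requires an anterior count ≥ 1.
Penetrance is positives/embryos.

**Bootstrap test (difference in means).** The observed statistic is
mean(x) − mean(y). The null distribution pools x ∪ y and redraws |x| and
|y| values with replacement, B = 10,000 times; p is the fraction of null
statistics at least as extreme as the observed one (equality counts as
extreme). Pooled resampling is the standard bootstrap null for a
difference in means when the resampling set is "the original dataset".
Default sidedness is two-sided on |statistic|, with one-sided options. The
null draws are generated in size-canonical order so the two-sided p is
exactly invariant to swapping x and y at a given seed. At finite B the p
may be 0; a (k+1)/(B+1) correction is available behind a flag, off by
default. Type-I calibration at α = 0.05 is verified by simulation
(500 null datasets, n = 20 per group, B = 1,000 — scaled down from the
reporting default purely for suite speed; the statistic is identical).

**Fisher's exact test.** Penetrance comparisons build the 2×2 table of
embryos with/without the phenotype per group and evaluate the one-sided
hypergeometric tail (default direction: variant lower than control). The
implementation delegates to `scipy.stats.fisher_exact`; the test suite
verifies it against an exhaustive rational-arithmetic enumeration of all
fixed-margin tables with total ≤ 12. Significance is declared at α = 0.05.

## SEC calibration

Kav = (Ve − Vo)/(Vt − Vo); the bundled column constants are the
Superose 6 PC 3.2/30 values Vo = 0.86 mL, Vt = 2.4 mL. Kav outside [0, 1]
(void aggregation, matrix interaction) warns but does not error. The
calibration line is an OLS fit of log₁₀(MW/kDa) on Kav (any log base gives
identical predictions; base 10 is used consistently), and apparent
MW = 10^(slope·Kav + intercept). Oligomer calls use the apparent-to-monomer
mass ratio with nearest-integer-multiple cut-points 1.5 and 2.5
(configurable): ratio < 1.5 monomer, < 2.5 dimer, else higher. The
cut-points are this package's convention — the underlying judgment
("apparent MW close to a dimer") is qualitative.

## Synthetic data generator

The generator emulates just enough of a projected two-channel micrograph
to give every statistic a known ground truth:

- an axis-aligned elliptical mask (default semi-axes 70×40 px in a 160×96
  frame — a specimen filling most of a modest projected field);
- anchor channel: baseline + A·exp(−x̂/λ) + N(0, noise_sd²) inside the
  mask, with x̂ the normalized AP coordinate (0 = anterior); defaults
  baseline 100, noise SD 5, amplitude A = 2, decay λ = 0.15 of the AP
  extent — an anterior-peaked signal a few tenths of the noise SD per
  pixel, detectable only through spatial integration, which is the regime
  the enrichment statistic exists for;
- target channel: baseline + α·(noise-free anchor signal) +
  (1 − α)·independent noise, so the mixing coefficient α ∈ [0, 1] is the
  ground-truth colocalization strength, and α = 1 with zero noise makes
  the channels identical (r = 1 exactly);
- intensities are clipped at 0 (negligible at the default
  baseline-to-noise ratio) and pixels outside the mask are 0;
- score cohorts: one categorical draw per embryo
  (negative/attempt/positive); positive embryos draw anterior counts from
  a Poisson truncated at ≥ 1 (inverse-CDF, so it is exact and vectorized);
  all embryos draw posterior counts from an untruncated Poisson. Default
  count means 20.5 (anterior, positives) and 24.3 (posterior) match the
  scale of real cohorts; the true count distribution of such data is
  unknown, so Poisson is a modelling convenience, not an inference.

Everything is a pure function of the parameter record including its seed;
identical parameters are bit-identical.

What the generator deliberately omits: 3-D stacks, optics/PSF, detector
noise statistics, nuclear/actin channels, specimen-shape variability, and
stage-dependent signal. Tests passing on these phantoms therefore
demonstrate the correctness and calibration of the *statistics*, not
performance on real micrographs — segmentation quality, staining
variability, and inclusion criteria remain the experimenter's
responsibility.

The colocalization recovery check (mean r strictly increasing in α) is run
at amplitude 5, noise SD 2 rather than the generator defaults: the
measurement protocol only admits specimens with clearly detectable anchor
signal above background, and in the default weak-signal regime the
high-anchor selection is noise-dominated, which tests the selection rule
rather than the correlation. The enrichment recovery check uses the
default (weak-signal) regime, where spatial integration is doing the work.

## Numerical and interface conventions

- Coordinates are 0-based (row y, column x); masks are strictly binary.
- Projection precedes masking; rotation uses bilinear interpolation for
  images and nearest-neighbour for masks (so they stay binary), with the
  frame enlarged to hold the rotated footprint; rotation is
  counter-clockwise in array coordinates. Orientation metadata
  (rotation_deg, flip_lr) comes from the manifest, one row per sample.
- Sum projection widens the accumulator dtype (int64/float64) so deep
  16-bit stacks cannot overflow.
- All fractional pixel counts round half-up; all tie-breaks are
  lexicographic in (y, x) or documented otherwise — there is no
  platform-dependent ordering anywhere, which is what makes full pipeline
  reruns byte-identical.
- Degenerate inputs are explicit errors (constant channel for z-scores,
  single-column masks for profiles, empty regions, identical-Kav
  standards, zero-embryo groups), except where the protocol defines a
  non-error outcome (undefined colocalization, empty high-anchor
  selection, empty score table for a zero-size cohort).

## Known limitations

- The anterior fraction, threshold rule, filter σ, and bootstrap
  sidedness are conventions of this implementation wherever the protocol
  it standardizes leaves them open; all are configurable and their
  defaults are stated above.
- The bootstrap null is pooled resampling; per-group (fixed-label)
  resampling is a different null and is not implemented.
- Fisher p-values for very unbalanced tables are conservative, as usual
  for exact conditional tests.
- The SEC oligomer call assumes the calibration standards and the sample
  share hydrodynamic behaviour; elongated or glycosylated proteins break
  the apparent-MW-to-stoichiometry mapping, and the call should then be
  treated as descriptive only.
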