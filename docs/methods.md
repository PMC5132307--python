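# Methods

## The assay and its statistic

Dauer larvae that re-enter development resume feeding; arrested dauers keep
their mouths sealed. Incubating worms with 0.5 µm fluorescent microspheres
therefore converts "has this population received a food signal?" into an
imaging measurement: gut fluorescence. The per-image statistic is

    activity = (Im · Am) / Aw          [arbitrary units]

with `Aw` the worm-occupied area in the bright-field channel and `Im·Am`
estimated directly as the sum of raw fluorescence intensities over bead
pixels inside the worm region. Normalizing by `Aw` makes images with
different worm loads comparable; intersecting the bead mask with the worm
mask discards stray, un-washed beads. The experimental unit is the image.

## Segmentation model and its behaviour

The worm detector is deliberately simple and parameter-light; its two
scales derive from one measured quantity, the apparent worm width `w`:

1. **Top-hat** (disk radius = `w`, after inversion when worms are dark):
   removes background structure larger than the disk. Output is
   nonnegative; exact greyscale morphology with a disk footprint and
   symmetric (reflective) border handling.
2. **Gaussian blur** (σ = 2`w`, reflective boundaries): merges the worm
   interior into a homogeneous plateau. Reflective boundaries avoid border
   dimming that would bias the subsequent threshold.
3. **Mean threshold**: foreground = pixels strictly greater than the grand
   mean of the blurred image. The strict inequality makes the degenerate
   constant image yield an empty mask.
4. **Size filter**: 8-connected components with area < typical worm area
   are removed (strictly-smaller convention; the operation is idempotent).

Manual exclusion ROIs (simple polygons, even-odd fill, clipped to the
frame) are applied last; self-intersecting polygons are rejected because
their interior is ambiguous.

A consequence worth stating plainly: because the blur scale (2`w`) is much
wider than the worms themselves and the mean threshold sits far below the
blurred worm plateau at realistic worm densities, the resulting mask is a
*dilated envelope* of the worms, not a tight outline. On synthetic scenes
the mask recovers essentially all true worm pixels (recall ≈ 1.0) but is
several times larger than the true worm area, giving
intersection-over-union scores of roughly 0.15–0.4 depending on worm
density — with a hard ceiling well below tight-mask performance, since
narrowing the mask would require the grand mean to land within a few
percent of the blurred plateau value, which no fixed density achieves
robustly. This does not impair the assay statistic: `Aw` inflates by a
consistent factor across conditions within an experiment, and the
normalization to the positive control absorbs it, exactly as the global
fluorescence gain is absorbed. Tests therefore pin recall, structural
properties and end-to-end discrimination rather than tight-mask overlap.

## Quantification conventions

- Bead threshold comparison is inclusive (pixel ≥ threshold). Instrument
  profiles carry the threshold: 1000 counts for the confocal setup, 50 for
  the stereomicroscope setup.
- `bead_sum` uses raw fluorescence values over the intersected mask, not
  the binarized mask, matching the "sum of microsphere image intensity"
  definition of Im·Am.
- Saturated pixels are counted at their recorded value; the fraction of
  saturated bead pixels is logged per image (gain is supposed to be set to
  avoid saturation, so a nonzero fraction flags a suspect image).
- A field of view with `Aw` = 0 produces an invalid measurement (no ratio)
  rather than an exception or a zero, so unusable images are visible
  downstream.

## Statistics

- **Normalization**: percentage = 100 × ratio / mean(control ratios), the
  control being the positive-control condition (BE); "average" is the
  arithmetic mean of per-image ratios. With several solvents the control
  group is the BE group with the maximum mean ratio. Rescaling all ratios
  by a constant (global gain change) provably leaves percentages unchanged.
- **Mann–Whitney**: two-sided. Exact enumeration null when both n ≤ 12 and
  the pooled sample is tie-free; otherwise normal approximation with
  midranks, tie-corrected variance and continuity correction. The method
  used is recorded on every result. The 12-observation switch covers the
  assay's typical 4–13 images per group while keeping enumeration cheap;
  ties (frequent at 0% activity) always route to the corrected
  approximation.
- **Holm**: standard step-down (sort ascending, reject while
  p(k) ≤ α/(m−k+1)), applied to the family of all pairwise tests against
  the stated negative control within one analysis. Never more permissive
  than per-test α, never stricter than Bonferroni.
- **Tiers**: "*" p ≤ 10⁻³, "**" p ≤ 10⁻⁴, "***" p ≤ 10⁻⁵; "(*)" marks
  tests significant only after Holm correction; "ns" otherwise.
- **Dose-response**: cubic (default) least squares in an orthonormal
  polynomial basis obtained by QR decomposition of the Vandermonde matrix
  on the actual design points — the discrete Gram–Schmidt construction, so
  basis columns are orthogonal on the design regardless of spacing or
  replication. Fitted values are mathematically identical to a raw-power
  cubic fit; the orthogonal basis only conditions the problem. The 95%
  band is pointwise (not simultaneous): fitted ± t(0.975, n−p)·σ̂√hᵢᵢ with
  hat-matrix leverage hᵢᵢ. Designs need ≥ order+2 points and ≥ order+1
  distinct levels; anything less is rejected.

## Mass identification

Monoisotopic masses use IUPAC most-abundant-isotope values (≥ 8 decimals);
m/z subtracts one electron mass per positive charge (0.8 ppm at m/z 664 —
material at Orbitrap accuracy). The NAD⁺ series is assembled by composition
arithmetic from the free acid C₂₁H₂₇N₇O₁₄P₂: protonation, sequential
neutral losses of nicotinamide (C₆H₆N₂O) and water, plus [ADP+H]⁺
(C₁₀H₁₆N₅O₁₀P₂⁺), [adenosine+H−2H₂O]⁺ (C₁₀H₁₀N₅O₂⁺) and [adenine+H]⁺ —
the standard positive-mode fragmentation of a dinucleotide around its
pyrophosphate and glycosidic bonds. Compositions are validated by sub-ppm
agreement with the observed values; the default matching tolerance is
5 ppm. Subtraction guarding (no negative element counts) catches impossible
neutral-loss assignments at construction time.

## Synthetic scenes: what they emulate, and what they do not

The generator models: dark curvilinear worms (random smoothly wandering
centerline, dilated to width `w`, soft 1 px edges) on a slowly varying
illumination field (bicubically upsampled 6×6 random grid, length scale
≫ `w`); punctate bead signal confined to the middle 60% of each responder
worm's centerline ("gut"), intensity 1200–4000 counts on 16-bit against a
confocal bead threshold of 1000; sub-threshold diffuse autofluorescence
(300 counts) in all worm bodies; Poisson-count stray beads outside worms;
additive Gaussian sensor noise (σ = 40) on both channels, clipped to the
representable range. Ground truth (masks, per-worm labels, expected `Aw`,
bead sum and ratio) is recorded from the noiseless quantized channels, so
on a noise-free scene quantification on the true masks reproduces the
expected ratio exactly.

Default geometry emulates a binned 10× field: 1.6 µm/pixel, worms 13 px
wide and 250–350 px long (≈ 21 µm × 400–560 µm dauers), ten worms per
1024² frame.

Not modelled: optical PSF and focus effects, worm internal texture and
birefringence, bead clumping, motion blur, illumination flicker, and the
partial-volume appearance of real 0.5 µm beads (sub-pixel at this scale;
rendered as single-pixel puncta). Passing tests on these scenes therefore
demonstrate the pipeline's arithmetic and its robustness to the modelled
nuisances (background, noise, stray beads, autofluorescence) — not
segmentation accuracy on real micrograph texture.

## Problem sizes used in validation

- Segmentation recovery runs 20 seeded default 1024² ten-worm scenes.
- The quantification oracle compares against a naive pixel loop on 1000
  random grids up to 32×32.
- The discrimination (power) study uses scaled-down 192² three-worm scenes
  so that 200 replicates of a 10-vs-10-image experiment — each image passed
  through the full segment/threshold/measure pipeline — complete quickly;
  the comparison design itself (group sizes, test, α) is unchanged by the
  scaling. Observed: ≥ 95% Holm-corrected rejection.

## Known limitations

- The mask-envelope behaviour above: `Aw` is an internally consistent but
  inflated area estimate; absolute activity values are only meaningful
  relative to the in-experiment control (which is how the assay is defined).
- Exact Mann–Whitney p-values are not attempted in the presence of ties.
- The confidence band is pointwise; simultaneous coverage over the dose
  range is not claimed.
- ROI polygons must be simple; composite exclusions should be supplied as
  multiple polygons.
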