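# Methods

This note records the models, numerical choices and limitations behind
`chromacard`, in the order data flows through the package.

## Color model

Images are float32 H×W×3 arrays tagged with an encoding
(`srgb_encoded`, `linear_rgb`, `cielab`) and a white point; conversions
are the only way to change the tag, so gamma-encoded values can never be
silently treated as linear. The RGB↔Lab path is: sRGB transfer function
(the standard piecewise EOTF) ↔ linear RGB → XYZ with sRGB/D65 primaries
→ **Bradford** chromatic adaptation to the working white point → CIELAB.
D50 is the default white everywhere because reference palettes for print
are specified under D50; D65 is supported for simulator internals. Per-
pixel math is float32; statistics (means, covariances, CDFs) accumulate
in float64.

CIEDE2000 is implemented in full (lightness, chroma, hue and rotation
terms, kL = kC = kH = 1) with the standard conventions for degenerate
chroma (h′ := 0 when C′ = 0, ΔH′ = 0 when either chroma vanishes). It is
verified against scikit-image's independent implementation to 1e-4 on
random pairs and against published verification values (e.g. the
(50, 2.6772, −79.7751)/(50, 0, −82.7485) pair → 2.0425).

## Card model

The card carries 26 logical colors: 24 chromatic/grayscale patches plus
one black and one white reference extending the brightness range. Each
of the 24 colors is printed twice at positions relating by reflection
across both card axes (equivalently 180° rotation), giving 50 physical
patches; the black/white references appear once. The duplication is a
diagnostic: under uniform illumination both prints of an ink measure the
same color, so an inter-instance divergence above 3 ΔE00 (the
"close-examination" perceptibility band) flags glare or shadow — a
*local* fault that a global color transfer cannot repair. The flag is a
warning, not a hard stop.

The real reference palette of a commercial card is proprietary, so the
bundled default (`data/palette_default.json`) is a documented synthetic
stand-in: the classic 24-patch ColorChecker CIELAB(D50) values plus pure
black (0,0,0) and white (100,0,0). Entries outside the sRGB gamut
(notably the cyan) have their chroma scaled to 97 % of the maximum
in-gamut chroma at their lightness, so the fixture card is exactly
renderable and render→measure roundtrips are lossless. The bundled
layout places primary instances in the two left columns (13 rows),
mirrors in the two right columns, and six sample wells in the center.

Patch extraction shrinks each rectangle by 20 % per side (default)
before pooling pixels, protecting against print bleed and mask
misregistration; the two instances of a mirrored color are pooled by
default (a switch disables pooling). Extraction converts to CIELAB@D50
and reports per-patch mean, SD and pixel count.

## Correction pipeline

Stage order is white balance → MVGD → DNIL → MVGD, with patch statistics
*refit from the current image state* between stages (composing all
stages from the raw image is the alternative; refitting was chosen so
each stage corrects the residual left by the previous one, and it makes
the per-stage ΔE00 report meaningful).

- **White balance** operates in linear RGB (gains on gamma-encoded
  values would not be physically meaningful). Gains are
  reference/measured on the white patch; a channel below 1e-4 raises
  "white patch unusable" (severe underexposure). Clipped pixels are
  counted and reported.
- **MVGD** is the closed-form optimal-transport map between Gaussians,
  computed from CIELAB samples. The target sample replicates each
  palette reference with multiplicity equal to the source patch's pixel
  count, so source and target moments weight patches identically.
  Covariances get +λI (λ = 1e-4) before matrix roots/inverses; T is
  symmetrized against roundoff and is PSD by construction. Only masked
  patch pixels enter the fit; the map is applied to all pixels.
- **DNIL** matches empirical CDFs per CIELAB channel on a 256-point
  quantile grid (float32 values, not integer bins). Duplicate source
  knots are merged with their target values averaged, keeping the knot
  sequence strictly increasing and the LUT monotone. Candidate
  interpolants: piecewise linear, monotone cubic (PCHIP), cubic
  smoothing spline; a candidate whose evaluated map is non-monotone
  over the knot range is rejected for that channel. The selection
  objective — nowhere standardized, therefore configurable — defaults
  to the negative mean ΔE00 of the corrected patch means against the
  references, evaluated greedily per channel with the other channels
  held at their current values; ties break toward the simpler (earlier)
  candidate. Outside the knot range the LUT extrapolates linearly from
  the terminal knot slope (clamped non-negative) and clamps to channel
  bounds (L: 0–100, a/b: ±128). A zero-variance source channel yields
  an identity-offset LUT to the target median, with a warning.
- The final CIELAB image is converted back to sRGB; out-of-gamut
  components are clipped and counted.

An ablation harness (`PipelineConfig(bit_depth=8, ...)`) quantizes each
stage's output to 256 levels per channel and, combined with a
linear-only interpolant set, reproduces the legacy 8-bit/linear
pipeline; on the synthetic stress suite it is consistently a few
percent worse than the float32/DNIL pipeline, never better.

The pipeline is deterministic: identical inputs give bit-identical
outputs, and the fitted `TransferModel` (gains, two MVGD maps, three
LUTs) serializes to JSON and re-applies frozen to any image of the same
card.

## Illumination simulator

`render_card` paints every patch instance with its reference color
converted to sRGB (background mid-gray). `simulate_illumination`
degrades in linear RGB: a **von Kries diagonal** cast from the design
white toward the Planckian white of the requested CCT (gains normalized
to max 1 — colored light removes energy, it does not add), a brightness
scalar (the only model of lux; 0.25 is the low-light stress preset), an
optional linear shading ramp, seeded Gaussian noise, clip, re-encode.

Planckian whites come from integrating Planck's law against the CIE
1931 2° color-matching functions on the 5 nm 380–780 nm grid. The CMF
table is generated at import from the published multi-lobe
piecewise-Gaussian analytic fit (Wyman, Sloan & Shirley, JCGT 2013);
the resulting locus matches published chromaticities to < 0.0011 over
3000–6500 K and McCamy's approximation inverts it to within ~1 %. The
reference (undegraded) white is the Planckian point at 5003 K, the
design CCT, so a 5003 K spec is exactly the identity degradation —
exact D50 lies on the daylight locus, slightly off the blackbody curve,
and anchoring the simulator on the locus keeps the degradation model
self-consistent.

Two modeling consequences are worth stating plainly. First, a pure CCT
cast in this model is diagonal in linear RGB, which the white-balance
stage inverts *exactly* (given a noise-free white patch); pure-cast
recovery tests therefore validate plumbing, not the transfer stages. The
gradient, brightness and noise options supply the conditions under which
MVGD/DNIL carry the correction. Second, with a noisy source and a
point-mass (replicated-reference) target, the fitted MVGD slightly
over-shrinks the color distribution — the noise inflates the source
covariance — so on noisy inputs the post-white-balance stages can trade
a few tenths of a ΔE00 of patch-mean accuracy for distribution
alignment. Real illuminant spectra (LED/halogen phosphors off the
Planckian locus), lens shading, JPEG artifacts and card-detection
errors are not modeled; passing the synthetic suite demonstrates the
algorithms' correctness and stability, not field performance.

The five-site study generator mirrors the standard validation design:
CCTs 5800/5000/4000/3000/2700 K, three captures per site, per-capture
noise SD 0.004 in linear RGB units (a realistic handheld shot-noise
level; at 8-bit scale roughly ±1 count).

## QC statistics

All consistency protocols reduce to pairwise CIEDE2000: k replicate
measurement sets give k(k−1)/2 unordered pairs per patch (10 sets → 45
pairs; × 26 patches → 1170 values), aggregated as a flat mean/max/SD
over patches and pairs jointly. Ground-truth reports compare measured
patch means to palette references. Site studies report intra-site
(pairwise within a site's replicates, grand mean across sites),
inter-site (pairwise across sites, on per-site mean patch colors by
default — image-level pairing across sites is a switch) and per-site
versus-truth statistics.

## Assay validation statistics

The color→concentration calibrator is deliberately transparent: the
corrected well-ROI mean CIELAB is projected onto the first principal
axis of the calibration colors and concentration is affine in that
scalar (≥ 4 distinct levels required). A trained regression model could
substitute; the validation statistics below are model-agnostic.

- **Precision**: one-way variance components per level with *site* as
  the grouping factor (the full two-way day×run nested design collapses
  to the site structure actually present in multi-site phone studies;
  this is a documented simplification). Repeatability SD = pooled
  within-site SD; reproducibility SD adds the between-site component
  (method of moments, negative estimates truncated to zero, unbalanced
  designs handled via the effective group size). CV = SD/mean × 100.
- **LoB/LoD**: parametric normal-quantile forms at α = β = 0.05,
  LoB = mean_B + 1.645·SD_B, LoD = LoB + 1.645·SD_L; a nonparametric
  LoB (95th percentile of blanks) is available. Below 20 replicates a
  warning is issued.
- **LoQ**: the precision profile cv(c) is fitted with a two-parameter
  power law a·c^b by least squares on log–log scale (the variance
  function family is a package choice; the profile shape near the
  detection limit is well described by a power law) and solved for the
  target CV (default 20 %). A fitted profile exceeding the target
  across the observed range raises a dedicated "LoQ undeterminable"
  error — the expected outcome for an uncorrected, illumination-noisy
  arm.
- **Linearity**: polynomial order testing — fit orders 1–3, declare
  nonlinearity only if the highest-order coefficient of the order-2 or
  order-3 fit differs from zero at the 5 % level. When replicates share
  a site effect, the test should be applied to level×site cell means;
  raw correlated replicates inflate the type-I error of the polynomial
  terms (the acceptance script does this).

The synthetic assay generator emulates the validation design (five
levels 1.5–9 g/dL, 3 sites, 6 replicates; within-SD 0.35 g/dL,
between-site SD 0.25 g/dL for the corrected arm — chosen to sit in the
CV range reported for corrected smartphone colorimetry) plus an
`illumination_sd` term representing residual ambient-light error, zero
for the corrected arm and dominant for the uncorrected arm. It
generates predictions directly rather than images; it cannot test the
image→feature path (the card simulator covers that) nor matrix effects
or reagent kinetics.

## Problem sizes and determinism

Synthetic cards are rendered at 180×300 px (≈ 165 px per patch instance
after shrink), which puts every Monte-Carlo statistic used in the test
suite well inside its tolerance while keeping a full five-site
before/after study under a minute on one core. MVGD/DNIL accuracy
checks use 10⁵/10⁴ samples. Every stochastic component takes an
explicit seed; the pipeline itself has none.

## Known limitations

- Card detection/rectification from cluttered photographs is out of
  scope; inputs are pre-rectified card images.
- Glare/shadow are flagged (mirror divergence), not corrected.
- The default palette is a stand-in; quantitative claims about a real
  card require its measured palette.
- Illuminant model is Planckian-only; real mixed spectra sit off-locus.
- The precision design is one-way (site); day/run/operator components
  are not separated.
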