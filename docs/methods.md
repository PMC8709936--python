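# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `gazefuse`.  Empirical statements here are the ones the
test suite and `scripts/acceptance.py` compute; nothing else is claimed.

## Coordinate and transform conventions

Pixels are 0-based, centers at integer coordinates, x rightward, y
downward.  All rigid transforms belong to the center-pivoted family
`T(p) = R(θ)(p − c) + c + t` with `c` the geometric center of the
untransformed image; this family is closed under composition and
inversion for a shared pivot, which keeps the consensus algebra linear.
A `RegistrationResult` stores, per image, the transform into the anchor
image's pixel frame; a pairwise estimate for `(i, j)` maps image j's
coordinates onto image i's.  Gaze offsets are abstract planar degrees:
no nasal/temporal convention is imposed, because none is needed
computationally.

## Registration

**Low-pass filter.** A normalized circular-mean (pillbox) kernel,
default radius 25 px, reflect boundary (implemented as FFT convolution
on a mirror-padded image).  "Radius" naturally describes a pillbox; a
Gaussian would need a σ convention.  The filter suppresses the cone
mosaic and shot noise that would otherwise dominate the correlation
spectra.  It is used *only* for registration; fusion always consumes
native intensities.

**Pairwise estimation.** Every unordered pair whose nominal overlap
(from the manifest gaze offsets and the field width) is ≥ 20% is
estimated.  Two candidate estimates are formed:

1. *Seeded*: both filtered images are cropped to the nominally
   overlapping region, so phase correlation only has to find the small
   residual due to fixation error rather than a shift comparable to the
   image size.  Rotation is estimated first on the crops by the
   Fourier–Mellin construction — Hann window, centered log-magnitude
   spectrum with the DC region suppressed, log-polar resampling, phase
   correlation along the angle axis.  The radial (scale) channel is part
   of the same resampling but its shift is discarded: fixational eye
   movements translate and cyclotort the retina, they do not rescale it.
   The angular peak uses plain (unwhitened) correlation: full whitening
   anchors on residual windowing artifacts shared by the two spectra and
   snaps sub-degree rotations to zero.  After derotation, the residual
   translation comes from whitened phase correlation of Hann-windowed
   crops, and the full-image transform is recomposed analytically from
   the crop offsets.
2. *Blind*: full-frame phase correlation with no prior, so the data can
   override a wrong manifest (two identical images declared 2° apart
   register at zero shift).

Candidates are ranked by a masked Pearson correlation of the warped
overlap (this score, clipped to [0, 1], is also the pair quality used
downstream), and the winner is polished by a robust intensity fit:
Levenberg–Marquardt-style least squares over (dx, dy, θ) on
difference-of-Gaussian band-passed native images, evaluated on a pixel
set frozen at the seed transform (a moving support would make the
objective discontinuous), with a Cauchy loss so pixels where the two
views *genuinely* differ — gaze-modulated lesion rims, which are signal
downstream — act as outliers rather than bias.  The polish runs
coarse-to-fine: first on a 3–12 px band that excludes the quasi-periodic
cone mosaic (wide convergence basin), then on a 1.5–8 px band that
includes it (precise subpixel lock).  Whitened phase correlation alone
is *not* sufficient on very clean images: with no noise, whitening
resurrects the heavily attenuated mosaic lattice and can lock onto a
lattice-aliased peak; the candidate scoring plus coarse-band polish is
what makes the estimator robust across noise levels.

**Global consensus.** Pairs with quality below `q_min = 0.1` are
dropped; every image must remain connected to the anchor (by protocol
the central, straight-ahead image), else the run fails with the images
named — mirroring the real failure mode of inaccurate fixation or poor
image quality.  The retained pairs enter a quality-weighted linear least
squares.  When the image shape is known, each pairwise constraint is
expressed as point correspondences `T_i(q_i) = T_j(q_j)` at five points
spread across that pair's overlap rectangle, plus a weakly weighted
rotation-difference row, solved by three Gauss–Newton relinearizations.
The reason for the correspondence form: a pair whose shared content sits
in an off-center corner (the 25%-overlap diagonal pairs) constrains
rotation and translation only in a nearly degenerate combination;
sampling the mapping where the data actually lives keeps that degeneracy
from leaking correlated errors into the mosaic.  Without an image shape
(pure offset input), a plain relative-constraint solve is used; with
only anchor-pairs present, both reduce to averaging each image's
pairwise offsets.

Measured on phantoms (the acceptance script recomputes this): with true
shifts up to ±60 px and rotations up to ±2°, all nine transforms are
recovered within 0.5 px and 0.2°, typically 0.1–0.3 px.  On the full
±2° protocol (150 px nominal shifts, 25–50% overlap) recovery is
typically 0.2–0.4 px but can reach ~0.5–0.9 px for unfavorable lesion
layouts; immediate axis-aligned neighbor pairs are individually accurate
to 0.5 px / 0.2°, while corner-overlap pairs are reliable only inside
their overlap (by design, per the above).

**Canvas assembly.** The canvas is the union bounding box of all
transformed footprints in the anchor frame (near-integer bounds snapped
within 0.01 px so estimation noise cannot pad a spurious pixel).  Native
images are resampled bilinearly; any output pixel whose interpolation
support is not fully inside the source is undefined (NaN + mask) — the
conservative choice, so no fused statistic ever draws on fabricated
intensities (verified by poisoning undefined pixels and asserting
unchanged output).

## Fusion

All statistics use the sample (n−1) convention.  Consequences: the
two-sample SD of a pair is |xᵢ−xⱼ|/√2, max-pair SD equals (max−min)/√2
over the defined values, and max-pair SD ≥ the overall sample SD with
equality exactly at coverage 2 — the dominance property the test suite
asserts.  "Covariance" is defined as the absolute mean pairwise
deviation product, which is analytically variance/n; it behaves like
variance up to scale.  Minimum coverage is 1 for sum/mean and 2 for the
dispersion statistics; pixels below it are undefined.

**Photometric normalization** (default on before SD-type fusion): each
layer is linearly rescaled so its mean and SD over the pixels mutually
defined with the anchor match the anchor's.  Per-acquisition gain and
offset drift would otherwise masquerade as gaze-dependent signal.
Layers sharing no defined pixel with the anchor are left unchanged with
a warning — with the standard protocol this affects at most the
far-corner images and only when few pairs survive.

**Display export** percentile-normalizes (0.5–99.5% of defined pixels)
before integer quantization; raw statistic values are written separately
as 32-bit float TIFF so no analysis is run on display-scaled data.

**Directional fusion** is the per-pixel sample SD across an already
co-registered, fixed-field stack — mathematically `fuse(stat="sd")` on a
fully defined stack.

## The phantom

The generator emulates the acquisition, not the optics.  A master
"retina" (~9°×9° at 75 px/deg) carries:

- a jittered hexagonal cone mosaic (spacing 6 px, Gaussian spots
  σ 1.5 px, amplitude ~15 on a baseline of 100) — at this resolution a
  stylized texture, not an anatomically scaled mosaic;
- a smooth random fundus field (amplitude 8, correlation length
  ~0.3–0.5°) standing in for the large-scale structure real images have
  and registration needs;
- lesions: drusen as annuli (Gaussian rim whose FWHM is 20% of the
  radius, clipped to 1.5–10 px; darker center), SDDs as lower-amplitude
  rings, atrophy as static hyper-bright patches.

Rim brightness is modulated per rendered view by
`1 + polarity · amplitude · e · cos(φ − ψ)`, where ψ points from the
window center toward the lesion and e is the lesion's eccentricity
fraction within the field (0 center, 1 edge).  Polarity is +1 for drusen
(near-edge margin brighter), −1 for SDDs, 0 for atrophy; default
amplitudes 0.5 (druse) and 0.25 (SDD, reflecting their lower contrast).
This is a minimal phenomenological model: only the sign and
monotonicity of the modulation are meaningful, the true functional form
in vivo being unknown.  Directional-mode rendering reuses the same model
with the beam's pupil displacement in place of gaze eccentricity at 0.4×
amplitude, so the gaze-vs-directional contrast ordering is exercisable;
the 0.4 factor is a modeling choice, and only the ordering (not the
ratio) is asserted anywhere.

Acquisition variability: fixation error N(0, 0.1°) per axis, torsion
uniform ±1°, gain jitter 3%, offset jitter 2 units, additive noise σ 2
(2% of the baseline).  Defaults for the default phantom: 10 drusen,
2 SDDs, 2 atrophy patches, diameters log-uniform in 11–320 µm (drusen
populations are dominated by small deposits), placed within ±2.5° with
rejection sampling; failures are placed anyway and flagged confluent,
since confluent drusen are a real presentation.

**Scale note.** Physical sizes convert to pixels through the device
scale 0.77 µm/px, while the rendering grid is 75 px/deg for speed.
These are mutually inconsistent with the ~288 µm/deg of a real eye (a
real device at 0.77 µm/px is ~374 px/deg); the phantom accepts this so
that micron arithmetic round-trips exactly (a catalogued 100 µm druse
renders with a 130 px outer rim and measures back to 100 µm), at the
cost of lesions being ~5× larger in angular terms than reality.  Margin
geometry, not angular subtense, is what the pipeline's claims depend on.

**What passing phantom tests does and does not show.**  They show the
pipeline's mechanics are correct: registration recovers known
transforms, the statistics equal their oracles, modulated structures
rise above background while static ones do not, and polarity behaves as
modeled.  They do not validate the biological model (the cosine
modulation is invented), nor performance on real FIAO data with
vasculature, uncorrected aberrations, intra-frame distortion, or
pathology-induced quality loss.

## Detection and suppression statistics

For scoring fused images against phantom truth, a druse counts as
detected when the upper quartile of its margin-ring pixels exceeds the
99th percentile of the lesion-free background — the quartile, because
the cosine modulation leaves roughly half of each rim unmodulated in any
single view, so the enhancement concentrates in an arc.  Atrophy is
summarized by its region median (the claim is about the static region as
a whole, not a margin).  On the default phantom at the standard
conditions all ten drusen margins clear the threshold and both atrophy
regions stay below it; across other seeds detection is typically
80–100%, the misses being drusen near the protocol's periphery where
only two views contribute and tiny (<20 µm) rims are blurred by
resampling.  Lesion-free, variability-free acquisitions (the
young-control analogue) fuse to a 99.9th percentile below 0.5% of the
background dynamic range — the floor set by residual registration and
interpolation error.

## Quantification conventions

- Diameter = 2 × major semi-axis × scale (default 0.77 µm/px).
- Size classes: small < 63 µm, intermediate 63–125 µm (both boundaries
  inclusive), large > 125 µm.
- Count comparisons default to test/reference × 100% (so 25 vs 10 reads
  as 250%); percent increase is available but not default.
- Intergrader variability = coefficient of variation, 100 × sample
  SD / mean, the standard reading when no formula is specified.
- ROI tables normalize a < b rows by swapping axes and rotating the
  angle 90°, with a warning, so the major axis is always `a`.
- `detect_blobs` (threshold + hole-filling + connected components) is a
  scoring aid for phantom experiments only; it makes no claim of
  replicating human grading, which the measurement conventions above
  were designed for.

## Numerical details and edge cases

- Phase correlation refuses constant inputs (undefined spectrum phase)
  and reports shifts in the principal interval; callers with a prior
  unwrap toward it.
- The rotation estimator returns θ in (−45°, 45°] (the spectral
  magnitude's 180° symmetry makes larger angles ambiguous) and falls
  back to 0 with a low quality score on an ambiguous peak.
- Writing images maps defined pixels linearly onto the full integer
  range (constant images to mid-gray), undefined pixels to 0; round
  trips preserve relative intensities to quantization (correlation
  > 0.999 at 16 bit).
- All randomness flows through `numpy.random.default_rng` seeds;
  identical seeds give byte-identical phantoms, renders, and CLI
  outputs.

## Problem sizes

Tests and the acceptance script run the protocol at 300×300 px views
(75 px/deg), nine views per set, with full pipeline runs taking a few
seconds each; the fusion oracle sweeps 200 random 16×16 masked stacks
of 2–9 layers.  These sizes exercise every code path at comfortable
margins over the tolerances asserted.
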