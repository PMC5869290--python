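# Methods

This note records the models, numerical choices and limitations behind
`spectromics3d`, in the order the pipeline runs.

## Spectral model

All spectra live on one uniform, strictly decreasing wavenumber grid
ν_k = start − k·step.  The default instrument grid is 1800 cm⁻¹ down in
4 cm⁻¹ steps for 225 channels, so the last channel is 904 cm⁻¹; 900 cm⁻¹
itself is not a grid point (`floor((1800−900)/4) = 225`).  Band windows are
closed wavenumber intervals; window limits that fall off the grid (1710,
1027, …) simply bound the channel selection — there is no nearest-channel
rounding, which keeps the discretisation deterministic and tie-break free.
Band integrals are trapezoidal against ν with positive orientation; on a
uniform grid this makes adjacent windows sharing a boundary channel exactly
additive.  A single-channel (degenerate) window integrates to zero width.

Second derivatives are Savitzky–Golay, default window 7 channels
(28 cm⁻¹) and polynomial order 3 — standard for protein-region spectra at
4 cm⁻¹ sampling; both are configurable.  The derivative is stored as
d²A/dν², so absorbance peaks give negative lobes, and edge channels come
from the filter's one-sided fits.  The filter is exact for polynomials up
to the fit order but *attenuates* narrow bands: a σ = 8 cm⁻¹ Gaussian loses
roughly 40 % of its negative-lobe area at these settings.  The attenuation
is a fixed multiplicative shape factor, identical wherever the band shape
is identical, so the assay-anchored calibration absorbs it; band areas must
therefore never be compared across different SG settings.

Band ratios return NaN when the denominator area is at or below 1e-12 of
the full-range area of a unit spectrum.

## Phantom

The phantom supplies the study conditions for every test: two hemisphere
ellipsoids plus a cerebellum lobe on a 20 µm isotropic grid, a white-matter
core at 0.45 of each hemisphere's radii (white matter is a modest fraction
of the mouse brain), and an ellipsoidal tumor in the right hemisphere.
Tissue spectra are sums of Gaussian bands: amide I 1655, amide II 1545,
lipid ester 1740 cm⁻¹ (σ = 12 cm⁻¹) and glucose 1031, glycogen 1024 and
1162, lactate 1127 cm⁻¹ (σ = 8 cm⁻¹).  The glycogen centres follow the
quantification windows (1024/1162 pairing with 1027–1018 and 1167–1157
cm⁻¹).  Metabolite band amplitudes are linear in concentration with one
shared peak absorptivity of 0.05 a.u. per µmol g⁻¹, split evenly over a
metabolite's bands (glycogen's two bands carry half each) — a species'
absorbance distributes over its bands.  Healthy tissue carries the
enzymatic-assay cohort means (2.2 / 5.1 / 1.2 µmol g⁻¹ of glucose /
glycogen / lactate); the tumor carries the Warburg-effect profile
(0.8 / 1.2 / 2.4), is protein-rich and lipid-poor.  Additive Gaussian noise
(default SD 0.014 a.u., 2 % of the gray-matter amide I amplitude) is
clipped at zero absorbance.

Sectioning cuts one plane per 20 µm across the occupied extent and
alternates sections between the IR and histology series, as when every
other frozen section is stored for staining.  Each section is distorted by
an anisotropic shrink (means 11 % in height, 8 % in width — the deviations
observed when correcting real sections — with 2 % jitter), a small rotation
(SD 1°) and translation (SD 1.5 px), and with probability 0.1 a straight
tear that rigidly offsets one side by up to 3 px.  Spectra ride along
unchanged pixel-by-pixel (nearest resampling).  All randomness derives from
one seed via independent spawned streams, so runs are bit-reproducible.

What the phantom does **not** emulate: scattering and baseline artefacts,
instrument drift between sections, folds (tears are the only defect class),
partial-volume section thickness effects, and continuous within-class
chemical gradients — classes are spectrally homogeneous up to noise.
Passing tests therefore demonstrate the correctness of the processing
chain, not robustness to every artefact of real measurements.

## Shape correction

Virtual masks are the reference volume's planes at the section spacing
across its occupied extent; planes inside the extent that miss the organ
stay as empty masks to preserve section order.  Sparse atlas stacks are
completed by shape-based interpolation: signed Euclidean distance
transforms, linear interpolation along the stack, threshold at zero.  At a
knot the input mask is returned bit-exactly, and the scheme is monotone for
nested inputs.  The choice of signed-distance interpolation is this
package's; nothing canonical exists for completing masks between atlas
planes.

Label correction maps each target-mask pixel into the source image by the
moment affine (centroids, principal axes resolved toward the identity —
sections are nearly upright — and per-axis SD scaling) and resamples labels
nearest-neighbour; samples landing outside the source foreground are moved
to the nearest source foreground pixel (a distance-transform-guided
displacement).  By construction the output foreground equals the target
mask and no new labels appear.

IR correction applies the same geometry forward, as mass redistribution:
every source pixel is split into 4×4 sub-pixels each carrying 1/16 of the
pixel's spectrum, mapped to the target frame, and deposited with bilinear
weights; deposits falling outside the mask are redirected to the nearest
mask pixel so boundary pixels lose no mass.  A single global
renormalisation then makes the output's total spectral absorbance equal the
input's exactly (float64 throughout; the per-section residual before
renormalisation is reported so genuinely lossy warps remain visible, and is
typically at machine precision).  A shrunken section therefore comes back
with uniformly lower per-pixel amplitude (its mass spread over the larger
mask); the scale cancels in calibration because the anchor is measured on
the same corrected data.

Coordinates are pixel centres, 0-based, row = image height; masks and
corrected slices share the reference volume's in-plane grid.

## Reconstruction

After correction each slice's foreground equals its mask, so alignment
reduces to the integer translation matching foreground and mask centroids
(recorded per slice); rotation was already absorbed by the correction and
no further resampling occurs.  Alternating series are reconstructed at
their physical section z — missing planes are neither duplicated nor
interpolated — so a series covering every other 20 µm plane has an
effective 40 µm plane spacing, which volume and surface computations use as
the z voxel dimension.  Display intensity scaling is metadata only; stored
spectra are never rescaled.

## Quantification

Band areas are Σ_windows ∫ max(−A''(ν), 0) dν × 10⁴, i.e. the magnitude of
the negative lobes only, reported in a.u.² × 10⁻⁴.  Signed or
absolute-value alternatives would let positive side-lobes of neighbouring
bands contaminate the area.  Rejection is two-stage and single-pass: exact
zeros first (a voxel whose window shows no negative lobe at all), then one
mean ± 3 SD trim (sample SD, inclusive comparison) on the nonzero values —
no iteration to convergence.  Calibration divides the assay reference
concentration by the mean retained band area of the healthy calibration
region (the occupied voxels left of the occupancy-centroid sagittal plane,
minus the chemical tumor segmentation), making the mean mapped healthy
concentration equal the reference to machine precision — asserted on every
run.

Region statistics re-run the two-stage rejection *within* each region.
The healthy hemisphere and the tumor have deliberately different
distributions; trimming the tumor against the whole-volume mean would
reject most of it and destroy the contrast being measured.  The whole-cube
rejection still defines the exported map's inclusion mask (NaN = rejected),
and both retention fractions (per region and whole-volume) are reported.
Group comparisons use Welch's unequal-variance two-sided t-test
(significance 0.05); identical zero-variance samples are reported as
indistinguishable (p = 1).

Two known limitations.  First, the glucose and glycogen windows meet at
1027 cm⁻¹ and the underlying bands overlap; no spectral unmixing is
applied, leaving a deterministic cross-talk bias of about −6 % on the
recovered tumor glucose and under 1 % on glycogen at the phantom's
composition.  Second, trimmed anchored calibration mis-specifies when the
calibration region is strongly bimodal with a rare minority mode: a tissue
class contributing only a few percent of voxels at areas more than 3 SD
from the mixture mean is excluded wholesale by the trim, biasing the
factor.  With continuous regional gradation (or a minority fraction above
roughly 15–20 %) the trim behaves as intended.

## Segmentation and comparison

The chemical tumor segmentation thresholds the protein-to-lipid ratio map
(Otsu over defined foreground ratios by default, or a fixed threshold) and
keeps the largest 26-connected component; the display-style inverse ratio
×100 is available as a preset.  Otsu on data with few distinct values
(label-image green channels) uses an exact search over unique-value cuts,
because histogram-binned Otsu can return a threshold inside the bin holding
a mode and split that mode across classes.  Surfaces are marching-cubes at
the 0.5 level of the zero-padded binary mask, vertices in µm with the
series' z spacing.  The Hausdorff distance is the symmetric max (or 95th
percentile) of nearest-neighbour distances between surface vertex sets —
the volumes being compared are meshed surfaces, not voxel sets — and the
per-point distance fields are returned for distance-coloured rendering.
Percent volume difference is reported under both denominator conventions
(reference/histological and other/chemical) because published percentages
appear under either reading; the configured default is the histological
reference.

## Problem sizes

The default phantom is a (56, 48, 64)-voxel volume at 20 µm, cut into 52
sections (26 IR + 26 histology) of 48×64 pixels × 225 channels — a
deliberately compact stand-in for a full-scale experiment (hundreds of
sections, megapixel grids) chosen so that the complete chain, including
every validation, runs in well under a minute.  All statistics that matter
(calibration closure, recovery, significance) are computed on thousands of
voxels per region and are insensitive to this scale.
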