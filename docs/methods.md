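# Methods

Definitions and conventions used by `poremap`. All angles are **axial**
(π-periodic orientations, not directions), in degrees, counterclockwise
positive with 0° along the image horizontal axis and the y axis pointing
up, folded to [−90°, 90°).

## Riesz gradient and structure tensor

The gradient is computed in the frequency domain with the Riesz filter
pair, transfer functions `−i·u/‖(u,v)‖` and `−i·v/‖(u,v)‖` with zero DC
response. The image is mirror-padded (pad = min(64, min(shape)/2)) before
the FFT to suppress wrap-around; a constant image yields exact zeros.

The structure tensor is the Gaussian-windowed outer product of the
gradient, `J = W ∗ (g gᵀ)` with window sigma `window_sigma_px`
(default 2 px, scipy mirror boundary). Derived maps:

* **energy** `E = Jxx + Jyy` (trace; local gradient activity),
* **coherency** `C = √((Jxx−Jyy)² + 4Jxy²) / E ∈ [0, 1]`, NaN where `E`
  vanishes (flagged, never silently zero),
* **orientation** `θ = ½·atan2(−2Jxy, Jxx−Jyy) + 90°`, i.e. the *line*
  direction (perpendicular to the dominant gradient); the sign flip on the
  mixed term converts the array's row-down convention to y-up.

Validated against a definition-level spatial-domain convolution oracle
and by rotation-equivariance tests (gratings rotated by 15/30/45° shift
the recovered mean by the same amount within 1°).

Practical note: textures assembled from *short* soft-ended segments carry
broadband orientation content near the end caps and can bias the global
circular mean by several degrees. The synthetic generator therefore
accepts explicit `length_um`/`width_um`; single-orientation validation
textures use frame-spanning fibres.

## Monogenic signal

Single scale, chosen explicitly (`scale_px`, default 8 px = band-pass
centre wavelength). The band-pass is an isotropic log-Gabor with
σ/f₀ = 0.55 (≈ two-octave bandwidth) and zero DC. With band-passed image
`I` and Riesz pair `(R₁, R₂)`:

* amplitude `A = √(I² + R₁² + R₂²)` — invariant to local phase (e.g. to a
  quarter-period grating shift),
* phase `φ = atan2(‖R‖, I)`, signed by the vertical Riesz component:
  `|φ| ≈ 0` bright ridge, `≈ π` dark ridge, `≈ π/2` edge,
* orientation `atan2(−R₂, R₁) + 90°`, folded to [−90°, 90°).

Contrast inversion maps the unsigned phase `φ → π − φ` and leaves the
amplitude unchanged. `enhance_modulus` percentile-clips and
gamma-compresses the amplitude for display; the mapping is monotone.

## Co-occurrence texture descriptors

Images are quantized to `levels` equal-width bins (default 32). A GLCM at
distance `d` and angle θ counts quantized-value pairs at the pixel offset
(dcol, drow): 0° → (d, 0), 45° → (d, −d), 90° → (0, −d) (y-up angles).
Matrices are symmetrized (transpose added) and normalized to sum 1.
Distance 0 is supported and is, by construction, the diagonal
self-co-occurrence matrix (its trace equals the pixel count before
normalization).

Each matrix yields **23 named descriptors** (`DESCRIPTOR_NAMES`):
angular second moment, contrast, correlation, sum-of-squares variance,
inverse difference moment, sum average, sum variance, sum entropy,
entropy, difference variance, difference entropy, the two information
measures of correlation, autocorrelation, dissimilarity, cluster shade,
cluster prominence, maximum probability, inverse difference, the two
normalized inverse-difference variants, sum-of-squares intensity, and the
maximal correlation coefficient. Entropies use log₂ (bits); the second
information measure is `√(1 − 2^(−2(HXY2 − HXY)))`; the maximal
correlation coefficient is the square root of the second-largest
eigenvalue of the standard Q matrix. All 23 are verified against an
independent loop-based implementation to 1e-10, and pair counting against
both brute-force enumeration and `skimage.feature.graycomatrix`.

The feature table (rows = image × distance × angle, columns =
descriptors) is standardized per column (population std; constant columns
map to 0 with a warning) before PCA (scikit-learn SVD). Explained
variance is reported in percent.

## Nuclei statistics

Segmentation is a deterministic classical recipe: background subtraction
by morphological opening with a disc of 5× the expected nucleus radius;
Gaussian smoothing (σ = 1 px); a robust amplitude test (99.5th percentile
minus median against a median-centred MAD noise estimate) that returns an
empty mask for blank or pure-noise frames; thresholding at half the
robust amplitude (tracks the nominal boundary of soft-edged nuclei better
than Otsu, which lands in the skirt and inflates coverage);
distance-transform peak markers (or optional Laplacian-of-Gaussian
seeds); watershed on the negative distance transform to split touching
nuclei; and an area filter [min_area_um2, max_area_um2] with consecutive
relabelling. Reported statistics: object count, per-object areas in µm²
(full object areas even when an ROI clips them), and percentage coverage
over the ROI. The reference ROI is 350 µm × 350 µm; the seeded ROI
sampler avoids an exclusion mask (e.g. pore pixels).

## Polar statistics

Circular summaries double the angles, average unit vectors, and halve the
mean back, so a resultant length of 1 means perfect alignment and 0 an
isotropic field. Histograms are binned over [−90°, 90°) (default 72 bins)
with optional energy weighting, ROI restriction, and restriction to
high-energy features (top 5% of the energy map by default, or Otsu).
Display scaling multiplies the plotted curve only; normalized weights and
summaries are invariant. The two-sample comparison is a permutation test
on the distance between mean resultant vectors of angle-doubled
pseudo-samples drawn from the histograms.

## Pattern design

For a lattice of circular through-pores of diameter `d` on pitches
`(p_x, p_y)`, porosity is `π(d/2)²/(p_x·p_y)`. Rasterization uses s×s
supersampling per pixel for sub-pixel-accurate coverage (within 0.1% of
the analytic value at 0.25 µm/px, supersample 4). Ion fluence in pC/mm²
converts to ions/mm² via the elementary charge (1.602176634 × 10⁻¹⁹ C),
assuming singly charged ions: 122,293 pC/mm² → 7.6 × 10¹¹ ions/mm².

## Synthetic scenes

Filament orientations are drawn from an axial von Mises distribution
(angles doubled before sampling, κ = 0 meaning uniform), optionally per
rectangular domain. Noise models: additive Gaussian or Poisson, with SNR
referenced to the **foreground** level (mean over pixels above 10% of
max), so sparse scenes are not trivially noise-free. Nuclei are
soft-edged (logistic profile) discs with exact label masks; pore scenes
multiply the texture by zero inside pores with an optional linear
depletion-halo ramp. Identical (seed, spec) inputs are bit-identical.

### Limitations

The generator produces straight filaments, circular nuclei and sharp pore
edges; it does not model filament curvature, intensity vignetting,
out-of-focus light or anisotropic point-spread functions. Recovery
numbers quoted in the acceptance report are therefore upper bounds on
what the same pipeline achieves on real micrographs. Problem sizes used
in tests (frame sizes, filament counts, scene counts) are the package's
own choices, balancing statistical power against a desk-scale runtime.
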