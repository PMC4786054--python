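# Methods

## The detection cascade and its noise algebra

The simulated detector is a 1024×1024-pixel p-t-CCD module for
monoenergetic 12 keV X-rays at normal incidence. Detection is modelled
as a chain of independent stochastic stages; each stage contributes its
relative variance, normalised by the number of quanta entering it, to
the relative variance of the stored charge. For a region of interest
receiving a Poisson-distributed n̄ X-rays:

| stage | model | parameter (default) |
|---|---|---|
| phosphor absorption | binomial | q̄ₐ = 0.85 |
| scintillation gain | gamma distribution | ḡ = 281.5, σ_g = 163.3 photons |
| optical chain + CCD QE | binomial per photon | t̄ = 0.50·0.14·0.70·0.35 = 0.01715 |
| photoelectron yield | deterministic | ē = 1 |
| ADC | g_ADC = 0.2 ADU/e⁻ | read noise σ_r = 10 e⁻, quantization U(1 ADU) |

Folding the chain gives the cascade factor
γ = 1 + (σ_g/ḡ)² + (1/t̄ − 1)/ḡ = 1.5401 and, per pixel, the factor
ψ = (g_ADC σ_r)² + 1/12 = 4.083 ADU². The variance of a bias-corrected
region sum p over N pixels is γ·G·p + N·ψ with G = ḡ t̄ ē g_ADC. The
pseudo-quantization model (uniform error over 1 ADU) is valid because
the read noise spans 2 ADU > 1 ADU. ē is carried as a parameter, fixed
at 1, so the algebra stays general; count-unit and ADU-unit variances
are one operation viewed at two scales (divide by G, G²), not two
formulas.

The ADU-per-electron reading of g_ADC = 0.2 is adopted: it is the only
value consistent with the signal equation p = g_ADC·m and the printed
gains (an "electrons per ADU" label would make it 5, which is the same
conversion stated in the other direction).

## Simulator

Photons are treated individually. The scintillation spectrum is a
gamma distribution matched to (ḡ, σ_g) and stochastically rounded to
integers (mean-preserving); every region-sum statistic of the cascade
depends on the spectrum only through these two moments. Each emitted
photon is displaced by a radial PSF draw and survives the optical chain
with probability t̄. Because survival is independent of position, the
implementation thins each shower *before* displacing the survivors —
statistically identical to displacing all ~280 photons per event and
thinning afterwards, and an order of magnitude cheaper; the literal
stage-by-stage path is also exposed and the equivalence is tested.

**PSF.** The full-system PSF (phosphor plus the rest of the optical
chain) is a two-component radial mixture: an isotropic Gaussian core
(σ = 16 µm, weight 0.5) and a Gamma(2, 35 µm) radial tail, giving a
radial intensity profile with FWHM = 38.6 µm and FW10%M = 77.8 µm at
the detector face — inside the phosphor-alone envelope (< 40 µm,
< 100 µm) that the hardware constraints set. The width matters only for
inter-pixel correlation (and hence the profile-fitting results); region
sums are invariant to it. Sized much below this envelope, showers no
longer split across the 30 µm CCD pixels and the raw-image
profile-fitting variance ratio collapses toward γ alone, contradicting
the PSF-driven correlation this detector class exhibits.

**Taper.** Demagnification 2.7:1 with a radial cubic distortion
r_ccd = (r/2.7)(1 + k₂r²), k₂ = 4.19·10⁻¹² µm⁻² — a pincushion
displacing the grid by ~3 corrected pixels at the face edge.
Bijectivity (monotonicity of r_ccd(r)) is checked at construction; the
inverse is a dense monotone lookup table (sub-µm accurate).

**CCD.** Photoelectrons are binned into 30 µm pixels; dark current
0.01 e⁻/pixel/s, Gaussian read noise, round-half-even digitization,
bias 500 ADU, clipping at 65535. Coordinates: face pixels are 0-based
73 µm squares (pixel i spans [73i, 73(i+1)) µm), CCD pixels 0-based
30 µm squares; radial maps are centred on each grid's centre.

## Correction chain

Order: dark subtraction (removes the bias), flat-field division,
distortion correction. The flat field is the average dark-corrected
flood scaled by each CCD pixel's effective collection area — the
back-projected quadrilateral area through the taper, since the
distortion is non-area-preserving — and normalised to mean 1. The
distortion correction reapportions each raw pixel value over the
orthogonal 73 µm face grid in proportion to clipped-polygon overlap
areas (Sutherland–Hodgman clipping of the convex quadrilaterals against
pixel rectangles, shoelace areas). Quadrilaterals partly outside the
corrected window contribute their in-grid fraction; the lost total is
reported, and the per-raw-pixel kept fractions are exposed so the
effective raw-pixel counts of a corrected-image measurement box can be
computed. Corrected images keep full precision internally; the stored
16-bit form re-adds a configurable pedestal (default 10 ADU). Flood
fields for the flat build default to 100 images at 100 X-rays/pixel.

## Integration

The measurement box follows the MOSFLM parameterisation: odd side
lengths NX, NY; rim widths NRX, NRY; corner cut-off NC. Pixels with
|dx|+|dy| ≥ NC are assigned to the *background* (not discarded) — the
box renders cut corners as background and mm symmetry is preserved;
this choice is isolated in one mask-construction function. For the
reference box (23, 23, 5, 4, 11): M = 171 peak and N = 358 background
pixels.

Boxes are defined on the corrected (73 µm) grid. When integrating raw
images the same *physical* box is used: every parameter is scaled by
the face-to-CCD pixel-size ratio 73/(30·2.7) ≈ 0.90 and rounded (sides
to odd integers), giving (21, 21, 5, 4, 10) with M = 131, N = 310. The
alternative — reusing the corrected-pixel parameters verbatim on the
30 µm raw grid — would integrate a ~23% larger solid angle of
background and shift every background-dependent statistic upward.

Background: unweighted least-squares plane over the background pixels;
by mm symmetry its interpolated sum under the peak equals (M/N)·Σ_bg,
so the summation intensity and its variance use the region-sum algebra
directly. Two variance estimates are computed per spot: the classical
independent-Poisson form G·(I_S + I_bg(1 + M/N)) and the cascade form
γG·P_peak + M_raw·ψ + (M/N)²(γG·P_bg + N_raw·ψ). With γ = 1, ψ = 0 the
two coincide identically. On corrected images the raw-pixel counts
M_raw, N_raw default to the corrected-box counts (a slight, documented
overestimate); exact fractional counts from the distortion map are
available.

**Profile fitting.** A reference profile (mean of 20
background-plane- and pedestal-corrected boxes, integer-rounded) is
fitted jointly with a background plane — four parameters — over all box
pixels, I_P = K·Σprofile. In the classical mode the weights assume
independent Poisson pixels (per-pixel variance G·ρ, floored at 1 ADU)
and Var(I_P) is the normal-equations variance scaled by the weighted
reduced χ² of the fit, i.e. an error based on the quality of fit of the
profile. This is the estimator whose optimism the package quantifies:
pixel correlations smooth both data and profile, shrink the apparent
residuals, and the estimate collapses (most severely on
distortion-corrected images, and nonuniformly with grid registration).
In the GLS mode a banded empirical variance–covariance matrix **M**_f
(covariances to lag 7 in X and Y, zero beyond) replaces the diagonal
weights and Var(I_P) comes directly from (AᵀM_f⁻¹A)⁻¹.

**M_f estimation.** Banding a sample covariance can break positive
semi-definiteness, and distortion-corrected pixels are nearly linearly
dependent (near-null directions at quantization-noise scale would
dominate the GLS inverse). Eigenvalues are therefore clipped at 1% of
the mean pixel variance and the observed per-pixel variances are
restored by a diagonal congruence, which keeps the matrix PSD.
Raw-image spectra sit far above this floor and are untouched. The GLS
route needs ensembles of a few thousand images to estimate M_f usefully
(at a few hundred it is visibly under-sampled); single-image covariance
estimation is out of scope.

## Study conditions (ensemble driver)

Zone A centres the box on corrected pixel (306, 306); zone B is shifted
six pixels in X and Y, sampling a different distortion registration.
Defaults: spot of Poisson mean 10⁴ X-rays, isotropic Gaussian σ =
90 µm — chosen so that, after PSF convolution, > 99.9% of spot photons
land inside the raw-image peak region (summation statistics are then
insensitive to σ); background 20 X-rays per face pixel; 200 dark
images; 10⁴ replicates (configurable). Ensembles simulate a 35×35
face-pixel window around the box rather than full frames; the window is
large enough that PSF spill and the box's contributing quadrilaterals
lie fully inside it.

## What the synthetic data do and do not show

The generator reproduces the stochastic response of an idealised
detector: uniform phosphor, radially symmetric distortion, no zingers,
no pixel bleeding, no chicken-wire or shear taper defects, no
reflective phosphor backing, monoenergetic normal-incidence beam, one
read-out channel. Passing tests therefore validate the *error algebra*
and the correction/integration machinery, not any particular hardware:
on real detectors γ, G and q̄ₐ are energy- and obliquity-dependent and
must be measured (the tabular calibration workflow exists for that),
and position-dependent systematic errors from fine-grained nonuniformity
are absent here by construction. The beamline response fixture is
synthetic: a sawtooth monitor trend (relative SD 1.3%) with
cascade-model scatter; it exercises the trend-removal and recovery
machinery but does not emulate any specific storage-ring behaviour.
Residual variances are pooled unweighted across sections, one degree of
freedom per fitted scale.

## Numerical choices

Rounding: round-half-even in the ADC; stochastic (mean-preserving)
rounding of scintillation yields; reference profiles rounded to whole
ADU. Polygon areas by the shoelace formula; overlap fractions sum to 1
within 1e-9 and match a 1000× supersampling oracle to 1e-3. Degenerate
inputs (zero-area quadrilaterals, non-bijective distortions, collinear
background geometries, variance below the pixel-noise floor, mixed dark
exposures) raise typed errors. The gain fit uses an ordinary linear
model with intercept; its standard error combines both measurement
stages in quadrature.

## Known limitations

The profile-fit variance ratios depend on PSF shape and distortion
coefficients, for which only envelope constraints exist; they are
validated with widened (±20%) tolerance while orderings and the GLS
recovery property are exact requirements. Full-frame distortion-map
construction (10⁶ quadrilaterals) takes minutes and is intended for
offline calibration, not per-image work. Spot prediction, partiality,
scaling/merging and frequency-dependent DQE are out of scope.
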