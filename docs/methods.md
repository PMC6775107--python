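# Methods

This note documents the physical model, the numerical choices, and the
simulation conditions behind the `isoct` package, in enough detail to judge
what a passing test suite does and does not demonstrate.

## Scattering model

Refractive-index fluctuations are modelled by the Whittle-Matérn family
B_n(r) = A_n (r/L_n)^ν K_ν(r/L_n), ν = (D−3)/2.  The autocorrelation and its
power spectrum are defined for any D > 0; the Born-approximation optics are
restricted to D ∈ [1.2, 6], which covers the biologically observed range
(~1.5–5) and avoids the regimes where the spectral-exponent mapping
degrades.  The 3-D spectral density is

    Φ_n(q) = A_n L_n³ Γ(D/2) 2^((D−5)/2) π^(−3/2) (1 + q²L_n²)^(−D/2),

the d = 3 Matérn spectral density analytically continued to D ≤ 3; the
prefactor is fixed by requiring the inverse transform to reproduce B_n with
amplitude A_n and is verified numerically against a radial Fourier quadrature
in the tests (1% over q ∈ [10⁻⁴, 10⁻¹] nm⁻¹).

Scalar waves are assumed (differential scattering coefficient
dμ_s/dΩ = 2π k⁴ Φ_n(2k sin(θ/2)), k = 2π·n_medium/λ, default n = 1.35); the
dipole (1+cos²θ)/2 factor is available behind a `dipole=True` flag for
sensitivity checks.  With u = 1 − cos θ and x = 2k²L_n², all angular
integrals reduce to elementary antiderivatives; `anisotropy_g` and
`mu_s_spectrum` default to adaptive quadrature (relative tolerance 1e-8,
refinement points near θ = 0) with the closed forms as a cross-checked fast
path used inside optimization loops and the lookup builder.  Under this
normalization the Born μ_s integral converges throughout the supported D
range at finite k; the range check itself is the guard.

### Backscattering scale convention

The physical backscattering coefficient is defined as the θ = π differential
scattering coefficient times a configured collection solid angle (default
0.02 sr): μ_b = 2πk⁴Φ_n(2k)·ΔΩ, in cm⁻¹.  On this intensity scale
μ_b ∝ λ^(D−4) for L_n ≫ λ, and the albedo α = μ_b/μ_s is independent of A_n
— which is what makes the g(α, D) lookup well-posed.  The OCT *amplitude*
spectrum, √μ_b, carries the familiar λ^(D/2−2) exponent; the fractal-
dimension fit accepts either scale (`scale="amplitude"`: D = 2·(slope+2);
`scale="intensity"`: D = slope+4 — the same fit).  Only the spectral shape
of μ_b is model-exact; the absolute scale is calibrated against a standard
sample, so the collection solid angle merely fixes a consistent internal
scale between simulator, calibration and lookup.

### The g(α, D) lookup

For each D on a 0.05-step grid, the correlation length is swept over
5 nm–30 μm (400 log-spaced points), α and g are evaluated in closed form at
the reference wavelength (620 nm, chosen away from the 660 nm absorption
peak because the albedo is a scattering quantity), and g is resampled onto a
common albedo grid by monotone interpolation.  Queries use bilinear
interpolation; anything outside the table's support returns NaN plus a mask
bit — never extrapolation.  The table serializes to an HDF5 container with
named axes and a metadata attribute block.

## Forward simulator

The simulator realizes exactly the signal model the inversion assumes.  Each
phantom is a stack of homogeneous layers under an arbitrary surface height
field; per-layer spectra derive from the layer's Whittle-Matérn parameters
and chlorophyll-a concentration (skeleton-type layers are non-absorbing by
construction), or can be supplied directly (e.g. Mie suspensions).  The
interferogram at wavenumber k is the real part of a coherent sum over
scatterers spaced 1 μm (configurable) in depth, with amplitude
√(μ_b Δz)·exp(−∫μ_t dz′)·rolloff(z), round-trip phase 2 k n z, and frozen
per-scatterer complex circular-Gaussian reflectivity — fully developed
speckle with a Rayleigh envelope (verified by a KS test over 10⁴ columns).
Sensitivity roll-off is −10 dB/mm (amplitude scale) by default; white
detector noise is added to reach a configured band-intensity SNR at the
surface.  Every stochastic output is reproducible bit-for-bit from
(phantom, acquisition, seed).

Speckle-free ("ideal") mode synthesizes the expectation of the band
intensity — μ_b e^(−2∫μ_t) rolloff² — directly as a spectral cube rather
than as one interferogram, because a single real fringe with per-scatterer
phases cannot carry a deterministic exponential envelope.  It is the
reference against which the Beer-Lambert contract is exact (ln-slope
= −2 μ_t to 1e-6 relative).

Like a real spectral-domain system, the simulator has a finite unambiguous
depth range (n_k/2 axial pixels); phantoms extending beyond it fold back
(complex-conjugate ambiguity) and a warning is issued.  Validation phantoms
are sized to stay inside the range.

## Inversion pipeline

**STFT.**  22 Gaussian windows, uniform in λ with centers inset half a FWHM
from the 520–720 nm band edges, each 20 nm FWHM mapped to k-space
(Δk = 2πΔλ/λ_c²) where the transform is performed.  Stored intensity is
|FFT(w·S)|²/Σw², so a spectrally white fringe reads equally in every band;
depth is optical path; the known spectrometer roll-off is divided out.

**Surface.**  Band-summed intensity, lightly smoothed (7×7 lateral × 3
axial), percentile contrast stretch, extended-maxima binarization
(h = 0.2), morphological closing/opening, minimum object size, then a
half-maximum edge refinement: the 50%-of-local-peak crossing of the smoothed
axial profile localizes the PSF-blurred surface step to sub-pixel accuracy
under speckle (≥99% of columns within ±1 axial pixel at 30 dB SNR on the
flat phantom).  Manual masks override detection; validity filters flag
roll-off-limited and specular columns by reason bits.

**Attenuation.**  Per band and column, weighted linear regression of
ln(intensity) on depth over a 90 μm window below the surface; μ_t = −slope/2
(magnitude-squared convention), converted to a physical cm⁻¹ with the medium
index because the depth axis is optical path.  Two numerical choices matter:

* The window starts a per-band guard (1.5× the band's axial PSF FWHM,
  λ-dependent) below the surface.  Inside the guard the PSF-blurred surface
  step flattens the decay and biases μ_t low — by more at long wavelengths,
  which would tilt the recovered μ_b spectrum and bias D.
* Weights come from the *predicted* (first-pass) intensity rather than the
  observed one: weighting by the observed intensity correlates weights with
  the speckle residuals (E[s ln s] > 0) and biases the slope steep.

Negative fitted μ_t is floored at zero with a flag.  Compensation divides
each voxel by e^(−2 μ_t (z−z_s)); the μ_t it uses is laterally smoothed
(7×7; map-median for the homogeneous calibration standard) because
compensating each column with its own noisy μ̂_t inflates the window mean
multiplicatively (Jensen bias) with a PSF-width-dependent, hence
λ-dependent, magnitude.  The reported per-pixel μ_t maps are untouched.

**Backscattering spectrum and calibration.**  μ_b(band, x, y) is the mean
compensated intensity over the same guarded 90 μm window, scaled to cm⁻¹ by
per-band factors from a standard-sample scan with known μ_b(λ) (a
Rayleigh-type bead suspension).  The standard is processed with the
identical surface/fit/compensate/window chain, so window, PSF and speckle
systematics cancel in the ratio.

**Spectral decomposition.**  With all spectra max-normalized (the *
convention), the objective Σ_i |μ_t*(λ_i) − c_a μ_a*(λ_i) − c_s μ_s*(λ_i; D,
L_n)|² is minimized by multi-start Nelder-Mead (8 Latin-hypercube starts over
the bounds, fixed seed, ties broken toward smaller D).  Because the
normalized objective constrains only the spectral shape, the optimizer works
in the scale-free parameterization (ρ = c_a/(c_a+c_s), D, ln L_n); the
coefficients are then expressed in the canonical gauge where the model
reaches the normalized spectrum's maximum (max_λ f = 1), from which the
absolute spectra follow: μ_a = c_a μ_a* max{μ_t}, μ_s = c_s μ_s* max{μ_t}.
Reported c_a, c_s are additionally clipped to [0, ½] with a `clipped` flag —
scattering-dominated spectra routinely have canonical c_s > ½ whenever the
absorption and scattering peaks do not coincide — while the absolute spectra
always use the unclipped canonical values, keeping μ_a + μ_s = μ_t exact at
the spectrum's maximum.  The 660 nm chlorophyll feature is what identifies
the split; with a featureless absorber shape the multi-start solutions for ρ
disperse, which the result reports as `start_dispersion`.  Skeleton mode
fixes ρ = 0 (skeletal absorption neglected).  Decomposition runs on 8×8
super-pixel blocks of the μ_t maps (speckle averaging; per-pixel μ_t spectra
at 30 dB SNR are too noisy to split stably), with results broadcast back to
pixels.

**D and g.**  D is fit per pixel by ordinary least squares on the log
backscattering spectrum over the 90 μm window average (amplitude-scale
exponent D/2 − 2), with a per-pixel standard error; nonpositive bands are
dropped and fewer than 6 surviving bands invalidates the pixel.  Both the
μ_b-derived and decomposition-derived D are reported; maps and the g lookup
use the μ_b-derived value.  g is looked up at (α, D) with α evaluated at the
band nearest 620 nm; out-of-support pixels are masked.

**Chlorophyll a.**  μ_a at the reference shape's peak (660 nm) converts to
molarity by C = μ_a/(ln 10 · ε_peak) — the packaged fixture records the
decadic convention and ε_peak = 71,930 M⁻¹cm⁻¹ (chlorophyll a in methanol),
molar mass 893.5 g mol⁻¹ — and to areal density by multiplying with the
90 μm window thickness (constant-concentration assumption).  The packaged
spectrum is a synthetic analytic stand-in (Gaussian Q-bands at 660/620 nm,
σ = 11/14 nm, secondary amplitude 0.28); any tabulated two-column spectrum
can be swapped in via the config, and the simulator builds μ_a through the
same fixture, so forward/inverse closure holds for whichever spectrum is
loaded.  No solvent-to-in-vivo spectral shift is applied.

**Spatial-variance QC.**  A randomized square averaging box samples the D
map at each of several edge lengths (uniform positions over the valid-mask
interior; boxes touching invalid pixels are rejected and redrawn, avoiding
edge bias); the standard deviation of the box means versus edge length
separates true spatial heterogeneity from instrument variance.  Defaults:
300 samples per edge, seeded.

## Simulation conditions and what the tests show

The validation phantoms emulate the measurement conditions of a visible-band
spectral-domain system: 520–720 nm, 4096-pixel spectrometer (tests and the
acceptance run use 2048 samples, which halves the unambiguous depth range to
~0.96 mm and leaves the physics unchanged), −10 dB/mm roll-off, 30 dB
surface SNR, fully developed speckle.  The headline recovery phantom is
64×64 columns of 150 μm tissue (D = 2.5, L_n = 1000 nm, μ_s(600) =
150 cm⁻¹, 0.3 mg cm⁻³ chlorophyll a, model g(620) = 0.845) over skeleton
(D = 3.5, L_n = 500 nm, μ_s(600) = 250 cm⁻¹), with a skeleton-only rescan
emulating tissue removal, and a 32×32 Rayleigh-standard scan (L_n = 20 nm,
μ_s(600) = 30 cm⁻¹) for calibration.  Achieved recovery at these conditions
(seed 1): median D within 0.06, μ_t within ~1.3%, g within 0.005, and
chlorophyll-a areal density within ~8% of the 2.7 μg cm⁻² ground truth.

What the phantoms deliberately do not contain: depth-varying optics inside
the fit window (real tissue layers epidermis/mesoglea/gastrodermis differ),
topographic roughness beyond smooth height fields, multiple scattering
(the simulator is single-scatter, as is the Born inversion), polarization
and birefringence, focus/confocal gating, and instrument dispersion.
Passing tests therefore demonstrate the *inversion is correct against its
own forward model and against Mie physics for the attenuation step* — not
that the Born/Whittle-Matérn description is adequate for any particular
real sample.

## Known limitations

* The [0, ½] coefficient box is reported for compatibility, but an exact
  max-normalized representation with both coefficients below ½ exists only
  when the absorption and scattering spectra peak together; the canonical
  (unclipped) coefficients carry the physical content.
* Albedo-based g is only as good as the absolute μ_b calibration; without a
  reference scan the lookup is queried with arbitrary units and most pixels
  mask out.
* For D ≤ 2 at large L_n the closed-form/quadrature agreement is verified,
  but no external oracle for the ultrastructure-to-optics mapping exists in
  that regime beyond the model itself.
* Depth aliasing (conjugate ambiguity) is reproduced, not resolved; deep
  phantoms must be sized to the configured unambiguous range, as deep
  samples must be in a real instrument.
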