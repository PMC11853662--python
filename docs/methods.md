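# Methods

## The measurement being modeled

A birefringent sample of thickness *d* splits linearly polarized light into
ordinary and extraordinary waves that accumulate a relative phase
φ(λ) = 2π·d·Δn/λ, where Δn is the birefringence. Between crossed polarizers
this phase turns into a wavelength-dependent transmission, and under a
broadband source the sensor therefore records an *interference color* — the
classical Michel-Lévy correspondence between retardance d·Δn and hue. The
package implements the quantitative version of this experiment as used in
lensless, on-chip polarized-light microscopy: a forward model that predicts
the color for any retardance, and an inverse that reads retardance (and,
with known thickness, birefringence) back out of observed colors.

## Forward model

Each element of the train — polarizer (LP1), optional full waveplate (FWP),
sample, analyzer (LP2) — is a 2×2 Jones matrix per wavelength. Retarders are
R(θ)·diag(e^{+iφ/2}, e^{-iφ/2})·R(−θ) with φ(λ) = 2π·OPD/λ; the optical path
difference OPD = d·Δn is held constant over the band (no dispersion, the
standard thin-film approximation — the FWP is a constant 560 nm, matching a
one-wave film at 560 nm). Light propagates LP1 → FWP → sample → LP2 and the
transmitted power is the squared field magnitude times the source power.
Intensities are normalized to the polarized field after LP1, so a clear path
between parallel polarizers transmits 1. For a single retarder at angle θ
between ideal crossed polarizers the chain reduces to the closed form
T(λ) = sin²(2θ)·sin²(π·OPD/λ), which the tests use as an independent oracle
for the full matrix chain (agreement to 1e-10 over random draws).

Sub-epsilon values of cos/sin in the matrix builders are snapped to exact
zero so that the right-angle geometries (crossed polarizers alone, samples
on an eigen-axis) extinguish *identically*, not merely to ~1e-33.

## Colorimetry

Transmitted spectra integrate against the CIE 1931 2° observer (native 5 nm
table, embedded; trapezoidal rule on the 380–780 nm grid) to XYZ, then to
CIELAB against a reference white taken as the unobstructed illuminant itself
(Y = 100) — the camera is assumed white-balanced to the source. Display sRGB
uses the standard D65-referred matrix without chromatic adaptation; it is a
preview/interchange encoding, and out-of-gamut channels are clipped. Color
matching always happens in Lab; ΔE is the full CIEDE2000 formula
(vectorized), validated against the standard 34-pair verification set and
against scikit-image's implementation to 1e-4.

The default illuminant is a two-Gaussian white-LED model (blue pump 450 nm /
25 nm FWHM, phosphor 560 nm / 110 nm FWHM, peak ratio 0.8) — a generic
cool-white LED. Measured spectra can be loaded from two-column CSV instead;
every LUT records the spectrum's content hash so retrieval can verify it was
built under the same illumination.

## Phase retrieval

The reference LUT tabulates the forward model for a 45°-axis sample on an
OPD grid (default 0–3000 nm in 1 nm steps, spanning third-order colors at
sub-JND spacing). Retrieval converts each pixel to Lab under the LUT's white
and takes the ΔE-argmin over the table; exact ties break to the smallest OPD
(lowest interference order, the conventional reading of a Michel-Lévy
chart). Because different orders can be near-metameric, a pixel is flagged
ambiguous when two or more local minima of its ΔE(OPD) curve lie within a
tolerance (default ΔE = 1, one just-noticeable difference) of the global
minimum. A luminance-invariant mode (L* held fixed on both sides) is
available for images of unknown exposure.

With the source broadband, one scalar phase must summarize the band: the
average of φ(λ) over [λi, λf], which for constant OPD has the closed form
φ̄ = 2π·OPD·ln(λf/λi)/(λf−λi). Its inverse at known thickness,

    Δn = (λf − λi)·φ̄ / (2π·d·ln(λf/λi)),

is exact to 1e-12 round-trip and is the quantity the package reports as
birefringence. The worked mica example (φ̄ = 3.85π, d = 210 µm, 380–780 nm)
gives Δn = 0.0051.

## Sign of birefringence (±45° waveplate test)

The FWP adds retardance when the object's slow axis is parallel to the
plate's slow axis and subtracts when crossed, so imaging the same scene with
the FWP at +45° and −45° and retrieving both images yields a larger OPD in
the orientation whose slow axis matches the object's. Comparing that axis
with the object's long morphological axis gives the sign: slow ∥ long → +1;
slow ⊥ long → −1 (negative birefringence, the monosodium-urate signature in
gout diagnostics). Pixels whose OPD difference is below one LUT step are
undetermined, which correctly covers the zero-OPD background.

Design choice: both FWP images are retrieved against the *plain
crossed-polarizer* LUT, not per-FWP tables. In the aligned geometry the
plate and sample combine into a single retarder of OPD |OPD ± Γ0|, so the
no-FWP table is the correct dictionary and the retrieved value directly
equals the effective retardance. Per-FWP tables contain exact metamer pairs
(entries k and 2Γ0−k produce identical spectra), and the smallest-OPD
tie-break then collapses the two orientations to the same answer for
positive-sign objects, destroying the comparison.

## Synthetic scenes

Generators produce ground-truth maps on a 1.4 µm-pitch sensor grid (the
pixel size of a small-format CMOS die): uniform plates (mica-like; the
end-to-end test uses d = 210 µm, Δn = 0.0054 → OPD 1134 nm), needles
(rotated rectangles with the optic axis along the long axis; width 1.1 µm
and sign −1 emulate MSU crystals), and radial-axis crystal centers whose
rendering produces the Maltese cross with dark arms on the polarizer
azimuths. Rendering adds, in order: optional Gaussian blur of stated FWHM
(an empirical stand-in for lensless sample-to-sensor spreading; full
Fresnel propagation is out of scope), then seeded additive Gaussian noise
(default σ 0.01) in the encoded sRGB domain, then clipping to [0, 1].

What the generator does *not* emulate: the real camera's ISP (demosaic,
white balance, tone curve), shot noise, FWP dispersion, sample dispersion
Δn(λ), and diffraction. Passing tests therefore demonstrate correctness of
the computation under its own stated model, not color fidelity to any
particular physical device — the measured spectrum of a given LED and its
camera pipeline would be needed for that.

The apparent size of small objects is estimated by least-squares fitting an
intensity squared-sinc (central diffraction lobe) A·sinc²((x−x0)/s)+B to a
1-D profile; FWHM = 0.885894·s. "Sinc" profiles reported for bead images are
ambiguous between amplitude sinc and intensity sinc²; the intensity reading
is implemented (an amplitude-sinc fit would scale the FWHM by a known
constant). Profiles with two comparable peaks are rejected from the
single-lobe fit; a two-lobe mode recovers both centers for resolution
(Rayleigh-criterion) checks.

## Numerical choices and limitations

- Canonical grid 380–780 nm, 5 nm (81 points); all spectral integrals
  trapezoidal on this grid. LUT default 0–3000 nm, 1 nm.
- LUT files are CSV with a commented YAML header (train config, spectrum
  hash, white point); floats serialize with shortest round-trip repr, so
  identical inputs give byte-identical files.
- Gamut: saturated interference colors (mainly second-order blues/greens
  under the default LED) fall outside sRGB; their encoded previews are
  clipped, and retrieval *through the RGB encoding* can alias for those
  entries (ΔE distortion up to ~8). Retrieval from Lab (or from renders of
  in-gamut colors, which includes the 1134 nm mica color) is exact at every
  grid point. For quantitative work with strongly saturated colors, match in
  Lab or use a luminance-invariant/weighted scheme rather than 8-bit RGB.
- Retrieval assumes the image was produced (or white-balanced) under the
  LUT's illuminant and encoded as sRGB; thickness must be known for Δn
  (joint estimation of d and Δn is out of scope); multi-order disambiguation
  beyond smallest-OPD tie-breaking plus the ambiguity flag is out of scope.
- Problem sizes in the test-suite and acceptance computations (24×24 to
  64×64 frames, 10⁴-sample Monte-Carlo draws) are the package's default
  desk-scale settings; all quantitative checks are deterministic or run at
  fixed seeds.
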