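"""Synthetic birefringent scenes, camera-like rendering, and profile fitting.

Scenes are per-pixel ground-truth maps of optical path difference, optic-axis
angle, and sign of birefringence, on a sensor grid with a physical pixel
pitch (1.4 um by default, matching a small-format CMOS die).  Rendering
pushes every pixel through the wavelength-resolved Jones forward model to an
sRGB image, then applies an optional Gaussian blur standing in for the
lensless sample-to-sensor spreading, and seeded Gaussian sensor noise.

The profile-fitting helper estimates an apparent object size as the FWHM of
a squared-sinc (diffraction central lobe) model fitted to a 1-D intensity
profile, the same way bead profiles are measured to gauge a lensless
system's resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal

from . import jones
from .colorimetry import reference_white, spectra_to_xyz, xyz_to_srgb
from .spectra import BandLimits, ColorMatchingFunctions, SpectralDistribution, cie_1931_cmf

DEFAULT_PIXEL_PITCH_UM = 1.4

#: Half width at half maximum of sinc^2(x) in units of its argument:
#: sinc^2(u) = 1/2 at pi*u = 1.39155737825151.
_SINC2_HWHM = 1.39155737825151 / np.pi


@dataclass(frozen=True)
class SamplePhaseMap:
    """Ground-truth per-pixel OPD (nm), optic-axis angle (deg), and sign."""

    opd_nm: np.ndarray
    axis_angle_deg: np.ndarray
    sign: np.ndarray
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM

    def __post_init__(self):
        for name in ("opd_nm", "axis_angle_deg", "sign"):
            v = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} contains non-finite values")
            object.__setattr__(self, name, v)
        if np.any(self.opd_nm < 0):
            raise ValueError("opd_nm must be >= 0 everywhere")
        if self.axis_angle_deg.shape != self.opd_nm.shape or (
            self.sign.shape != self.opd_nm.shape
        ):
            raise ValueError("opd_nm, axis_angle_deg, sign must share one shape")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be > 0")

    @property
    def shape(self):
        return self.opd_nm.shape


@dataclass(frozen=True)
class SceneRecipe:
    """Reproducible description of a rendered scene (for sidecar files)."""

    kind: str
    geometry: dict = field(default_factory=dict)
    noise_sigma: float = 0.01
    blur_fwhm_um: float = 0.0
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "geometry": dict(self.geometry),
            "noise_sigma": float(self.noise_sigma),
            "blur_fwhm_um": float(self.blur_fwhm_um),
            "seed": self.seed,
        }


def make_uniform_plate(
    opd_nm: float,
    axis_deg: float,
    shape: tuple[int, int],
    sign: int = 1,
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM,
) -> SamplePhaseMap:
    """Uniform retarder plate filling the frame (e.g. a flat mica sheet)."""
    if opd_nm < 0:
        raise ValueError("opd_nm must be >= 0")
    return SamplePhaseMap(
        np.full(shape, float(opd_nm)),
        np.full(shape, float(axis_deg)),
        np.full(shape, float(sign)),
        pixel_pitch_um,
    )


def make_needle(
    length_um: float,
    width_um: float,
    angle_deg: float,
    opd_nm: float,
    sign: int,
    shape: tuple[int, int],
    center_um: tuple[float, float] | None = None,
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM,
) -> SamplePhaseMap:
    """Needle-shaped crystal: a rotated rectangle of constant OPD.

    The optic axis follows the needle's long axis; ``sign = -1`` makes the
    long axis the fast axis (negative birefringence, MSU-like).
    """
    if not (length_um > width_um > 0):
        raise ValueError("need length_um > width_um > 0")
    h, w = shape
    fh, fw = h * pixel_pitch_um, w * pixel_pitch_um
    if length_um > np.hypot(fh, fw):
        raise ValueError(
            f"needle length {length_um} um exceeds the frame diagonal "
            f"({np.hypot(fh, fw):.1f} um)"
        )
    if center_um is None:
        center_um = (fh / 2.0, fw / 2.0)
    yy, xx = np.indices(shape, dtype=float)
    # pixel centers in um; y down, x right; angle measured from +x, CCW
    y = (yy + 0.5) * pixel_pitch_um - center_um[0]
    x = (xx + 0.5) * pixel_pitch_um - center_um[1]
    a = np.deg2rad(angle_deg)
    along = x * np.cos(a) + y * np.sin(a)
    across = -x * np.sin(a) + y * np.cos(a)
    mask = (np.abs(along) <= length_um / 2.0) & (np.abs(across) <= width_um / 2.0)
    opd = np.where(mask, float(opd_nm), 0.0)
    return SamplePhaseMap(
        opd,
        np.full(shape, float(angle_deg)),
        np.where(mask, float(sign), 1.0),
        pixel_pitch_um,
    )


def make_radial_center(
    radius_um: float,
    opd_profile,
    shape: tuple[int, int],
    center_um: tuple[float, float] | None = None,
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM,
) -> SamplePhaseMap:
    """Crystal center with radially aligned optic axes (Maltese-cross scene).

    ``opd_profile`` is either a constant OPD (nm) or a callable mapping
    radius (um) to OPD (nm); pixels beyond ``radius_um`` are background.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be > 0")
    h, w = shape
    if center_um is None:
        center_um = (h * pixel_pitch_um / 2.0, w * pixel_pitch_um / 2.0)
    yy, xx = np.indices(shape, dtype=float)
    y = (yy + 0.5) * pixel_pitch_um - center_um[0]
    x = (xx + 0.5) * pixel_pitch_um - center_um[1]
    r = np.hypot(x, y)
    if callable(opd_profile):
        opd = np.asarray(opd_profile(r), dtype=float)
    else:
        opd = np.full(shape, float(opd_profile))
    opd = np.where(r <= radius_um, np.clip(opd, 0.0, None), 0.0)
    axis = np.degrees(np.arctan2(y, x))
    return SamplePhaseMap(opd, axis, np.ones(shape), pixel_pitch_um)


def render_scene(
    sample: SamplePhaseMap,
    source: SpectralDistribution,
    train: jones.OpticalTrainConfig,
    noise_sigma: float = 0.0,
    blur_fwhm_um: float = 0.0,
    seed: int | None = None,
    cmf: ColorMatchingFunctions | None = None,
    band: BandLimits | None = None,
    exposure: float = 1.0,
) -> tuple[np.ndarray, SamplePhaseMap]:
    """Render a phase map to a camera-like sRGB image.

    Per pixel: transmitted spectrum -> XYZ -> display sRGB (under the
    illuminant's white, scaled by ``exposure`` before encoding); then an
    optional Gaussian blur of the stated FWHM (in um, converted with the
    pixel pitch), then seeded additive Gaussian noise in the encoded domain,
    clipped to [0, 1].  Returns the image and the ground-truth map.
    """
    if cmf is None:
        cmf = cie_1931_cmf(source.wavelengths_nm)
    if band is None:
        band = BandLimits()
    lam = source.wavelengths_nm
    h, w = sample.shape
    phase = (
        sample.sign.reshape(-1, 1)
        * 2.0
        * np.pi
        * sample.opd_nm.reshape(-1, 1)
        / lam[None, :]
    )
    axis = np.deg2rad(sample.axis_angle_deg).reshape(-1, 1)
    out = np.empty((h * w, 3))
    white = reference_white(source, cmf, band)
    scale = 100.0 / spectra_to_xyz(source.power, cmf, band)[1]
    chunk = 4096
    for lo in range(0, h * w, chunk):
        hi = min(lo + chunk, h * w)
        fields = jones._propagate_fields(lam, train, phase[lo:hi], axis[lo:hi])
        power = source.power * np.clip(
            np.sum(np.abs(fields) ** 2, axis=-1), 0.0, 1.0
        )
        xyz = spectra_to_xyz(power, cmf, band) * scale * exposure
        out[lo:hi] = xyz_to_srgb(xyz, white)
    image = out.reshape(h, w, 3)
    if blur_fwhm_um > 0:
        sigma_px = blur_fwhm_um / (2.0 * np.sqrt(2.0 * np.log(2.0))) / sample.pixel_pitch_um
        image = ndimage.gaussian_filter(image, sigma=(sigma_px, sigma_px, 0.0))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_sigma, size=image.shape)
    return np.clip(image, 0.0, 1.0), sample


def render_linear_rgb(
    sample: SamplePhaseMap,
    source: SpectralDistribution,
    train: jones.OpticalTrainConfig,
    cmf: ColorMatchingFunctions | None = None,
    band: BandLimits | None = None,
    exposure: float = 1.0,
) -> np.ndarray:
    """Linear (pre-gamma, unclipped) RGB render, for radiometric checks."""
    if cmf is None:
        cmf = cie_1931_cmf(source.wavelengths_nm)
    if band is None:
        band = BandLimits()
    from .colorimetry import _SRGB_FROM_XYZ

    lam = source.wavelengths_nm
    phase = (
        sample.sign.reshape(-1, 1)
        * 2.0
        * np.pi
        * sample.opd_nm.reshape(-1, 1)
        / lam[None, :]
    )
    axis = np.deg2rad(sample.axis_angle_deg).reshape(-1, 1)
    fields = jones._propagate_fields(lam, train, phase, axis)
    power = source.power * np.clip(np.sum(np.abs(fields) ** 2, axis=-1), 0.0, 1.0)
    white = reference_white(source, cmf, band)
    scale = 100.0 / spectra_to_xyz(source.power, cmf, band)[1]
    xyz = spectra_to_xyz(power, cmf, band) * scale * exposure
    lin = (xyz / white[1]) @ _SRGB_FROM_XYZ.T
    return lin.reshape(sample.shape + (3,))


@dataclass(frozen=True)
class ProfileFit:
    """Result of a squared-sinc profile fit."""

    fwhm_um: float
    center_um: float
    amplitude: float
    baseline: float
    scale_um: float
    residual_norm: float


def _sinc2(x_um, amplitude, center_um, scale_um, baseline):
    return amplitude * np.sinc((x_um - center_um) / scale_um) ** 2 + baseline


def fit_profile_fwhm(
    intensity_profile: np.ndarray,
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM,
) -> ProfileFit:
    """Fit a squared-sinc central lobe to a 1-D intensity profile.

    Models the apparent (diffraction-broadened) image of a small object as
    A * sinc^2((x - x0)/s) + B and reports the central-lobe FWHM
    (= 0.885894 * s) in um.  Requires a single dominant interior peak;
    profiles with two comparable peaks are rejected (use
    :func:`fit_two_peak_profile` for bead pairs).
    """
    y = np.asarray(intensity_profile, dtype=float)
    if y.ndim != 1 or y.size < 7:
        raise ValueError("profile must be 1-D with >= 7 samples")
    x = np.arange(y.size) * pixel_pitch_um
    imax = int(np.argmax(y))
    if imax in (0, y.size - 1):
        raise ValueError("profile has no interior maximum")
    span = y.max() - y.min()
    if span <= 0:
        raise ValueError("profile is constant")
    peaks, _ = signal.find_peaks(y, prominence=0.25 * span)
    if peaks.size >= 2:
        raise ValueError(
            f"profile has {peaks.size} comparable peaks; single-peak fit "
            "rejected (two-peak mode available)"
        )
    # initial scale from the half-max crossing width
    above = y >= y.min() + 0.5 * span
    width0 = max(above.sum(), 2) * pixel_pitch_um
    p0 = [span, x[imax], width0 / (2.0 * _SINC2_HWHM), y.min()]
    popt, _ = optimize.curve_fit(_sinc2, x, y, p0=p0, maxfev=20000)
    amplitude, center, scale, baseline = popt
    scale = abs(scale)
    resid = y - _sinc2(x, *popt)
    return ProfileFit(
        fwhm_um=2.0 * _SINC2_HWHM * scale,
        center_um=center,
        amplitude=amplitude,
        baseline=baseline,
        scale_um=scale,
        residual_norm=float(np.linalg.norm(resid)),
    )


def fit_two_peak_profile(
    intensity_profile: np.ndarray,
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM,
) -> tuple[ProfileFit, ProfileFit]:
    """Fit two squared-sinc lobes to a twin-peak profile (resolved beads).

    Returns one fit per lobe; the center separation measures whether the
    pair is resolved in the Rayleigh sense.
    """
    y = np.asarray(intensity_profile, dtype=float)
    if y.ndim != 1 or y.size < 11:
        raise ValueError("profile must be 1-D with >= 11 samples")
    x = np.arange(y.size) * pixel_pitch_um
    span = y.max() - y.min()
    peaks, _ = signal.find_peaks(y, prominence=0.25 * span)
    if peaks.size < 2:
        raise ValueError(f"expected 2 peaks, found {peaks.size}")
    order = np.argsort(y[peaks])[::-1]
    c1, c2 = np.sort(x[peaks[order[:2]]])

    def model(xv, a1, x1, s1, a2, x2, s2, b):
        return (
            a1 * np.sinc((xv - x1) / s1) ** 2
            + a2 * np.sinc((xv - x2) / s2) ** 2
            + b
        )

    s0 = max((c2 - c1) / 4.0, pixel_pitch_um)
    p0 = [span, c1, s0, span, c2, s0, y.min()]
    popt, _ = optimize.curve_fit(model, x, y, p0=p0, maxfev=40000)
    resid = float(np.linalg.norm(y - model(x, *popt)))
    fits = []
    for a, c, s in (popt[0:3], popt[3:6]):
        s = abs(s)
        fits.append(
            ProfileFit(2.0 * _SINC2_HWHM * s, c, a, popt[6], s, resid)
        )
    fits.sort(key=lambda f: f.center_um)
    return tuple(fits)
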