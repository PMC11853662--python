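"""Jones-calculus propagation through the crossed-polarizer imaging train.

The optical train is: linear polarizer (LP1) -> full waveplate (FWP,
optional) -> birefringent sample (optional) -> analyzer (LP2) -> sensor.
Each element is a 2x2 complex Jones matrix acting on the transverse field
(Ex, Ey); retarders are wavelength-dependent through their phase
phi(lambda) = 2*pi*OPD/lambda with the optical path difference OPD = d*dn
held constant over the band (no dispersion).  All matrix builders broadcast:
scalar arguments give a (2, 2) array, array arguments give (..., 2, 2).

Angle convention: counterclockwise positive, 0 deg along the sensor x-axis.
A retarder's ``axis_angle`` is its slow axis; a sign flip on the phase (or a
``SampleElement.sign`` of -1) exchanges fast and slow axes.  Intensities are
reported relative to the fully polarized field emerging from LP1, i.e. a
transparent isotropic path between parallel polarizers transmits 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import SpectralDistribution


@dataclass(frozen=True)
class OpticalTrainConfig:
    """Geometry and retardance of the fixed optical elements.

    ``fwp_design_opd_nm`` is the full waveplate's optical path difference
    Gamma0 (560 nm for the WP560 film): exactly one wave of retardance at
    560 nm, with phase 2*pi*Gamma0/lambda elsewhere.  ``polarizer_extinction``
    is the *field-amplitude* leakage of the crossed axis (0 = ideal).
    """

    polarizer_angle_deg: float = 0.0
    analyzer_angle_deg: float = 90.0
    fwp_present: bool = False
    fwp_angle_deg: float = 45.0
    fwp_design_opd_nm: float = 560.0
    polarizer_extinction: float = 0.0

    def __post_init__(self):
        for name in ("polarizer_angle_deg", "analyzer_angle_deg", "fwp_angle_deg"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.fwp_design_opd_nm <= 0:
            raise ValueError("fwp_design_opd_nm must be > 0")
        if not (0.0 <= self.polarizer_extinction < 1.0):
            raise ValueError("polarizer_extinction must be in [0, 1)")

    def to_dict(self) -> dict:
        return {
            "polarizer_angle_deg": float(self.polarizer_angle_deg),
            "analyzer_angle_deg": float(self.analyzer_angle_deg),
            "fwp_present": bool(self.fwp_present),
            "fwp_angle_deg": float(self.fwp_angle_deg),
            "fwp_design_opd_nm": float(self.fwp_design_opd_nm),
            "polarizer_extinction": float(self.polarizer_extinction),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalTrainConfig":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


@dataclass(frozen=True)
class SampleElement:
    """A uniform birefringent element: OPD, optic-axis angle, and sign.

    ``sign`` = +1 means ``axis_angle_deg`` is the slow axis; -1 means it is
    the fast axis (negative birefringence along that morphological axis, as
    for monosodium urate needles).
    """

    opd_nm: float
    axis_angle_deg: float = 45.0
    sign: int = 1

    def __post_init__(self):
        if self.opd_nm < 0:
            raise ValueError("opd_nm must be >= 0")
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")


def _cos_sin(angle_rad):
    """cos/sin with sub-epsilon values snapped to exact zero.

    Keeps the right-angle geometries (crossed polarizers, eigen-axis
    samples) *identically* extinguishing instead of leaving ~1e-33 residual
    intensities from cos(pi/2) = 6.1e-17.
    """
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    c = np.where(np.abs(c) < 1e-15, 0.0, c)
    s = np.where(np.abs(s) < 1e-15, 0.0, s)
    return c, s


def rotation_matrix(angle_rad) -> np.ndarray:
    """2x2 rotation R(theta); broadcasts over array angles to (..., 2, 2)."""
    a = np.asarray(angle_rad, dtype=float)
    c, s = _cos_sin(a)
    out = np.empty(a.shape + (2, 2))
    out[..., 0, 0] = c
    out[..., 0, 1] = -s
    out[..., 1, 0] = s
    out[..., 1, 1] = c
    return out


def linear_polarizer(axis_angle_rad: float, extinction: float = 0.0) -> np.ndarray:
    """Jones matrix of a linear polarizer with transmission axis at ``axis_angle_rad``.

    Ideal (extinction 0): projector onto the transmission axis.  Non-ideal:
    diattenuator diag(1, extinction) in the polarizer frame, where
    ``extinction`` is the crossed-axis field-amplitude leakage.
    """
    if not (0.0 <= extinction < 1.0):
        raise ValueError("extinction must be in [0, 1)")
    r = rotation_matrix(axis_angle_rad)
    d = np.array([[1.0, 0.0], [0.0, extinction]])
    return r @ d @ r.swapaxes(-1, -2)


def retarder(phase_rad, axis_angle_rad) -> np.ndarray:
    """Linear retarder R(theta) diag(e^{+i phi/2}, e^{-i phi/2}) R(-theta).

    ``phase_rad`` and ``axis_angle_rad`` broadcast against each other; the
    slow axis (positive phase lead in this convention) sits at
    ``axis_angle_rad``.  The result is unitary for any real phase.
    """
    phi = np.asarray(phase_rad, dtype=float)
    theta = np.asarray(axis_angle_rad, dtype=float)
    phi, theta = np.broadcast_arrays(phi, theta)
    c, s = _cos_sin(theta)
    ep = np.exp(0.5j * phi)
    em = np.conj(ep)
    out = np.empty(phi.shape + (2, 2), dtype=complex)
    out[..., 0, 0] = c * c * ep + s * s * em
    out[..., 0, 1] = c * s * (ep - em)
    out[..., 1, 0] = out[..., 0, 1]
    out[..., 1, 1] = s * s * ep + c * c * em
    return out


def sample_retarder(sample: SampleElement, wavelength_nm) -> np.ndarray:
    """Jones matrix of a sample element at the given wavelength(s) (nm)."""
    lam = np.asarray(wavelength_nm, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be > 0")
    phase = sample.sign * 2.0 * np.pi * sample.opd_nm / lam
    return retarder(phase, np.deg2rad(sample.axis_angle_deg))


def _propagate_fields(
    wavelengths_nm: np.ndarray,
    train: OpticalTrainConfig,
    sample_phase: np.ndarray | None,
    sample_axis_rad: np.ndarray | None,
) -> np.ndarray:
    """Transmitted field for each (pixel-like leading axes, wavelength).

    ``sample_phase``/``sample_axis_rad`` broadcast against the wavelength
    axis (last axis).  Element order follows the physical light path:
    LP1 field -> FWP -> sample -> LP2.
    """
    lam = np.asarray(wavelengths_nm, dtype=float)
    pol = np.deg2rad(train.polarizer_angle_deg)
    # LP1 prepares the state; its leakage only matters for unpolarized input
    # modeling, so the non-ideal extinction is applied at the analyzer.
    field = np.array(_cos_sin(pol), dtype=complex)
    if train.fwp_present:
        fwp_phase = 2.0 * np.pi * train.fwp_design_opd_nm / lam
        m_fwp = retarder(fwp_phase, np.deg2rad(train.fwp_angle_deg))
        field = np.einsum("...ij,j->...i", m_fwp, field)
    else:
        field = np.broadcast_to(field, lam.shape + (2,))
    if sample_phase is not None:
        m_s = retarder(sample_phase, sample_axis_rad)
        field = np.einsum("...ij,...j->...i", m_s, field)
    m_an = linear_polarizer(
        np.deg2rad(train.analyzer_angle_deg), train.polarizer_extinction
    ).astype(complex)
    return np.einsum("ij,...j->...i", m_an, field)


def transmitted_spd(
    source: SpectralDistribution,
    train: OpticalTrainConfig,
    sample: SampleElement | None = None,
) -> SpectralDistribution:
    """Spectral power reaching the sensor through the full train.

    Per wavelength, the unit field prepared by LP1 propagates through the
    FWP (if present) and the sample (if any) and is projected by the
    analyzer; the transmitted power is the source power times the squared
    field magnitude, so it never exceeds the source at any wavelength.
    """
    lam = source.wavelengths_nm
    if sample is None:
        phase = axis = None
    else:
        phase = sample.sign * 2.0 * np.pi * sample.opd_nm / lam
        axis = np.deg2rad(sample.axis_angle_deg)
    field = _propagate_fields(lam, train, phase, axis)
    t = np.sum(np.abs(field) ** 2, axis=-1)
    # guard against accumulated rounding pushing |t| infinitesimally past 1
    t = np.clip(t, 0.0, 1.0)
    return SpectralDistribution(lam, source.power * t)


def effective_retardance(sample: SampleElement, train: OpticalTrainConfig) -> float:
    """Signed OPD (nm) of the sample + FWP combination in aligned geometry.

    Valid only when the sample's optic axis is parallel or perpendicular to
    the FWP axis, where the two retarders combine into a single one: slow
    axes parallel add (OPD + Gamma0), crossed subtract (OPD - Gamma0).  The
    sign is relative to the sample's slow axis: a negative value means the
    net slow axis lies along the FWP's slow axis instead.
    """
    if not train.fwp_present:
        raise ValueError("effective_retardance requires fwp_present=True")
    sample_slow = sample.axis_angle_deg + (90.0 if sample.sign < 0 else 0.0)
    rel = (sample_slow - train.fwp_angle_deg) % 180.0
    if min(abs(rel - x) for x in (0.0, 90.0, 180.0)) > 1e-9:
        raise ValueError(
            "sample axis must be parallel or perpendicular to the FWP axis "
            f"(relative angle {rel:.3f} deg); no closed form otherwise"
        )
    parallel = min(abs(rel), abs(rel - 180.0)) <= 1e-9
    if parallel:
        return sample.opd_nm + train.fwp_design_opd_nm
    return sample.opd_nm - train.fwp_design_opd_nm
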