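"""Spectra to CIE XYZ / CIELAB / display sRGB, and CIEDE2000 differences.

Tristimulus values are trapezoidal integrals of I(lambda) against the CIE
1931 2-degree observer over the visible band; CIELAB is computed against an
explicit reference white (by default the unobstructed illuminant itself,
mimicking a camera white-balanced to the source).  Display sRGB uses the
standard D65-referred primaries without chromatic adaptation — adequate for
previews and for round-tripping synthetic images, not colorimetric truth.

Colors are plain float arrays with a trailing axis of length 3; every
function broadcasts over leading axes.
"""

from __future__ import annotations

import numpy as np

from .spectra import BandLimits, ColorMatchingFunctions, SpectralDistribution

# sRGB (IEC 61966-2-1) linear-RGB <-> XYZ matrices, D65 white, Y in [0, 1]
_SRGB_FROM_XYZ = np.array(
    [
        [3.2406, -1.5372, -0.4986],
        [-0.9689, 1.8758, 0.0415],
        [0.0557, -0.2040, 1.0570],
    ]
)
_XYZ_FROM_SRGB = np.linalg.inv(_SRGB_FROM_XYZ)

_DELTA = 6.0 / 29.0


def spd_to_xyz(
    spd: SpectralDistribution,
    cmf: ColorMatchingFunctions,
    band: BandLimits | None = None,
) -> np.ndarray:
    """Tristimulus (X, Y, Z) of a spectrum by trapezoidal integration.

    ``spd`` and ``cmf`` must share their grid; the integral runs over the
    grid points inside ``band`` (full grid by default).
    """
    if band is None:
        band = BandLimits()
    if spd.wavelengths_nm.shape != cmf.wavelengths_nm.shape or not np.array_equal(
        spd.wavelengths_nm, cmf.wavelengths_nm
    ):
        raise ValueError(
            "spectrum and CMF grids differ: "
            f"spd [{spd.wavelengths_nm[0]}..{spd.wavelengths_nm[-1]}] "
            f"({spd.wavelengths_nm.size} pts) vs "
            f"cmf [{cmf.wavelengths_nm[0]}..{cmf.wavelengths_nm[-1]}] "
            f"({cmf.wavelengths_nm.size} pts)"
        )
    w = spd.wavelengths_nm
    sel = (w >= band.lambda_i) & (w <= band.lambda_f)
    if sel.sum() < 2:
        raise ValueError("band selects fewer than 2 grid points")
    lam = w[sel]
    i = spd.power[sel]
    return np.array(
        [
            np.trapezoid(i * cmf.xbar[sel], lam),
            np.trapezoid(i * cmf.ybar[sel], lam),
            np.trapezoid(i * cmf.zbar[sel], lam),
        ]
    )


def spectra_to_xyz(
    power: np.ndarray,
    cmf: ColorMatchingFunctions,
    band: BandLimits | None = None,
) -> np.ndarray:
    """Vectorized :func:`spd_to_xyz` for a stack of spectra (..., n_lambda)."""
    if band is None:
        band = BandLimits()
    w = cmf.wavelengths_nm
    sel = (w >= band.lambda_i) & (w <= band.lambda_f)
    lam = w[sel]
    p = np.asarray(power, dtype=float)[..., sel]
    bars = np.stack([cmf.xbar[sel], cmf.ybar[sel], cmf.zbar[sel]], axis=-1)
    return np.trapezoid(p[..., :, None] * bars, lam, axis=-2)


def reference_white(
    source: SpectralDistribution,
    cmf: ColorMatchingFunctions,
    band: BandLimits | None = None,
) -> np.ndarray:
    """XYZ of the unobstructed illuminant, scaled so Y = 100."""
    xyz = spd_to_xyz(source, cmf, band)
    if xyz[1] <= 0:
        raise ValueError("illuminant has zero luminance over the band")
    return xyz * (100.0 / xyz[1])


def _lab_f(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.where(t > _DELTA**3, np.cbrt(t), t / (3.0 * _DELTA**2) + 4.0 / 29.0)


def xyz_to_lab(xyz: np.ndarray, white: np.ndarray) -> np.ndarray:
    """CIELAB (L*, a*, b*) relative to ``white`` (Xw, Yw, Zw with Yw = 100)."""
    white = np.asarray(white, dtype=float)
    if np.any(white <= 0):
        raise ValueError("reference white components must be > 0")
    r = np.asarray(xyz, dtype=float) / white
    fx, fy, fz = _lab_f(r[..., 0]), _lab_f(r[..., 1]), _lab_f(r[..., 2])
    return np.stack([116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)], axis=-1)


def _srgb_encode(linear: np.ndarray) -> np.ndarray:
    linear = np.asarray(linear, dtype=float)
    return np.where(
        linear <= 0.0031308,
        12.92 * linear,
        1.055 * np.power(np.clip(linear, 0.0031308, None), 1.0 / 2.4) - 0.055,
    )


def _srgb_decode(encoded: np.ndarray) -> np.ndarray:
    encoded = np.asarray(encoded, dtype=float)
    return np.where(
        encoded <= 0.04045,
        encoded / 12.92,
        np.power((np.clip(encoded, 0.04045, None) + 0.055) / 1.055, 2.4),
    )


def xyz_to_srgb(xyz: np.ndarray, white: np.ndarray) -> np.ndarray:
    """Display sRGB in [0, 1]: Y-normalize by the white, apply the standard
    D65 matrix, clip out-of-gamut channels, gamma-encode."""
    white = np.asarray(white, dtype=float)
    lin = np.asarray(xyz, dtype=float) / white[1] @ _SRGB_FROM_XYZ.T
    return _srgb_encode(np.clip(lin, 0.0, 1.0))


def srgb_to_xyz(rgb: np.ndarray, white: np.ndarray) -> np.ndarray:
    """Inverse of :func:`xyz_to_srgb` for in-gamut colors."""
    white = np.asarray(white, dtype=float)
    lin = _srgb_decode(np.asarray(rgb, dtype=float))
    return (lin @ _XYZ_FROM_SRGB.T) * white[1]


def srgb_to_lab(rgb: np.ndarray, white: np.ndarray) -> np.ndarray:
    """Decode sRGB pixels straight to CIELAB under the given white."""
    return xyz_to_lab(srgb_to_xyz(rgb, white), white)


def ciede2000(lab1: np.ndarray, lab2: np.ndarray) -> np.ndarray:
    """CIEDE2000 color difference, broadcasting over leading axes.

    Full formula: lightness/chroma/hue weightings S_L, S_C, S_H, the
    rotation term R_T coupling chroma and hue in the blue region, and the
    C^7/(C^7 + 25^7) chroma correction.  Symmetric, zero iff the Lab
    coordinates coincide.
    """
    lab1 = np.asarray(lab1, dtype=float)
    lab2 = np.asarray(lab2, dtype=float)
    L1, a1, b1 = lab1[..., 0], lab1[..., 1], lab1[..., 2]
    L2, a2, b2 = lab2[..., 0], lab2[..., 1], lab2[..., 2]

    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    c7 = Cbar**7
    G = 0.5 * (1.0 - np.sqrt(c7 / (c7 + 25.0**7)))
    a1p = (1.0 + G) * a1
    a2p = (1.0 + G) * a2
    C1p = np.hypot(a1p, b1)
    C2p = np.hypot(a2p, b2)

    h1p = np.where((a1p == 0) & (b1 == 0), 0.0, np.degrees(np.arctan2(b1, a1p)) % 360.0)
    h2p = np.where((a2p == 0) & (b2 == 0), 0.0, np.degrees(np.arctan2(b2, a2p)) % 360.0)

    dLp = L2 - L1
    dCp = C2p - C1p
    hdiff = h2p - h1p
    dhp = np.where(
        C1p * C2p == 0,
        0.0,
        np.where(
            np.abs(hdiff) <= 180.0,
            hdiff,
            np.where(hdiff > 180.0, hdiff - 360.0, hdiff + 360.0),
        ),
    )
    dHp = 2.0 * np.sqrt(C1p * C2p) * np.sin(np.radians(0.5 * dhp))

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)
    hsum = h1p + h2p
    habs = np.abs(h1p - h2p)
    hbp = np.where(
        C1p * C2p == 0,
        hsum,
        np.where(
            habs <= 180.0,
            0.5 * hsum,
            np.where(hsum < 360.0, 0.5 * (hsum + 360.0), 0.5 * (hsum - 360.0)),
        ),
    )

    T = (
        1.0
        - 0.17 * np.cos(np.radians(hbp - 30.0))
        + 0.24 * np.cos(np.radians(2.0 * hbp))
        + 0.32 * np.cos(np.radians(3.0 * hbp + 6.0))
        - 0.20 * np.cos(np.radians(4.0 * hbp - 63.0))
    )
    dtheta = 30.0 * np.exp(-(((hbp - 275.0) / 25.0) ** 2))
    cb7 = Cbp**7
    RC = 2.0 * np.sqrt(cb7 / (cb7 + 25.0**7))
    SL = 1.0 + 0.015 * (Lbp - 50.0) ** 2 / np.sqrt(20.0 + (Lbp - 50.0) ** 2)
    SC = 1.0 + 0.045 * Cbp
    SH = 1.0 + 0.015 * Cbp * T
    RT = -np.sin(np.radians(2.0 * dtheta)) * RC

    tL = dLp / SL
    tC = dCp / SC
    tH = dHp / SH
    return np.sqrt(tL**2 + tC**2 + tH**2 + RT * tC * tH)
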