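"""Retardance lookup table, CIEDE2000 phase retrieval, and birefringence.

The forward model maps an optical path difference (OPD, nm) to an
interference color; this module tabulates that map on a dense OPD grid (the
reference LUT), inverts it per pixel by minimizing the CIEDE2000 distance
between the observed color and the table, and converts the result to
birefringence.

Because the illuminant is broadband, a single phase value must stand in for
the whole band: the band average of phi(lambda) = 2*pi*OPD/lambda.  With
OPD constant over the band this has the closed form

    phi_avg = 2*pi * OPD * ln(lambda_f/lambda_i) / (lambda_f - lambda_i)

and its inverse at known thickness d gives the birefringence

    dn = (lambda_f - lambda_i) * phi_avg / (2*pi * d * ln(lambda_f/lambda_i)).

Color similarity across interference orders makes the inversion ambiguous;
ties are broken toward the smallest OPD (lowest order, the conventional
reading of interference charts) and pixels whose ΔE(OPD) curve has several
near-degenerate local minima are flagged.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import jones
from .colorimetry import (
    ciede2000,
    reference_white,
    spectra_to_xyz,
    srgb_to_lab,
    xyz_to_lab,
    xyz_to_srgb,
)
from .spectra import BandLimits, ColorMatchingFunctions, SpectralDistribution, cie_1931_cmf

_LUT_MAGIC = "polchip-lut-v1"


def single_wavelength_phase(opd_nm, wavelength_nm):
    """Phase shift 2*pi*OPD/lambda (rad) at one wavelength."""
    lam = np.asarray(wavelength_nm, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be > 0")
    return 2.0 * np.pi * np.asarray(opd_nm, dtype=float) / lam


def average_phase(opd_nm, band: BandLimits | None = None):
    """Band-averaged phase shift (rad) of a constant-OPD retarder."""
    if band is None:
        band = BandLimits()
    opd = np.asarray(opd_nm, dtype=float)
    return (
        2.0
        * np.pi
        * opd
        * np.log(band.lambda_f / band.lambda_i)
        / (band.lambda_f - band.lambda_i)
    )


@dataclass(frozen=True)
class BirefringenceEstimate:
    """Birefringence dn with the thickness, band, and phase that produced it."""

    delta_n: float
    thickness_um: float
    band: BandLimits
    avg_phase_rad: float

    @property
    def opd_nm(self) -> float:
        return self.delta_n * self.thickness_um * 1e3


def birefringence_from_phase(
    avg_phase_rad, thickness_um: float, band: BandLimits | None = None
) -> BirefringenceEstimate:
    """Invert the band-averaged phase relation at known thickness.

    Exact inverse of :func:`average_phase` composed with OPD = d * dn.
    """
    if band is None:
        band = BandLimits()
    if thickness_um <= 0:
        raise ValueError("thickness_um must be > 0")
    phi = float(avg_phase_rad)
    d_nm = thickness_um * 1e3
    dn = (
        (band.lambda_f - band.lambda_i)
        * phi
        / (2.0 * np.pi * d_nm * np.log(band.lambda_f / band.lambda_i))
    )
    return BirefringenceEstimate(dn, thickness_um, band, phi)


@dataclass(frozen=True)
class ColorLUT:
    """Reference table OPD -> (Lab, display RGB, band-averaged phase).

    ``metadata`` records the optical-train configuration, the spectrum hash,
    the reference white, and the band, so a LUT can be matched against the
    acquisition settings of an image before retrieval.
    """

    opd_grid_nm: np.ndarray
    lab: np.ndarray
    rgb: np.ndarray
    avg_phase_rad: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        n = self.opd_grid_nm.size
        if not np.all(np.diff(self.opd_grid_nm) > 0):
            raise ValueError("opd_grid_nm must be strictly ascending")
        if self.lab.shape != (n, 3) or self.rgb.shape != (n, 3):
            raise ValueError("lab and rgb must have shape (n_opd, 3)")
        if self.avg_phase_rad.shape != (n,):
            raise ValueError("avg_phase_rad must have shape (n_opd,)")

    @property
    def step_nm(self) -> float:
        return float(np.min(np.diff(self.opd_grid_nm)))

    @property
    def white_xyz(self) -> np.ndarray:
        return np.asarray(self.metadata["white_xyz"], dtype=float)

    @property
    def band(self) -> BandLimits:
        lo, hi = self.metadata.get("band", (380.0, 780.0))
        return BandLimits(lo, hi)

    def to_csv(self, path) -> None:
        """Write the LUT with a commented YAML metadata header.

        Floats are serialized with shortest round-trip ``repr``, so identical
        inputs give byte-identical files.
        """
        buf = io.StringIO()
        buf.write(f"# {_LUT_MAGIC}\n")
        meta = yaml.safe_dump(self.metadata, sort_keys=True, default_flow_style=False)
        for line in meta.rstrip("\n").split("\n"):
            buf.write(f"# {line}\n")
        buf.write("opd_nm,L,a,b,R,G,B,avg_phase_rad\n")
        for i in range(self.opd_grid_nm.size):
            row = [
                self.opd_grid_nm[i],
                *self.lab[i],
                *self.rgb[i],
                self.avg_phase_rad[i],
            ]
            buf.write(",".join(repr(float(v)) for v in row) + "\n")
        with open(path, "w", newline="\n") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def from_csv(cls, path) -> "ColorLUT":
        meta_lines = []
        rows = []
        with open(path) as fh:
            first = fh.readline().strip()
            if first != f"# {_LUT_MAGIC}":
                raise ValueError(f"{path}: not a {_LUT_MAGIC} file")
            for line in fh:
                if line.startswith("#"):
                    meta_lines.append(line[2:] if line.startswith("# ") else line[1:])
                elif line.startswith("opd_nm"):
                    continue
                elif line.strip():
                    rows.append([float(v) for v in line.split(",")])
        metadata = yaml.safe_load("".join(meta_lines)) or {}
        data = np.asarray(rows, dtype=float)
        return cls(
            opd_grid_nm=data[:, 0],
            lab=data[:, 1:4],
            rgb=data[:, 4:7],
            avg_phase_rad=data[:, 7],
            metadata=metadata,
        )


def build_color_lut(
    source: SpectralDistribution,
    train: jones.OpticalTrainConfig,
    opd_min_nm: float = 0.0,
    opd_max_nm: float = 3000.0,
    step_nm: float = 1.0,
    cmf: ColorMatchingFunctions | None = None,
    band: BandLimits | None = None,
    sample_axis_deg: float = 45.0,
) -> ColorLUT:
    """Tabulate the forward model on a dense OPD grid.

    For every OPD on the grid, a uniform retarder with its optic axis at
    ``sample_axis_deg`` (45 degrees by default, the maximum-contrast
    placement between crossed polarizers) is propagated through the train
    and the transmitted spectrum converted to Lab and display RGB under the
    illuminant's own white.
    """
    if step_nm <= 0:
        raise ValueError("step_nm must be > 0")
    if not (opd_max_nm > opd_min_nm >= 0):
        raise ValueError("need opd_max_nm > opd_min_nm >= 0")
    if cmf is None:
        cmf = cie_1931_cmf(source.wavelengths_nm)
    if band is None:
        band = BandLimits()
    opd = np.arange(opd_min_nm, opd_max_nm + 0.5 * step_nm, step_nm)
    lam = source.wavelengths_nm
    phases = 2.0 * np.pi * opd[:, None] / lam[None, :]
    fields = jones._propagate_fields(
        lam, train, phases, np.deg2rad(sample_axis_deg)
    )
    power = source.power * np.clip(np.sum(np.abs(fields) ** 2, axis=-1), 0.0, 1.0)
    xyz = spectra_to_xyz(power, cmf, band)
    white = reference_white(source, cmf, band)
    scale = 100.0 / spectra_to_xyz(source.power, cmf, band)[1]
    xyz = xyz * scale
    lab = xyz_to_lab(xyz, white)
    rgb = xyz_to_srgb(xyz, white)
    metadata = {
        "train": train.to_dict(),
        "spectrum_sha256": source.sha256(),
        "white_xyz": [float(v) for v in white],
        "band": [float(band.lambda_i), float(band.lambda_f)],
        "sample_axis_deg": float(sample_axis_deg),
        "opd_min_nm": float(opd_min_nm),
        "opd_max_nm": float(opd_max_nm),
        "step_nm": float(step_nm),
    }
    return ColorLUT(opd, lab, rgb, average_phase(opd, band), metadata)


@dataclass(frozen=True)
class RetrievedPhaseMap:
    """Per-pixel retrieval result: matched OPD, phase, residual, ambiguity."""

    opd_nm: np.ndarray
    avg_phase_rad: np.ndarray
    delta_e: np.ndarray
    ambiguous: np.ndarray
    grid_step_nm: float
    metadata: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.opd_nm.shape


def _local_minima_mask(de: np.ndarray) -> np.ndarray:
    """Strict local minima (incl. endpoints) along the last (OPD) axis."""
    lower_prev = np.empty_like(de, dtype=bool)
    lower_next = np.empty_like(de, dtype=bool)
    lower_prev[..., 0] = True
    lower_prev[..., 1:] = de[..., 1:] < de[..., :-1]
    lower_next[..., -1] = True
    lower_next[..., :-1] = de[..., :-1] <= de[..., 1:]
    return lower_prev & lower_next


def retrieve_phase_from_lab(
    lab: np.ndarray,
    lut: ColorLUT,
    ambiguity_tol: float = 1.0,
    luminance_invariant: bool = False,
    chunk: int = 2048,
) -> RetrievedPhaseMap:
    """Match Lab pixels (..., 3) against the LUT by CIEDE2000 minimization.

    The matched OPD is the argmin of ΔE over the table; exact ties resolve
    to the smallest OPD.  A pixel is flagged ambiguous when two or more
    local minima of its ΔE(OPD) curve lie within ``ambiguity_tol`` of the
    global minimum — the color-aliasing between interference orders.

    ``luminance_invariant`` matches on (a*, b*) only (L* of both sides held
    at 50), for images whose exposure is not calibrated to the LUT white.
    """
    lab = np.asarray(lab, dtype=float)
    if lab.shape[-1] != 3:
        raise ValueError("lab must have a trailing axis of length 3")
    lut_lab = lut.lab
    if luminance_invariant:
        lab = lab.copy()
        lab[..., 0] = 50.0
        lut_lab = lut_lab.copy()
        lut_lab[:, 0] = 50.0
    flat = lab.reshape(-1, 3)
    n = flat.shape[0]
    idx = np.empty(n, dtype=np.intp)
    best = np.empty(n)
    amb = np.empty(n, dtype=bool)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        de = ciede2000(flat[lo:hi, None, :], lut_lab[None, :, :])
        i = np.argmin(de, axis=1)  # first occurrence = smallest OPD
        idx[lo:hi] = i
        dmin = np.take_along_axis(de, i[:, None], axis=1)[:, 0]
        best[lo:hi] = dmin
        minima = _local_minima_mask(de)
        near = minima & (de <= dmin[:, None] + ambiguity_tol)
        amb[lo:hi] = near.sum(axis=1) >= 2
    shape = lab.shape[:-1]
    return RetrievedPhaseMap(
        opd_nm=lut.opd_grid_nm[idx].reshape(shape),
        avg_phase_rad=lut.avg_phase_rad[idx].reshape(shape),
        delta_e=best.reshape(shape),
        ambiguous=amb.reshape(shape),
        grid_step_nm=lut.step_nm,
        metadata={
            "ambiguity_tol": float(ambiguity_tol),
            "luminance_invariant": bool(luminance_invariant),
            **{k: lut.metadata[k] for k in ("spectrum_sha256", "train") if k in lut.metadata},
        },
    )


def retrieve_phase(
    image: np.ndarray,
    lut: ColorLUT,
    ambiguity_tol: float = 1.0,
    luminance_invariant: bool = False,
) -> RetrievedPhaseMap:
    """Retrieve per-pixel OPD from an sRGB image in [0, 1].

    Pixels are decoded through the inverse sRGB transfer function to XYZ and
    Lab under the LUT's reference white, then matched with
    :func:`retrieve_phase_from_lab`.
    """
    image = np.asarray(image, dtype=float)
    if image.shape[-1] != 3:
        raise ValueError("image must have a trailing RGB axis of length 3")
    if np.any(image < 0) or np.any(image > 1) or not np.all(np.isfinite(image)):
        raise ValueError("image values must lie in [0, 1]")
    lab = srgb_to_lab(image, lut.white_xyz)
    return retrieve_phase_from_lab(lab, lut, ambiguity_tol, luminance_invariant)


def sign_from_fwp_pair(
    map_plus: RetrievedPhaseMap,
    map_minus: RetrievedPhaseMap,
    object_axis_deg: float,
    fwp_plus_angle_deg: float = 45.0,
    fwp_minus_angle_deg: float = -45.0,
    min_diff_nm: float | None = None,
) -> np.ndarray:
    """Sign of birefringence from a +/-45 degree full-waveplate image pair.

    The waveplate adds retardance when the object's slow axis is parallel to
    its own slow axis and subtracts when crossed, so the orientation giving
    the *larger* retrieved OPD locates the object's slow axis.  Comparing
    that axis with the object's long (morphological) axis yields the sign:
    +1 when the slow axis lies along the long axis, -1 when across it
    (negative birefringence, the monosodium-urate signature).  Pixels whose
    OPD difference is below ``min_diff_nm`` (one LUT step by default) return
    0 (undetermined); a zero-OPD background is undetermined everywhere.
    """
    if map_plus.shape != map_minus.shape:
        raise ValueError(
            f"phase-map shapes differ: {map_plus.shape} vs {map_minus.shape}"
        )
    if min_diff_nm is None:
        min_diff_nm = max(map_plus.grid_step_nm, map_minus.grid_step_nm)
    diff = map_plus.opd_nm - map_minus.opd_nm
    slow_axis = np.where(diff > 0, fwp_plus_angle_deg, fwp_minus_angle_deg)
    rel = np.abs((slow_axis - object_axis_deg + 90.0) % 180.0 - 90.0)
    sign = np.where(rel < 45.0, 1, -1).astype(np.int8)
    sign[np.abs(diff) < min_diff_nm] = 0
    return sign
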