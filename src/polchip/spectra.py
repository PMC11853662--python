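"""Wavelength grids, illuminant spectra, and CIE 1931 color-matching functions.

Everything downstream (Jones propagation, tristimulus integration, the
retardance lookup table) works on a shared wavelength grid.  The canonical
grid is 380-780 nm in 5 nm steps, the native resolution of the embedded
CIE 1931 2-degree observer tabulation; all spectral integrals in the package
are trapezoidal on whatever grid a distribution carries.
"""

from __future__ import annotations

import csv
import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np

from ._cmf_data import CIE_1931_2DEG_5NM

logger = logging.getLogger(__name__)

VISIBLE_MIN_NM = 380.0
VISIBLE_MAX_NM = 780.0
#: Widest band the CMF interpolator accepts; outside the shipped table the
#: observer curves are taken as zero.
CMF_GRID_MIN_NM = 360.0
CMF_GRID_MAX_NM = 830.0


def canonical_grid() -> np.ndarray:
    """The 81-point 380-780 nm / 5 nm wavelength grid used by default."""
    return np.arange(VISIBLE_MIN_NM, VISIBLE_MAX_NM + 1.0, 5.0)


def _validate_grid(wavelengths_nm: np.ndarray) -> np.ndarray:
    w = np.asarray(wavelengths_nm, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValueError("wavelength grid must be a 1-D array with >= 2 points")
    if not np.all(np.isfinite(w)):
        raise ValueError("wavelength grid contains non-finite values")
    if not np.all(np.diff(w) > 0):
        raise ValueError("wavelength grid must be strictly ascending")
    return w


@dataclass(frozen=True)
class SpectralDistribution:
    """Relative spectral power I(lambda) on a strictly ascending grid (nm)."""

    wavelengths_nm: np.ndarray
    power: np.ndarray

    def __post_init__(self):
        w = _validate_grid(self.wavelengths_nm)
        p = np.asarray(self.power, dtype=float)
        if p.shape != w.shape:
            raise ValueError(
                f"power shape {p.shape} does not match grid shape {w.shape}"
            )
        if not np.all(np.isfinite(p)):
            raise ValueError("spectral power contains non-finite values")
        if np.any(p < 0):
            raise ValueError("spectral power must be non-negative")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "power", p)
        w.setflags(write=False)
        p.setflags(write=False)

    def resample(self, grid: np.ndarray) -> "SpectralDistribution":
        """Linear interpolation onto ``grid``; zero outside the stored range."""
        grid = _validate_grid(grid)
        if grid.shape == self.wavelengths_nm.shape and np.array_equal(
            grid, self.wavelengths_nm
        ):
            return self
        p = np.interp(grid, self.wavelengths_nm, self.power, left=0.0, right=0.0)
        return SpectralDistribution(grid, p)

    def sha256(self) -> str:
        """Content hash used to tie LUTs and configs to a specific spectrum."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.wavelengths_nm).tobytes())
        h.update(np.ascontiguousarray(self.power).tobytes())
        return h.hexdigest()


@dataclass(frozen=True)
class ColorMatchingFunctions:
    """CIE 1931 2-degree observer curves xbar, ybar, zbar on a common grid."""

    wavelengths_nm: np.ndarray
    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray

    def __post_init__(self):
        w = _validate_grid(self.wavelengths_nm)
        object.__setattr__(self, "wavelengths_nm", w)
        for name in ("xbar", "ybar", "zbar"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != w.shape:
                raise ValueError(f"{name} shape {v.shape} != grid shape {w.shape}")
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise ValueError(f"{name} must be finite and non-negative")
            object.__setattr__(self, name, v)
            v.setflags(write=False)
        w.setflags(write=False)


@dataclass(frozen=True)
class BandLimits:
    """Integration band [lambda_i, lambda_f] for the tristimulus integrals."""

    lambda_i: float = 380.0
    lambda_f: float = 780.0

    def __post_init__(self):
        if not (self.lambda_i < self.lambda_f):
            raise ValueError(
                f"lambda_i ({self.lambda_i}) must be < lambda_f ({self.lambda_f})"
            )


def led_spectrum(
    blue_peak_nm: float = 450.0,
    blue_fwhm_nm: float = 25.0,
    phosphor_peak_nm: float = 560.0,
    phosphor_fwhm_nm: float = 110.0,
    phosphor_ratio: float = 0.8,
    grid: np.ndarray | None = None,
) -> SpectralDistribution:
    """Parametric white-LED model: blue pump plus broad phosphor emission.

    The spectrum is a sum of two Gaussians — a narrow band at ``blue_peak_nm``
    (the InGaN die) and a broad band at ``phosphor_peak_nm`` with relative
    peak amplitude ``phosphor_ratio`` (the YAG-type phosphor) — normalized so
    its maximum on the grid equals 1.  Defaults emulate a generic cool-white
    epoxy LED.
    """
    if grid is None:
        grid = canonical_grid()
    grid = _validate_grid(grid)
    if grid[0] < VISIBLE_MIN_NM:
        raise ValueError(
            f"grid minimum {grid[0]} nm is below the visible band "
            f"({VISIBLE_MIN_NM} nm)"
        )
    if grid[-1] > VISIBLE_MAX_NM:
        raise ValueError(
            f"grid maximum {grid[-1]} nm is above the visible band "
            f"({VISIBLE_MAX_NM} nm)"
        )
    for name, peak in (("blue", blue_peak_nm), ("phosphor", phosphor_peak_nm)):
        if not (VISIBLE_MIN_NM <= peak <= VISIBLE_MAX_NM):
            raise ValueError(f"{name} peak {peak} nm outside [380, 780] nm")
    if blue_fwhm_nm <= 0 or phosphor_fwhm_nm <= 0:
        raise ValueError("FWHM values must be positive")
    if phosphor_ratio < 0:
        raise ValueError("phosphor_ratio must be >= 0")

    def gauss(peak, fwhm):
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return np.exp(-0.5 * ((grid - peak) / sigma) ** 2)

    p = gauss(blue_peak_nm, blue_fwhm_nm) + phosphor_ratio * gauss(
        phosphor_peak_nm, phosphor_fwhm_nm
    )
    return SpectralDistribution(grid, p / p.max())


def load_spectrum(path, grid: np.ndarray | None = None) -> SpectralDistribution:
    """Load a two-column (wavelength nm, relative power) CSV spectrum.

    A single non-numeric header line is auto-detected and skipped.  The data
    are linearly interpolated onto ``grid`` (canonical grid by default); grid
    points outside the file's range get zero power; negative readings are
    clipped to zero with a warning.
    """
    if grid is None:
        grid = canonical_grid()
    rows = []
    with open(path, newline="") as fh:
        for i, rec in enumerate(csv.reader(fh)):
            if not rec:
                continue
            if len(rec) < 2:
                raise ValueError(
                    f"{path}: line {i + 1} has fewer than 2 columns"
                )
            try:
                rows.append((float(rec[0]), float(rec[1])))
            except ValueError:
                if i == 0:
                    continue  # header line
                raise ValueError(f"{path}: non-numeric data at line {i + 1}")
    if len(rows) < 10:
        raise ValueError(f"{path}: need >= 10 data rows, got {len(rows)}")
    data = np.asarray(rows, dtype=float)
    w, p = data[:, 0], data[:, 1]
    if not np.all(np.diff(w) > 0):
        raise ValueError(f"{path}: wavelengths must be strictly ascending")
    if w[-1] - w[0] < 300.0:
        raise ValueError(
            f"{path}: spectrum spans {w[-1] - w[0]:.0f} nm, need >= 300 nm"
        )
    if np.any(p < 0):
        logger.warning(
            "%s: %d negative power sample(s) clipped to 0", path, int((p < 0).sum())
        )
        p = np.clip(p, 0.0, None)
    grid = _validate_grid(grid)
    power = np.interp(grid, w, p, left=0.0, right=0.0)
    return SpectralDistribution(grid, power)


def cie_1931_cmf(grid: np.ndarray | None = None) -> ColorMatchingFunctions:
    """CIE 1931 2-degree color-matching functions interpolated onto ``grid``.

    The shipped table is the native 5 nm tabulation over 380-780 nm;
    interpolation is linear and the curves are taken as zero outside the
    table (they are < 2e-3 of peak at both ends).
    """
    if grid is None:
        grid = canonical_grid()
    grid = _validate_grid(grid)
    if grid[0] < CMF_GRID_MIN_NM or grid[-1] > CMF_GRID_MAX_NM:
        raise ValueError(
            f"grid [{grid[0]}, {grid[-1]}] nm outside the supported "
            f"[{CMF_GRID_MIN_NM}, {CMF_GRID_MAX_NM}] nm range"
        )
    w = CIE_1931_2DEG_5NM[:, 0]
    curves = [
        np.interp(grid, w, CIE_1931_2DEG_5NM[:, k], left=0.0, right=0.0)
        for k in (1, 2, 3)
    ]
    return ColorMatchingFunctions(grid, *curves)
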