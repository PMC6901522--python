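"""CD and fluorescence post-processing.

Buffer-baseline subtraction, conversion of CD millidegrees to molar
ellipticity [theta] = theta_mdeg / (10 * c * l) in deg cm^2 dmol^-1,
Savitzky–Golay smoothing, and emission-peak location by polynomial fit
(sixth order by default, matching routine spectrofluorometer practice).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .io_formats import XYSpectrum

__all__ = [
    "CdSpectrum",
    "SmoothParams",
    "PeakMaxResult",
    "subtract_baseline",
    "to_molar_ellipticity",
    "savgol_smooth",
    "polyfit_peak_max",
    "average_spectra",
]


@dataclass(frozen=True)
class CdSpectrum:
    """A CD scan in millidegrees plus the sample parameters for conversion."""

    spectrum: XYSpectrum
    concentration_m: float
    pathlength_cm: float

    def __post_init__(self) -> None:
        if self.concentration_m <= 0:
            raise ValueError("concentration must be positive")
        if self.pathlength_cm <= 0:
            raise ValueError("pathlength must be positive")


@dataclass(frozen=True)
class SmoothParams:
    window: int = 11
    polyorder: int = 3

    def __post_init__(self) -> None:
        if self.window % 2 == 0:
            raise ValueError("window must be odd")
        if self.window < self.polyorder + 2:
            raise ValueError("window must be >= polyorder + 2")


@dataclass(frozen=True)
class PeakMaxResult:
    """Location of an emission maximum from a polynomial trendline."""

    wavelength_nm: float
    degree: int
    rmse: float
    edge_maximum: bool  # True when the maximum sits on the data boundary


def _require_same_grid(a: XYSpectrum, b: XYSpectrum) -> None:
    if len(a) != len(b) or not np.array_equal(a.x, b.x):
        raise ValueError("wavelength grids do not match exactly (no interpolation)")


def subtract_baseline(sample: XYSpectrum, buffer: XYSpectrum) -> XYSpectrum:
    """Pointwise sample - buffer on an identical wavelength grid."""
    _require_same_grid(sample, buffer)
    return XYSpectrum(sample.x.copy(), sample.y - buffer.y, dict(sample.meta))


def average_spectra(scans: Sequence[XYSpectrum]) -> XYSpectrum:
    """Pointwise mean of replicate scans (identical grids required)."""
    if not scans:
        raise ValueError("no scans to average")
    for s in scans[1:]:
        _require_same_grid(scans[0], s)
    y = np.mean([s.y for s in scans], axis=0)
    return XYSpectrum(scans[0].x.copy(), y, dict(scans[0].meta))


def to_molar_ellipticity(cd: CdSpectrum, n_residues: int | None = None) -> XYSpectrum:
    """Convert mdeg to molar ellipticity, deg cm^2 dmol^-1.

    [theta] = theta_mdeg / (10 * c * l) with c in M and l in cm. Passing
    ``n_residues`` divides additionally by (n_residues - 1) to give
    mean-residue ellipticity.
    """
    denom = 10.0 * cd.concentration_m * cd.pathlength_cm
    if n_residues is not None:
        if n_residues < 2:
            raise ValueError("mean-residue conversion needs n_residues >= 2")
        denom *= n_residues - 1
    meta = dict(cd.spectrum.meta)
    meta["units"] = "deg·cm²·dmol⁻¹"
    return XYSpectrum(cd.spectrum.x.copy(), cd.spectrum.y / denom, meta)


def savgol_smooth(spec: XYSpectrum, params: SmoothParams = SmoothParams()) -> XYSpectrum:
    """Savitzky–Golay smoothing on a uniform grid.

    Each point is replaced by the centre value of the local least-squares
    polynomial; edges are handled by polynomial extension of the terminal
    windows (scipy ``mode="interp"``). Polynomials of degree <= polyorder
    pass through unchanged.
    """
    dx = np.diff(spec.x)
    if not np.allclose(dx, dx[0], rtol=1e-6, atol=1e-9):
        raise ValueError("Savitzky–Golay smoothing requires a uniform x grid")
    if params.window > len(spec):
        raise ValueError("window exceeds spectrum length")
    y = savgol_filter(spec.y, params.window, params.polyorder, mode="interp")
    return XYSpectrum(spec.x.copy(), y, dict(spec.meta))


def polyfit_peak_max(spec: XYSpectrum, degree: int = 6) -> PeakMaxResult:
    """Locate the emission maximum of a polynomial trendline fit.

    A least-squares polynomial of the given degree is fit over the full
    spectrum; the maximum is taken over its real critical points inside the
    scanned window, falling back to a dense-grid evaluation, and never
    extrapolates. A maximum sitting on the window edge is flagged.
    """
    if len(spec) < degree + 2:
        raise ValueError(f"need >= {degree + 2} points for a degree-{degree} fit")
    # centre/scale x for numerical conditioning of the high-degree fit
    x0, xs = spec.x.mean(), np.ptp(spec.x) / 2.0
    z = (spec.x - x0) / xs
    coeffs = np.polynomial.polynomial.polyfit(z, spec.y, degree)
    poly = np.polynomial.Polynomial(coeffs)
    fitted = poly(z)
    rmse = float(np.sqrt(np.mean((fitted - spec.y) ** 2)))

    lo, hi = z.min(), z.max()
    candidates = [lo, hi]
    crit = poly.deriv().roots()
    candidates.extend(
        r.real for r in crit if abs(r.imag) < 1e-9 and lo <= r.real <= hi
    )
    dense = np.linspace(lo, hi, 2001)  # fallback guard against missed roots
    candidates.append(dense[np.argmax(poly(dense))])
    best = max(candidates, key=lambda zz: poly(zz))
    span = hi - lo
    edge = bool(min(best - lo, hi - best) < 1e-9 * max(span, 1.0))
    return PeakMaxResult(
        wavelength_nm=float(best * xs + x0), degree=degree, rmse=rmse, edge_maximum=edge
    )
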