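"""pH-titration curves of amide chemical-shift perturbations and pKa fits.

For each assigned residue the combined perturbation ddNH relative to the
lowest-pH spectrum is tracked across the pH series. Two pKa extractors are
provided:

* ``fit_cubic_pka`` — least-squares third-order polynomial in pH with the
  pKa taken at the inflection (second derivative zero, pKa = -b/(3a)). This
  is the simple graphical method used for incomplete titrations.
* ``fit_hh_pka`` — nonlinear fit of the single-site Henderson–Hasselbalch
  model d(pH) = d_acid + amplitude / (1 + 10**(pKa - pH)), the physical
  model for one protonation event in fast exchange; used as cross-check.

An inflection outside the sampled pH window is reported with
``in_range=False`` and should be treated as an estimate only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .csp import compute_csp
from .io_formats import AssignmentLabel, PeakList

__all__ = [
    "TitrationCurve",
    "PkaFit",
    "FlatCurveError",
    "NoInflectionError",
    "build_titration_curves",
    "fit_cubic_pka",
    "fit_hh_pka",
    "hh_model",
    "percent_of_max",
]


class FlatCurveError(ValueError):
    """The residue shows no titration (ddNH range below tolerance)."""


class NoInflectionError(ValueError):
    """The cubic fit has a vanishing leading coefficient: no inflection."""


@dataclass(frozen=True)
class TitrationCurve:
    """ddNH (ppm) of one residue vs pH, relative to the reference pH."""

    label: AssignmentLabel
    pH: tuple[float, ...]
    delta_NH: tuple[float, ...]
    reference_pH: float

    def __post_init__(self) -> None:
        if len(self.pH) != len(self.delta_NH):
            raise ValueError("pH and delta_NH length mismatch")
        if len(self.pH) < 2:
            raise ValueError("titration curve needs at least 2 points")
        if not all(b > a for a, b in zip(self.pH, self.pH[1:])):
            raise ValueError("pH values must be strictly increasing")

    @property
    def n_points(self) -> int:
        return len(self.pH)

    @property
    def span(self) -> float:
        """Range of ddNH over the curve (ppm)."""
        return max(self.delta_NH) - min(self.delta_NH)

    def is_flat(self, tol: float = 1e-12) -> bool:
        return self.span <= tol


@dataclass(frozen=True)
class PkaFit:
    """Result of a pKa extraction.

    ``coefficients`` holds (a, b, c, d) of y = a x^3 + b x^2 + c x + d for
    the cubic method, or (pKa, d_acid, amplitude) for Henderson–Hasselbalch.
    ``in_range`` is False when the pKa falls outside the sampled window, in
    which case the value is an extrapolated estimate.
    """

    label: AssignmentLabel
    pka: float
    method: str  # "cubic-inflection" | "henderson-hasselbalch"
    coefficients: tuple[float, ...]
    rmse: float
    in_range: bool

    @property
    def pka_rounded(self) -> float:
        """pKa at reporting precision (one decimal)."""
        return round(self.pka, 1)

    @property
    def quality(self) -> str:
        return "fit" if self.in_range else "estimate"


def build_titration_curves(
    lists: Sequence[PeakList], flat_tol: float = 1e-12
) -> tuple[list[TitrationCurve], list[AssignmentLabel]]:
    """Per-residue ddNH-vs-pH curves relative to the lowest-pH spectrum.

    Every list must carry a pH in its condition. Residues unassigned at the
    reference pH are excluded and returned separately; residues missing at
    some other pH simply lack that point. ddNH at the reference pH is 0 by
    construction.
    """
    if len(lists) < 2:
        raise ValueError("need at least 2 pH conditions")
    for pl in lists:
        if pl.condition.pH is None:
            raise ValueError(f"condition {pl.condition.name!r} has no pH")
    ordered = sorted(lists, key=lambda pl: pl.condition.pH)  # type: ignore[arg-type]
    phs = [pl.condition.pH for pl in ordered]
    if len(set(phs)) != len(phs):
        raise ValueError("duplicate pH conditions")
    reference = ordered[0]
    ref_ph = float(reference.condition.pH)  # type: ignore[arg-type]

    all_labels = set().union(*(pl.labels for pl in ordered))
    curves: list[TitrationCurve] = []
    excluded: list[AssignmentLabel] = []
    for label in sorted(all_labels):
        if label not in reference:
            excluded.append(label)
            continue
        ph_pts: list[float] = []
        dd_pts: list[float] = []
        for pl in ordered:
            peak = pl.get(label)
            if peak is None:
                continue
            ph_pts.append(float(pl.condition.pH))  # type: ignore[arg-type]
            dd_pts.append(compute_csp(reference[label], peak).delta_NH)
        curves.append(
            TitrationCurve(
                label=label, pH=tuple(ph_pts), delta_NH=tuple(dd_pts), reference_pH=ref_ph
            )
        )
    return curves, excluded


def fit_cubic_pka(curve: TitrationCurve, a_tol: float = 1e-12) -> PkaFit:
    """Cubic-inflection pKa: fit y = a x^3 + b x^2 + c x + d, pKa = -b/(3a).

    The inflection is where the fitted second derivative vanishes. Requires
    >= 4 points and a non-flat curve; a leading coefficient within ``a_tol``
    of zero (after scale normalisation) has no usable inflection.
    """
    if curve.n_points < 4:
        raise ValueError(
            f"{curve.label.render()}: cubic fit needs >= 4 points, have {curve.n_points}"
        )
    if curve.is_flat():
        raise FlatCurveError(f"{curve.label.render()}: no titration (flat curve)")
    x = np.asarray(curve.pH)
    y = np.asarray(curve.delta_NH)
    # unweighted least squares in the monomial basis
    a, b, c, d = np.polyfit(x, y, 3)
    scale = max(abs(a), abs(b), abs(c), abs(d), 1.0)
    if abs(a) <= a_tol * scale:
        raise NoInflectionError(f"{curve.label.render()}: cubic has no inflection (a ~ 0)")
    pka = -b / (3.0 * a)
    fitted = np.polyval([a, b, c, d], x)
    rmse = float(np.sqrt(np.mean((fitted - y) ** 2)))
    in_range = bool(x.min() <= pka <= x.max())
    return PkaFit(
        label=curve.label,
        pka=float(pka),
        method="cubic-inflection",
        coefficients=(float(a), float(b), float(c), float(d)),
        rmse=rmse,
        in_range=in_range,
    )


def hh_model(ph: np.ndarray, pka: float, d_acid: float, amplitude: float) -> np.ndarray:
    """Single-site fast-exchange titration shift: d_acid + A/(1+10**(pKa-pH))."""
    return d_acid + amplitude / (1.0 + 10.0 ** (pka - ph))


def fit_hh_pka(curve: TitrationCurve, flat_tol: float = 1e-12) -> PkaFit:
    """Henderson–Hasselbalch pKa by nonlinear least squares."""
    if curve.n_points < 4:
        raise ValueError(
            f"{curve.label.render()}: HH fit needs >= 4 points, have {curve.n_points}"
        )
    if curve.is_flat(flat_tol):
        raise FlatCurveError(f"{curve.label.render()}: no titration (flat curve)")
    x = np.asarray(curve.pH)
    y = np.asarray(curve.delta_NH)
    # start at the midpoint of the observed transition
    amp0 = y[-1] - y[0] if abs(y[-1] - y[0]) > flat_tol else curve.span
    half = y[0] + amp0 / 2.0
    pka0 = float(x[np.argmin(np.abs(y - half))])
    try:
        popt, _ = curve_fit(
            hh_model,
            x,
            y,
            p0=(pka0, float(y[0]), float(amp0)),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise ValueError(f"{curve.label.render()}: HH fit did not converge ({exc})") from None
    pka, d_acid, amplitude = map(float, popt)
    fitted = hh_model(x, *popt)
    rmse = float(np.sqrt(np.mean((fitted - y) ** 2)))
    in_range = bool(x.min() <= pka <= x.max())
    return PkaFit(
        label=curve.label,
        pka=pka,
        method="henderson-hasselbalch",
        coefficients=(pka, d_acid, amplitude),
        rmse=rmse,
        in_range=in_range,
    )


def percent_of_max(curve: TitrationCurve) -> TitrationCurve:
    """Rescale a curve to percent of its maximum ddNH (max point = 100).

    Idempotent: applying it twice equals applying it once.
    """
    peak = max(curve.delta_NH)
    if peak <= 0:
        raise FlatCurveError(f"{curve.label.render()}: flat curve, cannot normalise")
    return TitrationCurve(
        label=curve.label,
        pH=curve.pH,
        delta_NH=tuple(100.0 * v / peak for v in curve.delta_NH),
        reference_pH=curve.reference_pH,
    )
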