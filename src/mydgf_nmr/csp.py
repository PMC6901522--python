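"""Chemical-shift-perturbation (CSP) analysis of 1H,15N HSQC peak lists.

The combined perturbation of a backbone amide between two conditions is

    ddNH = sqrt(ddH**2 + (ddN / 5)**2)        [ppm]

where ddH and ddN are the peak displacements in the 1H and 15N dimensions;
the factor 1/5 compensates the wider 15N shift dispersion. Spectra are first
aligned to a reference amide (W77 by default for hMYDGF) so that bulk
carrier/referencing offsets do not masquerade as perturbations.

Perturbations are discretised into ten bins whose common width is the Tukey
upper fence (Q3 + 1.5*IQR) of a replicate-pair ddNH distribution — the bin
boundary separating "within reproducibility" from genuine movement — with
the last bin open-topped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np

from .io_formats import (
    AssignmentLabel,
    Peak,
    PeakList,
    StructureEnsemble,
    write_ensemble,
)

__all__ = [
    "CspValue",
    "BinScheme",
    "CspMap",
    "NITROGEN_SCALE",
    "compute_csp",
    "align_to_reference",
    "bin_csp",
    "map_bins_to_structure",
    "compare_conditions",
]

#: Scale applied to the 15N displacement in the combined CSP.
NITROGEN_SCALE = 5.0

#: B-factor written for residues missing in at least one condition.
MISSING_BFACTOR = -1.0


@dataclass(frozen=True)
class CspValue:
    """Per-residue peak displacement between two conditions (ppm)."""

    label: AssignmentLabel
    delta_H: float
    delta_N: float

    @property
    def delta_NH(self) -> float:
        return math.sqrt(self.delta_H**2 + (self.delta_N / NITROGEN_SCALE) ** 2)


def compute_csp(a: Peak, b: Peak) -> CspValue:
    """Displacement of peak ``b`` relative to ``a`` (same assignment).

    Returns signed per-dimension displacements; the combined ``delta_NH``
    depends only on their magnitudes and is symmetric under argument swap.
    """
    if a.label != b.label:
        raise ValueError(
            f"assignment mismatch: {a.label.render()} vs {b.label.render()}"
        )
    return CspValue(a.label, delta_H=b.delta_H - a.delta_H, delta_N=b.delta_N - a.delta_N)


def align_to_reference(
    lists: Sequence[PeakList], reference: AssignmentLabel
) -> list[PeakList]:
    """Align spectra on a single reference amide peak.

    Each list is rigidly shifted (one constant ppm offset per dimension) so
    its reference peak coincides with the reference position in the first
    list. After alignment the reference CSP between any pair is exactly 0.
    """
    if not lists:
        raise ValueError("no peak lists to align")
    for pl in lists:
        if reference not in pl:
            raise ValueError(
                f"reference peak {reference.render()} missing from condition "
                f"{pl.condition.name!r}"
            )
    anchor = lists[0][reference]
    aligned = []
    for pl in lists:
        ref = pl[reference]
        shifted = pl.shifted(anchor.delta_H - ref.delta_H, anchor.delta_N - ref.delta_N)
        # pin the reference peak to the anchor exactly (no FP residue)
        peaks = [
            Peak(reference, anchor.delta_N, anchor.delta_H, ref.height)
            if p.label == reference
            else p
            for p in shifted
        ]
        aligned.append(PeakList(pl.condition, peaks))
    return aligned


@dataclass(frozen=True)
class BinScheme:
    """Equal-width CSP bins with an open-topped last bin.

    ``first_bound`` b is the upper edge of bin 1; bin k covers
    ((k-1)*b, k*b] for k < n_bins and bin n_bins covers ((n_bins-1)*b, inf).
    Zero falls in bin 1.
    """

    first_bound: float
    n_bins: int = 10
    quartile_method: str = "linear"

    def __post_init__(self) -> None:
        if self.first_bound <= 0:
            raise ValueError(
                "first bin bound is non-positive; supply an explicit bound "
                "(reference CSPs were all zero)"
            )
        if self.n_bins < 2:
            raise ValueError("need at least 2 bins")

    @property
    def bounds(self) -> np.ndarray:
        """Finite upper edges of bins 1 .. n_bins-1."""
        return self.first_bound * np.arange(1, self.n_bins)

    def bin_of(self, delta_nh: float) -> int:
        if delta_nh < 0:
            raise ValueError("delta_NH cannot be negative")
        if delta_nh == 0.0:
            return 1
        k = int(math.ceil(delta_nh / self.first_bound))
        return min(k, self.n_bins)

    @classmethod
    def from_reference(
        cls,
        reference_values: Iterable[CspValue | float],
        n_bins: int = 10,
        quartile_method: str = "linear",
    ) -> "BinScheme":
        """Tukey-fence bound from a replicate-pair ddNH distribution.

        b = Q3 + 1.5*IQR with quartiles computed by the given interpolation
        method (numpy ``percentile`` conventions; default ``linear`` = the
        common "type 7").
        """
        vals = np.asarray(
            [v.delta_NH if isinstance(v, CspValue) else float(v) for v in reference_values]
        )
        if vals.size == 0:
            raise ValueError("empty reference distribution")
        q1, q3 = np.percentile(vals, [25, 75], method=quartile_method)
        bound = q3 + 1.5 * (q3 - q1)
        return cls(first_bound=float(bound), n_bins=n_bins, quartile_method=quartile_method)


@dataclass
class CspMap:
    """Per-residue bin assignment plus the residues missing an assignment."""

    bins: dict[int, int]  # residue number -> bin index (1..n_bins)
    missing: set[int]
    scheme: BinScheme
    provenance: str = ""

    def color_table(self) -> list[tuple[int, int, str]]:
        """(residue, bin, colour) rows; gray->green ramp, missing = black."""
        rows = []
        for res in sorted(self.bins):
            k = self.bins[res]
            frac = (k - 1) / max(self.scheme.n_bins - 1, 1)
            # ramp from gray (190,190,190) to dark green (0,100,0)
            r = round(190 * (1 - frac))
            g = round(190 + (100 - 190) * frac)
            b = round(190 * (1 - frac))
            rows.append((res, k, f"#{r:02x}{g:02x}{b:02x}"))
        for res in sorted(self.missing):
            rows.append((res, 0, "#000000"))
        rows.sort(key=lambda t: t[0])
        return rows


def bin_csp(
    values: Iterable[CspValue],
    reference_values: Iterable[CspValue | float] | None = None,
    n_bins: int = 10,
    first_bound: float | None = None,
    missing: Iterable[int] = (),
    quartile_method: str = "linear",
    provenance: str = "",
) -> tuple[BinScheme, CspMap]:
    """Bin per-residue CSPs on the Tukey-fence scheme.

    Either ``reference_values`` (replicate-pair CSPs from which the fence is
    computed) or an explicit ``first_bound`` must be given.
    """
    if first_bound is not None:
        scheme = BinScheme(first_bound=first_bound, n_bins=n_bins)
    elif reference_values is not None:
        scheme = BinScheme.from_reference(
            reference_values, n_bins=n_bins, quartile_method=quartile_method
        )
    else:
        raise ValueError("provide reference_values or an explicit first_bound")
    bins = {v.label.residue_number: scheme.bin_of(v.delta_NH) for v in values}
    return scheme, CspMap(
        bins=bins, missing=set(missing) - set(bins), scheme=scheme, provenance=provenance
    )


def map_bins_to_structure(
    csp_map: CspMap, ensemble: StructureEnsemble, pdb_dest: TextIO, table_dest: TextIO
) -> None:
    """Paint CSP bins onto a structure.

    Writes a PDB copy with the bin index in the B-factor column (missing
    residues get the sentinel -1) and a per-residue colour table.
    """
    structure_residues = {a.residue_number for a in ensemble.atoms}
    mapped = set(csp_map.bins) | csp_map.missing
    if not (structure_residues & mapped):
        raise ValueError("no residue overlap between CSP map and structure")
    b_factors: dict[int, float] = {res: float(k) for res, k in csp_map.bins.items()}
    b_factors.update({res: MISSING_BFACTOR for res in csp_map.missing})
    write_ensemble(ensemble, pdb_dest, b_factors=b_factors, default_b=0.0)
    table_dest.write("residue\tbin\tcolor\n")
    for res, k, colour in csp_map.color_table():
        table_dest.write(f"{res}\t{k}\t{colour}\n")


@dataclass
class PerturbationReport:
    """Outcome of comparing two aligned spectra against a ddNH threshold."""

    values: dict[AssignmentLabel, CspValue]
    threshold: float
    exceeding: list[AssignmentLabel]

    @property
    def max_delta_NH(self) -> float:
        return max(v.delta_NH for v in self.values.values())

    @property
    def unperturbed(self) -> bool:
        return not self.exceeding

    @property
    def verdict(self) -> str:
        return "unperturbed" if self.unperturbed else "perturbed"


def compare_conditions(
    a: PeakList, b: PeakList, threshold: float = 0.02
) -> PerturbationReport:
    """Per-residue ddNH between two aligned spectra, with a verdict.

    The verdict is "unperturbed" iff every common residue's ddNH is below
    ``threshold`` (ppm); otherwise exceeding residues are listed.
    """
    common = sorted(a.common_labels(b))
    if not common:
        raise ValueError("no common assignments between the two conditions")
    values = {lab: compute_csp(a[lab], b[lab]) for lab in common}
    exceeding = [lab for lab in common if values[lab].delta_NH >= threshold]
    return PerturbationReport(values=values, threshold=threshold, exceeding=exceeding)
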