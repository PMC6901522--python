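"""Ensemble statistics and structure-derived quantities.

Kabsch least-squares superposition, pairwise ensemble RMSD against the
lowest-energy conformer over ordered residues, NOE-restraint range
classification (short |i-j| <= 1, medium 1 < |i-j| <= 5, long |i-j| > 5),
5-Å interface enumeration between docked partners, and sequence-derived
mass / extinction-coefficient / Beer's-law utilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Data.IUPACData import protein_letters
from Bio.SeqUtils import molecular_weight
from scipy.spatial import cKDTree

from .io_formats import RestraintRecord, StructureEnsemble

__all__ = [
    "BACKBONE_ATOMS",
    "ORDERED_REGIONS_HMYDGF",
    "RegionSet",
    "SuperpositionResult",
    "RestraintClassCounts",
    "SequenceProps",
    "kabsch_superpose",
    "ensemble_rmsd",
    "classify_restraints",
    "interface_residues",
    "sequence_props",
]

#: Backbone heavy atoms used for superposition (carbonyl O optional).
BACKBONE_ATOMS = ("N", "CA", "C")

#: Ordered residues of hMYDGF (CYRANGE definition): P35-A126 and D133-A168.
ORDERED_REGIONS_HMYDGF = ((35, 126), (133, 168))


@dataclass(frozen=True)
class RegionSet:
    """Ordered-residue ranges plus the atom selection used for RMSD."""

    ranges: tuple[tuple[int, int], ...] = ORDERED_REGIONS_HMYDGF
    atom_selection: str = "backbone"  # "backbone" | "heavy"
    include_carbonyl_o: bool = False

    def __post_init__(self) -> None:
        prev_hi = 0
        for lo, hi in self.ranges:
            if hi < lo or lo <= prev_hi:
                raise ValueError("ranges must be ascending and non-overlapping")
            prev_hi = hi
        if self.atom_selection not in ("backbone", "heavy"):
            raise ValueError(f"unknown atom selection {self.atom_selection!r}")

    @property
    def residues(self) -> set[int]:
        out: set[int] = set()
        for lo, hi in self.ranges:
            out.update(range(lo, hi + 1))
        return out

    def mask(self, ensemble: StructureEnsemble) -> np.ndarray:
        if self.atom_selection == "backbone":
            names = BACKBONE_ATOMS + (("O",) if self.include_carbonyl_o else ())
            return ensemble.atom_mask(residues=self.residues, atom_names=names)
        return ensemble.atom_mask(residues=self.residues, heavy_only=True)


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid motion of mobile onto target and the residual RMSD."""

    rotation: np.ndarray  # (3, 3), proper orthogonal
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Classic SVD solution over centred coordinates with the reflection
    corrected to a proper rotation (det = +1); the returned RMSD is the
    minimum over all rigid motions.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and target must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs >= 3 points")
    mob_c = mobile.mean(axis=0)
    tar_c = target.mean(axis=0)
    p = mobile - mob_c
    q = target - tar_c
    if np.linalg.matrix_rank(p) < 2 or np.linalg.matrix_rank(q) < 2:
        raise ValueError("degenerate (collinear) geometry")
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = tar_c - rot @ mob_c
    moved = p @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def ensemble_rmsd(
    ensemble: StructureEnsemble, region: RegionSet
) -> tuple[float, float, np.ndarray]:
    """Average pairwise RMSD of models 2..N against model 1.

    Each model is superposed onto model 1 over the selected atoms of the
    ordered region and the RMSD evaluated on those atoms. Returns
    (mean, sd, per-model RMSDs for models 2..N); sd is the sample standard
    deviation (ddof=1) when more than one comparison exists.
    """
    if ensemble.n_models < 2:
        raise ValueError("ensemble RMSD needs >= 2 models")
    mask = region.mask(ensemble)
    if not mask.any():
        raise ValueError("region selects no atoms in the ensemble")
    reference = ensemble.coords[0][mask]
    values = np.array(
        [
            kabsch_superpose(ensemble.coords[k][mask], reference).rmsd
            for k in range(1, ensemble.n_models)
        ]
    )
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return float(values.mean()), sd, values


@dataclass(frozen=True)
class RestraintClassCounts:
    """Restraint totals by sequence separation."""

    short: int
    medium: int
    long: int

    @property
    def total(self) -> int:
        return self.short + self.medium + self.long


def classify_restraints(restraints: Iterable[RestraintRecord]) -> RestraintClassCounts:
    """Count restraints by |i-j|: short <= 1, medium in (1, 5], long > 5.

    Raw-record convention: every record counts exactly once.
    """
    short = medium = long_ = 0
    for r in restraints:
        sep = r.sequence_separation
        if sep <= 1:
            short += 1
        elif sep <= 5:
            medium += 1
        else:
            long_ += 1
    return RestraintClassCounts(short=short, medium=medium, long=long_)


def interface_residues(
    a: StructureEnsemble,
    b: StructureEnsemble,
    cutoff: float = 5.0,
    model_a: int = 0,
    model_b: int = 0,
) -> set[int]:
    """Residues of ``a`` with any heavy atom within ``cutoff`` Å of ``b``.

    Hydrogens are excluded on both sides. Uses a k-d tree over the partner
    atoms; equivalent to the all-pairs scan.
    """
    mask_a = a.atom_mask(heavy_only=True)
    mask_b = b.atom_mask(heavy_only=True)
    if not mask_a.any() or not mask_b.any():
        return set()
    coords_a = a.coords[model_a][mask_a]
    coords_b = b.coords[model_b][mask_b]
    residues_a = np.array([atom.residue_number for atom in a.atoms])[mask_a]
    tree = cKDTree(coords_b)
    dists, _ = tree.query(coords_a, k=1)
    return set(residues_a[dists <= cutoff].tolist())


# --------------------------------------------------------------------------
# sequence-derived properties
# --------------------------------------------------------------------------

_H_AVG = 1.00794  # average H atom mass, Da
_H_MONO = 1.0078250319

# ProtParam extinction coefficients at 280 nm (M^-1 cm^-1)
_EPS_TRP = 5500
_EPS_TYR = 1490
_EPS_CYSTINE = 125


@dataclass(frozen=True)
class SequenceProps:
    """Mass and absorbance properties of a protein sequence."""

    sequence: str
    n_disulfides: int
    average_mass_da: float
    monoisotopic_mass_da: float
    extinction_280: float

    @property
    def average_mass_kda(self) -> float:
        return self.average_mass_da / 1000.0

    def concentration(self, a280: float, pathlength_cm: float = 1.0) -> float:
        """Beer's-law concentration in M: c = A / (eps * l)."""
        if self.extinction_280 <= 0:
            raise ValueError("extinction coefficient is zero; cannot invert Beer's law")
        if pathlength_cm <= 0:
            raise ValueError("pathlength must be positive")
        return a280 / (self.extinction_280 * pathlength_cm)


def sequence_props(sequence: str, n_disulfides: int = 0) -> SequenceProps:
    """Masses and the 280-nm extinction coefficient of a protein sequence.

    Masses are residue-table sums plus one water, minus two hydrogen atoms
    per disulfide. Extinction follows the ProtParam rule
    eps = 5500*nW + 1490*nY + 125*n_cystine.
    """
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    for pos, letter in enumerate(seq, start=1):
        if letter not in protein_letters:
            raise ValueError(f"unknown residue {letter!r} at position {pos}")
    if 2 * n_disulfides > seq.count("C"):
        raise ValueError(
            f"{n_disulfides} disulfides need {2 * n_disulfides} cysteines, "
            f"sequence has {seq.count('C')}"
        )
    avg = molecular_weight(seq, seq_type="protein") - 2 * _H_AVG * n_disulfides
    mono = (
        molecular_weight(seq, seq_type="protein", monoisotopic=True)
        - 2 * _H_MONO * n_disulfides
    )
    eps = _EPS_TRP * seq.count("W") + _EPS_TYR * seq.count("Y") + _EPS_CYSTINE * n_disulfides
    return SequenceProps(
        sequence=seq,
        n_disulfides=n_disulfides,
        average_mass_da=float(avg),
        monoisotopic_mass_da=float(mono),
        extinction_280=float(eps),
    )
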