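"""Seeded synthetic-data generators for every pipeline stage.

Each generator is a pure function of its scenario (including the seed) and
emits machine-readable ground truth alongside the data, so parameter
recovery can be scored closed-loop: titrating HSQC peak lists with known
per-residue pKa, single-exponential decay series with known time constants,
Gaussian-jittered coordinate ensembles with computable expected RMSD,
restraint sets with requested range-class counts, and unimodal emission
spectra with known peak centres.

Defaults reproduce the hMYDGF study conditions: the usable pH grid
{5.5, 6.0, 6.25, 6.5, 7.0, 7.4, 8.0} (the pH 4.0 sample precipitated; 7.4
comes from the calcium-study buffer), the T2 delay grid 10–210 ms and T1
grid 80–2000 ms, shift noise of 0.005 ppm (about the digital resolution of
an HSQC), and amplitude scales resembling histidine titration excursions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import (
    AssignmentLabel,
    AtomRecord,
    Condition,
    Peak,
    PeakList,
    RestraintRecord,
    StructureEnsemble,
    XYSpectrum,
)
from .relaxation import T2_DELAYS_MS, DecaySeries
from .titration import hh_model

__all__ = [
    "STUDY_PH_GRID",
    "TitrationResidue",
    "TitrationScenario",
    "DecayScenario",
    "EnsembleScenario",
    "make_titration_dataset",
    "make_decay_dataset",
    "make_ensemble",
    "make_base_coordinates",
    "make_restraint_set",
    "make_emission_spectrum",
    "default_titration_scenario",
]

#: pH conditions with usable HSQC spectra in the study.
STUDY_PH_GRID = (5.5, 6.0, 6.25, 6.5, 7.0, 7.4, 8.0)

#: Emission grid of the fluorescence scans: 305-400 nm in 0.5 nm steps.
EMISSION_GRID_NM = tuple(np.arange(305.0, 400.0 + 0.25, 0.5))


# --------------------------------------------------------------------------
# titration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TitrationResidue:
    """Ground truth for one residue: pKa None means pH-insensitive."""

    label: AssignmentLabel
    pka: float | None
    amp_h: float  # full 1H titration amplitude, ppm
    amp_n: float  # full 15N titration amplitude, ppm
    acid_delta_H: float = 8.2  # acid-limit shifts
    acid_delta_N: float = 120.0


@dataclass(frozen=True)
class TitrationScenario:
    residues: tuple[TitrationResidue, ...]
    ph_grid: tuple[float, ...] = STUDY_PH_GRID
    noise_sd: float = 0.005  # ppm, additive, per dimension per condition
    seed: int = 0


def make_titration_dataset(scenario: TitrationScenario) -> list[PeakList]:
    """One peak list per pH following the single-site titration model.

    delta(pH) = delta_acid + amplitude / (1 + 10**(pKa - pH)) per dimension,
    plus independent additive Gaussian noise; flat residues keep their
    acid-limit position at every pH (up to noise). Deterministic in the
    scenario seed.
    """
    rng = np.random.default_rng(scenario.seed)
    lists = []
    for ph in scenario.ph_grid:
        peaks = []
        for res in scenario.residues:
            if res.pka is None:
                d_h, d_n = res.acid_delta_H, res.acid_delta_N
            else:
                d_h = float(hh_model(np.array([ph]), res.pka, res.acid_delta_H, res.amp_h)[0])
                d_n = float(hh_model(np.array([ph]), res.pka, res.acid_delta_N, res.amp_n)[0])
            noise_h, noise_n = rng.normal(0.0, scenario.noise_sd, size=2) if scenario.noise_sd > 0 else (0.0, 0.0)
            peaks.append(Peak(res.label, delta_N=d_n + noise_n, delta_H=d_h + noise_h))
        lists.append(PeakList(Condition(name=f"pH {ph:g}", pH=ph), peaks))
    return lists


def default_titration_scenario(
    n_residues: int = 30,
    seed: int = 0,
    noise_sd: float = 0.005,
    pka_range: tuple[float, float] = (5.8, 7.0),
    flat_fraction: float = 0.2,
) -> TitrationScenario:
    """A mixed scenario: titrating residues plus a pH-insensitive subset.

    Titrating amplitudes are drawn up to 0.12 ppm (1H) / 0.6 ppm (15N), the
    scale of histidine-neighbourhood excursions in the study spectra.
    """
    rng = np.random.default_rng(seed)
    residues = []
    n_flat = int(round(flat_fraction * n_residues))
    for i in range(n_residues):
        label = AssignmentLabel("A", i + 30, ("N", "H"))
        flat = i < n_flat
        residues.append(
            TitrationResidue(
                label=label,
                pka=None if flat else float(rng.uniform(*pka_range)),
                amp_h=float(rng.uniform(0.04, 0.12)),
                amp_n=float(rng.uniform(0.2, 0.6)),
                acid_delta_H=float(rng.uniform(7.5, 9.5)),
                acid_delta_N=float(rng.uniform(110.0, 130.0)),
            )
        )
    return TitrationScenario(
        residues=tuple(residues), noise_sd=noise_sd, seed=seed + 1
    )


# --------------------------------------------------------------------------
# relaxation decays
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DecayScenario:
    """Per-residue true time constants on a delay grid, with noise."""

    true_T_ms: tuple[float, ...]
    delays_ms: tuple[float, ...] = T2_DELAYS_MS
    noise_sd: float = 0.02  # multiplicative Gaussian sd
    I0: float = 100.0
    experiment: str = "T2"
    seed: int = 0


def make_decay_dataset(scenario: DecayScenario) -> list[DecaySeries]:
    """I(t) = I0 * exp(-t/T) * (1 + eps), eps ~ N(0, noise_sd)."""
    rng = np.random.default_rng(scenario.seed)
    t = np.asarray(scenario.delays_ms, dtype=float)
    out = []
    for i, T in enumerate(scenario.true_T_ms):
        clean = scenario.I0 * np.exp(-t / T)
        noisy = clean * (1.0 + rng.normal(0.0, scenario.noise_sd, size=t.shape)) if scenario.noise_sd > 0 else clean
        out.append(
            DecaySeries(
                label=AssignmentLabel("A", i + 30, ("N", "H")),
                delays_ms=tuple(t),
                intensities=tuple(noisy),
                experiment=scenario.experiment,
            )
        )
    return out


# --------------------------------------------------------------------------
# coordinate ensembles
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EnsembleScenario:
    """Jittered copies of a base structure; model 1 is the unjittered base.

    Expected per-atom displacement gives a pre-superposition RMSD of
    jitter_sd * sqrt(3).
    """

    base_atoms: tuple[AtomRecord, ...]
    base_coords: np.ndarray  # (n_atoms, 3)
    n_models: int = 20
    jitter_sd: float = 0.5  # Å, i.i.d. per coordinate
    seed: int = 0

    @property
    def expected_rmsd(self) -> float:
        return self.jitter_sd * np.sqrt(3.0)


def make_base_coordinates(
    n_residues: int = 125, atoms_per_residue: int = 4, seed: int = 0, extent: float = 20.0
) -> tuple[tuple[AtomRecord, ...], np.ndarray]:
    """A random compact protein-like point cloud with backbone atom names.

    Residues are numbered from 30 (matching the mature-protein numbering
    convention); each carries N, CA, C and O pseudo-atoms.
    """
    rng = np.random.default_rng(seed)
    names = ("N", "CA", "C", "O", "CB", "CG")[:atoms_per_residue]
    atoms = []
    for res in range(30, 30 + n_residues):
        for name in names:
            atoms.append(
                AtomRecord(
                    chain="A",
                    residue_number=res,
                    residue_type="ALA",
                    atom_name=name,
                    element=name[0],
                )
            )
    coords = rng.uniform(-extent, extent, size=(len(atoms), 3))
    return tuple(atoms), coords


def make_ensemble(scenario: EnsembleScenario) -> StructureEnsemble:
    """Model 1 = base; models 2..N add i.i.d. Gaussian coordinate jitter."""
    rng = np.random.default_rng(scenario.seed)
    base = np.asarray(scenario.base_coords, dtype=float)
    models = [base]
    for _ in range(scenario.n_models - 1):
        models.append(base + rng.normal(0.0, scenario.jitter_sd, size=base.shape))
    return StructureEnsemble(list(scenario.base_atoms), np.stack(models))


# --------------------------------------------------------------------------
# restraints
# --------------------------------------------------------------------------


def make_restraint_set(
    n_short: int,
    n_medium: int,
    n_long: int,
    n_residues: int = 142,
    first_residue: int = 32,
    seed: int = 0,
) -> list[RestraintRecord]:
    """Random restraints whose range-class counts are exactly as requested.

    Sequence separations are drawn inside each class: short |i-j| <= 1,
    medium 2..5, long > 5 (capped by the chain length).
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    last = first_residue + n_residues - 1
    max_sep = n_residues - 1
    if n_medium > 0 and max_sep < 2:
        raise ValueError("chain too short for medium-range restraints")
    if n_long > 0 and max_sep < 6:
        raise ValueError("chain too short for long-range restraints")
    rng = np.random.default_rng(seed)
    records = []
    specs = [
        (n_short, 0, min(1, max_sep)),
        (n_medium, 2, min(5, max_sep)),
        (n_long, 6, max_sep),
    ]
    for count, sep_lo, sep_hi in specs:
        for _ in range(count):
            sep = int(rng.integers(sep_lo, sep_hi + 1))
            i = int(rng.integers(first_residue, last - sep + 1))
            records.append(
                RestraintRecord(
                    res_i=i,
                    atom_i="HA",
                    res_j=i + sep,
                    atom_j="HN" if sep else "HB",
                    upper_bound=float(rng.uniform(2.5, 6.0)),
                    resname_i="ALA",
                    resname_j="ALA",
                )
            )
    return records


# --------------------------------------------------------------------------
# emission spectra
# --------------------------------------------------------------------------


def make_emission_spectrum(
    center_nm: float,
    width_nm: float = 25.0,
    noise_frac: float = 0.0,
    grid_nm: Sequence[float] = EMISSION_GRID_NM,
    amplitude: float = 1000.0,
    seed: int = 0,
) -> XYSpectrum:
    """A Gaussian-shaped emission peak plus multiplicative noise.

    ``noise_frac`` is the noise sd as a fraction of the amplitude. The true
    centre must lie inside the grid.
    """
    x = np.asarray(grid_nm, dtype=float)
    if not (x.min() <= center_nm <= x.max()):
        raise ValueError(f"peak centre {center_nm} nm outside grid {x.min()}-{x.max()} nm")
    rng = np.random.default_rng(seed)
    y = amplitude * np.exp(-0.5 * ((x - center_nm) / width_nm) ** 2)
    if noise_frac > 0:
        y = y + rng.normal(0.0, noise_frac * amplitude, size=x.shape)
    return XYSpectrum(x, y, {"true_center_nm": center_nm, "seed": seed})
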